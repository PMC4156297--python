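import numpy as np
import pytest

from phylodiscord.alignment import Alignment, TaxonInfo
from phylodiscord.coalescent import LocusConfig
from phylodiscord.models import SubstitutionModel
from phylodiscord.synthetic import ScenarioConfig, generate_scenario


def small_loci():
    """Two short loci with the nuclear/plastid rate+heredity contrast,
    sized for fast tests."""
    its = LocusConfig(
        model=SubstitutionModel.sym(rates=(1, 3, 1, 1, 3, 1), alpha=0.5),
        length=160,
        mu_rel=1.016,
        heredity=2.0,
    )
    cp = LocusConfig(
        model=SubstitutionModel.hky85(
            kappa=2.0, freqs=(0.3, 0.2, 0.2, 0.3), alpha=0.5, p_inv=0.3
        ),
        length=200,
        mu_rel=0.385,
        heredity=1.0,
    )
    return [("ITS", its), ("cpDNA", cp)]


@pytest.fixture(scope="session")
def small_bundle():
    """A compact synthetic two-locus study used across test modules."""
    cfg = ScenarioConfig(
        n_species=4,
        samples_per_species=3,
        loci=small_loci(),
        homogenization=0.3,
        seed=7,
    )
    return generate_scenario(cfg)


@pytest.fixture()
def toy_alignment():
    return Alignment(
        [
            ("a", "ACGTACGT"),
            ("b", "ACGTACGA"),
            ("c", "ACGTTCGT"),
            ("d", "ACGTTCGA"),
        ],
        partitions={"left": (0, 4), "right": (4, 8)},
        taxon_map={
            "a": TaxonInfo("spA"),
            "b": TaxonInfo("spA"),
            "c": TaxonInfo("spB"),
            "d": TaxonInfo("out", ingroup=False),
        },
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
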