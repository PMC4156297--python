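"""Synthetic multi-locus studies with known truth.

Generates the data shape the pipeline is designed for: a small rooted
species tree with per-branch population sizes and a divergent outgroup,
two loci with different relative rates and heredity scalars (an ITS-like
biparental nuclear marker and a cpDNA-like maternally inherited plastid
marker), gene-tree discordance from incomplete lineage sorting, optional
recent hybridization pulses, and intra-individual ribotype mixing that
produces IUPAC ambiguity codes with tunable concerted-evolution
homogenization.

For the nuclear locus every individual carries two gene copies
(ribotypes); the individual's reported sequence is the site-wise mixture
of the two, written as an ambiguity code where they differ unless
homogenization (probability ``c`` per differing site) erases the
additivity.  The plastid locus is haploid: one copy per individual.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import iupac
from .alignment import Alignment, TaxonInfo, write_alignment, write_taxon_map
from .coalescent import (
    LocusConfig,
    SpeciesTreeSample,
    simulate_alignment,
    simulate_gene_tree,
)
from .models import SubstitutionModel
from .trees import Node, write_newick

__all__ = [
    "ScenarioConfig",
    "TruthBundle",
    "default_loci",
    "generate_scenario",
    "make_pseudo_posterior",
    "apply_ribotype_mixing",
    "make_planted_alignment",
]


def default_loci() -> list[tuple[str, LocusConfig]]:
    """The two default loci: an ITS-like and a cpDNA-like marker.

    Rates and heredity scalars follow the nuclear/plastid convention
    (relative rates 1.016 and 0.385; heredity scalars 2 and 1); lengths
    653 and 960 sites.  Model parameters are chosen as typical for such
    markers: a transition-rich symmetric model with strong rate
    heterogeneity for ITS, an AT-rich transversion model with invariant
    sites for the plastid spacer.
    """
    its = LocusConfig(
        model=SubstitutionModel.sym(
            rates=(1.0, 3.0, 1.0, 1.0, 3.0, 1.0), alpha=0.3
        ),
        length=653,
        mu_rel=1.016,
        heredity=2.0,
    )
    cp = LocusConfig(
        model=SubstitutionModel.tvm(
            rates=(1.0, 0.8, 1.2, 1.0, 3.0),
            freqs=(0.33, 0.17, 0.17, 0.33),
            alpha=0.5,
            p_inv=0.4,
        ),
        length=960,
        mu_rel=0.385,
        heredity=1.0,
    )
    return [("ITS", its), ("cpDNA", cp)]


@dataclass
class ScenarioConfig:
    """Study-design parameters for one synthetic scenario.

    Defaults mirror the shape of the motivating study: a handful of
    closely related ingroup species, uneven sampling, two loci with the
    nuclear/plastid rate and heredity contrasts, and a divergent
    outgroup.
    """

    n_species: int = 5
    birth_rate: float = 80.0  # speciations per substitution/site of depth
    theta_range: tuple[float, float] = (0.002, 0.006)
    loci: list = field(default_factory=default_loci)
    samples_per_species: int | dict = 4
    hybridization: list = field(default_factory=list)
    homogenization: float = 0.5
    outgroup_stem: float = 0.08
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.homogenization <= 1.0:
            raise ValueError("homogenization must be in [0, 1]")
        if self.n_species < 1:
            raise ValueError("need at least one species")


@dataclass
class TruthBundle:
    """A generated study plus the truth needed to score every stage."""

    species_tree: SpeciesTreeSample
    gene_trees: dict[str, list[Node]]
    alignments: dict[str, Alignment]
    species_map: dict[str, str]
    taxon_map: dict[str, TaxonInfo]
    hybrid_individuals: list[str]
    mixed_individuals: dict[str, tuple[str, str]]  # label -> parental ribotypes
    config: ScenarioConfig

    def write(self, outdir: str) -> None:
        import os

        os.makedirs(outdir, exist_ok=True)
        for name, aln in self.alignments.items():
            write_alignment(aln, os.path.join(outdir, f"{name}.fasta"))
        with open(os.path.join(outdir, "species_tree.nwk"), "w") as fh:
            fh.write(write_newick(self.species_tree.tree, metadata=True) + "\n")
        for name, gts in self.gene_trees.items():
            with open(os.path.join(outdir, f"gene_trees_{name}.nwk"), "w") as fh:
                for gt in gts:
                    fh.write(write_newick(gt) + "\n")
        write_taxon_map(self.taxon_map, os.path.join(outdir, "taxon_map.tsv"))
        manifest = {
            "seed": self.config.seed,
            "n_species": self.config.n_species,
            "homogenization": self.config.homogenization,
            "hybrid_individuals": self.hybrid_individuals,
            "mixed_individuals": {
                k: list(v) for k, v in self.mixed_individuals.items()
            },
            "loci": {
                name: {"length": a.length, "n": a.n} for name, a in self.alignments.items()
            },
        }
        with open(os.path.join(outdir, "truth.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


def _yule_like_tree(n: int, birth_rate: float, rng) -> Node:
    """Random-join pure-birth-style ultrametric tree with n labelled tips."""
    tips = [Node(f"sp{i + 1}") for i in range(n)]
    for t in tips:
        t.height = 0.0
    height = 0.0
    lineages = list(tips)
    while len(lineages) > 1:
        k = len(lineages)
        height += rng.exponential(1.0 / (birth_rate * k))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        a, b = lineages[i], lineages[j]
        parent = Node()
        parent.height = height
        parent.add(a)
        parent.add(b)
        lineages = [x for x in lineages if x is not a and x is not b] + [parent]
    return lineages[0]


def _set_lengths_from_heights(root: Node) -> None:
    for node in root.preorder():
        if node.parent is not None:
            node.length = node.parent.height - node.height
        else:
            node.length = None


def apply_ribotype_mixing(
    ribotype_a: str, ribotype_b: str, c: float, rng=None, seed: int | None = None
) -> str:
    """Merge two ribotypes into one IUPAC-coded consensus sequence.

    At each site where the ribotypes differ, with probability ``c``
    (concerted-evolution homogenization) the site collapses to one parent
    chosen uniformly; otherwise it is written as the ambiguity code of
    the two bases.  Identical sites are copied through.
    """
    if not 0.0 <= c <= 1.0:
        raise ValueError("c must be in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(seed)
    a = iupac.encode(ribotype_a)
    b = iupac.encode(ribotype_b)
    if a.size != b.size:
        raise ValueError("ribotypes must have equal length")
    out = a.copy()
    diff = np.nonzero(a != b)[0]
    for j in diff:
        if rng.random() < c:
            out[j] = a[j] if rng.random() < 0.5 else b[j]
        else:
            out[j] = a[j] | b[j]
    return iupac.decode(out)


def generate_scenario(cfg: ScenarioConfig) -> TruthBundle:
    """Generate a complete synthetic study (deterministic under the seed).

    The ingroup species tree is drawn from a pure-birth process, a
    divergent outgroup species is attached above its root, per-branch θ
    values are drawn uniformly from ``theta_range``, gene trees are
    simulated under the multispecies coalescent with any configured
    hybridization pulses, and sequences are evolved per locus.  Nuclear
    loci (heredity 2) sample two gene copies per individual and mix them
    into one IUPAC-coded sequence under the homogenization probability.
    """
    rng = np.random.default_rng(cfg.seed)
    ingroup = _yule_like_tree(cfg.n_species, cfg.birth_rate, rng)
    root = Node()
    root.height = ingroup.height + cfg.outgroup_stem
    outg = Node("outgroup")
    outg.height = 0.0
    root.add(ingroup)
    root.add(outg)
    for node in root.preorder():
        node.theta = float(rng.uniform(*cfg.theta_range))
    _set_lengths_from_heights(root)
    species_tree = SpeciesTreeSample(tree=root)

    species = [n.label for n in root.leaves()]
    if isinstance(cfg.samples_per_species, dict):
        n_samples = {sp: cfg.samples_per_species.get(sp, 1) for sp in species}
    else:
        n_samples = {sp: int(cfg.samples_per_species) for sp in species}
        n_samples["outgroup"] = min(n_samples["outgroup"], 2)
    individuals = [
        f"{sp}_i{k + 1}" for sp in species for k in range(n_samples[sp])
    ]
    species_map = {lab: lab.rsplit("_i", 1)[0] for lab in individuals}
    taxon_map = {
        lab: TaxonInfo(taxon=sp, population=lab, ingroup=sp != "outgroup")
        for lab, sp in species_map.items()
    }

    for ev in cfg.hybridization:
        if ev.time >= root.height:
            raise ValueError(
                f"hybridization time {ev.time} not within tree height {root.height}"
            )

    gene_trees: dict[str, list[Node]] = {}
    alignments: dict[str, Alignment] = {}
    mixed: dict[str, tuple[str, str]] = {}
    hybrid_individuals: set[str] = set()

    for locus_name, locus in cfg.loci:
        diploid = locus.heredity >= 2.0
        copies = 2 if diploid else 1
        sampling = {
            sp: [
                f"{sp}_i{k + 1}{{{cpy}}}" if diploid else f"{sp}_i{k + 1}"
                for k in range(n_samples[sp])
                for cpy in (range(copies) if diploid else [0])
            ]
            for sp in species
        }
        gt = simulate_gene_tree(
            species_tree,
            sampling,
            heredity=locus.heredity,
            hybridization=list(cfg.hybridization) or None,
            rng=rng,
        )
        gene_trees[locus_name] = [gt]
        raw = simulate_alignment(gt, locus.model, locus.length, mu_rel=locus.mu_rel, rng=rng)
        if diploid:
            entries = []
            for lab in individuals:
                r0 = raw.sequence(f"{lab}{{0}}")
                r1 = raw.sequence(f"{lab}{{1}}")
                seq = apply_ribotype_mixing(r0, r1, cfg.homogenization, rng=rng)
                if r0 != r1:
                    mixed[lab] = (r0, r1)
                entries.append((lab, seq))
            aln = Alignment(entries, partitions={locus_name: (0, locus.length)},
                            taxon_map=taxon_map)
        else:
            aln = Alignment(
                [(lab, raw.sequence(lab)) for lab in individuals],
                partitions={locus_name: (0, locus.length)},
                taxon_map=taxon_map,
            )
        alignments[locus_name] = aln

        if cfg.hybridization:
            # truth labels: individuals of recipient species whose lineages
            # could have moved — recorded at species resolution
            for ev in cfg.hybridization:
                if ev.gamma > 0:
                    hybrid_individuals.update(
                        lab for lab, sp in species_map.items() if sp == ev.recipient
                    )

    return TruthBundle(
        species_tree=species_tree,
        gene_trees=gene_trees,
        alignments=alignments,
        species_map=species_map,
        taxon_map=taxon_map,
        hybrid_individuals=sorted(hybrid_individuals),
        mixed_individuals=mixed,
        config=cfg,
    )


def make_pseudo_posterior(
    truth: SpeciesTreeSample,
    n_samples: int,
    jitter: float = 0.1,
    seed: int | None = None,
) -> list[SpeciesTreeSample]:
    """A posterior stand-in: copies of the truth with multiplicative
    lognormal noise (mean 1, relative sd ``jitter``) on the height scale
    (one factor per sample, preserving ultrametricity) and on each
    branch's θ independently.  ``jitter=0`` returns exact copies."""
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(jitter**2)))
    out = []
    for _ in range(n_samples):
        tree = truth.tree.copy()
        f = float(rng.lognormal(-sigma**2 / 2, sigma)) if jitter else 1.0
        for node in tree.preorder():
            node.height = node.height * f
            if jitter:
                node.theta = float(
                    node.theta * rng.lognormal(-sigma**2 / 2, sigma)
                )
        _set_lengths_from_heights(tree)
        out.append(SpeciesTreeSample(tree=tree))
    return out


def make_planted_alignment(
    n_ingroup: int = 6,
    n_outgroup: int = 4,
    k_diagnostic: int = 5,
    length: int = 60,
    seed: int = 0,
) -> tuple[Alignment, list[int]]:
    """Alignment with ``k`` planted clade-diagnostic (symmetric) columns.

    Diagnostic columns fix the ingroup for one state and the outgroup for
    another; the remaining columns are constant across everyone.  Returns
    the alignment and the planted column indices.
    """
    rng = np.random.default_rng(seed)
    cols = np.full((length, n_ingroup + n_outgroup), "A", dtype="<U1")
    planted = sorted(rng.choice(length, size=k_diagnostic, replace=False).tolist())
    for j in planted:
        cols[j, :n_ingroup] = "C"
        cols[j, n_ingroup:] = "T"
    labels = [f"in{i+1}" for i in range(n_ingroup)] + [
        f"out{i+1}" for i in range(n_outgroup)
    ]
    taxon_map = {
        lab: TaxonInfo(taxon=lab, ingroup=lab.startswith("in")) for lab in labels
    }
    entries = [(lab, "".join(cols[:, i])) for i, lab in enumerate(labels)]
    return Alignment(entries, taxon_map=taxon_map), planted
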