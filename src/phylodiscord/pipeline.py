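"""Workflow orchestration: run the discordance-diagnosis stages in
dependency order and emit a plain-text report bundle.

Stage order: polymorphism -> dataset split -> parsimony / spectra /
network -> topology tests -> hybridization test.  Every stage draws from
its own RNG stream derived from the master seed and the stage name, so
toggling one stage never shifts another stage's randomness.  All outputs
are tab-separated tables plus one JSON summary; reruns with identical
config and seed are byte-identical.
"""

from __future__ import annotations

import json
import os
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import parsimony, polymorphism, spectrum, trees
from .alignment import (
    Alignment,
    concatenate,
    merge_identical,
    read_alignment,
    read_taxon_map,
    write_alignment,
)
from .coalescent import LocusConfig, posterior_predictive_test, read_posterior, write_test_results
from .haplonet import build_parsimony_network, collapse_haplotypes, network_summary
from .likelihood import SiteLikelihoodMatrix, optimize_branch_lengths, rell_tests, site_loglik
from .models import SubstitutionModel, empirical_frequencies

__all__ = ["PipelineConfig", "run_report", "validate_against_supplementary"]

ALL_STAGES = (
    "polymorphism",
    "parsimony",
    "ild",
    "spectrum",
    "network",
    "topotest",
    "hybtest",
)


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_report`.

    ``alignments`` maps locus names to file paths; the first locus is
    treated as the nuclear (polymorphism-bearing) marker and the second,
    when present, as the plastid marker used for the haplotype network.
    """

    alignments: dict[str, str] = field(default_factory=dict)
    taxon_map: str | None = None
    posterior: str | None = None
    outdir: str = "report"
    stages: tuple = ALL_STAGES
    alignment_format: str = "fasta"
    scope: str = "ingroup"  # or "all"
    tcs_limit: int = 30
    ild_reps: int = 100
    bootstrap_reps: int = 0
    rell_boot: int = 5000
    n_starts: int = 1
    burn_in: int = 0
    thinning: int = 1
    alpha: float = 0.05
    mu_rel: dict = field(default_factory=dict)
    heredity: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    def validate_inputs(self) -> None:
        for name, path in self.alignments.items():
            if not os.path.exists(path):
                raise FileNotFoundError(f"alignment {name!r}: {path}")
        if self.taxon_map and not os.path.exists(self.taxon_map):
            raise FileNotFoundError(f"taxon map: {self.taxon_map}")
        if "hybtest" in self.stages:
            if not self.posterior:
                raise ValueError("hybtest stage enabled but no posterior file given")
            if not os.path.exists(self.posterior):
                raise FileNotFoundError(f"posterior: {self.posterior}")


def _stage_seed(master: int, stage: str) -> int:
    return (int(master) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


def _scoped_labels(aln: Alignment, scope: str) -> list[str]:
    return aln.ingroup_labels() if scope == "ingroup" else list(aln.labels)


def run_report(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages and write the report bundle.

    Returns a dict with per-stage status ("ok", "skipped", or an error
    message) and the headline numbers of each completed stage.  Hard
    errors in a stage are recorded; stages depending on its output are
    skipped.
    """
    cfg.validate_inputs()
    os.makedirs(cfg.outdir, exist_ok=True)
    status: dict[str, str] = {}
    summary: dict = {"seed": cfg.seed}
    tmap = read_taxon_map(cfg.taxon_map) if cfg.taxon_map else {}
    alns: dict[str, Alignment] = {}
    for name, path in cfg.alignments.items():
        a = read_alignment(path, cfg.alignment_format)
        a.taxon_map = dict(tmap)
        alns[name] = a
    locus_names = list(alns)
    nuclear = locus_names[0] if locus_names else None
    plastid = locus_names[1] if len(locus_names) > 1 else nuclear

    def out(fname: str) -> str:
        return os.path.join(cfg.outdir, fname)

    report = None
    if "polymorphism" in cfg.stages and nuclear:
        try:
            aln = alns[nuclear]
            scope = _scoped_labels(aln, cfg.scope)
            report = polymorphism.classify_aps(
                polymorphism.detect_ips(aln, scope), aln
            )
            report.write_tables(out("ips_columns.tsv"), out("ips_sequences.tsv"))
            free, bearing = polymorphism.split_by_aps(aln, report)
            write_alignment(free, out(f"{nuclear}_aps_free.fasta"))
            write_alignment(bearing, out(f"{nuclear}_aps_bearing.fasta"))
            summary["polymorphism"] = report.summary()
            status["polymorphism"] = "ok"
        except Exception as e:  # noqa: BLE001 - stage isolation
            status["polymorphism"] = f"error: {e}"

    if "parsimony" in cfg.stages:
        try:
            rows = []
            for name, aln in alns.items():
                merged, _ = merge_identical(aln)
                cls = parsimony.classify_sites(aln)
                if merged.n < 4:
                    # too few distinct sequences for a tree search
                    rows.append({
                        "alignment": name, "n_sequences": aln.n,
                        "n_merged": merged.n, "characters": aln.length,
                        "variable_sites": cls.n_variable,
                        "informative_sites": cls.n_informative,
                        "mp_trees": None, "tree_length": None,
                        "consistency_index": None, "retention_index": None,
                    })
                    continue
                best, length = parsimony.mp_search(
                    merged,
                    n_starts=cfg.n_starts,
                    seed=_stage_seed(cfg.seed, f"parsimony:{name}"),
                )
                stats = parsimony.ci_ri(best[0], merged)
                with open(out(f"mp_trees_{name}.nwk"), "w") as fh:
                    for t in best:
                        fh.write(trees.write_newick(t, lengths=False) + "\n")
                if len(best) > 1:
                    cons = trees.strict_consensus(best)
                    with open(out(f"mp_consensus_{name}.nwk"), "w") as fh:
                        fh.write(trees.write_newick(cons, lengths=False) + "\n")
                row = {
                    "alignment": name,
                    "n_sequences": aln.n,
                    "n_merged": merged.n,
                    "characters": aln.length,
                    "variable_sites": cls.n_variable,
                    "informative_sites": cls.n_informative,
                    "mp_trees": len(best),
                    "tree_length": length,
                    "consistency_index": round(stats.ci, 3),
                    "retention_index": round(stats.ri, 3),
                }
                if cfg.bootstrap_reps:
                    support = parsimony.bootstrap_support(
                        merged,
                        n_reps=cfg.bootstrap_reps,
                        seed=_stage_seed(cfg.seed, f"bootstrap:{name}"),
                        n_starts=1,
                        swap="nni",
                    )
                    with open(out(f"bootstrap_{name}.tsv"), "w") as fh:
                        fh.write("split\tsupport\n")
                        for s, v in sorted(support.items(), key=lambda kv: -kv[1]):
                            fh.write(f"{','.join(sorted(s))}\t{v:.1f}\n")
                rows.append(row)
            pd.DataFrame(rows).to_csv(out("parsimony_stats.tsv"), sep="\t", index=False)
            summary["parsimony"] = rows
            status["parsimony"] = "ok"
        except Exception as e:
            status["parsimony"] = f"error: {e}"

    if "ild" in cfg.stages:
        try:
            if len(locus_names) < 2:
                raise ValueError("ILD needs two loci")
            shared = [l for l in alns[nuclear].labels if l in alns[plastid].labels]
            combined = concatenate(
                alns[nuclear].subset(shared), alns[plastid].subset(shared)
            )
            merged, _ = merge_identical(combined)
            nA = alns[nuclear].length
            d_obs, p = parsimony.ild_test(
                merged,
                range(nA),
                range(nA, combined.length),
                n_reps=cfg.ild_reps,
                seed=_stage_seed(cfg.seed, "ild"),
            )
            summary["ild"] = {"D_obs": d_obs, "p": p, "n_reps": cfg.ild_reps}
            status["ild"] = "ok"
        except Exception as e:
            status["ild"] = f"error: {e}"

    if "spectrum" in cfg.stages and nuclear:
        try:
            aln = alns[nuclear]
            taxa: dict[str, list[str]] = {}
            for lab in aln.labels:
                taxa.setdefault(aln.info(lab).taxon, []).append(lab)
            named_splits = []
            for taxon, labels in sorted(taxa.items()):
                others = [l for l in aln.labels if l not in set(labels)]
                if labels and others:
                    named_splits.append((taxon, (labels, others)))
            table = spectrum.spectrum_table(aln, named_splits)
            table.to_csv(out("split_spectrum.tsv"), sep="\t", index=False)
            summary["spectrum"] = table.to_dict("records")
            status["spectrum"] = "ok"
        except Exception as e:
            status["spectrum"] = f"error: {e}"

    if "network" in cfg.stages and plastid:
        try:
            aln = alns[plastid]
            scoped = aln.subset(_scoped_labels(aln, cfg.scope))
            haps = collapse_haplotypes(scoped)
            net = build_parsimony_network(haps, limit=cfg.tcs_limit)
            net.write_node_table(out("haplotype_nodes.tsv"))
            net.write_dot(out("haplotype_network.dot"))
            net.write_graphml(out("haplotype_network.graphml"))
            summary["network"] = network_summary(net)
            status["network"] = "ok"
        except Exception as e:
            status["network"] = f"error: {e}"

    if "topotest" in cfg.stages and nuclear:
        try:
            aln, _ = merge_identical(alns[nuclear])
            model = SubstitutionModel.hky85(
                kappa=2.0, freqs=tuple(empirical_frequencies(aln)), alpha=0.5
            )
            seed = _stage_seed(cfg.seed, "topotest")
            best, _ = parsimony.mp_search(aln, n_starts=cfg.n_starts, seed=seed)
            candidates = {"best": best[0]}
            taxa: dict[str, list[str]] = {}
            for lab in aln.labels:
                info = aln.info(lab)
                if info.ingroup:
                    taxa.setdefault(info.taxon, []).append(lab)
            for taxon, labels in sorted(taxa.items()):
                if len(labels) >= 2 and len(labels) < aln.n - 1:
                    cons, _ = parsimony.mp_search(
                        aln, n_starts=cfg.n_starts, seed=seed,
                        constraint=[frozenset(labels)],
                    )
                    candidates[f"monophyly:{taxon}"] = cons[0]
            rows_ll = []
            labels_list = []
            for name, topo in candidates.items():
                opt, _ = optimize_branch_lengths(topo, aln, model, max_sweeps=5)
                rows_ll.append(site_loglik(opt, aln, model))
                labels_list.append(name)
            M = SiteLikelihoodMatrix(np.vstack(rows_ll), labels_list)
            res = rell_tests(M, n_boot=cfg.rell_boot, seed=seed)
            table = pd.DataFrame(
                {
                    "topology": labels_list,
                    "neg_lnL": [-t for t in res["totals"]],
                    "delta": res["delta"],
                    "p_WKH": res["p_wkh"],
                    "p_WSH": res["p_wsh"],
                }
            )
            table.to_csv(out("topology_tests.tsv"), sep="\t", index=False)
            summary["topotest"] = table.to_dict("records")
            status["topotest"] = "ok"
        except Exception as e:
            status["topotest"] = f"error: {e}"

    if "hybtest" in cfg.stages:
        try:
            posterior = read_posterior(cfg.posterior)
            flagged_pairs = []
            hyb_summary = {}
            for name, aln in alns.items():
                species_map = {
                    lab: aln.info(lab).taxon
                    for lab in aln.labels
                    if aln.info(lab).taxon in set(posterior[0].species)
                }
                locus = LocusConfig(
                    model=SubstitutionModel.hky85(
                        kappa=2.0, freqs=tuple(empirical_frequencies(aln)), alpha=0.5
                    ),
                    length=aln.length,
                    mu_rel=cfg.mu_rel.get(name, 1.0),
                    heredity=cfg.heredity.get(name, 1.0),
                )
                results = posterior_predictive_test(
                    posterior,
                    aln,
                    species_map,
                    locus,
                    burn_in=cfg.burn_in,
                    thinning=cfg.thinning,
                    seed=_stage_seed(cfg.seed, f"hybtest:{name}"),
                    alpha=cfg.alpha,
                )
                write_test_results(results, out(f"hybridization_{name}.tsv"), gene=name)
                flagged = [r for r in results if r.flagged]
                flagged_pairs.extend(
                    {"locus": name, "pair": list(r.species_pair), "p": r.p_value}
                    for r in flagged
                )
                hyb_summary[name] = {
                    "n_pairs": len(results),
                    "n_flagged": len(flagged),
                }
            summary["hybtest"] = hyb_summary
            summary["flagged_pairs"] = flagged_pairs
            status["hybtest"] = "ok"
        except Exception as e:
            status["hybtest"] = f"error: {e}"

    summary["status"] = status
    with open(os.path.join(cfg.outdir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary


# -- published-value validation ---------------------------------------------

# Printed reference values for the original supplementary alignments; used
# only to tabulate agreement when a user supplies those files locally.
PUBLISHED = {
    "ITS_1": {"n_sequences": 117, "characters": 653, "variable_sites": 167,
              "informative_sites": 138, "tree_length": 252,
              "consistency_index": 0.774, "retention_index": 0.935},
    "ITS_2": {"polymorphic_columns": 148, "aps_columns": 42,
              "max_ips_per_sequence": 16},
    "cpDNA": {"n_sequences": 219, "n_merged": 112, "characters": 960,
              "variable_sites": 101, "informative_sites": 60,
              "tree_length": 127, "consistency_index": 0.898,
              "retention_index": 0.955, "ingroup_haplotypes": 34},
    "ITS_cpDNA": {"n_sequences": 117, "characters": 1613,
                  "variable_sites": 263, "informative_sites": 207,
                  "tree_length": 430, "consistency_index": 0.702,
                  "retention_index": 0.895},
}

_CANDIDATE_EXT = (".fasta", ".fas", ".fa", ".txt", ".nex", ".nexus", ".phy")


def _find_file(directory: str, stem: str) -> str | None:
    for ext in _CANDIDATE_EXT:
        path = os.path.join(directory, stem + ext)
        if os.path.exists(path):
            return path
    return None


def validate_against_supplementary(
    directory: str,
    taxon_map: str | None = None,
    do_search: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Recompute published dataset statistics from locally supplied files.

    Looks for ``ITS_1``, ``ITS_2``, ``cpDNA`` and ``ITS_cpDNA`` alignments
    in ``directory`` (FASTA or NEXUS), recomputes sequence counts, site
    classifications, polymorphism counts and haplotype counts, and
    tabulates them against the printed reference values with match flags.
    Search-dependent statistics (MP tree length, CI, RI) are only computed
    with ``do_search=True`` since heuristic search on hundreds of
    sequences is slow.  Missing files are listed as skipped.
    """
    tmap = read_taxon_map(taxon_map) if taxon_map else {}
    rows = []

    def add(dataset: str, stat: str, computed) -> None:
        expected = PUBLISHED.get(dataset, {}).get(stat)
        match = None
        if expected is not None and computed is not None:
            match = (
                abs(float(computed) - float(expected)) < 5e-4
                if isinstance(expected, float)
                else int(computed) == int(expected)
            )
        rows.append(
            {"dataset": dataset, "statistic": stat, "computed": computed,
             "published": expected, "match": match}
        )

    for dataset in ("ITS_1", "ITS_2", "cpDNA", "ITS_cpDNA"):
        path = _find_file(directory, dataset)
        if path is None:
            rows.append({"dataset": dataset, "statistic": "file",
                         "computed": "skipped (missing)", "published": None,
                         "match": None})
            continue
        fmt = "nexus" if path.endswith((".nex", ".nexus")) else "fasta"
        aln = read_alignment(path, fmt)
        aln.taxon_map = dict(tmap)
        add(dataset, "n_sequences", aln.n)
        add(dataset, "characters", aln.length)
        if dataset == "ITS_2":
            scope = aln.ingroup_labels() if tmap else list(aln.labels)
            rep = polymorphism.classify_aps(polymorphism.detect_ips(aln, scope), aln)
            s = rep.summary()
            add(dataset, "polymorphic_columns", s["polymorphic_columns"])
            add(dataset, "aps_columns", s["aps_columns"])
            add(dataset, "max_ips_per_sequence", s["max_ips_per_sequence"])
            continue
        cls = parsimony.classify_sites(aln)
        add(dataset, "variable_sites", cls.n_variable)
        add(dataset, "informative_sites", cls.n_informative)
        merged, _ = merge_identical(aln)
        if dataset == "cpDNA":
            add(dataset, "n_merged", merged.n)
            scoped = aln.subset(aln.ingroup_labels() if tmap else aln.labels)
            haps = collapse_haplotypes(scoped)
            add(dataset, "ingroup_haplotypes", len(haps))
        if do_search:
            best, length = parsimony.mp_search(merged, n_starts=2, seed=seed)
            stats = parsimony.ci_ri(best[0], merged)
            add(dataset, "tree_length", length)
            add(dataset, "consistency_index", round(stats.ci, 3))
            add(dataset, "retention_index", round(stats.ri, 3))
    return pd.DataFrame(rows)
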