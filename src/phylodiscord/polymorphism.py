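"""Intra-individual polymorphic sites (IPS) and additive polymorphic sites (APS).

An IPS is an alignment column where an accession carries a 2-, 3- or 4-base
IUPAC ambiguity code — the direct-sequencing signature of two or more
ribotypes within one individual.  An IPS is *additive* (APS) when every
constituent base of the code is also observed as an unambiguous state in at
least one other scoped accession at the same column: the individual then
looks like the sum of two parental variants segregating in the data, which
is the pattern expected from hybridization with incomplete concerted
evolution.  ``N`` is treated as missing, not as a polymorphism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import iupac
from .alignment import Alignment

__all__ = ["PolymorphismReport", "detect_ips", "classify_aps", "split_by_aps"]

_FULL = 15  # mask of N


@dataclass
class ColumnRecord:
    """Per-column polymorphism record."""

    column: int
    states: frozenset[str]  # unambiguous states observed in scope
    carriers: list[str]  # labels with an ambiguity code here
    aps_labels: list[str] = field(default_factory=list)

    @property
    def is_aps(self) -> bool:
        return bool(self.aps_labels)


@dataclass
class PolymorphismReport:
    """IPS/APS classification of an alignment over a label scope."""

    scope: list[str]
    n_columns: int
    columns: list[ColumnRecord]
    ips_per_label: dict[str, int]
    aps_per_label: dict[str, int] | None = None
    classified: bool = False

    @property
    def polymorphic_columns(self) -> list[int]:
        return [rec.column for rec in self.columns]

    @property
    def aps_columns(self) -> list[int]:
        if not self.classified:
            raise ValueError("report not APS-classified")
        return [rec.column for rec in self.columns if rec.is_aps]

    def summary(self) -> dict:
        out = {
            "columns": self.n_columns,
            "polymorphic_columns": len(self.columns),
            "max_ips_per_sequence": max(self.ips_per_label.values(), default=0),
        }
        if self.classified:
            out["aps_columns"] = len(self.aps_columns)
            out["max_aps_per_sequence"] = max(self.aps_per_label.values(), default=0)
            out["aps_bearing_sequences"] = sum(
                1 for v in self.aps_per_label.values() if v > 0
            )
        return out

    def write_tables(self, per_column_path: str, per_sequence_path: str) -> None:
        with open(per_column_path, "w") as fh:
            fh.write("column\tstates\tcarriers\taps_labels\n")
            for rec in self.columns:
                fh.write(
                    f"{rec.column}\t{','.join(sorted(rec.states))}\t"
                    f"{','.join(rec.carriers)}\t{','.join(rec.aps_labels)}\n"
                )
        with open(per_sequence_path, "w") as fh:
            fh.write("label\tips\taps\n")
            for lab in self.scope:
                aps = self.aps_per_label.get(lab, 0) if self.classified else ""
                fh.write(f"{lab}\t{self.ips_per_label.get(lab, 0)}\t{aps}\n")


def _scope_rows(aln: Alignment, scope) -> tuple[list[str], np.ndarray]:
    if scope is None:
        labels = aln.ingroup_labels()
    else:
        labels = [lab for lab in aln.labels if lab in set(scope)]
        missing = set(scope) - set(labels)
        if missing:
            raise ValueError(f"scope labels not in alignment: {sorted(missing)}")
    if not labels:
        raise ValueError("empty scope")
    idx = [aln.labels.index(lab) for lab in labels]
    return labels, aln.matrix[idx]


def detect_ips(aln: Alignment, scope=None) -> PolymorphismReport:
    """Detect intra-individual polymorphic sites.

    A column is polymorphic iff at least one scoped sequence carries a
    2-, 3- or 4-base ambiguity code there, ``N`` excepted (an N is an
    uninformative base call, not evidence of two ribotypes).  ``scope``
    defaults to the ingroup labels.
    """
    labels, M = _scope_rows(aln, scope)
    npc = iupac.popcount(M)
    is_code = (npc >= 2) & (M != _FULL)
    ips_per_label = {lab: int(is_code[i].sum()) for i, lab in enumerate(labels)}
    columns: list[ColumnRecord] = []
    for j in np.nonzero(is_code.any(axis=0))[0]:
        col = M[:, j]
        states = frozenset(
            iupac.code_of(int(m)) for m in np.unique(col[npc[:, j] == 1])
        )
        carriers = [labels[i] for i in np.nonzero(is_code[:, j])[0]]
        columns.append(ColumnRecord(column=int(j), states=states, carriers=carriers))
    return PolymorphismReport(
        scope=labels,
        n_columns=aln.length,
        columns=columns,
        ips_per_label=ips_per_label,
    )


def classify_aps(report: PolymorphismReport, aln: Alignment) -> PolymorphismReport:
    """Flag additive polymorphic sites in an IPS report.

    An ambiguity code at (column, label) is APS iff every constituent base
    occurs as an unambiguous state at the same column in at least one
    *other* scoped accession.  3-/4-base codes require all constituents
    observed.
    """
    missing = [lab for lab in report.scope if lab not in aln.labels]
    if missing or report.n_columns != aln.length:
        raise ValueError("report does not match alignment")
    idx = {lab: aln.labels.index(lab) for lab in report.scope}
    M = aln.matrix
    npc = iupac.popcount(M)
    aps_per_label = {lab: 0 for lab in report.scope}
    rows = np.array([idx[lab] for lab in report.scope])
    for rec in report.columns:
        j = rec.column
        rec.aps_labels = []
        for lab in rec.carriers:
            i = idx[lab]
            code_mask = int(M[i, j])
            others = rows[rows != i]
            observed = 0
            for r in others:
                if npc[r, j] == 1:
                    observed |= int(M[r, j])
            if code_mask & observed == code_mask:
                rec.aps_labels.append(lab)
                aps_per_label[lab] += 1
    report.aps_per_label = aps_per_label
    report.classified = True
    return report


def split_by_aps(
    aln: Alignment, report: PolymorphismReport
) -> tuple[Alignment, Alignment]:
    """Split into APS-free and APS-bearing datasets.

    The APS-free alignment keeps every scoped sequence with zero APS plus
    all out-of-scope sequences (outgroups are never dropped); the
    APS-bearing alignment holds the remaining scoped sequences.
    """
    if not report.classified:
        raise ValueError("report not APS-classified")
    scoped = set(report.scope)
    bearing = {lab for lab, k in report.aps_per_label.items() if k > 0}
    free_labels = [lab for lab in aln.labels if lab not in bearing]
    bear_labels = [lab for lab in aln.labels if lab in bearing and lab in scoped]
    return aln.subset(free_labels), aln.subset(bear_labels)
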