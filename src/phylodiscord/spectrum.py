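"""Supporting-position split spectra.

For a bipartition of accessions into a functional ingroup and a functional
outgroup, each alignment column is classified into the three
Wägele–Rödding categories:

* **symmetric** (binary): exactly two states overall, each side fixed for a
  different one — supports both sides of the split equally;
* **asymmetric** for side S: S is fixed for one state, the other side shows
  two or more states none of which equals it — supports S only;
* **noisy** for side S: S is fixed for a state that also occurs in the
  other side — a convergence, chance similarity, or autapomorphy of the
  split rather than support.

Ambiguity codes and gaps are treated as missing for the fixation tests; a
side is "fixed" only when all its resolved characters agree and at least
one character is resolved.  The headline support count of a split is
symmetric + asymmetric positions (noisy positions are tallied but not
counted as support).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import iupac
from .alignment import Alignment

__all__ = ["SupportSpectrum", "classify_supporting_positions", "spectrum_table"]


@dataclass
class SupportSpectrum:
    """Column classification for one bipartition."""

    ingroup: frozenset[str]
    outgroup: frozenset[str]
    symmetric_positions: list[int] = field(default_factory=list)
    asymmetric_ingroup: list[int] = field(default_factory=list)
    asymmetric_outgroup: list[int] = field(default_factory=list)
    noisy_ingroup: list[int] = field(default_factory=list)
    noisy_outgroup: list[int] = field(default_factory=list)

    @property
    def n_symmetric(self) -> int:
        return len(self.symmetric_positions)

    @property
    def n_asymmetric(self) -> tuple[int, int]:
        return len(self.asymmetric_ingroup), len(self.asymmetric_outgroup)

    @property
    def n_noisy(self) -> int:
        return len(set(self.noisy_ingroup) | set(self.noisy_outgroup))

    def support(self, side: str = "ingroup") -> int:
        """Supporting positions for a side: symmetric + asymmetric."""
        asym = self.asymmetric_ingroup if side == "ingroup" else self.asymmetric_outgroup
        return self.n_symmetric + len(asym)


def _side_states(M: np.ndarray, npc: np.ndarray, rows: list[int], j: int) -> set[int]:
    """Resolved (unambiguous) state masks of a side at column j."""
    return {int(M[i, j]) for i in rows if npc[i, j] == 1}


def classify_supporting_positions(aln: Alignment, split) -> SupportSpectrum:
    """Classify every column with respect to a bipartition.

    ``split`` is a pair ``(ingroup_labels, outgroup_labels)`` of disjoint
    label collections.  Columns where either side has no resolved state
    are skipped.  A constant column is, by the definitions above, noisy
    for both sides (each side is fixed for a state that also occurs
    opposite).
    """
    ing, out = (frozenset(split[0]), frozenset(split[1]))
    if ing & out:
        raise ValueError(f"split sides overlap: {sorted(ing & out)}")
    unknown = (ing | out) - set(aln.labels)
    if unknown:
        raise ValueError(f"split labels not in alignment: {sorted(unknown)}")
    rows_in = [aln.labels.index(l) for l in ing]
    rows_out = [aln.labels.index(l) for l in out]
    M, npc = aln.matrix, iupac.popcount(aln.matrix)
    spec = SupportSpectrum(ingroup=ing, outgroup=out)
    for j in range(aln.length):
        s_in = _side_states(M, npc, rows_in, j)
        s_out = _side_states(M, npc, rows_out, j)
        if not s_in or not s_out:
            continue
        fixed_in = len(s_in) == 1
        fixed_out = len(s_out) == 1
        if fixed_in and fixed_out and s_in != s_out:
            spec.symmetric_positions.append(j)
            continue
        if fixed_in:
            (x,) = s_in
            if x in s_out:
                spec.noisy_ingroup.append(j)
            elif len(s_out) >= 2:
                spec.asymmetric_ingroup.append(j)
        if fixed_out:
            (x,) = s_out
            if x in s_in:
                spec.noisy_outgroup.append(j)
            elif len(s_in) >= 2:
                spec.asymmetric_outgroup.append(j)
    return spec


def spectrum_table(aln: Alignment, splits) -> pd.DataFrame:
    """Tabulate spectra for a list of named bipartitions.

    ``splits`` is an iterable of ``(name, (ingroup, outgroup))``.  One row
    per split, with per-category counts and the headline support per side
    (the figure convention draws ingroup support above and outgroup
    support below the axis).
    """
    records = []
    for name, split in splits:
        spec = classify_supporting_positions(aln, split)
        records.append(
            {
                "split": name,
                "symmetric": spec.n_symmetric,
                "asymmetric_ingroup": len(spec.asymmetric_ingroup),
                "asymmetric_outgroup": len(spec.asymmetric_outgroup),
                "noisy": spec.n_noisy,
                "support_ingroup": spec.support("ingroup"),
                "support_outgroup": spec.support("outgroup"),
            }
        )
    return pd.DataFrame.from_records(
        records,
        columns=[
            "split",
            "symmetric",
            "asymmetric_ingroup",
            "asymmetric_outgroup",
            "noisy",
            "support_ingroup",
            "support_outgroup",
        ],
    )
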