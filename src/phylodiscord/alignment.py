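"""Alignment container and I/O for FASTA, NEXUS and relaxed PHYLIP.

The :class:`Alignment` is the substrate every analysis stage consumes:
labelled equal-length IUPAC-coded sequences, optional named column
partitions (0-based half-open), and a taxon map assigning each label a
taxon name, a population code and an ingroup flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from Bio import AlignIO, SeqIO

from . import iupac

__all__ = [
    "Alignment",
    "TaxonInfo",
    "AlignmentError",
    "AlignmentShapeError",
    "AlphabetError",
    "DuplicateLabelError",
    "read_alignment",
    "write_alignment",
    "read_taxon_map",
    "write_taxon_map",
    "merge_identical",
    "p_distance",
    "distance_matrix",
    "concatenate",
]


class AlignmentError(ValueError):
    """Base class for alignment construction/IO errors."""


class AlignmentShapeError(AlignmentError):
    """Sequences of unequal length."""


class AlphabetError(AlignmentError):
    """A character outside the IUPAC DNA alphabet plus gap/missing."""


class DuplicateLabelError(AlignmentError):
    """A label occurs more than once."""


@dataclass(frozen=True)
class TaxonInfo:
    """Per-accession metadata: taxon name, population code, ingroup flag."""

    taxon: str
    population: str = ""
    ingroup: bool = True


class Alignment:
    """Ordered labelled equal-length sequences with partitions and taxon map.

    Parameters
    ----------
    entries:
        Iterable of ``(label, sequence)`` pairs.  ``U`` is normalized to
        ``T``; lowercase is upcased.
    partitions:
        Mapping name -> (start, stop), 0-based half-open, disjoint.
    taxon_map:
        Mapping label -> :class:`TaxonInfo`; absent labels default to an
        ingroup taxon named after the label.
    """

    def __init__(
        self,
        entries,
        partitions: dict[str, tuple[int, int]] | None = None,
        taxon_map: dict[str, TaxonInfo] | None = None,
    ):
        labels: list[str] = []
        rows: list[np.ndarray] = []
        length = None
        for label, seq in entries:
            if label in labels:
                raise DuplicateLabelError(f"duplicate label {label!r}")
            try:
                row = iupac.encode(str(seq))
            except ValueError as e:
                raise AlphabetError(f"sequence {label!r}: {e}") from None
            if length is None:
                length = row.size
            elif row.size != length:
                raise AlignmentShapeError(
                    f"sequence {label!r} has length {row.size}, expected {length}"
                )
            labels.append(label)
            rows.append(row)
        self.labels: list[str] = labels
        self._matrix = (
            np.vstack(rows) if rows else np.zeros((0, 0), dtype=np.uint8)
        )
        self.partitions: dict[str, tuple[int, int]] = dict(partitions or {})
        self._check_partitions()
        self.taxon_map: dict[str, TaxonInfo] = dict(taxon_map or {})
        self._index = {lab: i for i, lab in enumerate(labels)}

    # -- basic protocol ----------------------------------------------------

    def _check_partitions(self) -> None:
        occupied: list[tuple[int, int]] = []
        for name, (start, stop) in self.partitions.items():
            if not (0 <= start <= stop <= self.length):
                raise AlignmentError(
                    f"partition {name!r} range ({start},{stop}) outside [0,{self.length})"
                )
            for s, t in occupied:
                if max(start, s) < min(stop, t):
                    raise AlignmentError(f"partition {name!r} overlaps another")
            occupied.append((start, stop))

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def length(self) -> int:
        return self._matrix.shape[1]

    @property
    def matrix(self) -> np.ndarray:
        """(n, length) uint8 array of IUPAC base-set masks (0 = missing)."""
        return self._matrix

    def sequence(self, label: str) -> str:
        return iupac.decode(self._matrix[self._index[label]])

    def row(self, label: str) -> np.ndarray:
        return self._matrix[self._index[label]]

    def __len__(self) -> int:
        return self.n

    def __iter__(self):
        for lab in self.labels:
            yield lab, self.sequence(lab)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.labels == other.labels
            and self.partitions == other.partitions
            and np.array_equal(self._matrix, other._matrix)
        )

    def info(self, label: str) -> TaxonInfo:
        """Taxon metadata for a label (defaults to ingroup, taxon = label)."""
        return self.taxon_map.get(label, TaxonInfo(taxon=label))

    def ingroup_labels(self) -> list[str]:
        return [lab for lab in self.labels if self.info(lab).ingroup]

    def subset(self, labels) -> "Alignment":
        """New alignment restricted to the given labels (input order kept)."""
        keep = [lab for lab in self.labels if lab in set(labels)]
        return Alignment(
            [(lab, self.sequence(lab)) for lab in keep],
            partitions=self.partitions,
            taxon_map={k: v for k, v in self.taxon_map.items() if k in set(keep)},
        )

    def columns(self, cols) -> "Alignment":
        """New alignment restricted to the given column indices (no partitions)."""
        cols = np.asarray(cols, dtype=int)
        sub = self._matrix[:, cols]
        return Alignment(
            [(lab, iupac.decode(sub[i])) for i, lab in enumerate(self.labels)],
            taxon_map=dict(self.taxon_map),
        )

    def species_of(self, label: str) -> str:
        return self.info(label).taxon


# -- readers / writers -----------------------------------------------------

_NEXUS_CHARSET = re.compile(
    r"charset\s+(\S+?)\s*=\s*([^;]+);", re.IGNORECASE
)


def _nexus_partitions(path: str) -> dict[str, tuple[int, int]]:
    """Extract contiguous CHARSET ranges from a NEXUS file.

    NEXUS ranges are 1-based inclusive; they are converted to 0-based
    half-open.  Only simple contiguous ``start-stop`` (or single-column)
    definitions are supported, matching the partition model used here.
    """
    with open(path) as fh:
        text = fh.read()
    parts: dict[str, tuple[int, int]] = {}
    for m in _NEXUS_CHARSET.finditer(text):
        name, body = m.group(1), m.group(2).strip()
        rm = re.fullmatch(r"(\d+)\s*-\s*(\d+)", body)
        if rm:
            parts[name] = (int(rm.group(1)) - 1, int(rm.group(2)))
        elif re.fullmatch(r"\d+", body):
            parts[name] = (int(body) - 1, int(body))
    return parts


def read_alignment(path: str, format: str = "fasta") -> Alignment:
    """Read an alignment from ``fasta``, ``nexus`` or ``phylip-relaxed``.

    NEXUS character sets populate :attr:`Alignment.partitions`.  Labels are
    preserved verbatim; sequence invariants are enforced on construction.
    """
    if format not in ("fasta", "nexus", "phylip-relaxed"):
        raise ValueError(f"unsupported format {format!r}")
    entries: list[tuple[str, str]] = []
    if format == "fasta":
        for rec in SeqIO.parse(path, "fasta"):
            entries.append((rec.id, str(rec.seq)))
        lengths = {len(s) for _, s in entries}
        if len(lengths) > 1:
            raise AlignmentShapeError(
                f"ragged sequence lengths {sorted(lengths)} in {path}"
            )
    else:
        try:
            msa = AlignIO.read(path, format)
        except ValueError as e:
            if "sequences of different length" in str(e).lower():
                raise AlignmentShapeError(str(e)) from None
            raise
        for rec in msa:
            entries.append((rec.id, str(rec.seq)))
    partitions = _nexus_partitions(path) if format == "nexus" else {}
    return Alignment(entries, partitions=partitions)


def write_alignment(aln: Alignment, path: str, format: str = "fasta") -> None:
    """Write in ``fasta``, ``nexus`` or ``phylip-relaxed``.

    NEXUS output includes a SETS block reproducing the partitions, so a
    read/write/read round trip is an identity on entries and partitions.
    """
    if format == "fasta":
        with open(path, "w") as fh:
            for lab, seq in aln:
                fh.write(f">{lab}\n{seq}\n")
    elif format == "phylip-relaxed":
        with open(path, "w") as fh:
            fh.write(f" {aln.n} {aln.length}\n")
            for lab, seq in aln:
                fh.write(f"{lab}  {seq}\n")
    elif format == "nexus":
        with open(path, "w") as fh:
            fh.write("#NEXUS\n\nBEGIN DATA;\n")
            fh.write(f"  DIMENSIONS NTAX={aln.n} NCHAR={aln.length};\n")
            fh.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n")
            for lab, seq in aln:
                fh.write(f"    {lab}  {seq}\n")
            fh.write("  ;\nEND;\n")
            if aln.partitions:
                fh.write("\nBEGIN SETS;\n")
                for name, (start, stop) in aln.partitions.items():
                    fh.write(f"  CHARSET {name} = {start + 1}-{stop};\n")
                fh.write("END;\n")
    else:
        raise ValueError(f"unsupported format {format!r}")


def read_taxon_map(path: str) -> dict[str, TaxonInfo]:
    """Read a tab-separated taxon map: label, taxon, in|out[, population]."""
    out: dict[str, TaxonInfo] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{ln}: expected >=3 tab-separated fields")
            label, taxon, flag = fields[0], fields[1], fields[2]
            if flag not in ("in", "out"):
                raise ValueError(f"{path}:{ln}: ingroup flag must be 'in' or 'out'")
            pop = fields[3] if len(fields) > 3 else ""
            out[label] = TaxonInfo(taxon=taxon, population=pop, ingroup=flag == "in")
    return out


def write_taxon_map(taxon_map: dict[str, TaxonInfo], path: str) -> None:
    with open(path, "w") as fh:
        for label, info in taxon_map.items():
            flag = "in" if info.ingroup else "out"
            fh.write(f"{label}\t{info.taxon}\t{flag}\t{info.population}\n")


# -- operations ------------------------------------------------------------


def _compatible(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Per-column truth: the two rows could be the same sequence.

    Under the missing-compatible policy two characters match when either is
    missing or their base sets intersect.
    """
    return (a == 0) | (b == 0) | ((a & b) != 0)


def merge_identical(
    aln: Alignment, missing_policy: str = "exact"
) -> tuple[Alignment, dict[str, list[str]]]:
    """Collapse duplicate sequences to one representative each.

    ``exact``: equivalence is character-for-character identity.
    ``missing-compatible``: greedy single-linkage grouping where a sequence
    joins the first existing representative it is compatible with (missing
    positions match anything, base sets need only intersect).

    Returns the reduced alignment plus a mapping representative label ->
    member labels (representative included, input order preserved).
    """
    if aln.n == 0:
        raise AlignmentError("empty alignment")
    if missing_policy not in ("exact", "missing-compatible"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    reps: list[int] = []
    mapping: dict[str, list[str]] = {}
    M = aln.matrix
    for i, lab in enumerate(aln.labels):
        home = None
        for r in reps:
            if missing_policy == "exact":
                same = np.array_equal(M[i], M[r])
            else:
                same = bool(_compatible(M[i], M[r]).all())
            if same:
                home = r
                break
        if home is None:
            reps.append(i)
            mapping[lab] = [lab]
        else:
            mapping[aln.labels[home]].append(lab)
    merged = Alignment(
        [(aln.labels[r], iupac.decode(M[r])) for r in reps],
        partitions=aln.partitions,
        taxon_map={aln.labels[r]: aln.info(aln.labels[r]) for r in reps},
    )
    return merged, mapping


def p_distance(a, b) -> float:
    """Uncorrected p-distance with pairwise deletion.

    Positions where either character is gap/missing are excluded.  Ambiguity
    codes are compared by base-set disjointness: overlapping sets (R vs A)
    count as a match, disjoint sets (R vs Y) as a difference — conservative
    for minimum-distance tests.
    """
    av = iupac.encode(a) if isinstance(a, str) else np.asarray(a, dtype=np.uint8)
    bv = iupac.encode(b) if isinstance(b, str) else np.asarray(b, dtype=np.uint8)
    if av.size != bv.size:
        raise AlignmentShapeError("sequences of unequal length")
    comparable = (av != 0) & (bv != 0)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        raise AlignmentError("no comparable positions: distance undefined")
    diffs = int((comparable & ((av & bv) == 0)).sum())
    return diffs / n_comp


def distance_matrix(aln: Alignment) -> np.ndarray:
    """All-pairs p-distance matrix; NaN where no position is comparable."""
    M = aln.matrix
    n = aln.n
    out = np.zeros((n, n))
    present = M != 0
    for i in range(n):
        comp = present[i] & present[i + 1:]
        disj = (M[i] & M[i + 1:]) == 0
        ncomp = comp.sum(axis=1)
        with np.errstate(invalid="ignore"):
            d = (comp & disj).sum(axis=1) / ncomp
        d = np.where(ncomp == 0, np.nan, d)
        out[i, i + 1:] = d
        out[i + 1:, i] = d
    return out


def concatenate(a: Alignment, b: Alignment) -> Alignment:
    """Join two alignments on their label sets.

    Labels must match one-to-one; partitions of ``b`` are shifted by the
    length of ``a``.  Taxon maps are merged with ``a`` taking precedence.
    """
    only_a = [lab for lab in a.labels if lab not in set(b.labels)]
    only_b = [lab for lab in b.labels if lab not in set(a.labels)]
    if only_a or only_b:
        raise AlignmentError(
            f"labels not joinable; only in first: {only_a}; only in second: {only_b}"
        )
    off = a.length
    partitions = dict(a.partitions)
    for name, (start, stop) in b.partitions.items():
        if name in partitions:
            name = f"{name}_2"
        partitions[name] = (start + off, stop + off)
    taxon_map = dict(b.taxon_map)
    taxon_map.update(a.taxon_map)
    return Alignment(
        [(lab, a.sequence(lab) + b.sequence(lab)) for lab in a.labels],
        partitions=partitions,
        taxon_map=taxon_map,
    )
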