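"""Pairwise homolog comparison: alignment, identity and region statistics.

The human and *D. discoideum* subunits of the Fe-S assembly machinery are
compared by optimal affine-gap alignment (BLOSUM62).  Two parameterisations
are shipped:

- ``mode="local"`` with BLASTp-style penalties (gap open 11, extend 1) —
  the reproduction mode for overall identity/similarity figures derived
  from blastp output;
- ``mode="global"`` (gap open 10, extend 0.5) for position-mapping tasks
  such as projecting structure-derived interface regions or disease
  positions from one homolog onto the other.

Identity over a *region* (e.g. the NFS1 residues within 4 A of frataxin)
uses all region positions as the denominator: a region position that falls
outside the aligned span counts as non-identical.  This is deliberately
conservative and is recorded in every report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal

import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "SequenceRecord",
    "PairwiseAlignment",
    "RegionIdentityReport",
    "align_pair",
    "identity_stats",
    "region_identity",
    "disease_position_report",
]

_AA = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class SequenceRecord:
    """An ungapped protein sequence (uppercase, 20 standard letters + X)."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        for i, ch in enumerate(self.residues, start=1):
            if ch not in _AA:
                raise ValueError(f"{self.id}: invalid residue {ch!r} at position {i}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class PairwiseAlignment:
    """Gapped alignment of two sequences with a 1-based position map."""

    seq_a_id: str
    seq_b_id: str
    aligned_a: str
    aligned_b: str
    mode: Literal["global", "local"]
    matrix_name: str
    gap_open: float
    gap_extend: float
    score: float
    start_a: int  # 1-based position in A of the first aligned column
    start_b: int
    len_a: int    # full (unaligned) sequence lengths
    len_b: int
    seq_a: str = ""  # full ungapped sequences, for out-of-span reporting
    seq_b: str = ""
    map_a_to_b: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    def columns(self):
        """Yield (pos_a, pos_b, res_a, res_b); positions are 1-based or None."""
        pa, pb = self.start_a - 1, self.start_b - 1
        for ca, cb in zip(self.aligned_a, self.aligned_b):
            if ca != "-":
                pa += 1
            if cb != "-":
                pb += 1
            yield (pa if ca != "-" else None, pb if cb != "-" else None, ca, cb)


@dataclass
class RegionIdentityReport:
    """Identity/similarity over a named set of positions in sequence A."""

    region_name: str
    positions_a: list[int]
    n_aligned: int
    n_identical: int
    n_similar: int
    identity_pct: float
    similarity_pct: float
    denominator_policy: str
    detail: pd.DataFrame = field(repr=False, default=None)


def _load_matrix(name: str):
    return substitution_matrices.load(name)


def align_pair(a: SequenceRecord, b: SequenceRecord,
               mode: Literal["global", "local"] = "local",
               matrix: str = "BLOSUM62",
               gap_open: float | None = None,
               gap_extend: float | None = None) -> PairwiseAlignment:
    """Optimal affine-gap alignment of two sequences.

    A gap of length k costs ``gap_open + gap_extend * (k - 1)``.  Defaults:
    local 11/1 (BLASTp-style), global 10/0.5.  The dynamic-programming
    traceback tie-break is fixed (first optimal path), so output is
    reproducible.
    """
    if gap_open is None:
        gap_open = 11.0 if mode == "local" else 10.0
    if gap_extend is None:
        gap_extend = 1.0 if mode == "local" else 0.5
    mat = _load_matrix(matrix)
    for rec in (a, b):
        bad = [ch for ch in set(rec.residues) if ch not in mat.alphabet]
        if bad:
            pos = next(i for i, ch in enumerate(rec.residues, 1) if ch in bad)
            raise ValueError(f"{rec.id}: residue {rec.residues[pos-1]!r} at "
                             f"position {pos} not in {matrix} alphabet")

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = mat
    aligner.mode = mode
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    alignments = aligner.align(a.residues, b.residues)
    try:
        aln = alignments[0]
    except IndexError:
        aln = None  # degenerate optimum: the empty local alignment (score 0)

    if aln is None or (mode == "local" and len(aln.aligned[0]) == 0):
        aligned_a = aligned_b = ""
        start_a = start_b = 1
        score = float(alignments.score)
    else:
        aligned_a, aligned_b = str(aln[0]), str(aln[1])
        score = float(aln.score)
        if mode == "local":
            start_a = int(aln.aligned[0][0][0]) + 1
            start_b = int(aln.aligned[1][0][0]) + 1
        else:
            start_a = start_b = 1

    pa = PairwiseAlignment(
        seq_a_id=a.id, seq_b_id=b.id,
        aligned_a=aligned_a, aligned_b=aligned_b,
        mode=mode, matrix_name=matrix,
        gap_open=float(gap_open), gap_extend=float(gap_extend),
        score=score,
        start_a=start_a, start_b=start_b,
        len_a=len(a), len_b=len(b),
        seq_a=a.residues, seq_b=b.residues,
    )
    pa.map_a_to_b = {p_a: p_b for p_a, p_b, ca, cb in pa.columns()
                     if p_a is not None and p_b is not None}
    return pa


def identity_stats(aln: PairwiseAlignment,
                   denominator: Literal["aligned_columns", "shorter_seq"]
                   = "aligned_columns") -> tuple[float, float, float]:
    """(identity %, similarity %, coverage %) of an alignment.

    Identity: identical-letter columns / denominator.  Similarity: columns
    with positive BLOSUM62 score (identities included).  Coverage: aligned
    span of sequence A / its full length.  Gap columns count in the
    ``aligned_columns`` denominator (BLAST convention).
    """
    mat = _load_matrix(aln.matrix_name)
    n_cols = aln.n_columns
    if n_cols == 0:
        warnings.warn("alignment has zero columns; all stats 0", stacklevel=2)
        return (0.0, 0.0, 0.0)
    n_id = n_sim = 0
    span_a = 0
    for _, _, ca, cb in aln.columns():
        if ca != "-":
            span_a += 1
        if ca == "-" or cb == "-":
            continue
        if ca == cb:
            n_id += 1
        if mat[ca, cb] > 0:
            n_sim += 1
    denom = n_cols if denominator == "aligned_columns" else min(aln.len_a, aln.len_b)
    identity = 100.0 * n_id / denom
    similarity = 100.0 * n_sim / denom
    coverage = 100.0 * span_a / aln.len_a
    return (identity, similarity, coverage)


def region_identity(aln: PairwiseAlignment, positions_a: Iterable[int],
                    region_name: str = "region",
                    matrix: str | None = None) -> RegionIdentityReport:
    """Identity/similarity over a set of 1-based positions in sequence A.

    Every region position contributes to the denominator; positions aligned
    to a gap (or outside a local alignment's span) count as non-identical.
    """
    positions = sorted(set(int(p) for p in positions_a))
    if not positions:
        raise ValueError("empty region")
    if positions[0] < 1 or positions[-1] > aln.len_a:
        raise ValueError(f"region positions outside 1..{aln.len_a}")
    mat = _load_matrix(matrix or aln.matrix_name)

    col_by_a: dict[int, tuple[str, str, int | None]] = {}
    for p_a, p_b, ca, cb in aln.columns():
        if p_a is not None:
            col_by_a[p_a] = (ca, cb, p_b)

    rows = []
    n_aligned = n_id = n_sim = 0
    for p in positions:
        fallback = aln.seq_a[p - 1] if aln.seq_a else "?"
        ca, cb, p_b = col_by_a.get(p, (fallback, "-", None))
        aligned = p_b is not None
        ident = aligned and ca == cb
        similar = aligned and mat[ca, cb] > 0
        n_aligned += aligned
        n_id += ident
        n_sim += similar
        rows.append({"pos_a": p, "a_residue": ca,
                     "b_residue": cb if aligned else "-",
                     "pos_b": p_b, "identical": bool(ident),
                     "similar": bool(similar)})
    denom = len(positions)
    return RegionIdentityReport(
        region_name=region_name, positions_a=positions,
        n_aligned=n_aligned, n_identical=n_id, n_similar=n_sim,
        identity_pct=100.0 * n_id / denom,
        similarity_pct=100.0 * n_sim / denom,
        denominator_policy="all_region_positions",
        detail=pd.DataFrame(rows),
    )


def disease_position_report(aln: PairwiseAlignment,
                            annotated: Iterable[tuple[int, str]]) -> pd.DataFrame:
    """Conservation of annotated positions (e.g. FRDA sites) across homologs.

    One row per (position_in_a, label): the residue in A, the mapped
    position/residue in B (or "unaligned"), and whether the letter is
    conserved.
    """
    col_by_a = {p_a: (ca, cb, p_b) for p_a, p_b, ca, cb in aln.columns()
                if p_a is not None}
    rows = []
    for pos, label in annotated:
        pos = int(pos)
        if pos < 1 or pos > aln.len_a:
            raise ValueError(f"annotated position {pos} beyond sequence A "
                             f"(length {aln.len_a})")
        fallback = aln.seq_a[pos - 1] if aln.seq_a else "?"
        ca, cb, p_b = col_by_a.get(pos, (fallback, "-", None))
        rows.append({
            "pos_a": pos, "res_a": ca,
            "pos_b": p_b if p_b is not None else "unaligned",
            "res_b": cb if p_b is not None else "-",
            "conserved": p_b is not None and ca == cb,
            "label": label,
        })
    return pd.DataFrame(rows, columns=["pos_a", "res_a", "pos_b", "res_b",
                                       "conserved", "label"])
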