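"""Multiple-alignment curation and column conservation statistics.

The frataxin domain alignment spans 54 representative genomes.  Curation
mirrors the published protocol: drop columns where most sequences are
gapped, then truncate everything beyond the last residue of the human
reference sequence.  Conservation of a column is the *modal amino-acid
frequency* with the full number of records as denominator — a gap counts
against conservation — and "conserved in more than X%" means strictly
greater than X.  Column information content is log2(20) minus the Shannon
entropy of the amino-acid distribution (gaps excluded from the
distribution itself).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from Bio import AlignIO

__all__ = [
    "MSA",
    "ConservationProfile",
    "read_and_trim",
    "column_profile",
    "threshold_counts",
    "map_column_to_reference",
]

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")
_GAPS = {"-", ".", "~"}


@dataclass
class MSA:
    """Aligned records (id, gapped sequence), all the same length."""

    records: list[tuple[str, str]]
    trim_log: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("an alignment needs at least 2 records")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_columns(self) -> int:
        return len(self.records[0][1])

    def column(self, i: int) -> str:
        return "".join(seq[i] for _, seq in self.records)

    def sequence(self, record_id: str) -> str:
        for rid, seq in self.records:
            if rid == record_id:
                return seq
        raise KeyError(f"record {record_id!r} not in alignment")


@dataclass
class ConservationProfile:
    """Per-column counts, modal residue/frequency and information content."""

    n_records: int
    counts: list[dict[str, int]]          # amino-acid counts per column
    gap_counts: list[int]
    modal_residue: list[str]
    modal_frequency: list[float]          # modal count / n_records
    information_bits: list[float]
    modal_ties: list[bool]

    @property
    def n_columns(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i in range(self.n_columns):
            row = {"column": i + 1, "modal_residue": self.modal_residue[i],
                   "modal_frequency": self.modal_frequency[i],
                   "information_bits": self.information_bits[i],
                   "gaps": self.gap_counts[i], "tie": self.modal_ties[i]}
            for aa in AMINO_ACIDS:
                row[aa] = self.counts[i].get(aa, 0)
            rows.append(row)
        return pd.DataFrame(rows)


def _read_alignment(path: str | Path, format: Literal["clustal", "fasta"]) -> MSA:
    text = Path(path).read_text()
    bio_fmt = {"clustal": "clustal", "fasta": "fasta"}[format]
    aln = AlignIO.read(StringIO(text), bio_fmt)
    return MSA(records=[(rec.id, str(rec.seq).upper()) for rec in aln])


def read_and_trim(path: str | Path, format: Literal["clustal", "fasta"],
                  reference_id: str, max_gap_fraction: float = 0.5) -> MSA:
    """Load an alignment and apply the curation rules.

    Removes columns whose gap fraction exceeds ``max_gap_fraction`` and all
    columns after the last column in which ``reference_id`` has a residue.
    The indices of removed columns (1-based, in original numbering) are kept
    in ``trim_log``.  Trimming an already-curated alignment is a no-op.
    """
    msa = _read_alignment(path, format)
    ref = msa.sequence(reference_id)  # raises KeyError if missing

    last_ref_col = max((i for i, ch in enumerate(ref) if ch not in _GAPS),
                       default=None)
    if last_ref_col is None:
        raise ValueError(f"reference {reference_id!r} is all gaps")

    n = msa.n_records
    removed_gap, removed_tail, kept = [], [], []
    for i in range(msa.n_columns):
        if i > last_ref_col:
            removed_tail.append(i + 1)
            continue
        gap_frac = sum(ch in _GAPS for ch in msa.column(i)) / n
        if gap_frac > max_gap_fraction:
            removed_gap.append(i + 1)
        else:
            kept.append(i)

    records = [(rid, "".join(seq[i] for i in kept)) for rid, seq in msa.records]
    return MSA(records=records, trim_log={
        "removed_gap_columns": removed_gap,
        "removed_tail_columns": removed_tail,
        "max_gap_fraction": max_gap_fraction,
        "reference_id": reference_id,
    })


def column_profile(msa: MSA) -> ConservationProfile:
    """Count residues per column and derive modal/information statistics.

    Gaps are never modal; modal ties are broken alphabetically and flagged.
    """
    counts, gaps, modal, freq, info, ties = [], [], [], [], [], []
    for i in range(msa.n_columns):
        col = msa.column(i)
        c: dict[str, int] = {}
        g = 0
        for ch in col:
            if ch in _GAPS:
                g += 1
            else:
                c[ch] = c.get(ch, 0) + 1
        counts.append(c)
        gaps.append(g)
        if c:
            best = max(c.values())
            winners = sorted(aa for aa, k in c.items() if k == best)
            modal.append(winners[0])
            ties.append(len(winners) > 1)
            freq.append(best / msa.n_records)
        else:
            modal.append("-")
            ties.append(False)
            freq.append(0.0)
        n_res = sum(c.values())
        if n_res:
            p = np.array([k / n_res for k in c.values()])
            entropy = float(-(p * np.log2(p)).sum())
            info.append(max(0.0, np.log2(20) - entropy))
        else:
            info.append(0.0)
    return ConservationProfile(n_records=msa.n_records, counts=counts,
                               gap_counts=gaps, modal_residue=modal,
                               modal_frequency=freq, information_bits=info,
                               modal_ties=ties)


def threshold_counts(profile: ConservationProfile,
                     thresholds: tuple[float, ...] = (0.5, 0.8, 0.9),
                     absolute: bool = True):
    """Columns conserved above each modal-frequency threshold (strict >).

    Returns ``(counts_per_threshold, absolute_list)`` where the absolute list
    holds ``(column_1based, residue)`` for columns whose modal residue fills
    every record.
    """
    for t in thresholds:
        if not (0.0 < t < 1.0):
            raise ValueError(f"threshold {t} outside (0, 1)")
    counts = {t: sum(f > t for f in profile.modal_frequency) for t in thresholds}
    absolutes = []
    if absolute:
        for i in range(profile.n_columns):
            aa = profile.modal_residue[i]
            if aa != "-" and profile.counts[i].get(aa, 0) == profile.n_records:
                absolutes.append((i + 1, aa))
    return counts, absolutes


def map_column_to_reference(msa: MSA, reference_id: str):
    """Bidirectional map between alignment columns and reference positions.

    Returns ``(col_to_pos, pos_to_col)`` with 1-based indices; columns where
    the reference is gapped map to ``None``.
    """
    ref = msa.sequence(reference_id)
    col_to_pos: dict[int, int | None] = {}
    pos_to_col: dict[int, int] = {}
    pos = 0
    for i, ch in enumerate(ref, start=1):
        if ch in _GAPS:
            col_to_pos[i] = None
        else:
            pos += 1
            col_to_pos[i] = pos
            pos_to_col[pos] = i
    return col_to_pos, pos_to_col
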