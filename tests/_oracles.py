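"""Independent brute-force oracles used to validate the implementations.

These deliberately avoid the code paths they check: contacts by an O(n^2)
all-pairs distance scan, alignment scores by exhaustive enumeration of
monotone matchings, conservation counts by hand tallies.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from Bio.Align import substitution_matrices

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def brute_force_contacts(structure, chain_a: str, chain_b: str,
                         cutoff: float = 4.0):
    """Residue numbers of chain_a/chain_b with any heavy-atom pair < cutoff."""
    atoms_a = [a for a in structure.atoms if a.chain_id == chain_a and a.is_heavy]
    atoms_b = [a for a in structure.atoms if a.chain_id == chain_b and a.is_heavy]
    res_a, res_b = set(), set()
    for a in atoms_a:
        for b in atoms_b:
            d = np.linalg.norm(np.array(a.coordinates) - np.array(b.coordinates))
            if d < cutoff:
                res_a.add((a.residue_number, a.insertion_code))
                res_b.add((b.residue_number, b.insertion_code))
    return sorted(res_a), sorted(res_b)


def _gap_cost(length: int, gap_open: float, gap_extend: float) -> float:
    if length <= 0:
        return 0.0
    return gap_open + gap_extend * (length - 1)


def _matching_score(a: str, b: str, pairs, gap_open: float, gap_extend: float,
                    end_gaps: bool) -> float:
    """Best score of any alignment realising a monotone matching.

    Unmatched residues between (and, for global mode, around) matched pairs
    are grouped into one gap run per sequence per segment, which is optimal
    under affine costs.
    """
    score = sum(float(BLOSUM62[a[i], b[j]]) for i, j in pairs)
    bounds = [(-1, -1), *pairs, (len(a), len(b))]
    segments = list(zip(bounds[:-1], bounds[1:]))
    if not end_gaps:
        segments = segments[1:-1]
    for (i0, j0), (i1, j1) in segments:
        score -= _gap_cost(i1 - i0 - 1, gap_open, gap_extend)
        score -= _gap_cost(j1 - j0 - 1, gap_open, gap_extend)
    return score


def enumerate_alignment_score(a: str, b: str, mode: str = "global",
                              gap_open: float = 10.0,
                              gap_extend: float = 0.5) -> float:
    """Optimal affine-gap alignment score by exhaustive enumeration.

    Enumerates every monotone matching of positions of ``a`` to positions of
    ``b`` (all column sets of every size).  Feasible for sequences up to ~7
    residues.  Local mode takes the best non-empty matching with no end
    gaps; global mode includes end gaps and allows the empty matching.
    """
    n, m = len(a), len(b)
    best = None
    if mode == "global":
        best = _matching_score(a, b, [], gap_open, gap_extend, end_gaps=True)
    else:
        best = 0.0  # the empty local alignment scores zero
    for k in range(1, min(n, m) + 1):
        for rows in combinations(range(n), k):
            for cols in combinations(range(m), k):
                pairs = list(zip(rows, cols))
                s = _matching_score(a, b, pairs, gap_open, gap_extend,
                                    end_gaps=(mode == "global"))
                if best is None or s > best:
                    best = s
    return best


def tally_threshold_counts(msa, thresholds):
    """Hand tally of modal-frequency threshold counts for an MSA."""
    n = msa.n_records
    counts = {t: 0 for t in thresholds}
    absolutes = []
    for i in range(msa.n_columns):
        col = msa.column(i)
        tallies = {}
        for ch in col:
            if ch not in "-.~":
                tallies[ch] = tallies.get(ch, 0) + 1
        if not tallies:
            continue
        best = max(tallies.values())
        for t in thresholds:
            if best / n > t:
                counts[t] += 1
        if best == n:
            winners = sorted(aa for aa, c in tallies.items() if c == best)
            absolutes.append((i + 1, winners[0]))
    return counts, absolutes
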