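"""Seeded synthetic-data generators with machine-readable ground truth.

Every input class the analysis consumes can be generated here: toy two-chain
complexes with planted contact pairs, ortholog sequence pairs with controlled
region/background identity, alignments with planted per-column conservation,
two-state unfolding curves (chemical and thermal) and Gaussian-band
absorbance spectra.  Each generator returns a :class:`FixtureBundle` whose
``truth`` dict is sufficient to predict the downstream result without
re-running the generator, and is byte-reproducible for a fixed seed.

Defaults mirror the study conditions: alignments of 54 sequences by 120
columns, chemical unfolding at dG0 = 4.3 kcal/mol and m = 1.55 kcal/mol/M
over 0-7.2 M urea at 20 C, spectra sampled at 0.1 nm over 240-340 nm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np

from fe_s_conserv.msa import AMINO_ACIDS, MSA
from fe_s_conserv.spectra import Spectrum
from fe_s_conserv.stability import (
    DenaturationCurve,
    chemical_signal,
    thermal_signal,
)
from fe_s_conserv.structures import Atom, Structure

__all__ = [
    "FixtureBundle",
    "GENERATOR_VERSION",
    "make_toy_complex",
    "make_ortholog_pair",
    "make_msa",
    "simulate_unfolding",
    "simulate_spectrum",
    "write_bundle",
]

GENERATOR_VERSION = "1"

# Chemical preset: the urea-unfolding parameters reported for DdFXN.
CHEMICAL_PRESET = {"dG0": 4.3, "m": 1.55, "aN": 1.0, "bN": -0.02,
                   "aU": 0.25, "bU": -0.005, "T_K": 293.15}
# Thermal preset: plausible small-protein stability curve with the fixed
# dCp used in the thermal analysis.
THERMAL_PRESET = {"Tm": 330.0, "dHm": 60.0, "dCp": 1.6,
                  "aN": -10.0, "bN": 0.01, "aU": -2.0, "bU": 0.005}


@dataclass
class FixtureBundle:
    """A generated payload plus the planted parameters that explain it."""

    kind: str
    payload: object
    truth: dict
    seed: int
    generator_version: str = GENERATOR_VERSION
    files: dict[str, str] = field(default_factory=dict)  # name -> text content


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(int(seed))


# --- toy complex ----------------------------------------------------------

def _pdb_atom_line(serial: int, name: str, resname: str, chain: str,
                   resnum: int, xyz: Sequence[float], element: str) -> str:
    return (f"ATOM  {serial:>5} {name:<4}{resname:>3} {chain}{resnum:>4}    "
            f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}  1.00  0.00"
            f"          {element:>2}")


def make_toy_complex(n_res_a: int, n_res_b: int, n_contacts: int,
                     seed: int) -> FixtureBundle:
    """Two pseudo-chains with exactly ``n_contacts`` residue pairs in contact.

    Residues are CA+CB pairs on a 10-A lattice along x.  Chain B residues
    chosen as contacts sit opposite their chain-A partner with a CB-CB
    separation of ~3.4 A (< 4); all other inter-chain residue pairs are
    > 6 A apart.  The truth lists the planted (resnum_a, resnum_b) pairs.
    """
    if n_contacts > min(n_res_a, n_res_b):
        raise ValueError("cannot plant more contacts than residues per chain")
    rng = _rng(seed)
    k = min(n_res_a, n_res_b)
    contact_idx = sorted(rng.choice(k, size=n_contacts, replace=False).tolist())
    contact_set = set(contact_idx)

    atoms: list[Atom] = []

    def add_residue(chain: str, resnum: int, ca, cb) -> None:
        atoms.append(Atom(chain, resnum, "", "GLY" if chain == "A" else "ALA",
                          "CA", "C", 1.0, tuple(ca)))
        atoms.append(Atom(chain, resnum, "", "GLY" if chain == "A" else "ALA",
                          "CB", "C", 1.0, tuple(cb)))

    jitter = lambda: float(rng.uniform(-0.05, 0.05))  # noqa: E731
    for i in range(n_res_a):
        x = 10.0 * i
        add_residue("A", i + 1, (x + jitter(), 0.0, 0.0), (x + jitter(), 1.5, 0.0))
    for j in range(n_res_b):
        x = 10.0 * j
        if j in contact_set:
            # CB at y ~ 4.9 -> CB-CB distance ~ 3.4 A, CA-CA ~ 6.5 A
            add_residue("B", j + 1, (x + jitter(), 6.5, 0.0),
                        (x + jitter(), 4.9, 0.0))
        else:
            add_residue("B", j + 1, (x + jitter(), 20.0, 0.0),
                        (x + jitter(), 18.5, 0.0))

    structure = Structure(atoms=atoms, source=f"toy_complex(seed={seed})",
                          format="synthetic")
    lines = []
    for n, a in enumerate(atoms, start=1):
        lines.append(_pdb_atom_line(n, a.atom_name, a.residue_name, a.chain_id,
                                    a.residue_number, a.coordinates, a.element))
    lines.append("END")
    pdb_text = "\n".join(lines) + "\n"
    truth = {
        "contact_pairs": [[i + 1, i + 1] for i in contact_idx],
        "contact_residues_a": [i + 1 for i in contact_idx],
        "contact_residues_b": [i + 1 for i in contact_idx],
        "n_res_a": n_res_a, "n_res_b": n_res_b,
    }
    return FixtureBundle("complex", structure, truth, seed,
                         files={"complex.pdb": pdb_text})


# --- ortholog pair --------------------------------------------------------

def _mutate(rng: np.random.Generator, aa: str) -> str:
    choices = [x for x in AMINO_ACIDS if x != aa]
    return choices[int(rng.integers(len(choices)))]


def make_ortholog_pair(length: int, region: Sequence[int],
                       region_identity: float, background_identity: float,
                       seed: int) -> FixtureBundle:
    """A sequence and a derived ortholog with planted identity levels.

    ``region`` is a list of 1-based positions; ``round(identity * n)``
    positions of the region (and likewise of the background) are kept
    identical, the rest are substituted with a different residue.  The truth
    records the exact identical-position sets.
    """
    for f in (region_identity, background_identity):
        if not (0.0 <= f <= 1.0):
            raise ValueError("identity fractions must be in [0, 1]")
    region = sorted(set(int(p) for p in region))
    if region and (region[0] < 1 or region[-1] > length):
        raise ValueError("region positions outside sequence")
    rng = _rng(seed)
    seq_a = "".join(AMINO_ACIDS[int(i)] for i in rng.integers(0, 20, size=length))
    background = [p for p in range(1, length + 1) if p not in set(region)]

    def pick_identical(positions: list[int], frac: float) -> set[int]:
        n_keep = int(round(frac * len(positions)))
        if not positions:
            return set()
        keep = rng.choice(len(positions), size=n_keep, replace=False)
        return {positions[i] for i in keep}

    id_region = pick_identical(region, region_identity)
    id_background = pick_identical(background, background_identity)
    identical = id_region | id_background
    seq_b = "".join(ch if p in identical else _mutate(rng, ch)
                    for p, ch in enumerate(seq_a, start=1))
    fasta = (f">seqA synthetic ortholog pair seed={seed}\n{seq_a}\n"
             f">seqB synthetic ortholog pair seed={seed}\n{seq_b}\n")
    truth = {
        "region": region,
        "identical_region_positions": sorted(id_region),
        "identical_background_positions": sorted(id_background),
        "region_identity_pct": 100.0 * len(id_region) / len(region) if region else 0.0,
        "overall_identity_pct": 100.0 * len(identical) / length,
    }
    return FixtureBundle("orthologs", (seq_a, seq_b), truth, seed,
                         files={"pair.fasta": fasta})


# --- MSA ------------------------------------------------------------------

def make_msa(n_seqs: int = 54, n_cols: int = 120,
             modal_freqs: Sequence[float] | None = None,
             gap_cols: Sequence[int] = (), seed: int = 0) -> FixtureBundle:
    """An alignment with planted per-column modal frequencies.

    Column ``i`` gets its modal residue in ``round(freq_i * n_seqs)`` rows;
    the remaining rows are filled with other residues, each kept strictly
    rarer than the modal one.  Columns listed in ``gap_cols`` (1-based) are
    instead given gaps in 60% of rows (for trimming tests).  The truth holds
    exact modal counts per column.
    """
    if modal_freqs is None:
        modal_freqs = [0.6] * n_cols
    if len(modal_freqs) != n_cols:
        raise ValueError("need one modal frequency per column")
    for f in modal_freqs:
        if not (0.0 < f <= 1.0):
            raise ValueError("modal frequencies must be in (0, 1]")
    gap_cols = set(int(c) for c in gap_cols)
    rng = _rng(seed)
    grid = np.empty((n_seqs, n_cols), dtype="<U1")
    modal_counts: list[int] = []
    modal_residues: list[str] = []
    for j in range(n_cols):
        if (j + 1) in gap_cols:
            n_gap = int(np.ceil(0.6 * n_seqs))
            gap_rows = set(rng.choice(n_seqs, size=n_gap, replace=False).tolist())
            aa = AMINO_ACIDS[int(rng.integers(20))]
            for i in range(n_seqs):
                grid[i, j] = "-" if i in gap_rows else aa
            modal_counts.append(n_seqs - n_gap)
            modal_residues.append(aa)
            continue
        k = int(round(modal_freqs[j] * n_seqs))
        k = max(1, min(n_seqs, k))
        rest = n_seqs - k
        others = [x for x in AMINO_ACIDS]
        modal_aa = others.pop(int(rng.integers(20)))
        if rest and int(np.ceil(rest / len(others))) >= k:
            raise ValueError(f"column {j + 1}: modal frequency {modal_freqs[j]} "
                             "too low to keep the modal residue unique")
        rows = rng.permutation(n_seqs)
        for r in rows[:k]:
            grid[r, j] = modal_aa
        # round-robin fill keeps every other residue strictly below k
        for idx, r in enumerate(rows[k:]):
            grid[r, j] = others[idx % len(others)]
        modal_counts.append(k)
        modal_residues.append(modal_aa)

    records = [(f"sp{i:03d}", "".join(grid[i])) for i in range(n_seqs)]
    msa = MSA(records=records)
    fasta = "".join(f">{rid}\n{seq}\n" for rid, seq in records)
    truth = {
        "modal_counts": modal_counts,
        "modal_frequencies": [c / n_seqs for c in modal_counts],
        "modal_residues": modal_residues,
        "gap_cols": sorted(gap_cols),
        "n_seqs": n_seqs, "n_cols": n_cols,
    }
    return FixtureBundle("msa", msa, truth, seed, files={"msa.fasta": fasta})


# --- unfolding curves -----------------------------------------------------

def simulate_unfolding(mode: Literal["chemical", "thermal"] = "chemical",
                       params: dict | None = None, n_points: int = 36,
                       noise_sd: float = 0.0, seed: int = 0) -> FixtureBundle:
    """Forward-model a two-state unfolding curve plus Gaussian noise.

    ``noise_sd`` is expressed as a fraction of the clean signal span.
    Chemical default: 0-7.2 M at the DdFXN preset (dG0 4.3, m 1.55, 20 C);
    thermal default: 293-368 K at Tm 330 K, dHm 60, dCp 1.6.
    """
    rng = _rng(seed)
    if mode == "chemical":
        p = dict(CHEMICAL_PRESET)
        p.update(params or {})
        x = np.linspace(0.0, 7.2, n_points)
        y = chemical_signal(x, p["dG0"], p["m"], p["aN"], p["bN"],
                            p["aU"], p["bU"], T_K=p["T_K"])
        curve_kwargs = {"mode": "chemical", "temperature_K": p["T_K"]}
    elif mode == "thermal":
        p = dict(THERMAL_PRESET)
        p.update(params or {})
        x = np.linspace(293.0, 368.0, n_points)
        y = thermal_signal(x, p["Tm"], p["dHm"], p["aN"], p["bN"],
                           p["aU"], p["bU"], p["dCp"])
        curve_kwargs = {"mode": "thermal"}
    else:
        raise ValueError(f"unknown mode {mode!r}")
    span = float(y.max() - y.min())
    sigma = noise_sd * span
    y_noisy = y + rng.normal(0.0, sigma, size=y.shape) if sigma > 0 else y
    curve = DenaturationCurve(x=x, y=y_noisy, **curve_kwargs)
    csv = "x,y\n" + "".join(f"{a:.6f},{b:.8f}\n" for a, b in zip(x, y_noisy))
    truth = {**p, "noise_sd_fraction": noise_sd, "signal_span": span,
             "n_points": n_points, "mode": mode}
    return FixtureBundle("curve", curve, truth, seed,
                         files={f"{mode}_curve.csv": csv})


# --- spectra --------------------------------------------------------------

def simulate_spectrum(bands: Sequence[tuple[float, float, float]],
                      range_nm: tuple[float, float] = (240.0, 340.0),
                      step: float = 0.1, noise_sd: float = 0.0,
                      seed: int = 0) -> FixtureBundle:
    """Sum-of-Gaussians absorbance spectrum plus optional noise.

    ``bands`` are (center_nm, sigma_nm, amplitude) triples; all centers must
    lie inside ``range_nm``.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    lo, hi = range_nm
    wl = np.arange(lo, hi + 0.5 * step, step)
    v = np.zeros_like(wl)
    for center, sigma, amp in bands:
        if not (lo <= center <= hi):
            raise ValueError(f"band center {center} outside range {range_nm}")
        v += amp * np.exp(-0.5 * ((wl - center) / sigma) ** 2)
    rng = _rng(seed)
    if noise_sd > 0:
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    spectrum = Spectrum(wavelengths=wl, values=v,
                        metadata={"seed": seed, "bands": list(bands)})
    csv = "wavelength_nm,value\n" + "".join(
        f"{a:.4f},{b:.10f}\n" for a, b in zip(wl, v))
    truth = {"bands": [list(b) for b in bands], "range_nm": list(range_nm),
             "step": step, "noise_sd": noise_sd}
    return FixtureBundle("spectrum", spectrum, truth, seed,
                         files={"spectrum.csv": csv})


def write_bundle(bundle: FixtureBundle, out_dir: str | Path) -> list[Path]:
    """Write a bundle's payload files and truth JSON into a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, text in bundle.files.items():
        p = out / name
        p.write_text(text)
        written.append(p)
    meta = {"kind": bundle.kind, "seed": bundle.seed,
            "generator_version": bundle.generator_version,
            "truth": bundle.truth}
    p = out / f"{bundle.kind}_truth.json"
    p.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    written.append(p)
    return written
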