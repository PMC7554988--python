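"""Two-state unfolding thermodynamics and related sequence/biophysics math.

Chemical (urea) unfolding follows the linear extrapolation model: the
unfolding free energy is linear in denaturant, dG(c) = dG0 - m*c, and the
observed signal is the population-weighted average of sloped native and
unfolded baselines,

    y(c) = [(aN + bN*c) + (aU + bU*c) * K(c)] / (1 + K(c)),
    K(c) = exp(-(dG0 - m*c) / (R*T)).

Thermal unfolding uses the Gibbs-Helmholtz stability curve with a fixed
heat-capacity change,

    dG(T) = dHm*(1 - T/Tm) + dCp*[(T - Tm) - T*ln(T/Tm)],

again with linear baselines in T.  Energies are kcal/mol throughout and
R = 1.9872e-3 kcal/(mol*K).

Also here: the Myers chain-length correlations (dASA -> urea m-value and
dCp), cross-homolog correlation of alanine-scan ddG values partitioned by
conservation class, sequence-derived constants (average mass, epsilon_280,
isoelectric point) and size-exclusion mass calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "R_KCAL",
    "DenaturationCurve",
    "TwoStateFitResult",
    "ThermalFitResult",
    "SeqProperties",
    "fit_chemical_unfolding",
    "fit_thermal_unfolding",
    "chemical_signal",
    "thermal_signal",
    "gibbs_helmholtz_dG",
    "myers_predict",
    "ddg_correlation",
    "read_ddg_table",
    "sequence_properties",
    "sec_infer_mass",
]

R_KCAL = 1.9872e-3  # kcal mol^-1 K^-1

DDG_CLASSES = ("conserved", "non_conserved", "disease")


@dataclass
class DenaturationCurve:
    """Signal vs denaturant molarity (mode="chemical") or Kelvin ("thermal")."""

    x: np.ndarray
    y: np.ndarray
    mode: Literal["chemical", "thermal"]
    temperature_K: float = 293.15  # bath temperature for chemical curves
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be equal-length 1-D arrays")
        if len(self.x) < 8:
            raise ValueError("need at least 8 points to fit a two-state model")
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x must be strictly increasing")


@dataclass
class TwoStateFitResult:
    """Linear-extrapolation fit of a chemical unfolding curve."""

    dG0: float                 # kcal/mol at zero denaturant
    m: float                   # kcal/mol/M
    native_intercept: float
    native_slope: float
    unfolded_intercept: float
    unfolded_slope: float
    temperature_K: float
    se: dict = field(default_factory=dict)
    covariance: np.ndarray | None = None
    rss: float = float("nan")
    residuals: np.ndarray | None = None

    @property
    def Cm(self) -> float:
        """Transition midpoint (M), dG0/m."""
        return self.dG0 / self.m

    def fraction_unfolded(self, c) -> np.ndarray:
        K = np.exp(-(self.dG0 - self.m * np.asarray(c, float))
                   / (R_KCAL * self.temperature_K))
        return K / (1.0 + K)


@dataclass
class ThermalFitResult:
    """Gibbs-Helmholtz fit of a thermal unfolding curve (dCp fixed)."""

    Tm: float                  # K
    dHm: float                 # kcal/mol at Tm
    dCp: float                 # kcal/mol/K, fixed input
    native_intercept: float
    native_slope: float
    unfolded_intercept: float
    unfolded_slope: float
    Tref_K: float
    dG_at_Tref: float
    se: dict = field(default_factory=dict)
    covariance: np.ndarray | None = None
    rss: float = float("nan")
    residuals: np.ndarray | None = None

    def dG(self, T) -> np.ndarray:
        return gibbs_helmholtz_dG(np.asarray(T, float), self.Tm, self.dHm, self.dCp)


def chemical_signal(c, dG0, m, aN, bN, aU, bU, T_K=293.15):
    """Observed signal of the two-state linear-extrapolation model."""
    c = np.asarray(c, dtype=float)
    K = np.exp(-(dG0 - m * c) / (R_KCAL * T_K))
    return ((aN + bN * c) + (aU + bU * c) * K) / (1.0 + K)


def gibbs_helmholtz_dG(T, Tm, dHm, dCp):
    """Stability curve dG(T), kcal/mol; zero at T = Tm by construction."""
    T = np.asarray(T, dtype=float)
    return dHm * (1.0 - T / Tm) + dCp * ((T - Tm) - T * np.log(T / Tm))


def thermal_signal(T, Tm, dHm, aN, bN, aU, bU, dCp):
    T = np.asarray(T, dtype=float)
    K = np.exp(-gibbs_helmholtz_dG(T, Tm, dHm, dCp) / (R_KCAL * T))
    return ((aN + bN * T) + (aU + bU * T) * K) / (1.0 + K)


def _plateau_guess(x: np.ndarray, y: np.ndarray, frac: float = 0.2):
    """Linear fits to the first/last ``frac`` of points -> baseline guesses."""
    k = max(2, int(round(frac * len(x))))
    bN, aN = np.polyfit(x[:k], y[:k], 1)
    bU, aU = np.polyfit(x[-k:], y[-k:], 1)
    return aN, bN, aU, bU


def _midpoint_guess(x: np.ndarray, y: np.ndarray) -> float:
    """x of steepest signal change (finite differences on a light smooth)."""
    ys = np.convolve(y, np.ones(3) / 3.0, mode="same") if len(y) >= 9 else y
    dy = np.gradient(ys, x)
    return float(x[np.argmax(np.abs(dy))])


def _check_transition(x, y, aN, bN, aU, bU) -> None:
    span = abs((aU + bU * x.mean()) - (aN + bN * x.mean()))
    if span < 1e-3 * (np.abs(y).max() + 1e-12):
        raise RuntimeError("no unfolding transition detected: native and "
                           "unfolded baselines are indistinguishable")


def fit_chemical_unfolding(curve: DenaturationCurve,
                           T_K: float | None = None) -> TwoStateFitResult:
    """Nonlinear least-squares fit of the six-parameter LEM model.

    Free parameters: dG0, m and both sloped baselines.  Initial guesses come
    from plateau linear fits and the point of steepest signal change; the
    transition temperature defaults to the curve's bath temperature.
    """
    if curve.mode != "chemical":
        raise ValueError("curve is not in denaturant-molarity mode")
    T = float(T_K if T_K is not None else curve.temperature_K)
    x, y = curve.x, curve.y
    aN, bN, aU, bU = _plateau_guess(x, y)
    _check_transition(x, y, aN, bN, aU, bU)
    Cm0 = _midpoint_guess(x, y)
    if Cm0 <= x[0] or Cm0 >= x[-1]:
        Cm0 = float(0.5 * (x[0] + x[-1]))
    m0 = 1.5  # kcal/mol/M, typical small-protein cooperativity
    p0 = [m0 * Cm0, m0, aN, bN, aU, bU]

    def model(c, dG0, m, aN, bN, aU, bU):
        return chemical_signal(c, dG0, m, aN, bN, aU, bU, T_K=T)

    try:
        popt, pcov = optimize.curve_fit(model, x, y, p0=p0, maxfev=20000,
                                        xtol=1e-14, ftol=1e-14)
    except RuntimeError as exc:
        raise RuntimeError(f"chemical unfolding fit did not converge: {exc}") from exc
    resid = y - model(x, *popt)
    names = ["dG0", "m", "aN", "bN", "aU", "bU"]
    se = dict(zip(names, np.sqrt(np.clip(np.diag(pcov), 0, None))))
    return TwoStateFitResult(
        dG0=popt[0], m=popt[1],
        native_intercept=popt[2], native_slope=popt[3],
        unfolded_intercept=popt[4], unfolded_slope=popt[5],
        temperature_K=T, se=se, covariance=pcov,
        rss=float(resid @ resid), residuals=resid,
    )


def fit_thermal_unfolding(curve: DenaturationCurve, dCp_fixed: float,
                          Tref_K: float = 293.15) -> ThermalFitResult:
    """Fit the two-state thermal model with fixed dCp; report dG(Tref).

    Free parameters: Tm, dHm and both sloped baselines.
    """
    if curve.mode != "thermal":
        raise ValueError("curve is not in temperature mode")
    if dCp_fixed <= 0:
        raise ValueError("dCp must be positive")
    x, y = curve.x, curve.y
    aN, bN, aU, bU = _plateau_guess(x, y)
    _check_transition(x, y, aN, bN, aU, bU)
    Tm0 = _midpoint_guess(x, y)
    if Tm0 <= x[0] or Tm0 >= x[-1]:
        Tm0 = float(0.5 * (x[0] + x[-1]))
    p0 = [Tm0, 60.0, aN, bN, aU, bU]

    def model(T, Tm, dHm, aN, bN, aU, bU):
        return thermal_signal(T, Tm, dHm, aN, bN, aU, bU, dCp_fixed)

    try:
        popt, pcov = optimize.curve_fit(model, x, y, p0=p0, maxfev=20000,
                                        xtol=1e-14, ftol=1e-14)
    except RuntimeError as exc:
        raise RuntimeError(f"thermal unfolding fit did not converge: {exc}") from exc
    resid = y - model(x, *popt)
    names = ["Tm", "dHm", "aN", "bN", "aU", "bU"]
    se = dict(zip(names, np.sqrt(np.clip(np.diag(pcov), 0, None))))
    return ThermalFitResult(
        Tm=popt[0], dHm=popt[1], dCp=dCp_fixed,
        native_intercept=popt[2], native_slope=popt[3],
        unfolded_intercept=popt[4], unfolded_slope=popt[5],
        Tref_K=Tref_K,
        dG_at_Tref=float(gibbs_helmholtz_dG(Tref_K, popt[0], popt[1], dCp_fixed)),
        se=se, covariance=pcov,
        rss=float(resid @ resid), residuals=resid,
    )


def myers_predict(n_residues: int) -> dict[str, float]:
    """Chain-length predictions of dASA, urea m-value and dCp.

    Empirical correlations (Myers, Pace & Scholtz 1995):
    dASA = -907 + 93*n (A^2); m_urea = (374 + 0.11*dASA)/1000 kcal/mol/M;
    dCp = (-251 + 0.19*dASA)/1000 kcal/mol/K.
    """
    n = int(n_residues)
    if n < 20:
        raise ValueError("correlation calibrated for proteins of >= 20 residues")
    dasa = -907.0 + 93.0 * n
    return {
        "deltaASA_A2": dasa,
        "m_urea_kcal_per_mol_M": (374.0 + 0.11 * dasa) / 1000.0,
        "dCp_kcal_per_mol_K": (-251.0 + 0.19 * dasa) / 1000.0,
    }


def read_ddg_table(path) -> pd.DataFrame:
    """Read a per-position ddG table: position_a, position_b, ddg_a, ddg_b, class."""
    df = pd.read_csv(path)
    required = {"position_a", "position_b", "ddg_a", "ddg_b", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ddG table missing columns {sorted(missing)}")
    bad = set(df["class"]) - set(DDG_CLASSES)
    if bad:
        raise ValueError(f"unknown conservation classes {sorted(bad)}; "
                         f"expected {DDG_CLASSES}")
    return df


def ddg_correlation(table: pd.DataFrame,
                    classes: Sequence[str] = ("all",) + DDG_CLASSES) -> pd.DataFrame:
    """Pearson correlation and least-squares line of ddg_b vs ddg_a per class.

    The class "all" pools every row.  Classes with fewer than 3 rows or with
    degenerate variance yield NaN statistics (reported, not raised).
    """
    rows = []
    for cls in classes:
        sub = table if cls == "all" else table[table["class"] == cls]
        n = len(sub)
        if n < 3 or sub["ddg_a"].nunique() < 2 or sub["ddg_b"].nunique() < 2:
            rows.append({"class": cls, "n": n, "pearson_r": np.nan,
                         "slope": np.nan, "intercept": np.nan})
            continue
        lr = stats.linregress(sub["ddg_a"], sub["ddg_b"])
        rows.append({"class": cls, "n": n, "pearson_r": lr.rvalue,
                     "slope": lr.slope, "intercept": lr.intercept})
    return pd.DataFrame(rows)


# --- sequence-derived physical constants ---------------------------------

# Average residue masses (Da), i.e. amino acid minus one water.
RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.0153

# Extinction contributions at 280 nm (M^-1 cm^-1).
EPS_TRP, EPS_TYR, EPS_CYSTINE = 5500.0, 1490.0, 125.0

# Side-chain / termini pKa values used for the isoelectric point.
PKA = {"D": 3.9, "E": 4.3, "C": 8.3, "Y": 10.1, "H": 6.0,
       "K": 10.5, "R": 12.0, "N_term": 9.0, "C_term": 2.0}


@dataclass
class SeqProperties:
    average_mass: float       # Da
    epsilon280: float         # M^-1 cm^-1
    pI: float
    composition: dict[str, int]
    n_residues: int


def extinction_280(n_trp: int, n_tyr: int, n_cystine: int = 0) -> float:
    """epsilon_280 = 5500*nTrp + 1490*nTyr + 125*n_cystine (M^-1 cm^-1)."""
    return EPS_TRP * n_trp + EPS_TYR * n_tyr + EPS_CYSTINE * n_cystine


def _net_charge(pH: float, comp: dict[str, int]) -> float:
    pos = 10.0 ** -pH / (10.0 ** -pH + 10.0 ** -PKA["N_term"])
    for aa, pka in (("K", PKA["K"]), ("R", PKA["R"]), ("H", PKA["H"])):
        pos += comp.get(aa, 0) * 10.0 ** -pH / (10.0 ** -pH + 10.0 ** -pka)
    neg = 10.0 ** -PKA["C_term"] / (10.0 ** -pH + 10.0 ** -PKA["C_term"])
    for aa, pka in (("D", PKA["D"]), ("E", PKA["E"]),
                    ("C", PKA["C"]), ("Y", PKA["Y"])):
        neg += comp.get(aa, 0) * 10.0 ** -pka / (10.0 ** -pH + 10.0 ** -pka)
    return pos - neg


def sequence_properties(sequence: str, n_cystine: int = 0) -> SeqProperties:
    """Average mass, epsilon_280 and pI from an amino-acid sequence.

    Mass is the sum of average residue masses plus one water.  The pI is the
    bisection root of the Henderson-Hasselbalch net-charge equation with the
    module's documented pKa set; treat it as indicative (+-0.2 pH units
    across published pKa sets).
    """
    seq = sequence.upper().strip()
    bad = sorted(set(seq) - set(RESIDUE_MASS))
    if bad:
        raise ValueError(f"nonstandard residue letter(s) {bad}")
    comp = {aa: seq.count(aa) for aa in RESIDUE_MASS if aa in seq}
    if 2 * n_cystine > comp.get("C", 0):
        raise ValueError("more cystine bridges than cysteine pairs")
    mass = sum(RESIDUE_MASS[ch] for ch in seq) + WATER_MASS
    eps = extinction_280(comp.get("W", 0), comp.get("Y", 0), n_cystine)
    lo, hi = 0.0, 14.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if _net_charge(mid, comp) > 0:
            lo = mid
        else:
            hi = mid
    return SeqProperties(average_mass=mass, epsilon280=eps,
                         pI=round(0.5 * (lo + hi), 2),
                         composition=comp, n_residues=len(seq))


def sec_infer_mass(standards: Iterable[tuple[float, float]],
                   unknown_ve: float) -> dict:
    """Infer a molecular mass from a size-exclusion calibration curve.

    ``standards`` are (mass_kDa, elution_volume) pairs; the calibration is a
    linear fit of log10(mass) on elution volume.  Returns the inferred mass
    with a propagated standard error and flags extrapolation beyond the
    standards' volume range.
    """
    st = sorted(standards, key=lambda p: p[1])
    if len(st) < 3:
        raise ValueError("need at least 3 calibration standards")
    masses = np.array([m for m, _ in st], dtype=float)
    ve = np.array([v for _, v in st], dtype=float)
    if np.any(masses <= 0):
        raise ValueError("standard masses must be positive")
    if np.any(np.diff(masses) >= 0):  # sorted by Ve: mass should fall as Ve rises
        warnings.warn("standards are not monotone in elution volume", stacklevel=2)
    lr = stats.linregress(ve, np.log10(masses))
    log_mass = lr.slope * unknown_ve + lr.intercept
    n = len(ve)
    ve_bar = ve.mean()
    sxx = float(((ve - ve_bar) ** 2).sum())
    resid = np.log10(masses) - (lr.slope * ve + lr.intercept)
    s2 = float(resid @ resid) / max(n - 2, 1)
    se_log = np.sqrt(s2 * (1.0 / n + (unknown_ve - ve_bar) ** 2 / sxx)) if sxx else 0.0
    mass = 10.0 ** log_mass
    return {
        "mass_kDa": float(mass),
        "se_kDa": float(mass * np.log(10) * se_log),
        "slope": float(lr.slope), "intercept": float(lr.intercept),
        "r_value": float(lr.rvalue),
        "extrapolated": bool(unknown_ve < ve.min() or unknown_ve > ve.max()),
    }
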