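# Methods

This note documents the models, conventions and design choices behind each
module, what the synthetic generators do and do not emulate, and the known
limitations. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Contact interfaces

A residue of chain A is an interface residue with respect to a partner
(chain or named ligand) when any of its heavy atoms lies at Euclidean
distance strictly below the cutoff (default 4.0 Å) from any heavy atom of
the partner. Conventions:

- **Strict `<`**, so a pair at exactly the cutoff is excluded; interfaces
  are therefore monotone in the cutoff.
- **Heavy atoms only** by default. Cryo-EM and most X-ray models carry no
  reliable hydrogens; including them would make results model-dependent.
  `heavy_only=False` is available for structures with trusted hydrogens.
- **Waters are dropped at parse time**; other hetero groups (cofactors such
  as pyridoxal phosphate, metals) are kept, flagged, and participate in
  contact searches only when addressed explicitly by a ligand selector
  (`"CHAIN:RESNAME"` or `":RESNAME"`). Cofactor interfaces are first-class:
  the conservation of a PLP-binding pocket is as informative as a
  protein–protein interface.
- **Altlocs** resolve to the highest-occupancy conformer, ties to the
  alphabetically first altloc id, so parsing is deterministic.
- In a homodimeric complex the two protomers are not equivalent once
  numbering or partner chains differ; the chain used for each role is a
  required configuration entry of the pipeline, never inferred.

Neighbour search uses a k-d tree; correctness is checked against an O(n²)
all-pairs oracle on generated complexes with planted contacts.

## Solvent accessibility

Shrake–Rupley sampling: each heavy atom's sphere (van der Waals radius +
probe, default 1.4 Å) is covered with a golden-spiral lattice of
`n_points` (default 960) quasi-uniform points; the accessible fraction is
the share of points strictly outside every neighbour's probe-inflated
sphere. Numerical choices:

- Boundary points count as buried; exactly coincident duplicate atoms are
  degenerate, and the lower-index copy keeps the shared surface (so two
  stacked atoms report one sphere's area, not two or zero).
- The radius table is a single documented Bondi-style set (C 1.70, N 1.55,
  O 1.52, S 1.80, P 1.80 Å, plus common ions); an element without a radius
  is an error listing the offending atoms, never a silent default.
- Quadrature error at 960 points is below 1% for an isolated sphere
  (checked against 4π(r+probe)²) and the total changes by <0.5% when the
  point count doubles on test fixtures.
- Relative accessibility divides by the theoretical residue maxima of the
  Tien et al. (2013) Gly-X-Gly set, named in the call so other tables can
  be added without changing results silently.

`chain_subset` restricts both the atoms evaluated and the occluders, which
is how "isolated chain" vs "in complex" accessibility is defined; the
per-residue difference of the two runs is the burial-on-binding signal.
The implementation is cross-checked in the tests against an independent
Shrake–Rupley implementation (biotite) on the same coordinates.

## Pairwise homolog comparison

Alignment is optimal affine-gap dynamic programming (Biopython's
PairwiseAligner) over BLOSUM62. A gap of length k costs
`gap_open + gap_extend·(k−1)`. Two shipped parameterisations:

- **local, 11/1** — the reproduction mode for identity/similarity figures
  derived from BLASTp-style output;
- **global, 10/0.5** — for position mapping, where every residue should be
  assigned a column.

Identity = identical columns / alignment length (gap columns included in
the denominator, the BLAST convention). Similarity = columns with positive
BLOSUM62 score. Coverage = aligned span of the query / query length.

Region identity uses **all region positions as denominator**: a region
position aligned to a gap, or outside a local alignment's span, counts as
non-identical. The published alternative (aligned positions only) can only
raise the value; the conservative choice is recorded in every report so
numbers are self-describing. Exact BLAST parameterisation (e.g.
composition-based statistics) cannot be recovered from printed tables;
reproductions of published identities should therefore be read with a
±1-point tolerance.

The DP score is validated against exhaustive enumeration of all monotone
matchings for sequences up to 7 residues, for both modes. The degenerate
optimum of local alignment (the empty alignment, score 0) is returned
explicitly rather than raising.

## Alignment conservation

Curation: columns whose gap fraction exceeds `max_gap_fraction` (default
0.5, i.e. "most sequences gapped") are removed, then all columns beyond
the last residue-bearing column of the named reference. Trimming is
idempotent and logs removed column indices.

Conservation of a column is the **modal amino-acid frequency with the full
record count as denominator** — gaps count against conservation and are
never modal; "conserved in more than X%" is a strict inequality. The
alternative denominator (non-gap records only) is intentionally *not* the
default; switching it silently would inflate counts for gappy columns.
Modal ties break alphabetically and are flagged. Information content is
log₂20 minus the Shannon entropy of the amino-acid distribution (gaps
excluded from the distribution), giving 0 bits for a uniform column and
log₂20 ≈ 4.32 bits for an invariant one; the per-column count/frequency/
bits matrix is exportable for any logo renderer.

## Unfolding thermodynamics

Energies are kcal·mol⁻¹ throughout; R = 1.9872×10⁻³ kcal·mol⁻¹·K⁻¹.
Chemical fits default to 293.15 K (20 °C, the isothermal condition of the
urea experiments emulated here).

**Chemical (LEM)**: six free parameters — ΔG°, m and two sloped baselines
(fluorescence baselines of real curves are sloped). Initial guesses come
from linear fits to the outer 20% of points and the point of steepest
signal change; the optimiser is Levenberg–Marquardt least squares with
tight tolerances. The midpoint Cm = ΔG°/m is derived, never fitted.
Parameter standard errors come from the asymptotic covariance; on 2%-noise
replicates the 95% intervals cover the truth at the nominal rate (checked:
coverage within [90%, 99%] over 500 seeds).

**Thermal (Gibbs–Helmholtz)**: ΔCp is a *fixed input*, not a fitted
parameter — with data spanning a single transition it is barely
identifiable and the convention here mirrors standard practice of fixing
it to a chain-length-based estimate. Free parameters: Tm, ΔHm and the two
baselines. ΔG(T_ref) is recomputed from the fitted (Tm, ΔHm, ΔCp) via the
stability curve; ΔG(Tm) = 0 by construction. A sensitivity scan over a
ΔCp grid is a re-fit loop the caller controls, not a hidden option. Only a
single heating ramp is fitted; refolding-scan data are not pooled.

**Myers correlations**: ΔASA = −907 + 93·n (Å²), m_urea = (374 +
0.11·ΔASA)/1000, ΔCp = (−251 + 0.19·ΔASA)/1000. The coefficients are from
the published correlation; the package pins their outputs at n = 116 in
tests to guard against transcription errors.

**Sequence constants**: average mass is the sum of average residue masses
plus one water; ε₂₈₀ = 5500·nTrp + 1490·nTyr + 125·n_cystine; pI is the
bisection root of the Henderson–Hasselbalch net-charge equation over a
single documented pKa set (D 3.9, E 4.3, C 8.3, Y 10.1, H 6.0, K 10.5,
R 12.0, N-term 9.0, C-term 2.0). pI shifts by roughly ±0.2 units across
published pKa sets, so it is reported as indicative and is not pinned in
tests.

**ΔΔG correlation**: alanine-scanning ΔΔG tables are *inputs* (CSV with
`position_a, position_b, ddg_a, ddg_b, class`); the energy calculations
that produce them are out of scope. Per class (all / conserved /
non_conserved / disease) the module reports n, Pearson r and the
least-squares line; degenerate variance yields NaN rather than an error,
because a report row is more useful than an exception in a batch run.

**SEC calibration** is a linear fit of log₁₀(mass) on elution volume with
first-order error propagation to the inferred mass; extrapolation beyond
the standards is flagged, non-monotone standards warn.

## Derivative spectroscopy

Savitzky–Golay filtering with default window 11 points and polynomial
order 5. At the 0.1-nm sampling the analysis emulates, an 11-point window
is 1.1 nm — wide enough to suppress noise, narrow relative to aromatic
band widths (σ ≈ 2–4 nm), and the order-5 polynomial reproduces any
quartic exactly, so fourth derivatives of smooth bands are unbiased. The
half-window edges are NaN-marked rather than zero-filled. Peak positions
are refined below the sampling step by a parabola through the three points
around each maximum; prominence is specified as a fraction of the local
value range. Non-uniformly sampled input is linearly resampled with a
warning.

The Ellman thiol ratio is ΔA/(ε·c·l). The emulated assay monitored 425 nm
rather than the canonical 412 nm, and no extinction coefficient was
stated, so ε_TNB is a required argument with no default. One documented
oddity in the source material: a free-chromophore tryptophan band is
quoted at "189.0 nm", which is almost certainly a typo for ~289 nm (Trp
fine structure lies at 289–294 nm); it is noted here and nothing is pinned
to it.

## Synthetic generators

All generators draw from a single seeded NumPy `default_rng` stream per
fixture, record the seed and a generator version, and are byte-identical
under a fixed seed. Defaults encode the emulated study conditions: 54
sequences × 120 columns for alignments, urea 0–7.2 M at 20 °C with
ΔG° = 4.3 kcal·mol⁻¹ and m = 1.55 kcal·mol⁻¹·M⁻¹ for chemical curves
(2% of signal span is the standard noise level in the recovery tests),
240–340 nm at 0.1 nm for spectra. The thermal preset (Tm = 330 K,
ΔHm = 60 kcal·mol⁻¹, ΔCp = 1.6 kcal·mol⁻¹·K⁻¹) is a plausible
small-protein stability curve; no measured Tm was available to pin it to.

What they deliberately do not emulate:

- toy complexes have lattice CA+CB pseudo-residues, not folded geometry —
  they exercise distance logic, not packing;
- ortholog pairs and alignments have independently drawn positions, no
  phylogenetic correlation and no indel process beyond planted gap columns;
- spectra are pure Gaussian bands without baselines or stray-light
  artifacts.

Passing tests on these fixtures therefore demonstrates correctness of the
algorithms under known truth, not robustness to every pathology of real
instrument or survey data.

## Problem sizes in the test suite

The oracle comparisons run at sizes where the oracle is exact and fast:
contact extraction on 200 seeded complexes of 3–8 residues per chain,
alignment enumeration up to 7 residues, threshold statistics on 200 seeded
54-row alignments, fit-recovery ensembles of 500 replicates of 36-point
curves. These sizes are the package's own choice of exhaustive-but-small
validation; all operations scale to realistic inputs (thousands of atoms,
hundreds of columns) through the k-d tree and vectorised numerics.

## Known limitations

- Reproductions that need the public cryo-EM complex, sequence accessions
  or the curated 54-genome alignment require those files under
  `data/external/`; they are not redistributed, and the corresponding
  acceptance tests fail with an explanatory message in their absence.
- No three-state or kinetic unfolding models; no global multi-probe fits.
- Structure handling is single-model, first model only; no superposition,
  RMSD or map handling.
- The pI calculation ignores charged-residue interactions and terminal
  modifications.
- Local-alignment identity reproduces BLAST-style figures only up to the
  unknowable details of the original engine's parameterisation (±1 point).
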