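# Methods

## Overview

The pipeline estimates ward-level heat-stress risk as the product of three
[0, 1] indices — hazard (HI), vulnerability (VI) and exposure (EI) — and
classifies wards into five standard-deviation categories. It is organised
as six file-driven stages (simulate, validate, utci, hazard, indices, risk)
so the CLI subcommands, the numbered analysis drivers and `run_pipeline`
produce identical artifacts.

## UTCI engine

UTCI is evaluated with the COST Action 730 sixth-order polynomial in
`Ta` (°C), `Tmrt − Ta` (K), `va` (m/s) and `pa/10` (kPa). The 210
coefficients ship as an exponent-keyed CSV inside the package, guarded by a
SHA-256 checksum: a transcription slip in one of 210 terms produces silently
wrong fields, so the table is machine-checked at load and cross-checked in
the tests against a second, literal written-out form of the polynomial and
against physical sanity bands (UTCI within ±3 °C of `Ta` at reference
conditions `Tmrt = Ta`, `va = 0.5 m/s`, RH 50 % for `Ta` 15–35 °C).

Envelope handling: the approximation is valid for `Ta ∈ [−50, 50] °C`,
`va ∈ [0.5, 17] m/s`, `Tmrt − Ta ∈ [−30, 70] K`, `pa ≤ 50 hPa`. Wind below
0.5 m/s is clamped up to 0.5 (the operational convention for calm air);
the radiant excess and vapour pressure are clamped to the envelope edge with
a per-cell validity flag; `Ta` beyond ±50 °C or wind above 17 m/s raises an
error rather than extrapolating a high-order polynomial.

Water vapour pressure uses Hardy's ITS-90 saturation formulation (the one
the UTCI operational software is calibrated with) scaled by RH/100.

**Mean radiant temperature.** The full six-direction flux weighting of a
reference body is reduced to a two-stream inversion

    σ Tmrt⁴ = [ε L↓ + (1 − α) S↓] / ε,   α = 0.3, ε = 0.97 (configurable)

which satisfies the blackbody identity (Tmrt = T when S↓ = 0 and
L↓ = σT⁴) and is strictly increasing in the solar flux. This is a
deliberately simple, documented stand-in for a full radiation-geometry
treatment: no shading, view factors or directional short-wave splitting.
Gridded UTCI values therefore depend on this choice, and the hazard index
is designed around band membership of ward means rather than exact cell
values. Precomputed `tmrt` fields are honoured when present.

## Hazard index

Ward values are unweighted arithmetic means of member grid cells, taken
after averaging the selected analysis instants (one instant per retained
day at the analysis hour). The categorical re-indexing maps the heat bands
of the 10-class UTCI assessment scale onto [0, 1] with linear interpolation
inside each band and saturation outside (0 below 9 °C — the index targets
heat stress, so the cold side is collapsed; 1 above 46 °C). Band bounds are
treated as closed on top (exactly 46 °C is still "very strong"). The
printed strong-heat band "32 to 48" in the source's category table overlaps
the very-strong band and is read as the standard 32–38; that reading is the
only one consistent with the printed normalized endpoints (39 °C → 0.78,
45.1 °C → 0.97), which the tests pin down.

Hazard categories use the same five SD bins as the other indices. The
source is ambiguous here (its text exempts the hazard index from SD
classification while its figures show five hazard classes); SD bins are the
only classification rule stated anywhere, so they are applied uniformly.

## Composite indices

Order of operations: orientation-aware min–max normalization (all nine
indicators are positively related to their index), then z-standardization
(sample SD, ddof = 1) for the PCA. Min–max alone does not fix the variance,
and PCA on the correlation matrix needs standardized inputs; doing both is
redundant but harmless (affine maps do not change correlations) and keeps
both normalization contracts explicit.

Factorability is reported, not enforced: KMO below 0.5 logs a warning
(0.5 is the conventional adequacy floor), Bartlett's test is written to the
PCA report. KMO of an exactly-identity correlation matrix is 0/0 and is
returned as NaN.

Retention follows the strict Kaiser rule (eigenvalue > 1, with a 1e-9
numerical guard so an identity correlation retains nothing on
floating-point noise); the index constructor enforces a floor of one
component so the index exists. Varimax rotation uses Kaiser
row-normalization and the classical pairwise planar rotations with the
closed-form angle, sweeping until the criterion improves by less than
1e-8. (A gradient/SVD-style iteration was tried first and oscillated
between near-identity and near-90° rotations on two nearly balanced
components; the pairwise algorithm is the one the legacy statistics
packages use and converges in a handful of sweeps. It is cross-checked
against statsmodels' GPA rotation in the tests.) Each component is sign-
flipped so its largest-magnitude loading is positive and components are
ordered by explained variance, removing eigenvector ambiguity so repeated
runs are reproducible.

Scores use the regression method `Z R⁻¹ Λ` with the rotated loadings when
rotation applies; weights are variance ratios of the rotated eigenvalues
(column sums of squared rotated loadings). The weighted score sum is
min–max rescaled to [0, 1]; with a single component the lone score column
is used directly.

## Risk

HSRI = HI·VI·EI elementwise, not re-normalized: the product is the risk
scale, bounded above by the smallest factor, and the classification handles
the location/scale. Classification ties (z exactly on ±0.5 or ±1.5) go to
the lower class, reading the bin phrasing as left-open/right-closed.

## Validation metrics

Pearson correlation, RMSE, MAE and Willmott's classical (1981) index of
agreement; the refined 2012 IoA variant is not used. Observations pair with
the nearest grid cell (no interpolation) at the exact hour-rounded
timestamp; unmatched records are dropped and counted in the log. Metrics
are pooled across stations by default, per-station on request. Constant
series make PCC undefined (NaN), and an all-constant IoA denominator is an
error.

## Synthetic-data generator

The generator emulates the statistical structure the analysis relies on,
not the physics behind it:

- **Meteorology** — per-variable sums of a diurnal harmonic, a fixed
  west→east gradient (the coastal pattern: east warmer, drier) and a static
  spatially smooth Gaussian texture (σ = 3 cells). Shortwave follows a
  clipped cosine day-arch peaking at the analysis hour (0700 UTC ≈ early
  afternoon local time at the emulated longitude), so the hottest instant is
  where the analysis samples it. Defaults (Ta base 29.5 °C, amplitude 4 °C,
  gradient 3 °C, RH base 68 %, S↓ max 420 W/m², L↓ base 414 W/m², wind
  2.5 + 1.5 m/s diurnal) are chosen so the 0700 UTC ward-average UTCI falls
  in the very-strong heat-stress band (38–46 °C) with a few degrees of
  east–west contrast — the hot-spell regime the index construction is meant
  for. RH is clipped to [0, 100] %, wind and radiation to ≥ 0.
- **Wards** — k-means clustering of cell centroids: compact, irregular,
  non-empty blobs that partition the grid exactly (asserted), exported as
  GeoJSON polygons from which the cell membership can be rebuilt.
- **Indicators** — a known latent-factor model (scores × loadingsᵀ + noise),
  affinely mapped into plausible positive magnitudes per indicator (affine
  maps preserve correlations, so recovery tests compare against the implied
  population correlation exactly). The default spec uses one density-driven
  vulnerability factor and two orthogonal exposure factors, mirroring the
  1-/2-component outcomes the index construction expects. A rank-deficient
  loading matrix with zero noise is flagged (singular correlation matrix
  downstream) but still generated, since the perfectly correlated case is
  itself a useful degenerate fixture.
- **Stations** — uniform random point locations, nearest-cell sampling plus
  iid Gaussian noise; stations are ideal point samples (no heights, siting
  or sensor error model).

What passing tests therefore do **not** show: agreement with any real
atmospheric simulation (no physics, no urban morphology, no land-cover
contrast), realistic indicator distributions (censuses are skewed and
spatially autocorrelated; the generator draws iid wards), or realistic
observation error. They do show that every algorithmic step — normalization,
PCA bookkeeping, rotation, scoring, weighting, aggregation, classification,
metric computation — is correct against independent oracles and recovers
known generating structure.

All randomness flows from one integer seed; sub-generators use fixed seed
offsets, and repeated runs with the same configuration are byte-identical
across all CSV/JSON/GeoJSON products (the manifest records a hash of the
scientific configuration, excluding the output path).

## Time-window selection

The time axis splits into consecutive segments of `segment_days` (default
3 days) from the first timestamp; the first `spinup_hours` (default 24) of
each segment are discarded — mimicking restarted simulation segments whose
first day forgets initialization transients — and only instants at the
analysis hour (default 0700 UTC) are kept. Over the default 15-day run this
leaves 10 analysis instants, which are averaged per cell before ward
aggregation; classification happens once on the period-mean ward values,
not per day.

## Problem sizes

Defaults run a 24×24 grid × 360 hourly steps, 24 wards, 36 stations; the
full pipeline takes a couple of seconds on one core. The test suite uses
8–10 cell grids and 6–8 wards for the end-to-end checks and n = 500 wards
for the factor-recovery checks.

## Known limitations

- The mean-radiant-temperature stand-in makes gridded UTCI values
  formulation-dependent; only band-level hazard behaviour is robust.
- SD classification is unstable for very small ward counts (a single
  outlier moves the bins); with fewer than ~10 wards the category shares
  are mostly noise.
- The multiplicative risk index has an absorbing zero: a ward at the
  minimum of any index gets zero risk regardless of the others, a known
  property of product-form risk equations (the min–max rescaling guarantees
  such wards exist).
- No missing-data handling: indicator tables must be complete.
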