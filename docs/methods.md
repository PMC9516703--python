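# Methods

## Two-state melt model

A variable-temperature CD measurement of a beta-sheet-rich protein gives
an ellipticity grid over temperature and wavelength. After conversion to
mean residue ellipticity (MRE = θ·MRW/(10·l·c), with θ in millidegrees,
path length l in cm and concentration c in mg/mL — the standard
convention; all three parameters are required metadata) the trace at the
beta-sheet band is reduced to a fractional signal change

    f(T) = (y − y₀) / (y_max − y₀),

where y₀ is the signal of minimum magnitude and y_max the strongest
(most negative band) signal, so f = 0 at y₀ and f = 1 at y_max. Each
sigmoidal transition is treated as a two-state equilibrium between the
initial and final conformational ensembles:

    K = f / (1 − f),        ΔG = −R·T_K·ln K   (R = 8.314 J/mol/K).

f is clipped to [1e−6, 1 − 1e−6] to keep ΔG finite; clipped points are
flagged and excluded from transition-window fits. ΔG is regressed on
temperature inside the near-transition window |ΔG| < 5 kJ/mol (at least
3 points required); T_m is the zero crossing, ΔS = −slope (in J/K/mol)
and ΔH is derived from T_m and ΔS.

### Temperature-axis convention for ΔH

Per-transition tables in this family of melt experiments satisfy the
identity ΔH ≈ T_m(°C)·ΔS, not the Kelvin product (e.g. 69.8 × 1.370 ≈ 96
kJ/mol, whereas the Kelvin product would be ≈ 470). The primary `dh`
output therefore uses the Celsius-axis convention so that reported
triples are internally consistent; the thermodynamically standard
Kelvin-axis value T_m(K)·ΔS (the van't Hoff enthalpy at T_m) is stored
alongside as `dh_kelvin_convention`. Neither is "corrected" toward the
other.

### Segmentation

f(T) is fitted with sums of k = 1..3 logistic components by nonlinear
least squares. Initialization is deterministic: candidate centers come
from the most prominent, mutually separated peaks of the smoothed
numerical derivative of f, with amplitude signs from the local
derivative sign, plus fixed quantile-grid fallback starts. Two
identifiability constraints bound the optimizer: component widths may
not drop below 0.6× the median temperature spacing (a narrower component
can only chase single points) and amplitudes may not exceed 3× the data
range (larger values occur only in mutually cancelling pairs).

k is selected by the small-sample-corrected Akaike criterion (AICc) with
two guards:

- a *noise floor* added to the RSS (default 0.5 % of the signal range,
  `noise_floor_fraction`): on effectively noiseless data the logistic
  approximation to a van't Hoff sigmoid leaves residuals of order 1e−3
  of the amplitude, and without a floor those sub-noise differences
  would always buy extra components;
- an *admissibility screen*: every component amplitude must exceed twice
  its standard error from the fit covariance, and adjacent centers must
  be separated by more than the larger of the two component widths.
  Inadmissible mixtures describe noise, not transitions; AICc selects
  among admissible fits (falling back to all fits if none pass).

After selection, components with amplitude below
max(5 % of the range, 3× the robust noise estimate from second
differences) are dropped. Region boundaries are midpoints between
consecutive centers. Within a single-component fit the global f is used
directly; with several components, each region's local fraction is the
data minus the fitted offset and sibling components, divided by the
component's own amplitude — this anchors the region entry at 0 and the
component plateau at 1 even when transitions overlap, which region-local
raw extrema cannot do.

## Free-energy landscape

Over the full ramp ΔG(T) traces a well; it is fitted with an inverted
Gaussian value(T) = offset ∓ A·exp(−(T − c)²/2σ²) (orientation "well"
for ΔG, "peak" for f). Initialization is deterministic (center at the
data extremum, amplitude at the data range, σ at a quarter span). The
stability metric is ΔG_min = offset − A; width is reported as
FWHM = 2.3548·σ and area as the closed-form integral A·σ·√(2π) — both
definitions are fixed rather than configurable so that fresh/stored
comparisons stay internally consistent. A constant trace yields a
degenerate flag (amplitude < 1e−9 of the data scale), not an error.

### Deviation (aggregation) flag

Extra sigmoidal structure at high temperature — the aggregation
signature — is detected by either of two config-exposed criteria:

1. a run of ≥ 3 consecutive points in the upper temperature quartile
   whose residuals above the fitted curve exceed 2 standardized units;
   the onset is the first temperature of the run. Residuals are
   standardized by the RSS of the *lower three quartiles* only, so a
   real deviation cannot inflate its own denominator. The threshold is
   applied one-sided (observed above the fit) because an extra
   high-temperature transition always pushes the trace upward; this also
   keeps the false-positive probability of the run rule negligible.
2. an RSS more than 2× a supplied reference RSS (e.g. the matching
   fresh sample's fit).

A single outlier can never trigger the run rule.

### Comparison and ranking

Fresh-versus-stored changes are percentages relative to the fresh value;
for ΔG_min the magnitudes are compared, so a well that deepens on
storage reports a positive change. Ranking is total and deterministic:
non-deviating samples first, then deeper ΔG_min, ties broken by higher
final-transition T_m, then sample id.

## Synthetic melts

`generate_melt` sums two-state van't Hoff components

    f_i(T) = 1 / (1 + exp[(ΔH_i/R)(1/T_K − 1/T_m,i,K)]),

so each population is exactly ½ at its T_m and a lone transition gives
ΔG(T) = ΔH_i(1 − T_K/T_m,K), exactly linear — the closed-form limit used
by the recovery tests. The default grid is 25–97 °C in 2 °C steps (the
usual acquisition protocol). Opposite-sign amplitudes on successive
transitions emulate the band-deepening-then-loss shape of real antibody
melts; noise is homoscedastic Gaussian (no instrument noise model is
assumed) and fully seed-deterministic. The generator does not emulate
wavelength-correlated noise, baseline drift, or heating-rate kinetics,
so passing recovery tests demonstrate estimator correctness under the
stated noise model, not robustness to every instrument artifact.

## Toy trajectories and preferential interaction

`generate_trajectory` places a rigid bead cluster (a centre bead plus an
octahedral shell, 2.5 Å spacing) at the centre of an orthorhombic
periodic box and scatters single-bead cation/anion/water molecules
uniformly, except inside a spherical shell (default 4–9 Å minimum
distance from the solute) where placement acceptance is multiplied by a
per-species enrichment factor. Defaults (150 cations, 150 anions, 600
waters, 60 Å box, 20 frames) were chosen once to give counting
statistics adequate for Γ estimation at toy scale while mimicking a
concentrated 1:1 salt solution; the solute has no internal dynamics,
which is sufficient for testing the distance-counting machinery but
says nothing about real solvation structure or dynamics.

Γ for species s at cutoff R is computed per frame as

    Γ_s = n_s(≤R) − (N_s^bulk / N_w^bulk) · n_w(≤R),

counting molecules by any-atom minimum distance (an atom is never
counted twice per molecule), with bulk ratios from molecules beyond R in
the same frame — estimating bulk per frame keeps small boxes usable.
The frame average is reported with a block-averaged standard error
(5 contiguous blocks by default). The generator's ground truth
re-derives Γ with explicit per-molecule Python loops, independent of the
vectorized implementation, and the two must agree exactly per frame.

Cation and anion coefficients are combined into one co-solute Γ₂₃ by
the indistinguishable-ion approach. Three conventions are selectable —
Γ₊ + Γ₋, ½(Γ₊ + Γ₋), and the default ½(Γ₊ + Γ₋) − Z₂/2, where Z₂ is the
protein net charge in e — because the combination formula is a
convention choice; all are symmetric under ion exchange. The default
includes the counter-charge correction appropriate for a charged
protein.

MDDF normalization divides observed shell counts by the expectation from
uniform placement at the bulk density (estimated from the outer 25 % of
r_max). Because the min-distance level sets around a multi-atom solute
are not spherical shells, shell volumes are estimated by Monte-Carlo
integration over the box with a fixed internal seed (deterministic,
200 000 samples; the solute is taken from frame 0, which is exact for a
rigid solute).

## Geometry

Superposition uses the least-squares rotation from the SVD of the
covariance (with the determinant correction for proper rotations);
RMSD is taken after fitting each frame's selection onto the reference,
and RMSF about the superposed-ensemble mean. Selections of fewer than
3 atoms are rejected as degenerate.

The conformer call uses domain centre-of-mass distances (equal atom
weights): a frame is λ-shaped when min(Fab1–Fc, Fab2–Fc) <
0.75 × Fab1–Fab2 — one arm folded onto Fc — and the trajectory label is
λ when ≥ 60 % of frames are λ, Y when ≤ 40 %, else ambiguous. The
thresholds (α = 0.75, 60/40 %) are package defaults for a quantity that
is usually reported qualitatively; all are arguments.

## Ionic-strength helper

For a fully dissociated 1:1 electrolyte, c = 10·wt%·ρ/M mol/L equals the
ionic strength. ρ defaults to 1.00 g/mL and is overridable: concentrated
solutions are denser than water, and the unit-density rule is exact only
where solution density happens to be near 1. No attempt is made to force
agreement for compositions where it is not.

## Problem sizes and numerical choices

The test and acceptance workloads use 37-point melts (the 25–97 °C
acquisition grid), 50 replicates for noisy-recovery medians, 100
replicates for the deviation flag's detection/false-positive rates, and
8–30-frame toy trajectories — sizes at which every stage's statistics
are informative while the whole suite runs in well under a minute per
module. Known limitations: three-state/kinetic unfolding, heat-capacity
corrections, non-orthorhombic boxes, and per-residue interaction
analyses are out of scope; transitions narrower than the temperature
spacing are not identifiable by design.
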