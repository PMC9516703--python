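"""Two-state thermodynamic analysis of CD melt traces.

The melt trace at the beta-sheet band is converted into a fractional
signal change f(T) between two normalization anchors, the trace is
segmented into sigmoidal transition regions, and each region is analysed
under the two-state equilibrium model:

    f = (y - y0) / (ymax - y0)          fractional content
    K = f / (1 - f)                     equilibrium constant
    dG = -R T ln K                      free energy (kJ/mol)

The transition midpoint Tm is where dG crosses zero; dS is minus the
slope of dG against temperature inside the near-transition window
(|dG| < 5 kJ/mol), and dH follows from Tm and dS.  The primary dH output
uses the Celsius-axis product dH = Tm(degC) * dS, the convention under
which the per-transition quantities reported for this family of melt
experiments are internally consistent; the thermodynamically standard
Kelvin-axis product is stored alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .cdio import MRETrace
from .errors import (
    DegenerateNormalizationError,
    FittingError,
    InsufficientWindowError,
    PreconditionError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "R_GAS",
    "CLIP_EPS",
    "DG_WINDOW_KJ",
    "FoldedFractionTrace",
    "SigmoidalRegion",
    "TransitionThermodynamics",
    "folded_fraction",
    "segment_transitions",
    "equilibrium_constant",
    "free_energy",
    "fit_transition",
    "analyze_trace",
]

R_GAS = 8.314  # J / (mol K)
CLIP_EPS = 1e-6
DG_WINDOW_KJ = 5.0  # |dG| window (kJ/mol) for the linear Tm fit
KELVIN = 273.15


@dataclass
class FoldedFractionTrace:
    """Fractional signal change versus temperature with its anchors."""

    temperatures: np.ndarray
    f: np.ndarray
    y0: float
    ymax: float
    source_region: Optional[Tuple[float, float]] = None
    clipped: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.f = np.asarray(self.f, dtype=float)
        if self.clipped is None:
            self.clipped = np.zeros(self.f.shape, dtype=bool)


@dataclass
class SigmoidalRegion:
    """One sigmoidal transition region with its local two-state quantities."""

    t_lo: float
    t_hi: float
    temperatures: np.ndarray
    f_local: np.ndarray
    K: np.ndarray
    dG: np.ndarray  # kJ/mol
    region_index: int  # 1-based
    at_clip_bound: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.t_lo >= self.t_hi:
            raise PreconditionError("region bounds must satisfy t_lo < t_hi")
        if self.at_clip_bound is None:
            self.at_clip_bound = np.zeros(np.asarray(self.f_local).shape, dtype=bool)


@dataclass
class TransitionThermodynamics:
    """Per-transition melting thermodynamics from the linear dG(T) fit.

    ``dh`` follows the Celsius-axis convention dH = Tm(degC) * dS;
    ``dh_kelvin_convention`` is the Kelvin-axis product Tm(K) * dS.
    """

    tm: float            # degC
    dh: float            # kJ/mol (Celsius-axis convention)
    ds: float            # J/(K mol)
    slope: float         # kJ/mol/degC
    intercept: float     # kJ/mol
    r_squared: float
    window: Tuple[float, float]
    n_points: int
    dh_kelvin_convention: float = float("nan")
    tm_sigmoid: Optional[float] = None     # logistic-fit midpoint, if available
    non_cooperative: bool = False


def folded_fraction(trace: MRETrace, y0: float, ymax: float) -> FoldedFractionTrace:
    """Map a signal trace onto [0, 1] between the anchors y0 and ymax.

    f = (y - y0)/(ymax - y0), clipped to [eps, 1 - eps] so downstream
    logarithms stay finite; clipped points are marked and later excluded
    from transition-window fits.
    """
    if y0 == ymax:
        raise DegenerateNormalizationError("normalization anchors coincide (y0 == ymax)")
    f_raw = (np.asarray(trace.mre, dtype=float) - y0) / (ymax - y0)
    f = np.clip(f_raw, CLIP_EPS, 1.0 - CLIP_EPS)
    return FoldedFractionTrace(
        temperatures=trace.temperatures,
        f=f,
        y0=float(y0),
        ymax=float(ymax),
        clipped=(f_raw <= CLIP_EPS) | (f_raw >= 1.0 - CLIP_EPS),
    )


def equilibrium_constant(f: np.ndarray) -> np.ndarray:
    """Two-state equilibrium constant K = f/(1-f) for f in (0, 1)."""
    f = np.asarray(f, dtype=float)
    if np.any(f <= 0) or np.any(f >= 1):
        raise PreconditionError("f must lie strictly inside (0, 1); clip first")
    return f / (1.0 - f)


def free_energy(K: np.ndarray, t_celsius: np.ndarray) -> np.ndarray:
    """dG = -R T ln K in kJ/mol, with T in kelvin from the Celsius input."""
    K = np.asarray(K, dtype=float)
    if np.any(K <= 0):
        raise PreconditionError("K must be strictly positive")
    t_kelvin = np.asarray(t_celsius, dtype=float) + KELVIN
    return -R_GAS * t_kelvin * np.log(K) / 1000.0


def _logistic_mixture(t: np.ndarray, offset: float, *params: float) -> np.ndarray:
    """offset + sum of amplitude_i * logistic((t - c_i)/w_i)."""
    out = np.full_like(t, offset, dtype=float)
    for amp, center, width in zip(params[0::3], params[1::3], params[2::3]):
        arg = np.clip((t - center) / width, -500.0, 500.0)
        out = out + amp / (1.0 + np.exp(-arg))
    return out


def _aicc(rss: float, n: int, k_params: int, rss_floor: float) -> float:
    # Gaussian log-likelihood AIC with small-sample correction.  The floor
    # keeps selection well-posed on (near-)noiseless data: RSS differences
    # below the floor reflect the logistic component shape, not structure,
    # and must not buy extra components.
    if n <= k_params + 1:
        return np.inf
    rss = max(rss, 1e-300) + rss_floor
    aic = n * np.log(rss / n) + 2 * k_params
    return aic + 2 * k_params * (k_params + 1) / (n - k_params - 1)


def _candidate_centers(t: np.ndarray, f: np.ndarray, k: int):
    """Derivative-guided initial centers and signs for k components.

    The smoothed numerical derivative of f(T) peaks at each transition
    midpoint; the k most prominent, mutually separated extrema seed the
    component centers, with the local derivative sign seeding the
    amplitude sign.  Deterministic.
    """
    df = np.gradient(f, t)
    win = max(3, t.size // 12)
    kernel = np.ones(win) / win
    df_s = np.convolve(df, kernel, mode="same")
    order = np.argsort(-np.abs(df_s))
    span = t[-1] - t[0]
    min_sep = span / (2.0 * k + 1.0)
    chosen: List[int] = []
    for idx in order:
        if all(abs(t[idx] - t[j]) >= min_sep for j in chosen):
            chosen.append(int(idx))
        if len(chosen) == k:
            break
    # pad with quantile positions if the derivative offered too few peaks
    quantiles = np.linspace(0.2, 0.8, k)
    while len(chosen) < k:
        target = t[0] + quantiles[len(chosen)] * span
        chosen.append(int(np.argmin(np.abs(t - target))))
    chosen.sort(key=lambda i: t[i])
    centers = [float(t[i]) for i in chosen]
    signs = [1.0 if df_s[i] >= 0 else -1.0 for i in chosen]
    return centers, signs


def _fit_k_logistics(t: np.ndarray, f: np.ndarray, k: int):
    """Deterministic NLLS fit of a k-component logistic mixture.

    Starts from derivative-guided centers/signs, plus a flipped-sign and a
    quantile-grid fallback start.  Returns (params, rss) of the best
    converged start, or None.
    """
    span = t[-1] - t[0]
    frange = float(f.max() - f.min()) or 1.0
    width0 = max(span / 20.0, 1.0)
    # identifiability constraints: a component narrower than the sampling
    # step would chase single points, and amplitudes far beyond the data
    # range only occur in mutually cancelling pairs
    w_min = max(0.6 * float(np.median(np.diff(t))), 0.05)
    a_max = 3.0 * frange

    centers, signs = _candidate_centers(t, f, k)
    grid_centers = list(t[0] + np.linspace(0.2, 0.8, k) * span)
    starts = [
        (centers, signs),
        (centers, [-s for s in signs]),
        (grid_centers, [1.0] * k),
        (grid_centers, [(-1.0) ** i for i in range(k)]),
    ]

    best = None
    lower = [-np.inf] + [-a_max, t[0] - span, w_min] * k
    upper = [np.inf] + [a_max, t[-1] + span, span] * k
    for cs, ss in starts:
        p0 = [float(f[0])]
        for c, s in zip(cs, ss):
            p0 += [s * frange, float(c), width0]
        try:
            popt, pcov = optimize.curve_fit(
                _logistic_mixture, t, f, p0=p0, bounds=(lower, upper),
                maxfev=3000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((f - _logistic_mixture(t, *popt)) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    return best


def _admissible(popt: np.ndarray, pcov: np.ndarray) -> bool:
    """Identifiability screen for a fitted mixture.

    Every component amplitude must be significant (|amp| > 2 SE from the
    fit covariance) and adjacent centers must be resolved: separated by
    more than the larger of the two component widths.  Mixtures failing
    either test describe noise, not transitions.
    """
    amps = np.asarray(popt[1::3])
    centers = np.asarray(popt[2::3])
    widths = np.asarray(popt[3::3])
    if pcov is not None and np.all(np.isfinite(pcov)):
        amp_se = np.sqrt(np.diag(pcov))[1::3]
        if np.any(np.abs(amps) <= 2.0 * amp_se):
            return False
    order = np.argsort(centers)
    c, w = centers[order], widths[order]
    for i in range(c.size - 1):
        if c[i + 1] - c[i] <= max(w[i], w[i + 1]):
            return False
    return True


def segment_transitions(
    fraction: FoldedFractionTrace,
    max_regions: int = 3,
    min_amplitude_fraction: float = 0.05,
    noise_floor_fraction: float = 0.005,
) -> List[SigmoidalRegion]:
    """Segment f(T) into 1..max_regions sigmoidal transition regions.

    Sums of k logistic components are fitted by nonlinear least squares for
    each candidate k; k is selected by the small-sample-corrected Akaike
    criterion (AICc).  Components whose amplitude falls below
    ``min_amplitude_fraction`` of the signal range are discarded before
    splitting.  Region boundaries are midpoints between consecutive
    component centers, and within each region f is renormalized between the
    local anchors (the region values of minimum and maximum magnitude), so
    each region carries its own two-state K and dG vectors.  The procedure
    is fully deterministic (fixed multi-start grid).

    ``noise_floor_fraction`` sets the smallest residual scale (as a
    fraction of the signal range) that counts as evidence during model
    selection; below it, extra components cannot lower the criterion.
    """
    t = fraction.temperatures
    f = fraction.f
    if t.size < 12:
        raise PreconditionError(f"need >= 12 temperature points, got {t.size}")
    frange_all = float(f.max() - f.min()) or 1.0
    rss_floor = t.size * (noise_floor_fraction * frange_all) ** 2

    fits = {}
    diagnostics = []
    for k in range(1, max_regions + 1):
        n_params = 1 + 3 * k
        if t.size <= n_params + 1:
            logger.info("skipping k=%d: %d points for %d parameters", k, t.size, n_params)
            continue
        res = _fit_k_logistics(t, f, k)
        if res is None:
            diagnostics.append(f"k={k}: no start converged")
            continue
        popt, pcov, rss = res
        fits[k] = (popt, rss, _aicc(rss, t.size, n_params, rss_floor),
                   _admissible(popt, pcov))
    if not fits:
        raise FittingError("no logistic mixture converged; " + "; ".join(diagnostics))

    admissible = {k: v for k, v in fits.items() if v[3]}
    pool = admissible or fits
    k_best = min(pool, key=lambda k: pool[k][2])
    popt = pool[k_best][0]
    offset = float(popt[0])
    amps = np.asarray(popt[1::3])
    centers = np.asarray(popt[2::3])
    widths = np.asarray(popt[3::3])
    # amplitude filter: a component must rise above both a fixed fraction
    # of the signal range and the detection limit set by instrument noise
    # (estimated robustly from second differences, which are insensitive
    # to the smooth melt shape)
    d2 = np.diff(f, n=2)
    sigma_noise = float(np.median(np.abs(d2 - np.median(d2)))) / (0.6745 * np.sqrt(6.0)) \
        if d2.size else 0.0
    amp_floor = max(min_amplitude_fraction * frange_all, 3.0 * sigma_noise)
    keep = np.abs(amps) >= amp_floor
    if not keep.any():
        keep[:] = True
    amps, centers, widths = amps[keep], centers[keep], widths[keep]
    order = np.argsort(centers)
    amps, centers, widths = amps[order], centers[order], widths[order]

    bounds = [t[0]] + [
        0.5 * (c1 + c2) for c1, c2 in zip(centers[:-1], centers[1:])
    ] + [t[-1]]

    regions: List[SigmoidalRegion] = []
    index = 0
    for i, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:])):
        mask = (t >= lo) & (t <= hi)
        if mask.sum() < 3:
            logger.info("component at %.3g degC has %d points; skipped",
                        centers[i], int(mask.sum()))
            continue
        index += 1
        ti = t[mask]
        if amps.size == 1:
            # single transition: the global normalization already anchors
            # f at 0 and 1, and is exact for noiseless two-state data
            f_raw = f[mask]
        else:
            # local normalization anchors from the fitted mixture: subtract
            # the offset and every sibling component, then scale by this
            # component's fitted amplitude -- the entry level maps to 0 and
            # the component plateau to 1 even when transitions overlap.
            background = np.full(ti.shape, offset)
            for j in range(amps.size):
                if j == i:
                    continue
                arg = np.clip((ti - centers[j]) / widths[j], -500.0, 500.0)
                background = background + amps[j] / (1.0 + np.exp(-arg))
            f_raw = (f[mask] - background) / amps[i]
        regions.append(_build_region(ti, f_raw, float(lo), float(hi), index))
    return regions


def _build_region(t: np.ndarray, f_raw: np.ndarray, lo: float, hi: float,
                  index: int) -> SigmoidalRegion:
    f_local = np.clip(f_raw, CLIP_EPS, 1.0 - CLIP_EPS)
    at_bound = (f_raw <= CLIP_EPS) | (f_raw >= 1.0 - CLIP_EPS)
    K = equilibrium_constant(f_local)
    dG = free_energy(K, t)
    return SigmoidalRegion(
        t_lo=lo, t_hi=hi, temperatures=t, f_local=f_local, K=K, dG=dG,
        region_index=index, at_clip_bound=at_bound,
    )


def fit_transition(region: SigmoidalRegion) -> TransitionThermodynamics:
    """Linear dG(T) fit inside the near-transition window.

    Ordinary least squares of dG (kJ/mol) on T (degC) restricted to
    |dG| < 5 kJ/mol and to points not sitting at the clip bound.
    Tm is the zero crossing of the fitted line; dS = -slope (in J/K/mol);
    dH = Tm(degC) * dS under the primary Celsius-axis convention, with the
    Kelvin-axis value stored alongside.  A non-negative slope yields a
    non-cooperative-transition warning but still returns a result.
    """
    mask = (np.abs(region.dG) < DG_WINDOW_KJ) & ~region.at_clip_bound
    t = region.temperatures[mask]
    dg = region.dG[mask]
    if t.size < 3:
        raise InsufficientWindowError(
            f"region {region.region_index}: only {t.size} points with "
            f"|dG| < {DG_WINDOW_KJ} kJ/mol (need >= 3)"
        )
    fit = stats.linregress(t, dg)
    slope, intercept = float(fit.slope), float(fit.intercept)
    non_coop = slope >= 0
    if non_coop:
        logger.warning("region %d: non-negative dG slope (%.3g); transition "
                       "is not cooperative", region.region_index, slope)
        tm = float("nan") if slope == 0 else intercept / (-slope)
    else:
        tm = intercept / (-slope)
    ds = -slope * 1000.0  # kJ/mol/degC -> J/K/mol
    dh = tm * ds / 1000.0  # Celsius-axis convention, kJ/mol
    dh_kelvin = (tm + KELVIN) * ds / 1000.0
    return TransitionThermodynamics(
        tm=tm, dh=dh, ds=ds, slope=slope, intercept=intercept,
        r_squared=float(fit.rvalue) ** 2,
        window=(float(t.min()), float(t.max())),
        n_points=int(t.size),
        dh_kelvin_convention=dh_kelvin,
        non_cooperative=non_coop,
    )


def analyze_trace(
    trace: MRETrace,
    y0: Optional[float] = None,
    ymax: Optional[float] = None,
    max_regions: int = 3,
) -> Tuple[FoldedFractionTrace, List[SigmoidalRegion], List[TransitionThermodynamics]]:
    """End-to-end melt analysis: normalize, segment, fit each transition.

    When anchors are not supplied they are selected automatically following
    the band-depth convention: y0 is the signal of minimum magnitude and
    ymax the strongest (most negative band = maximum magnitude) signal.
    Regions whose transition window is too sparse are skipped with a log
    entry rather than failing the whole trace.
    """
    y = np.asarray(trace.mre, dtype=float)
    if y0 is None:
        y0 = float(y[np.argmin(np.abs(y))])
    if ymax is None:
        ymax = float(y[np.argmax(np.abs(y))])
    frac = folded_fraction(trace, y0, ymax)
    regions = segment_transitions(frac, max_regions=max_regions)
    thermos: List[TransitionThermodynamics] = []
    for region in regions:
        try:
            thermos.append(fit_transition(region))
        except InsufficientWindowError as exc:
            logger.info("skipping region %d: %s", region.region_index, exc)
    return frac, regions, thermos
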