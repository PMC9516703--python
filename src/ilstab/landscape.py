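"""Gaussian free-energy-landscape fits and stability comparison.

Over the full temperature ramp, dG(T) of a cooperatively melting protein
traces a well: flat at low temperature, a minimum near the temperature of
greatest beta-sheet content, and a return at high temperature.  The well
(or, for the fractional-content trace, the peak) is summarized by an
inverted-Gaussian fit whose minimum is dG_min — the thermodynamic
stability metric — with the full width at half maximum and the closed-form
area as shape descriptors.  Systematic departure from the Gaussian at high
temperature (an extra sigmoidal transition) is the aggregation-propensity
flag; fresh and stored samples are compared by percentage change of the
fit descriptors relative to the fresh sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Literal, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from .errors import FittingError, PreconditionError
from .thermo import TransitionThermodynamics

logger = logging.getLogger(__name__)

__all__ = [
    "DeviationConfig",
    "LandscapeFit",
    "StabilityComparison",
    "fit_gaussian_landscape",
    "detect_deviation",
    "compare_fresh_stored",
    "rank_stability",
]

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ~2.3548


@dataclass(frozen=True)
class DeviationConfig:
    """Thresholds for the Gaussian-deviation (aggregation) flag.

    residual_threshold : standardized-residual cut, in residual SDs,
        applied one-sided in the direction extra high-temperature
        structure pushes the data (above the fitted curve).
    run_length : minimum number of consecutive flagged points.
    quartile : fraction of the temperature range (from the top) examined.
    rss_ratio : flag when rss > rss_ratio * reference_rss.
    """

    residual_threshold: float = 2.0
    run_length: int = 3
    quartile: float = 0.25
    rss_ratio: float = 2.0


@dataclass
class LandscapeFit:
    """Inverted-Gaussian (well) or Gaussian (peak) landscape fit."""

    amplitude: float          # well depth / peak height, trace units (> 0)
    center: float             # degC
    sigma: float              # degC
    offset: float             # trace units
    orientation: Literal["well", "peak"]
    rss: float
    dg_min: Optional[float] = None   # offset - amplitude, well orientation only
    deviation_flag: bool = False
    deviation_onset: Optional[float] = None
    degenerate: bool = False

    @property
    def fwhm(self) -> float:
        return FWHM_PER_SIGMA * self.sigma

    @property
    def area(self) -> float:
        """Closed-form Gaussian integral, amplitude * sigma * sqrt(2 pi)."""
        return self.amplitude * self.sigma * np.sqrt(2.0 * np.pi)

    def predict(self, temperatures: np.ndarray) -> np.ndarray:
        t = np.asarray(temperatures, dtype=float)
        bump = self.amplitude * np.exp(-((t - self.center) ** 2) / (2.0 * self.sigma ** 2))
        return self.offset - bump if self.orientation == "well" else self.offset + bump


@dataclass
class StabilityComparison:
    """Fresh-versus-stored percentage changes, relative to the fresh fit."""

    sample_id: str
    pct_change_dg_min: Optional[float]
    pct_change_width: float
    pct_change_area: float


def fit_gaussian_landscape(
    temperatures: np.ndarray,
    values: np.ndarray,
    orientation: Literal["well", "peak"],
) -> LandscapeFit:
    """Nonlinear least-squares fit of value(T) = offset -/+ amp*exp(-(T-c)^2/(2 s^2)).

    Initialization is deterministic: center at the data extremum, amplitude
    at the data range, sigma at a quarter of the temperature span.  A
    constant trace yields a degenerate fit (amplitude below 1e-9 of the
    data scale) flagged rather than raised.  ``dg_min`` (= offset -
    amplitude) is populated only for well orientation.
    """
    t = np.asarray(temperatures, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 6:
        raise PreconditionError(f"need >= 6 points to fit a landscape, got {t.size}")
    if orientation not in ("well", "peak"):
        raise PreconditionError(f"orientation must be 'well' or 'peak', got {orientation!r}")

    vrange = float(v.max() - v.min())
    scale = max(vrange, float(np.max(np.abs(v))), 1e-12)
    sign = -1.0 if orientation == "well" else 1.0
    extremum_idx = int(np.argmin(v)) if orientation == "well" else int(np.argmax(v))
    span = float(t[-1] - t[0])
    p0 = [max(vrange, 1e-12), float(t[extremum_idx]),
          max(span / 4.0, 1e-3), float(v[0]) if orientation == "well" else float(v.min())]

    def model(tt, amp, center, sigma_, offset):
        return offset + sign * amp * np.exp(-((tt - center) ** 2) / (2.0 * sigma_ ** 2))

    try:
        popt, _ = optimize.curve_fit(
            model, t, v, p0=p0,
            bounds=([0.0, t[0] - span, 1e-6, -np.inf],
                    [np.inf, t[-1] + span, 10.0 * span, np.inf]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FittingError(
            f"Gaussian landscape fit did not converge (initialization: "
            f"amp={p0[0]:.4g}, center={p0[1]:.4g}, sigma={p0[2]:.4g}, offset={p0[3]:.4g})"
        ) from exc
    amp, center, sigma_, offset = (float(x) for x in popt)
    rss = float(np.sum((v - model(t, *popt)) ** 2))
    degenerate = amp < 1e-9 * scale
    if degenerate:
        logger.warning("landscape fit degenerate: amplitude %.3g below resolution", amp)
    if not t[0] <= center <= t[-1]:
        logger.warning("fitted center %.3g degC outside data range [%.3g, %.3g]",
                       center, t[0], t[-1])
    return LandscapeFit(
        amplitude=amp, center=center, sigma=sigma_, offset=offset,
        orientation=orientation, rss=rss,
        dg_min=(offset - amp) if orientation == "well" else None,
        degenerate=degenerate,
    )


def detect_deviation(
    fit: LandscapeFit,
    temperatures: np.ndarray,
    values: np.ndarray,
    reference_rss: Optional[float] = None,
    config: DeviationConfig = DeviationConfig(),
) -> LandscapeFit:
    """Flag systematic departure from the Gaussian at high temperature.

    Two criteria, either sufficient:

    (a) a run of at least ``config.run_length`` consecutive points in the
        upper temperature quartile whose standardized residuals (observed
        above the fitted curve) exceed ``config.residual_threshold``;
        the onset is the first temperature of the run;
    (b) ``reference_rss`` given and rss > ``config.rss_ratio`` x reference.

    Returns the fit with ``deviation_flag``/``deviation_onset`` updated.
    A single outlier never triggers the run-length rule.
    """
    t = np.asarray(temperatures, dtype=float)
    v = np.asarray(values, dtype=float)
    resid = v - fit.predict(t)
    t_cut = t[-1] - config.quartile * (t[-1] - t[0])
    # null residual scale from outside the examined region, so a real
    # deviation cannot inflate its own denominator
    cool = resid[t < t_cut]
    dof = max(cool.size - 4, 1)
    resid_sd = float(np.sqrt(np.sum(cool ** 2) / dof)) if cool.size else 0.0
    flag = False
    onset: Optional[float] = None

    if resid_sd > 0:
        z = resid / resid_sd
        hot = t >= t_cut
        exceed = (z > config.residual_threshold) & hot
        run = 0
        for i in range(t.size):
            run = run + 1 if exceed[i] else 0
            if run >= config.run_length:
                flag = True
                onset = float(t[i - config.run_length + 1])
                break

    if not flag and reference_rss is not None and fit.rss > config.rss_ratio * reference_rss:
        flag = True

    fit.deviation_flag = flag
    fit.deviation_onset = onset
    return fit


def compare_fresh_stored(fresh: LandscapeFit, stored: LandscapeFit,
                         sample_id: str = "") -> StabilityComparison:
    """Percentage change of dG_min magnitude, FWHM and area after storage.

    Every change is relative to the fresh value; for dG_min the comparison
    uses magnitudes, so a stored well deeper than the fresh one (more
    negative dG_min) reports a positive percentage change.
    """
    if fresh.orientation != stored.orientation:
        raise PreconditionError(
            f"orientation mismatch: fresh={fresh.orientation}, stored={stored.orientation}"
        )
    pct_dg = None
    if fresh.orientation == "well":
        if fresh.dg_min == 0:
            raise PreconditionError("fresh dg_min is zero; percentage change undefined")
        pct_dg = 100.0 * (abs(stored.dg_min) - abs(fresh.dg_min)) / abs(fresh.dg_min)
    return StabilityComparison(
        sample_id=sample_id,
        pct_change_dg_min=pct_dg,
        pct_change_width=100.0 * (stored.fwhm - fresh.fwhm) / abs(fresh.fwhm),
        pct_change_area=100.0 * (stored.area - fresh.area) / abs(fresh.area),
    )


def rank_stability(
    samples: Sequence[Tuple[str, Sequence[TransitionThermodynamics], LandscapeFit]],
) -> List[str]:
    """Deterministic stability ordering of samples (most stable first).

    Non-deviating samples precede deviating ones; within each group the
    more negative dG_min wins; ties break by the higher final-transition
    Tm, then lexicographically by sample id.
    """
    if len(samples) < 2:
        raise PreconditionError("ranking needs at least 2 samples")

    def key(item):
        sample_id, thermos, fit = item
        final_tm = max((th.tm for th in thermos), default=float("-inf"))
        dg = fit.dg_min if fit.dg_min is not None else fit.offset - fit.amplitude
        return (int(fit.deviation_flag), dg, -final_tm, sample_id)

    return [sample_id for sample_id, _, _ in sorted(samples, key=key)]
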