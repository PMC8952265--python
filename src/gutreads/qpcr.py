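"""qPCR quantification: amplification efficiency, Cq, relative starting
template, and the theoretical limit of detection at Cq = 40.

The per-cycle amplification factor E (ideally 2.0) is estimated by the
window-of-linearity approach: a contiguous 4-6 cycle window inside the
exponential phase, placed where the curve carries the most information about
the log-slope, with a variance-weighted regression of log10 signal on cycle
number; then E = 10^slope. The relative initial template
concentration is back-calculated as N0 = Fq / E^Cq, with Fq the threshold
fluorescence and Cq the (fractional) threshold-crossing cycle.

Observed fluorescence saturates toward the plateau as reporter and reagents
deplete; to first order F = x / (1 + x/P) for exponential signal x and
plateau P. By default the fit desaturates the curve with the inverse
transform x = F·P/(P − F) (P taken as the observed maximum) before the
window regression and the threshold crossing, which removes the ≈ F/P
downward bias in E and N0. Disable with ``saturation_correction=False`` to
fit the raw fluorescence.

The limit of detection extrapolates each replicate's dilution standard curve
(Cq vs log10 template mass) to Cq = 40 and reports the geometric mean of the
extrapolated masses with its upper 95% confidence bound (t-based on the log
scale, appropriate for the small replicate counts typical of LOD assays).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats


class QpcrError(ValueError):
    pass


@dataclass
class AmpFit:
    """Fit of one amplification curve.

    ``efficiency`` is clipped (for reporting only) to the physically
    meaningful interval (1, 2]; ``efficiency_raw`` keeps the regression
    estimate. ``cq`` is None when the curve never crosses the threshold
    (undetected); then ``n0`` is None too.
    """

    sample_id: str
    efficiency: float | None
    efficiency_raw: float | None
    window: tuple[int, int] | None   # first/last cycle of the fitted window
    r_squared: float | None
    cq: float | None
    fq: float | None
    n0: float | None
    low_quality: bool = False

    @property
    def detected(self) -> bool:
        return self.cq is not None


def _robust_plateau(fluor: np.ndarray, n_tail: int = 3) -> float:
    """Plateau level as the mean of the terminal readings (the raw maximum is
    biased upward by noise extremes, and averaging over the rising shoulder
    biases it down; the desaturation transform is very sensitive to the
    plateau near the top)."""
    tail = float(np.mean(fluor[-n_tail:]))
    return tail if tail > 0 else float(np.max(fluor))


def _exponential_window(cycles: np.ndarray, fluor: np.ndarray,
                        upper_fraction: float,
                        n_baseline: int = 5) -> np.ndarray:
    """Boolean mask of cycles in the operational exponential phase:
    fluorescence between baseline + 5*noise_sd and a plateau fraction."""
    base = float(np.median(fluor[:n_baseline]))
    noise_sd = float(np.std(fluor[:n_baseline], ddof=1)) if n_baseline > 1 else 0.0
    lower = base + 5.0 * noise_sd
    upper = upper_fraction * _robust_plateau(fluor)
    return (fluor > lower) & (fluor <= upper) & (fluor > 0)


def fit_amplification(cycles: Sequence[int], fluorescence: Sequence[float],
                      threshold: float,
                      sample_id: str = "",
                      min_window: int = 4, max_window: int = 6,
                      r2_floor: float = 0.99,
                      saturation_correction: bool = True) -> AmpFit:
    """Window-of-linearity fit of one amplification curve.

    Returns an undetected AmpFit (cq=None) when the curve never crosses the
    threshold; sets ``low_quality`` when no window reaches r² >= ``r2_floor``.
    """
    c = np.asarray(cycles, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    if len(c) < 15:
        raise QpcrError("need >= 15 cycles")
    if not (threshold < np.max(f)):
        # never crosses: undetected, no efficiency is meaningful either
        return AmpFit(sample_id, None, None, None, None, None, None, None)

    # desaturate: invert F = x/(1 + x/P) so the exponential phase stays
    # log-linear up to near the plateau
    plateau = _robust_plateau(f)
    if saturation_correction:
        with np.errstate(divide="ignore", invalid="ignore"):
            x_curve = np.where(f < 0.96 * plateau,
                               f * plateau / np.maximum(plateau - f, 1e-12),
                               np.nan)
        x_th = threshold * plateau / max(plateau - threshold, 0.04 * plateau)
        upper_fraction = 0.85   # desaturated curve is log-linear well past P/2
    else:
        x_curve = f.copy()
        x_th = threshold
        upper_fraction = 0.5    # raw curve bends beyond half plateau

    mask = (_exponential_window(c, f, upper_fraction)
            & np.isfinite(x_curve) & (x_curve > 0))
    eligible = np.flatnonzero(mask)

    # Window choice: among the longest contiguous runs, take the window with
    # the largest Fisher information for the log-slope (weights (F(P-F))^2
    # under additive fluorescence noise). Selecting on r² instead lets short
    # noise-dominated windows win by chance alignment.
    def _weights(idx: np.ndarray) -> np.ndarray:
        return (f[idx] * (plateau - f[idx])) ** 2

    best = None  # (info, idx)
    for w in range(max_window, min_window - 1, -1):
        for k in range(len(eligible) - w + 1):
            idx = eligible[k:k + w]
            if idx[-1] - idx[0] != w - 1:
                continue  # not contiguous cycles
            info = float(_weights(idx).sum())
            if best is None or info > best[0]:
                best = (info, idx)
        if best is not None:
            break
    if best is None:
        return AmpFit(sample_id, None, None, None, None, None, None, None,
                      low_quality=True)
    idx = best[1]
    lo, hi = int(idx[0]), int(idx[-1])
    cc, y = c[idx], np.log10(x_curve[idx])
    wts = _weights(idx)
    wts = wts / wts.sum()
    cbar, ybar = float((wts * cc).sum()), float((wts * y).sum())
    slope = float((wts * (cc - cbar) * (y - ybar)).sum()
                  / (wts * (cc - cbar) ** 2).sum())
    r2 = float(stats.linregress(cc, y).rvalue ** 2)  # unweighted, for QC
    e_raw = 10.0 ** slope
    e = min(max(e_raw, 1.0 + 1e-9), 2.0)

    # Cq: linear interpolation of the log signal across the threshold crossing
    above = np.flatnonzero(f >= threshold)
    i = int(above[0])
    prev = x_curve[i - 1] if i > 0 else np.nan
    if i == 0 or not np.isfinite(prev) or prev <= 0:
        cq = float(c[i])
    else:
        y0, y1 = math.log10(prev), math.log10(x_curve[i])
        yt = math.log10(x_th)
        cq = float(c[i - 1] + (yt - y0) / (y1 - y0) * (c[i] - c[i - 1]))
    n0 = x_th / e ** cq
    return AmpFit(sample_id, e, e_raw, (int(c[lo]), int(c[hi])), float(r2),
                  cq, threshold, n0, low_quality=r2 < r2_floor)


def fit_amp_table(amp, threshold: float) -> "list[AmpFit]":
    """Fit every (sample, assay, replicate) series of a long-format table."""
    from .io_formats import SERIES_KEY, validate_amp_table
    validate_amp_table(amp)
    fits = []
    for key, grp in amp.groupby(SERIES_KEY, sort=True):
        fits.append(fit_amplification(grp["cycle"].to_numpy(),
                                      grp["fluorescence"].to_numpy(),
                                      threshold,
                                      sample_id="/".join(map(str, key))))
    return fits


# ---------------------------------------------------------------------------
# limit of detection
# ---------------------------------------------------------------------------

@dataclass
class LodEstimate:
    """Template mass (pg) detectable at Cq = 40: per-replicate extrapolations,
    their geometric mean, and the upper 95% confidence bound of that mean."""

    masses_pg: list[float]
    geometric_mean: float
    upper_ci95: float
    n: int


def lod_from_masses(masses_pg: Sequence[float]) -> LodEstimate:
    """Geometric mean and its upper 95% CI from per-replicate extrapolated
    masses, using the t distribution on the log10 scale."""
    m = np.asarray(masses_pg, dtype=float)
    if len(m) < 2:
        raise QpcrError("need >= 2 replicate estimates")
    if (m <= 0).any():
        raise QpcrError("extrapolated masses must be positive")
    logs = np.log10(m)
    mean = float(np.mean(logs))
    sd = float(np.std(logs, ddof=1))
    n = len(logs)
    tcrit = float(stats.t.ppf(0.975, n - 1))
    upper = mean + tcrit * sd / math.sqrt(n)
    return LodEstimate(list(m), 10.0 ** mean, 10.0 ** upper, n)


def lod_at_cq40(standard_series: Sequence[Sequence[tuple[float, float]]],
                cq_limit: float = 40.0) -> LodEstimate:
    """Theoretical LOD from replicate dilution series.

    Each replicate is a sequence of (log10_mass_pg, cq) points; a straight
    line cq = a + b*log10(mass) is fitted per replicate (b must be negative:
    more template, earlier Cq) and solved for the mass at the Cq limit.
    """
    if len(standard_series) < 2:
        raise QpcrError("need >= 2 replicate dilution series")
    masses = []
    for series in standard_series:
        pts = np.asarray(series, dtype=float)
        if pts.shape[0] < 3:
            raise QpcrError("each dilution series needs >= 3 points")
        res = stats.linregress(pts[:, 0], pts[:, 1])
        if res.slope >= 0:
            raise QpcrError(
                f"standard-curve slope {res.slope:.3f} is non-negative; "
                f"Cq must decrease with template mass")
        log_mass = (cq_limit - res.intercept) / res.slope
        masses.append(10.0 ** log_mass)
    return lod_from_masses(masses)
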