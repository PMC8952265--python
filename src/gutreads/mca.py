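"""Melt-curve analysis (MCA) for verifying qPCR amplicon identity.

The melting temperature Tm — the temperature at which half the duplex is
dissociated — appears as a peak in the negative derivative −dF/dT of the
raw fluorescence melt curve. This module estimates −dF/dT by local
least-squares quadratic fits, extracts peaks above a robust (median)
background, and applies a replicate-consensus positive/negative call:

* with a positive-control reference Tm: positive iff at least two technical
  replicates show −dF/dT more than 0.1 above background within the Tm
  window, or one replicate more than 0.2 above background;
* without a control: positive iff all (>=3) replicates share a single sharp
  dominant peak at a common Tm with no comparable secondary peak (multiple
  peaks indicate heterogeneous amplicons, primer dimers, or chimeras).

The 0.1/0.2 thresholds are on the instrument fluorescence-derivative scale;
inputs should be raw fluorescence as exported by the cycler.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .io_formats import validate_melt_table


@dataclass(frozen=True)
class Peak:
    tm: float
    height_above_baseline: float
    prominence: float


@dataclass
class DerivativeCurve:
    """−dF/dT over the temperature grid, with baseline and extracted peaks
    (sorted by height, largest first)."""

    temperatures: np.ndarray
    neg_dFdT: np.ndarray
    baseline: float
    peaks: list[Peak]

    @property
    def dominant(self) -> Peak | None:
        return self.peaks[0] if self.peaks else None

    def height_near(self, tm: float, tol: float) -> tuple[float, float]:
        """(max −dF/dT above baseline, its temperature) within [tm±tol]."""
        mask = np.abs(self.temperatures - tm) <= tol
        if not mask.any():
            return float("-inf"), float("nan")
        vals = self.neg_dFdT[mask]
        i = int(np.argmax(vals))
        return float(vals[i] - self.baseline), float(self.temperatures[mask][i])


def _local_quadratic_slopes(t: np.ndarray, f: np.ndarray,
                            window: int) -> np.ndarray:
    """dF/dT at each grid point from a quadratic least-squares fit over the
    nearest ``window`` points (one-sided windows at the ends)."""
    n = len(t)
    half = window // 2
    slopes = np.empty(n)
    for i in range(n):
        lo = max(0, min(i - half, n - window))
        hi = lo + window
        tt, ff = t[lo:hi], f[lo:hi]
        deg = min(2, len(tt) - 1)
        coeffs = np.polyfit(tt - t[i], ff, deg)
        slopes[i] = coeffs[-2] if deg >= 1 else 0.0
    return slopes


def derivative_curve(temperatures: Sequence[float],
                     fluorescence: Sequence[float],
                     smooth_window: int = 5,
                     prominence_floor: float = 0.02) -> DerivativeCurve:
    """Estimate −dF/dT from a raw melt scan and extract its peaks.

    Baseline is the median of −dF/dT over the whole scan — robust while a
    melt peak occupies a minority of the grid. Peaks are local maxima above
    baseline with prominence >= ``prominence_floor``; each peak Tm is refined
    by a parabolic fit through the three points around the maximum.
    """
    if smooth_window < 3 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be an odd integer >= 3")
    t = np.asarray(temperatures, dtype=float)
    f = np.asarray(fluorescence, dtype=float)
    if len(t) < smooth_window:
        raise ValueError(f"need >= {smooth_window} points, got {len(t)}")
    if not (np.diff(t) > 0).all():
        raise ValueError("temperatures must be strictly increasing")

    neg = -_local_quadratic_slopes(t, f, smooth_window)
    baseline = float(np.median(neg))
    idx, props = find_peaks(neg, height=baseline, prominence=prominence_floor)
    peaks = []
    for k, i in enumerate(idx):
        # refine Tm as the vertex of a parabola fitted over +-4 grid points
        # around the maximum (robust to point-level derivative noise)
        lo, hi = max(0, i - 4), min(len(t), i + 5)
        tm = float(t[i])
        if hi - lo >= 3:
            a, b, _c0 = np.polyfit(t[lo:hi] - t[i], neg[lo:hi], 2)
            if a < 0:
                vertex = float(t[i] - b / (2 * a))
                if t[lo] <= vertex <= t[hi - 1]:
                    tm = vertex
        peaks.append(Peak(tm, float(neg[i] - baseline),
                          float(props["prominences"][k])))
    peaks.sort(key=lambda p: -p.height_above_baseline)
    return DerivativeCurve(t, neg, baseline, peaks)


# ---------------------------------------------------------------------------
# replicate-consensus calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReplicateEvidence:
    replicate_id: str
    height_at_expected_tm: float
    observed_tm: float


@dataclass
class MCACall:
    sample_id: str
    assay_id: str
    expected_tm: float | None
    tm_tolerance: float
    replicate_evidence: list[ReplicateEvidence]
    call: Literal["positive", "negative", "indeterminate"]


# thresholds of the replicate-consensus rule, in −dF/dT units above background
MINOR_HEIGHT = 0.1   # needed in >=2 replicates
MAJOR_HEIGHT = 0.2   # sufficient in 1 replicate


def call_with_control(replicate_curves: Mapping[str, DerivativeCurve],
                      expected_tm: float,
                      tm_tolerance: float = 0.5,
                      sample_id: str = "", assay_id: str = "") -> MCACall:
    """Positive-control rule: a detection is positive iff >=2 replicates have
    −dF/dT more than 0.1 above background, or >=1 replicate more than 0.2
    above background, at the expected Tm (within ``tm_tolerance``).

    Evidence is the height of an extracted local peak whose Tm falls inside
    the window — not the raw maximum of −dF/dT there, which would see the
    flank of a neighbouring product melting at the wrong temperature."""
    if not replicate_curves:
        raise ValueError("no replicates supplied")
    evidence = []
    for rid, curve in replicate_curves.items():
        in_window = [p for p in curve.peaks
                     if abs(p.tm - expected_tm) <= tm_tolerance]
        if in_window:
            top = max(in_window, key=lambda p: p.height_above_baseline)
            evidence.append(ReplicateEvidence(str(rid),
                                              top.height_above_baseline,
                                              top.tm))
        else:
            evidence.append(ReplicateEvidence(str(rid), 0.0, float("nan")))
    n_minor = sum(1 for e in evidence if e.height_at_expected_tm > MINOR_HEIGHT)
    n_major = sum(1 for e in evidence if e.height_at_expected_tm > MAJOR_HEIGHT)
    call = "positive" if (n_minor >= 2 or n_major >= 1) else "negative"
    return MCACall(sample_id, assay_id, expected_tm, tm_tolerance, evidence, call)


def call_without_control(replicate_curves: Mapping[str, DerivativeCurve],
                         tm_tolerance: float = 0.5,
                         secondary_peak_max_fraction: float = 0.5,
                         sample_id: str = "", assay_id: str = "") -> MCACall:
    """No-control rule: positive iff all (>=3) replicates show the same single
    sharp Tm — dominant peaks within ``tm_tolerance`` of their common median,
    each above the 0.1 background margin, with every secondary peak smaller
    than ``secondary_peak_max_fraction`` of the dominant one."""
    evidence = []
    curves = list(replicate_curves.items())
    if len(curves) < 3:
        return MCACall(sample_id, assay_id, None, tm_tolerance,
                       [ReplicateEvidence(str(r), float("nan"), float("nan"))
                        for r, _ in curves], "indeterminate")
    ok = True
    dominants = []
    for rid, curve in curves:
        dom = curve.dominant
        if dom is None or dom.height_above_baseline <= MINOR_HEIGHT:
            ok = False
            evidence.append(ReplicateEvidence(str(rid), float("nan"),
                                              float("nan")))
            continue
        if any(p.height_above_baseline
               >= secondary_peak_max_fraction * dom.height_above_baseline
               for p in curve.peaks[1:]):
            ok = False  # heterogeneous amplicon
        dominants.append(dom.tm)
        evidence.append(ReplicateEvidence(str(rid), dom.height_above_baseline,
                                          dom.tm))
    if ok and dominants:
        median_tm = float(np.median(dominants))
        ok = all(abs(tm - median_tm) <= tm_tolerance for tm in dominants)
    call = "positive" if ok and len(dominants) == len(curves) else "negative"
    return MCACall(sample_id, assay_id, None, tm_tolerance, evidence, call)


# ---------------------------------------------------------------------------
# table-level driver
# ---------------------------------------------------------------------------

def call_melt_table(melt: pd.DataFrame,
                    expected_tms: Mapping[str, float] | None = None,
                    tm_tolerance: float = 0.5,
                    smooth_window: int = 5) -> pd.DataFrame:
    """Call every (sample, assay) group of a long-format melt table.

    ``expected_tms`` maps assay_id to a positive-control Tm; assays absent
    from the map are called with the no-control consensus rule. Returns one
    row per (sample_id, assay_id) with the call and supporting numbers.
    """
    validate_melt_table(melt)
    expected_tms = expected_tms or {}
    rows = []
    for (sample, assay), grp in melt.groupby(["sample_id", "assay_id"],
                                             sort=True):
        curves = {
            str(rep): derivative_curve(g["temperature"].to_numpy(),
                                       g["fluorescence"].to_numpy(),
                                       smooth_window=smooth_window)
            for rep, g in grp.groupby("replicate_id", sort=True)
        }
        if assay in expected_tms:
            call = call_with_control(curves, expected_tms[assay],
                                     tm_tolerance, str(sample), str(assay))
        else:
            call = call_without_control(curves, tm_tolerance,
                                        sample_id=str(sample),
                                        assay_id=str(assay))
        rows.append({
            "sample_id": sample, "assay_id": assay, "call": call.call,
            "expected_tm": call.expected_tm,
            "n_replicates": len(call.replicate_evidence),
            "max_height": max((e.height_at_expected_tm
                               for e in call.replicate_evidence),
                              default=float("nan")),
        })
    return pd.DataFrame(rows)
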