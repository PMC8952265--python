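"""Detection-performance evaluation.

Detections by a method (read-mapping or metabarcoding) are classified
against independent melt-curve verification:

* TP — detected, melt-curve positive;
* FP — detected, melt-curve negative;
* TN — not detected, melt-curve negative;
* FN — not detected, melt-curve positive, *and* the species is present in
  the method's reference database (a species absent from the database is
  not counted against the method: it is excluded);
* excluded — melt-curve not tested, or the database-coverage exemption.

Five performance metrics follow: sensitivity TP/(TP+FN), specificity
TN/(TN+FP), false discovery rate FP/(FP+TP), false omission rate FN/(FN+TN),
and accuracy (TP+TN)/(TP+TN+FP+FN). Zero-denominator metrics are reported as
missing (NaN), never as 0, and are excluded from cross-sample means.

The statistical comparisons used alongside: Welch's t (Welch–Satterthwaite
degrees of freedom), the paired t, logistic regression of verification
outcome on ln read count (logit link, binomial error, Wald chi-square), and
Pearson correlation with Fisher-transformation p-values. All p-values are
two-sided.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# confusion classification
# ---------------------------------------------------------------------------

Category = Literal["TP", "FP", "TN", "FN", "excluded"]
MCAResult = Literal["positive", "negative", "not_tested"]


@dataclass(frozen=True)
class ConfusionRecord:
    sample_id: str
    species: str
    method: str
    detected: bool
    mca_result: MCAResult
    in_reference_db: bool
    category: Category


def _categorize(detected: bool, mca: MCAResult, in_db: bool) -> Category:
    if mca == "not_tested":
        return "excluded"
    if detected:
        return "TP" if mca == "positive" else "FP"
    if mca == "negative":
        return "TN"
    return "FN" if in_db else "excluded"


def classify(detections: Mapping[str, pd.DataFrame],
             mca_calls: Mapping[tuple[str, str], MCAResult],
             db_species: Mapping[str, set[str]],
             candidate_species: set[str]) -> list[ConfusionRecord]:
    """Classify every (sample, species, method) combination.

    Parameters
    ----------
    detections : method -> detection table (sample_id, species, read_count)
    mca_calls : (sample_id, species) -> melt-curve verification result
    db_species : method -> species present in that method's reference database
    candidate_species : the species universe; must cover everything appearing
        in detections or melt-curve calls.
    """
    seen = set(candidate_species)
    for table in detections.values():
        extra = set(table["species"]) - seen
        if extra:
            raise ValueError(f"detected species outside candidates: {sorted(extra)}")
    for (_s, sp) in mca_calls:
        if sp not in seen:
            raise ValueError(f"MCA call for non-candidate species {sp!r}")

    samples = sorted({s for t in detections.values() for s in t["sample_id"]}
                     | {s for (s, _sp) in mca_calls})
    records = []
    for method, table in detections.items():
        detected_pairs = set(zip(table["sample_id"], table["species"]))
        in_db = db_species.get(method, candidate_species)
        for sample in samples:
            for sp in sorted(candidate_species):
                det = (sample, sp) in detected_pairs
                mca = mca_calls.get((sample, sp), "not_tested")
                cat = _categorize(det, mca, sp in in_db)
                records.append(ConfusionRecord(sample, sp, method, det, mca,
                                               sp in in_db, cat))
    return records


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetricsSummary:
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    fdr: float
    for_: float
    accuracy: float


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def metrics_from_counts(tp: int, fp: int, tn: int, fn: int) -> MetricsSummary:
    """The five performance metrics; undefined (0/0) values are NaN."""
    return MetricsSummary(
        tp, fp, tn, fn,
        sensitivity=_safe_div(tp, tp + fn),
        specificity=_safe_div(tn, tn + fp),
        fdr=_safe_div(fp, fp + tp),
        for_=_safe_div(fn, fn + tn),
        accuracy=_safe_div(tp + tn, tp + tn + fp + fn),
    )


def metrics(records: Iterable[ConfusionRecord]) -> MetricsSummary:
    """Pooled metrics over classified records (excluded records ignored)."""
    counts = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    for r in records:
        if r.category != "excluded":
            counts[r.category] += 1
    return metrics_from_counts(counts["TP"], counts["FP"], counts["TN"],
                               counts["FN"])


def metrics_per_sample(records: Sequence[ConfusionRecord]) -> pd.DataFrame:
    rows = []
    keys = sorted({(r.sample_id, r.method) for r in records})
    for sample, method in keys:
        ms = metrics([r for r in records
                      if r.sample_id == sample and r.method == method])
        rows.append({"sample_id": sample, "method": method, "tp": ms.tp,
                     "fp": ms.fp, "tn": ms.tn, "fn": ms.fn,
                     "sensitivity": ms.sensitivity,
                     "specificity": ms.specificity, "fdr": ms.fdr,
                     "for": ms.for_, "accuracy": ms.accuracy})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StatResult:
    kind: str
    estimate: float
    standard_error: float
    statistic: float
    df: float
    p_value: float


def welch_t(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Welch's unequal-variance t-test with Welch–Satterthwaite df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs >= 2 observations")
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    nx, ny = len(x), len(y)
    se2 = vx / nx + vy / ny
    if se2 == 0:
        raise ValueError("zero variance in both groups")
    diff = float(np.mean(x) - np.mean(y))
    se = math.sqrt(se2)
    t = diff / se
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return StatResult("welch_t", diff, se, t, float(df), float(p))


def paired_t(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Paired t-test on the differences x - y, df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("paired samples must have equal length >= 2")
    d = x - y
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        raise ValueError("all pairwise differences are zero")
    n = len(d)
    se = sd / math.sqrt(n)
    t = float(np.mean(d)) / se
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return StatResult("paired_t", float(np.mean(d)), se, t, float(n - 1),
                      float(p))


class SeparationError(RuntimeError):
    """Complete separation: the logistic MLE does not exist."""


def logistic_tp_vs_reads(ln_reads: Sequence[float],
                         tp_flags: Sequence[int]) -> StatResult:
    """Logistic regression of verification outcome on ln read count.

    Fits outcome ~ 1 + ln_reads by maximum likelihood (IRLS, logit link,
    binomial error) and reports the slope with its Wald chi-square
    ((slope/SE)², 1 df) — for a single regressor this equals the type-II
    statistic.
    """
    import statsmodels.api as sm

    x = np.asarray(ln_reads, dtype=float)
    yv = np.asarray(tp_flags, dtype=float)
    if len(x) < 10:
        raise ValueError("need >= 10 observations")
    if set(np.unique(yv)) != {0.0, 1.0}:
        raise SeparationError("both outcome classes must be present")
    X = sm.add_constant(x)
    with np.errstate(all="ignore"):
        fit = sm.GLM(yv, X, family=sm.families.Binomial()).fit(maxiter=100)
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(se) or abs(slope) > 50 or se > 1e3:
        raise SeparationError("complete separation suspected; slope unbounded")
    # flag perfect separation the IRLS may mask: all 1s above all 0s
    if x[yv == 1].min() > x[yv == 0].max() or x[yv == 0].min() > x[yv == 1].max():
        raise SeparationError("outcome classes perfectly separated by reads")
    chi2 = (slope / se) ** 2
    p = float(stats.chi2.sf(chi2, 1))
    return StatResult("logistic_wald", slope, se, chi2, 1.0, p)


def pearson_fisher(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Pearson correlation with a Fisher-transformation z-test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples of length >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    if abs(r) >= 1.0 - 1e-12:
        raise ValueError("|r| = 1: Fisher transformation diverges")
    z = math.atanh(r) * math.sqrt(len(x) - 3)
    p = 2.0 * stats.norm.sf(abs(z))
    return StatResult("pearson_fisher", r, 1.0 / math.sqrt(len(x) - 3), z,
                      float("nan"), float(p))


# ---------------------------------------------------------------------------
# detection summaries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectionSummary:
    per_sample_counts: list[int]
    total: int
    mean: float
    se: float


def summarize_counts(counts: Sequence[int]) -> DetectionSummary:
    """Total, mean, and standard error of per-sample detection counts."""
    c = np.asarray(counts, dtype=float)
    if len(c) == 0:
        raise ValueError("need >= 1 sample")
    se = float(np.std(c, ddof=1) / math.sqrt(len(c))) if len(c) > 1 else 0.0
    return DetectionSummary([int(v) for v in c], int(c.sum()),
                            float(c.mean()), se)


def summarize_detections(tables: Iterable[pd.DataFrame]) -> DetectionSummary:
    """Distinct detected species per sample table, then total/mean/SE."""
    counts = [int(t["species"].nunique()) if len(t) else 0 for t in tables]
    return summarize_counts(counts)
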