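"""Statistics for quantifying a predictor's signal-peptide dependence.

Given aggregated scores for original and perturbed sequences of a positive
(secreted) and a negative (non-secretory) class, the report computes:

* paired t-tests of modified vs original scores within each class, with
  Bonferroni (or Holm) adjustment across the family of modification kinds
  and significance declared at adjusted p <= 0.01;
* Spearman rank correlation between original and modified scores;
* Gaussian kernel density estimates of the score distributions;
* ROC curves of positive vs negative scores per modification kind, with
  trapezoidal AUC (equal to the concordance probability, ties counted
  half) and operating points at FPR <= alpha and at fixed thresholds.

The classification rule throughout is ``score >= threshold  =>  positive``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve
from statsmodels.stats.multitest import multipletests

from .modifications import ALL_KINDS, MODIFICATION_KINDS
from .scoring import ScoreTable

CLASSES_FOR_ROC = ("positive", "negative")


# ---------------------------------------------------------------------------
# result containers

@dataclass
class PairedTestResult:
    kind: str
    class_label: str
    n: int
    mean_diff: float
    t_stat: float
    df: int
    p_raw: float
    p_adj: float
    significant: bool
    flags: list[str] = field(default_factory=list)


@dataclass
class CorrelationResult:
    kind: str
    class_label: str
    rho: float
    n: int
    flags: list[str] = field(default_factory=list)


@dataclass
class DensityCurve:
    kind: str
    class_label: str
    grid: list[float]
    density: list[float]
    bandwidth: float
    rug: list[float]


@dataclass
class OperatingPoint:
    label: str
    threshold: float
    fpr: float
    tpr: float


@dataclass
class ROCResult:
    kind: str
    thresholds: list[float]
    fpr: list[float]
    tpr: list[float]
    auc: float
    n_pos: int
    n_neg: int
    operating_points: list[OperatingPoint] = field(default_factory=list)


@dataclass
class EvalConfig:
    """Knobs of the evaluation: significance level on adjusted p-values,
    the ROC operating FPR, fixed thresholds, and the adjustment method."""

    sig_alpha: float = 0.01
    roc_alpha: float = 0.05
    thresholds: tuple[float, ...] = (0.5, 0.6)
    adjust_method: str = "bonferroni"
    kde_grid_size: int = 256
    kde_bandwidth: float | None = None


@dataclass
class EvaluationReport:
    paired_tests: list[PairedTestResult]
    correlations: list[CorrelationResult]
    densities: list[DensityCurve]
    rocs: list[ROCResult]
    config: dict

    def to_json_dict(self) -> dict:
        return {
            "paired_tests": [asdict(t) for t in self.paired_tests],
            "correlations": [asdict(c) for c in self.correlations],
            "densities": [asdict(d) for d in self.densities],
            "rocs": [asdict(r) for r in self.rocs],
            "config": self.config,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_json_dict(), sort_keys=True, indent=1) + "\n"
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "EvaluationReport":
        raw = json.loads(Path(path).read_text())
        return cls(
            paired_tests=[PairedTestResult(**t) for t in raw["paired_tests"]],
            correlations=[CorrelationResult(**c) for c in raw["correlations"]],
            densities=[DensityCurve(**d) for d in raw["densities"]],
            rocs=[
                ROCResult(
                    **{**r, "operating_points": [
                        OperatingPoint(**p) for p in r["operating_points"]
                    ]}
                )
                for r in raw["rocs"]
            ],
            config=raw["config"],
        )

    def roc_for(self, kind: str) -> ROCResult:
        for r in self.rocs:
            if r.kind == kind:
                return r
        raise KeyError(kind)

    def paired_test_for(self, kind: str, class_label: str) -> PairedTestResult:
        for t in self.paired_tests:
            if t.kind == kind and t.class_label == class_label:
                return t
        raise KeyError((kind, class_label))


# ---------------------------------------------------------------------------
# elementary statistics

def paired_t_test(
    original: Sequence[float], modified: Sequence[float]
) -> tuple[float, float, int, float, list[str]]:
    """Two-sided paired t-test of modified vs original scores.

    Returns ``(mean_diff, t_stat, df, p_raw, flags)`` with
    ``mean_diff = mean(modified - original)``.  Zero-variance differences
    are handled explicitly: all-zero -> p=1; constant nonzero -> p=0.
    """
    x = np.asarray(original, dtype=float)
    y = np.asarray(modified, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = y - x
    mean_diff = float(d.mean())
    df = n - 1
    sd = float(d.std(ddof=1))
    flags: list[str] = []
    if sd == 0.0:
        if mean_diff == 0.0:
            return 0.0, 0.0, df, 1.0, ["degenerate_all_zero_differences"]
        t = math.copysign(math.inf, mean_diff)
        return mean_diff, t, df, 0.0, ["degenerate_constant_nonzero_differences"]
    res = stats.ttest_rel(y, x)
    return mean_diff, float(res.statistic), df, float(res.pvalue), flags


def adjust_pvalues(p_raw: Sequence[float], method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment; Bonferroni by default, Holm selectable."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("raw p-values must lie in [0,1]")
    if method not in ("bonferroni", "holm"):
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=method)[1]


def spearman_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, int, list[str]]:
    """Spearman rank correlation (average ranks for ties).

    Returns ``(rho, n, flags)``; a constant input vector yields NaN with a
    flag rather than an exception.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("length mismatch")
    n = xa.size
    if n < 3:
        raise ValueError("Spearman correlation needs at least 3 pairs")
    if np.all(xa == xa[0]) or np.all(ya == ya[0]):
        return float("nan"), n, ["constant_input"]
    rho = float(stats.spearmanr(xa, ya).statistic)
    return rho, n, []


def scott_bandwidth(scores: np.ndarray) -> float:
    """Scott's rule for a 1-D Gaussian KDE: n^(-1/5) * sd(ddof=1)."""
    return float(scores.size ** (-1.0 / 5.0) * scores.std(ddof=1))


def kde_curve(
    scores: Sequence[float],
    bandwidth: float | None = None,
    grid_size: int = 256,
    kind: str = "",
    class_label: str = "",
) -> DensityCurve:
    """Gaussian-kernel density estimate of a score distribution.

    The grid spans [0,1] extended by 3 bandwidths on each side so the
    density integrates to ~1 over the reported grid.  Bandwidth defaults
    to Scott's rule; a degenerate (constant) sample requires an explicit
    bandwidth.
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size < 2:
        raise ValueError("KDE needs at least 2 scores")
    h = bandwidth if bandwidth is not None else scott_bandwidth(arr)
    if not h > 0:
        raise ValueError(
            "bandwidth must be positive (constant scores need an explicit bandwidth)"
        )
    grid = np.linspace(0.0 - 3 * h, 1.0 + 3 * h, grid_size)
    z = (grid[:, None] - arr[None, :]) / h
    density = np.exp(-0.5 * z * z).sum(axis=1) / (arr.size * h * math.sqrt(2 * math.pi))
    return DensityCurve(
        kind=kind,
        class_label=class_label,
        grid=grid.tolist(),
        density=density.tolist(),
        bandwidth=float(h),
        rug=arr.tolist(),
    )


# ---------------------------------------------------------------------------
# ROC analysis

def roc_points(
    pos_scores: Sequence[float], neg_scores: Sequence[float], kind: str = ""
) -> ROCResult:
    """ROC curve for the rule ``score >= threshold => positive``.

    Thresholds sweep the distinct observed scores (plus a +inf sentinel
    giving the (0,0) endpoint); AUC is the trapezoidal integral, equal to
    the probability a random positive outscores a random negative with
    ties counted one half.
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score vectors must be non-empty")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    s = np.concatenate([pos, neg])
    fpr, tpr, thresholds = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(
        kind=kind,
        thresholds=thresholds.tolist(),
        fpr=fpr.tolist(),
        tpr=tpr.tolist(),
        auc=auc,
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )


def operating_point_at_fpr(roc: ROCResult, alpha: float = 0.05) -> OperatingPoint:
    """The discrete ROC point with maximal TPR among those with FPR <= alpha.

    Ties broken by minimal FPR, then maximal threshold.  The (0,0) point
    at the +inf sentinel always qualifies, so a point always exists.
    """
    best = None
    for thr, f, t in zip(roc.thresholds, roc.fpr, roc.tpr):
        if f > alpha:
            continue
        key = (t, -f, thr)
        if best is None or key > best[0]:
            best = (key, OperatingPoint(f"fpr<={alpha:g}", float(thr), float(f), float(t)))
    assert best is not None  # (0,0) always qualifies
    return best[1]


def operating_point_at_threshold(roc: ROCResult, t: float) -> OperatingPoint:
    """The discrete ROC point whose threshold is nearest to ``t``.

    An exact match wins; between two equally near thresholds the higher
    (more conservative) one is returned.  The +inf sentinel is never
    nearest while finite thresholds exist.
    """
    points = list(zip(roc.thresholds, roc.fpr, roc.tpr))
    d_min = min(abs(thr - t) for thr, _, _ in points)
    # tie comparison is tolerance-aware so exact float noise cannot break it
    tol = 1e-9 * max(1.0, abs(t))
    thr, f, tp = max(
        (p for p in points if abs(p[0] - t) <= d_min + tol), key=lambda p: p[0]
    )
    return OperatingPoint(f"thr~{t:g}", float(thr), float(f), float(tp))


# ---------------------------------------------------------------------------
# the full report

def evaluate_all(
    score_table: ScoreTable,
    labels: Mapping[str, str],
    config: EvalConfig | None = None,
) -> EvaluationReport:
    """Assemble the full SP-dependence report from aggregated scores.

    For each class (positive, negative) and each modification kind:
    paired test vs original (adjusted within the family of the five
    modification kinds per class), Spearman correlation vs original, and a
    KDE curve.  For each kind: the positive-vs-negative ROC with operating
    points at FPR <= roc_alpha and at each fixed threshold.
    """
    cfg = config or EvalConfig()
    ids_by_class = {
        c: sorted(rid for rid, lab in labels.items() if lab == c)
        for c in CLASSES_FOR_ROC
    }

    # completeness check: every class needs originals and every kind
    gaps = []
    for c in CLASSES_FOR_ROC:
        for kind in ALL_KINDS:
            series = score_table.scores_for(kind, ids_by_class[c]).dropna()
            if series.size < 3:
                gaps.append(f"{c}/{kind} (n={series.size})")
    if gaps:
        raise ValueError(f"score table incomplete for: {gaps}")

    paired_tests: list[PairedTestResult] = []
    correlations: list[CorrelationResult] = []
    densities: list[DensityCurve] = []

    for c in CLASSES_FOR_ROC:
        ids = ids_by_class[c]
        original = score_table.scores_for("original", ids)
        class_tests: list[PairedTestResult] = []
        for kind in ALL_KINDS:
            modified = score_table.scores_for(kind, ids)
            paired = pd.DataFrame({"o": original, "m": modified}).dropna()
            mean_diff, t_stat, df, p_raw, flags = paired_t_test(
                paired["o"].to_numpy(), paired["m"].to_numpy()
            )
            res = PairedTestResult(
                kind=kind, class_label=c, n=len(paired), mean_diff=mean_diff,
                t_stat=t_stat, df=df, p_raw=p_raw, p_adj=p_raw,
                significant=False, flags=flags,
            )
            if kind == "original":
                res.flags = sorted(set(res.flags) | {"self_comparison"})
            class_tests.append(res)

            rho, n_corr, cflags = spearman_correlation(
                paired["o"].to_numpy(), paired["m"].to_numpy()
            )
            correlations.append(
                CorrelationResult(kind=kind, class_label=c, rho=rho, n=n_corr,
                                  flags=cflags)
            )
            densities.append(
                kde_curve(
                    modified.dropna().to_numpy(),
                    bandwidth=cfg.kde_bandwidth,
                    grid_size=cfg.kde_grid_size,
                    kind=kind,
                    class_label=c,
                )
            )
        # adjust within the family of the five modification kinds of this class
        family = [t for t in class_tests if t.kind in MODIFICATION_KINDS]
        adjusted = adjust_pvalues([t.p_raw for t in family], cfg.adjust_method)
        for t, p_adj in zip(family, adjusted):
            t.p_adj = float(p_adj)
            t.significant = bool(t.p_adj <= cfg.sig_alpha)
        paired_tests.extend(class_tests)

    rocs: list[ROCResult] = []
    for kind in ALL_KINDS:
        pos = score_table.scores_for(kind, ids_by_class["positive"]).dropna()
        neg = score_table.scores_for(kind, ids_by_class["negative"]).dropna()
        roc = roc_points(pos.to_numpy(), neg.to_numpy(), kind=kind)
        roc.operating_points.append(operating_point_at_fpr(roc, cfg.roc_alpha))
        for thr in cfg.thresholds:
            roc.operating_points.append(operating_point_at_threshold(roc, thr))
        rocs.append(roc)

    return EvaluationReport(
        paired_tests=paired_tests,
        correlations=correlations,
        densities=densities,
        rocs=rocs,
        config={
            "sig_alpha": cfg.sig_alpha,
            "roc_alpha": cfg.roc_alpha,
            "thresholds": list(cfg.thresholds),
            "adjust_method": cfg.adjust_method,
            "kde_grid_size": cfg.kde_grid_size,
            "kde_bandwidth": cfg.kde_bandwidth,
        },
    )
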