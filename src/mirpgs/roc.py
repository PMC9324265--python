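"""ROC analysis of score discrimination.

AUC is estimated with the Mann-Whitney rank statistic — the fraction of
(case, control) pairs where the case scores higher, ties counted one half —
which equals the trapezoidal area under the empirical ROC curve.  The
confidence interval uses the DeLong structural-components (placement value)
variance estimator.  The operating point is chosen by the Youden index
J = sensitivity + specificity - 1, with ties broken toward higher
sensitivity and then the lower cutoff; the classification rule is
"score >= cutoff predicts case".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from .errors import EmptyInputError

__all__ = [
    "auc_mann_whitney",
    "delong_ci",
    "roc_points",
    "youden_point",
    "roc_summary",
    "RocSummary",
]


def _check_groups(case_scores: np.ndarray, control_scores: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(case_scores, dtype=float)
    y = np.asarray(control_scores, dtype=float)
    if x.size == 0 or y.size == 0:
        raise EmptyInputError("both score groups must be non-empty")
    return x, y


def _placements(case_scores: np.ndarray, control_scores: np.ndarray):
    """Midrank placement values: V10 (per case) and V01 (per control)."""
    cmp = (case_scores[:, None] > control_scores[None, :]).astype(float)
    cmp += 0.5 * (case_scores[:, None] == control_scores[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0)


def auc_mann_whitney(case_scores, control_scores) -> float:
    """AUC as the Mann-Whitney U statistic (ties counted one half)."""
    x, y = _check_groups(case_scores, control_scores)
    v10, _ = _placements(x, y)
    return float(v10.mean())


def delong_ci(case_scores, control_scores, level: float = 0.95):
    """Asymptotic normal CI for the AUC from the DeLong variance.

    Uses the structural-components estimator: the AUC variance is
    ``var(V10)/n + var(V01)/m`` with placement values V10, V01.  The
    interval is truncated to [0, 1].  With perfect separation the variance
    degenerates to 0 and the interval collapses to (auc, auc).

    Returns ``(ci_low, ci_high, auc, se)``.
    """
    x, y = _check_groups(case_scores, control_scores)
    if x.size < 2 or y.size < 2:
        raise EmptyInputError("DeLong CI needs at least two scores per group")
    v10, v01 = _placements(x, y)
    auc = float(v10.mean())
    var = v10.var(ddof=1) / x.size + v01.var(ddof=1) / y.size
    se = float(np.sqrt(var))
    z = float(stats.norm.ppf(0.5 + level / 2.0))
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return lo, hi, auc, se


def roc_points(case_scores, control_scores) -> pd.DataFrame:
    """Empirical ROC curve: columns fpr, tpr, cutoff.

    All operating points are retained (no convex-hull thinning).  The curve
    starts at (0, 0) with an infinite cutoff and ends at (1, 1); both
    coordinates are non-decreasing.
    """
    x, y = _check_groups(case_scores, control_scores)
    scores = np.concatenate([x, y])
    labels = np.concatenate([np.ones(x.size), np.zeros(y.size)])
    fpr, tpr, cutoffs = _sk_roc_curve(labels, scores, drop_intermediate=False)
    cutoffs = cutoffs.astype(float)
    cutoffs[0] = np.inf  # sklearn's sentinel first threshold
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "cutoff": cutoffs})


def youden_point(curve: pd.DataFrame) -> tuple[float, float, float]:
    """Cutoff maximising Youden's J = sensitivity + specificity - 1.

    Among cutoffs tied on J, prefers higher sensitivity, then the lower
    cutoff.  Returns ``(cutoff, sensitivity, specificity)``.
    """
    sens = curve["tpr"].to_numpy()
    spec = 1.0 - curve["fpr"].to_numpy()
    cut = curve["cutoff"].to_numpy()
    j = sens + spec - 1.0
    best = max(range(len(j)), key=lambda i: (j[i], sens[i], -cut[i]))
    return float(cut[best]), float(sens[best]), float(spec[best])


@dataclass
class RocSummary:
    """AUC with CI plus the Youden operating point and the full curve."""

    auc: float
    ci_low: float
    ci_high: float
    auc_se: float
    youden_cutoff: float
    sensitivity: float
    specificity: float
    curve: pd.DataFrame
    degenerate_ci: bool = False

    def to_json_dict(self) -> dict:
        return {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "youden_cutoff": self.youden_cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
        }

    def curve_to_tsv(self, path: str | Path) -> None:
        self.curve.to_csv(path, sep="\t", index=False)

    def plot(self, path: str | Path) -> None:
        """Write a ROC figure (requires matplotlib)."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4.5, 4.5))
        ax.plot(self.curve["fpr"], self.curve["tpr"], lw=1.5)
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
        ax.plot(1 - self.specificity, self.sensitivity, "o", color="crimson")
        ax.annotate(
            f"cutoff {self.youden_cutoff:.3g}\nsens {self.sensitivity:.2f}, "
            f"spec {self.specificity:.2f}",
            (1 - self.specificity, self.sensitivity),
            textcoords="offset points", xytext=(8, -12), fontsize=8,
        )
        ax.set_xlabel("False-positive rate (1 - specificity)")
        ax.set_ylabel("True-positive rate (sensitivity)")
        ax.set_title(f"AUC = {self.auc:.3f} ({self.ci_low:.2f}-{self.ci_high:.2f})")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def roc_summary(case_scores, control_scores, level: float = 0.95) -> RocSummary:
    """Full ROC analysis of one score: AUC, DeLong CI, Youden point, curve."""
    lo, hi, auc, se = delong_ci(case_scores, control_scores, level=level)
    curve = roc_points(case_scores, control_scores)
    cutoff, sens, spec = youden_point(curve)
    return RocSummary(
        auc=auc, ci_low=lo, ci_high=hi, auc_se=se,
        youden_cutoff=cutoff, sensitivity=sens, specificity=spec,
        curve=curve, degenerate_ci=(se == 0.0),
    )
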