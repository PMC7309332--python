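"""Cohort-level evaluation of a score against a binary outcome.

Orientation convention throughout: the positive class is weaning *success*
and a score at or above a threshold predicts success (decreased variability
has been linked to weaning failure, so higher WIN argues for readiness).

The AUC is the exact Mann-Whitney concordance
P(score_pos > score_neg) + 0.5 * P(tie), computed from average ranks; the
confidence interval is a percentile bootstrap with stratified (per-class)
resampling so every replica contains both classes; the operating point is the
Youden-optimal threshold (maximising sensitivity + specificity - 1, ties
broken toward the smallest cutoff).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import DegenerateCohortError


@dataclass(frozen=True)
class LabeledCohort:
    """Per-subject scores with binary outcomes (True/1 = weaning success)."""

    scores: np.ndarray
    labels: np.ndarray
    subject_ids: tuple | None = None

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels).astype(bool)
        if scores.shape != labels.shape or scores.ndim != 1:
            raise ValueError("scores and labels must be 1-D and the same length")
        if not np.all(np.isfinite(scores)):
            raise ValueError("scores must be finite")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "labels", labels)
        if self.subject_ids is not None and len(self.subject_ids) != scores.size:
            raise ValueError("subject_ids length mismatch")

    @property
    def n_positive(self) -> int:
        return int(np.count_nonzero(self.labels))

    @property
    def n_negative(self) -> int:
        return int(self.labels.size - self.n_positive)

    def require_both_classes(self) -> None:
        if self.n_positive == 0 or self.n_negative == 0:
            raise DegenerateCohortError(
                f"need both outcome classes, got {self.n_positive} positive / "
                f"{self.n_negative} negative"
            )

    @classmethod
    def from_csv(cls, path) -> "LabeledCohort":
        """Read a (subject_id, score, label) CSV; extra columns are ignored."""
        df = pd.read_csv(path)
        cols = {c.lower(): c for c in df.columns}
        missing = {"score", "label"} - set(cols)
        if missing:
            raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
        ids = tuple(df[cols["subject_id"]]) if "subject_id" in cols else None
        return cls(
            scores=df[cols["score"]].to_numpy(float),
            labels=df[cols["label"]].to_numpy(),
            subject_ids=ids,
        )


@dataclass(frozen=True)
class RocSummary:
    """Point AUC, bootstrap CI and Youden operating point for one cohort."""

    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    n_boot: int
    seed: int
    ci_excludes_point: bool = False  # percentile CI may rarely miss the point AUC

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def roc_curve(cohort: LabeledCohort) -> np.ndarray:
    """ROC operating points: array of (threshold, sensitivity, specificity).

    Thresholds are every distinct score plus finite extremes one unit below
    the minimum (everything predicted positive) and above the maximum
    (nothing predicted positive); a score >= threshold predicts success.
    """
    cohort.require_both_classes()
    s = cohort.scores
    uniq = np.unique(s)
    thresholds = np.concatenate(([uniq[0] - 1.0], uniq, [uniq[-1] + 1.0]))
    pos = np.sort(s[cohort.labels])
    neg = np.sort(s[~cohort.labels])
    # count of scores >= thr via searchsorted on the sorted class scores
    tp = pos.size - np.searchsorted(pos, thresholds, side="left")
    fp = neg.size - np.searchsorted(neg, thresholds, side="left")
    sens = tp / pos.size
    spec = 1.0 - fp / neg.size
    return np.column_stack([thresholds, sens, spec])


def auc(cohort: LabeledCohort) -> float:
    """Exact Mann-Whitney concordance: P(pos > neg) + 0.5 P(tie)."""
    cohort.require_both_classes()
    return _auc_from_arrays(cohort.scores, cohort.labels)


def _auc_from_arrays(scores: np.ndarray, labels: np.ndarray) -> float:
    n_pos = int(np.count_nonzero(labels))
    n_neg = labels.size - n_pos
    ranks = rankdata(scores)  # average ranks give ties half credit exactly
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def bootstrap_ci(
    cohort: LabeledCohort, n_boot: int = 1000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Percentile bootstrap CI for the AUC with stratified per-class resampling."""
    cohort.require_both_classes()
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    pos = cohort.scores[cohort.labels]
    neg = cohort.scores[~cohort.labels]
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    labels = np.concatenate([np.ones(pos.size, bool), np.zeros(neg.size, bool)])
    for i in range(n_boot):
        sp = pos[rng.integers(0, pos.size, pos.size)]
        sn = neg[rng.integers(0, neg.size, neg.size)]
        reps[i] = _auc_from_arrays(np.concatenate([sp, sn]), labels)
    alpha = 1.0 - level
    lo, hi = np.quantile(reps, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def youden_cutoff(cohort: LabeledCohort) -> tuple[float, float, float]:
    """Threshold maximising Youden J = sensitivity + specificity - 1.

    Ties are broken toward the smallest cutoff.  Returns
    (cutoff, sensitivity, specificity).
    """
    curve = roc_curve(cohort)
    j = curve[:, 1] + curve[:, 2] - 1.0
    order = np.argsort(curve[:, 0], kind="stable")  # ascending thresholds
    j_sorted = j[order]
    best = order[int(np.argmax(j_sorted))]  # argmax returns the first (smallest) maximiser
    thr, sens, spec = curve[best]
    return float(thr), float(sens), float(spec)


def evaluate_cohort(
    cohort: LabeledCohort, n_boot: int = 1000, level: float = 0.95, seed: int = 0
) -> RocSummary:
    """Point AUC, stratified percentile-bootstrap CI, and Youden operating point."""
    point = auc(cohort)
    lo, hi = bootstrap_ci(cohort, n_boot=n_boot, level=level, seed=seed)
    cutoff, sens, spec = youden_cutoff(cohort)
    return RocSummary(
        auc=point,
        ci_low=lo,
        ci_high=hi,
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        n_boot=n_boot,
        seed=seed,
        ci_excludes_point=not (lo <= point <= hi),
    )
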