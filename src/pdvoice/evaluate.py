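"""Repeated random subsampling aggregation and EER/DET evaluation.

The study design draws many (default 40) random class-balanced training
groups; all remaining subjects form that run's test group.  Each subject's
final score is the mean of their scores over the runs where they were tested
(an out-of-bag aggregate).  Performance is the equal error rate — the
operating point where false-positive and false-negative ratios cross — and
DET curves; the single-model performance is estimated by the EER of the
run-averaged DET curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm

N_RUNS_DEFAULT = 40


@dataclass
class SplitPlan:
    runs: list[dict]              # {"train_pd": ids, "train_hc": ids, "test": ids}
    seed: int
    n_train_pd: int
    n_train_hc: int

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def expected_test_counts(self) -> dict:
        """Number of times each subject appears in a test group."""
        counts: dict = {}
        for run in self.runs:
            for sid in run["test"]:
                counts[sid] = counts.get(sid, 0) + 1
        return counts


@dataclass
class ScoreTable:
    entries: list[tuple]          # (subject_id, run_id, score)
    labels: dict                  # subject_id -> "PD" | "HC"
    run_eers: list[float] = field(default_factory=list)
    run_curves: list["DetCurve"] = field(default_factory=list)

    def aggregated(self) -> dict:
        """Out-of-bag mean score per subject."""
        acc: dict = {}
        for sid, _, s in self.entries:
            acc.setdefault(sid, []).append(s)
        return {sid: float(np.mean(v)) for sid, v in acc.items()}

    def aggregated_eer(self) -> float:
        agg = self.aggregated()
        scores = np.array(list(agg.values()))
        labels = np.array([self.labels[s] == "PD" for s in agg])
        return compute_eer(scores, labels)[0]


@dataclass
class DetCurve:
    fpr: np.ndarray
    fnr: np.ndarray
    eer: float


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------


def make_splits(
    subjects,
    n_train_pd: int,
    n_train_hc: int,
    n_runs: int = N_RUNS_DEFAULT,
    seed: int = 0,
) -> SplitPlan:
    """Draw ``n_runs`` independent balanced train/test partitions.

    ``subjects`` are SubjectRecord-like objects with ``subject_id`` and
    ``label``.  Training groups are drawn without replacement; the test group
    is everyone else.  Deterministic in ``seed``.
    """
    pd_ids = [s.subject_id for s in subjects if s.label == "PD"]
    hc_ids = [s.subject_id for s in subjects if s.label == "HC"]
    if n_train_pd >= len(pd_ids) or n_train_hc >= len(hc_ids):
        raise ValueError("training counts leave no test subjects in a class")
    if n_train_pd < 1 or n_train_hc < 1:
        raise ValueError("training counts must be positive")
    rng = np.random.default_rng(seed)
    runs = []
    for _ in range(n_runs):
        tp = list(rng.choice(pd_ids, size=n_train_pd, replace=False))
        th = list(rng.choice(hc_ids, size=n_train_hc, replace=False))
        train = set(tp) | set(th)
        test = [s.subject_id for s in subjects if s.subject_id not in train]
        runs.append({"train_pd": tp, "train_hc": th, "test": test})
    return SplitPlan(runs=runs, seed=seed, n_train_pd=n_train_pd, n_train_hc=n_train_hc)


# ---------------------------------------------------------------------------
# EER / DET
# ---------------------------------------------------------------------------


def _sweep(scores: np.ndarray, labels: np.ndarray):
    """(FPR, FNR, threshold) over all achievable operating points.

    Thresholds sit between distinct score values (plus one below the minimum
    and one above the maximum); a frame is predicted positive iff its score
    is >= the threshold.  Tied scores therefore contribute a single sweep
    point.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise ValueError("both classes are required")
    n = len(scores)
    n_pos = labels.sum()
    n_neg = n - n_pos
    order = np.argsort(scores, kind="mergesort")
    s = scores[order]
    lab = labels[order]
    # at sweep point k the k lowest scores are predicted negative; k is
    # achievable only at distinct-value boundaries
    fn = np.concatenate([[0], np.cumsum(lab)])
    tn = np.concatenate([[0], np.cumsum(~lab)])
    ks = [0] + [k for k in range(1, n) if s[k - 1] < s[k]] + [n]
    ks = np.asarray(ks)
    thr = np.empty(len(ks))
    for i, k in enumerate(ks):
        if k == 0:
            thr[i] = s[0] - 1.0
        elif k == n:
            thr[i] = s[-1] + 1.0
        else:
            thr[i] = 0.5 * (s[k - 1] + s[k])
    fnr = fn[ks] / n_pos
    fpr = (n_neg - tn[ks]) / n_neg
    return fpr, fnr, thr


def compute_eer(scores, labels) -> tuple[float, float]:
    """Equal error rate with linear interpolation at the FPR/FNR crossing.

    Returns (eer, threshold).  High scores mean the positive class.
    """
    fpr, fnr, thr = _sweep(np.asarray(scores, float), np.asarray(labels, bool))
    diff = fnr - fpr  # non-decreasing: -1 at the first point, +1 at the last
    k = int(np.argmax(diff >= 0))
    if diff[k] == 0 or k == 0:
        return float(fpr[k]), float(thr[k])
    a, b = diff[k - 1], diff[k]
    frac = -a / (b - a)
    eer = float(fpr[k - 1] + frac * (fpr[k] - fpr[k - 1]))
    return eer, float(thr[k - 1] + frac * (thr[k] - thr[k - 1]))


def det_curve(scores, labels) -> DetCurve:
    """Full (FPR, FNR) tradeoff with the EER attached."""
    fpr, fnr, _ = _sweep(np.asarray(scores, float), np.asarray(labels, bool))
    eer, _ = compute_eer(scores, labels)
    return DetCurve(fpr=fpr, fnr=fnr, eer=eer)


def average_det(curves: Sequence[DetCurve], n_grid: int = 201) -> DetCurve:
    """Pointwise average of DET curves on a common probit-domain FPR grid.

    The EER of the averaged curve estimates the single-model performance.
    """
    if len(curves) == 0:
        raise ValueError("need at least one curve")
    eps = 1e-4
    grid_probit = np.linspace(norm.ppf(eps), norm.ppf(1 - eps), n_grid)
    grid_fpr = norm.cdf(grid_probit)
    fnrs = []
    for c in curves:
        # FNR as a (non-increasing) function of FPR; make FPR increasing
        order = np.argsort(c.fpr, kind="mergesort")
        f, m = c.fpr[order], c.fnr[order]
        # collapse duplicate FPR values, keeping the smallest FNR
        uniq_f, inv = np.unique(f, return_index=True)
        uniq_m = np.minimum.reduceat(m, inv)
        y = np.interp(grid_fpr, uniq_f, uniq_m)
        fnrs.append(norm.ppf(np.clip(y, eps, 1 - eps)))
    avg_fnr = norm.cdf(np.mean(fnrs, axis=0))
    diff = avg_fnr - grid_fpr
    sign_change = np.nonzero(np.diff(np.sign(diff)) != 0)[0]
    if len(sign_change):
        k = sign_change[0]
        a, b = diff[k], diff[k + 1]
        frac = 0.0 if b == a else -a / (b - a)
        eer = float(grid_fpr[k] + frac * (grid_fpr[k + 1] - grid_fpr[k]))
    else:
        eer = float(grid_fpr[np.argmin(np.abs(diff))])
    return DetCurve(fpr=grid_fpr, fnr=avg_fnr, eer=eer)


# ---------------------------------------------------------------------------
# ensemble
# ---------------------------------------------------------------------------


def run_ensemble(
    pipeline: Callable[[dict], dict],
    splits: SplitPlan,
    labels: dict,
) -> ScoreTable:
    """Run the train/score pipeline over every split and aggregate out-of-bag.

    ``pipeline(run)`` receives one split dict and returns
    ``{subject_id: score}`` for that run's test subjects; subjects it cannot
    score in a run (e.g. no valid segments) are simply absent and excluded
    from that run's mean.  Per-run EERs and DET curves are recorded for the
    single-model comparison.
    """
    table = ScoreTable(entries=[], labels=dict(labels))
    for k, run in enumerate(splits.runs):
        scores = pipeline(run)
        for sid in run["test"]:
            if sid in scores:
                table.entries.append((sid, k, float(scores[sid])))
        run_scores = np.array([scores[s] for s in run["test"] if s in scores])
        run_labels = np.array(
            [labels[s] == "PD" for s in run["test"] if s in scores]
        )
        if run_labels.any() and not run_labels.all():
            curve = det_curve(run_scores, run_labels)
            table.run_eers.append(curve.eer)
            table.run_curves.append(curve)
    return table
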