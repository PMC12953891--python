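"""Group comparison and ROC diagnostics for per-patient FTB fractions.

Implements the statistical workflow used to judge whether FTB fractions
separate tumor progression (TP) from treatment-related abnormalities
(TRA): Mann-Whitney U tests per class, ROC curves with bootstrap
percentile confidence intervals, Youden-index operating points, fixed
clinical cutoff rules (FTB_high > 24% → TP; FTB_low > 59% → TRA), and a
bootstrap D-test comparing two correlated AUROCs (the pROC-style
standardised difference referred to the normal distribution).

All AUC computation uses the rank/U identity
``AUC = U / (n_pos * n_neg)`` (ties counted half), which equals the
trapezoidal area under the empirical ROC curve.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "RocResult",
    "AucComparison",
    "mann_whitney",
    "roc_auc",
    "bootstrap_auc_ci",
    "youden_cutoff",
    "compare_auc_bootstrap",
    "roc_analysis",
    "YoudenThresholdClassifier",
    "evaluate_cohort",
]


# ---------------------------------------------------------------------------
# helpers


def _oriented(scores, labels, positive_class, direction) -> tuple[np.ndarray, np.ndarray]:
    """Return scores oriented so larger ⇒ more positive, and boolean labels."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    y = labels == positive_class
    if not y.any() or y.all():
        raise ValueError("both classes must be present")
    if direction == "higher":
        return scores, y
    if direction == "lower":
        return -scores, y
    raise ValueError("direction must be 'higher' or 'lower'")


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for x over y via midranks (ties count one half)."""
    n1 = len(x)
    ranks = sps.rankdata(np.concatenate([x, y]))
    return float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)


def _auc_matrix(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """AUC for each row-pair of resampled positive/negative score sets."""
    diff = pos[:, :, None] - neg[:, None, :]
    return ((diff > 0).sum(axis=(1, 2)) + 0.5 * (diff == 0).sum(axis=(1, 2))) / (
        pos.shape[1] * neg.shape[1]
    )


# ---------------------------------------------------------------------------
# core statistics


def mann_whitney(x, y, exact_max_n: int = 12) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of two independent samples.

    Returns ``(U, p)`` where U counts pairs with ``x > y`` plus half-ties
    (midrank convention). For combined sample sizes up to
    ``exact_max_n`` the p-value is computed by full enumeration of group
    assignments (valid under ties); larger samples use the tie-corrected,
    continuity-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    u = _u_statistic(x, y)
    n1, n2 = len(x), len(y)
    if n1 + n2 <= exact_max_n:
        pooled = np.concatenate([x, y])
        mu = n1 * n2 / 2
        observed = abs(u - mu)
        hits = 0
        total = 0
        idx = np.arange(n1 + n2)
        for subset in combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(subset)] = True
            u_perm = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u_perm - mu) >= observed - 1e-12:
                hits += 1
        p = hits / total
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(res.pvalue)
    return u, min(p, 1.0)


def roc_auc(scores, labels, positive_class, direction: str = "higher") -> float:
    """Area under the empirical ROC curve via the rank/U identity."""
    s, y = _oriented(scores, labels, positive_class, direction)
    u = _u_statistic(s[y], s[~y])
    return u / (y.sum() * (~y).sum())


def bootstrap_auc_ci(
    scores,
    labels,
    positive_class,
    direction: str = "higher",
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Stratified-bootstrap percentile confidence interval for the AUC.

    Cases are resampled with replacement within each outcome class, so
    every resample retains both classes; the interval is the central
    ``level`` percentile range of the resampled AUCs. Deterministic for a
    given seed.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200")
    s, y = _oriented(scores, labels, positive_class, direction)
    pos, neg = s[y], s[~y]
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    chunk = max(1, int(5e6 // (pos.size * neg.size)))
    for start in range(0, n_boot, chunk):
        m = min(chunk, n_boot - start)
        pi = rng.integers(0, pos.size, size=(m, pos.size))
        ni = rng.integers(0, neg.size, size=(m, neg.size))
        aucs[start : start + m] = _auc_matrix(pos[pi], neg[ni])
    alpha = (1 - level) / 2
    lo, hi = np.quantile(aucs, [alpha, 1 - alpha])
    return float(lo), float(hi)


def youden_cutoff(
    scores, labels, positive_class, direction: str = "higher"
) -> tuple[float, float, float]:
    """Operating cutoff maximising the Youden index J = sens + spec − 1.

    All midpoints between adjacent distinct score values, plus ±∞, are
    scanned; a case is called positive when its score strictly exceeds
    the cutoff (or falls strictly below it for ``direction='lower'``).
    Ties on J are broken toward higher specificity, then toward the
    cutoff that calls fewer cases positive. Returns
    ``(cutoff, sensitivity, specificity)`` with the cutoff on the
    original score scale.
    """
    s, y = _oriented(scores, labels, positive_class, direction)
    uniq = np.unique(s)
    candidates = np.concatenate([[-np.inf], (uniq[:-1] + uniq[1:]) / 2, [uniq[-1]]])
    pos, neg = s[y], s[~y]
    sens = (pos[:, None] > candidates).mean(axis=0)
    spec = (neg[:, None] <= candidates).mean(axis=0)
    j = sens + spec - 1
    # lexsort: primary key -j (max J), then -spec (max specificity), then the
    # cutoff that is lowest on the ORIGINAL scale (oriented sign flips it)
    order = np.lexsort((-candidates if direction == "lower" else candidates, -spec, -j))
    best = order[0]
    cutoff = candidates[best] if direction == "higher" else -candidates[best]
    return float(cutoff), float(sens[best]), float(spec[best])


@dataclass
class RocResult:
    """One diagnostic test's ROC summary with its operating point."""

    auc: float
    ci_low: float
    ci_high: float
    cutoff: float
    sensitivity: float
    specificity: float
    positive_class: str
    direction: str
    n_boot: int
    seed: int

    def __post_init__(self) -> None:
        if not self.ci_low <= self.auc <= self.ci_high:
            raise ValueError("bootstrap CI must bracket the point AUC")


@dataclass
class AucComparison:
    """Bootstrap comparison of two correlated AUROCs."""

    d_stat: float
    p_value: float
    auc_a: float
    auc_b: float
    n_boot: int
    seed: int
    paired: bool
    degenerate: bool = False


def roc_analysis(
    scores,
    labels,
    positive_class,
    direction: str = "higher",
    n_boot: int = 2000,
    seed: int = 0,
    level: float = 0.95,
) -> RocResult:
    """AUC, bootstrap CI and Youden operating point in one record."""
    auc = roc_auc(scores, labels, positive_class, direction)
    lo, hi = bootstrap_auc_ci(scores, labels, positive_class, direction, n_boot, seed, level)
    cutoff, sens, spec = youden_cutoff(scores, labels, positive_class, direction)
    return RocResult(
        auc=auc,
        ci_low=min(lo, auc),
        ci_high=max(hi, auc),
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        positive_class=str(positive_class),
        direction=direction,
        n_boot=n_boot,
        seed=seed,
    )


def compare_auc_bootstrap(
    scores_a,
    scores_b,
    labels,
    positive_class,
    direction_a: str = "higher",
    direction_b: str = "higher",
    n_boot: int = 10_000,
    seed: int = 0,
    paired: bool = True,
) -> AucComparison:
    """Bootstrap D-test for the difference of two AUROCs.

    Both scores are measured on the same patients (correlated ROC
    curves). For each stratified resample the AUC difference
    ``auc_a − auc_b`` is recomputed — on the same resampled patients when
    ``paired`` (the default), on independently resampled patients
    otherwise. The observed difference divided by the bootstrap standard
    deviation gives the standardised statistic D, referred to the
    standard normal for a two-sided p-value.
    """
    sa, y = _oriented(scores_a, labels, positive_class, direction_a)
    sb, y2 = _oriented(scores_b, labels, positive_class, direction_b)
    if sa.shape != sb.shape or not np.array_equal(y, y2):
        raise ValueError("paired scores must cover the same patients")
    pos_a, neg_a = sa[y], sa[~y]
    pos_b, neg_b = sb[y], sb[~y]
    auc_a = _auc_matrix(pos_a[None], neg_a[None])[0]
    auc_b = _auc_matrix(pos_b[None], neg_b[None])[0]
    d0 = auc_a - auc_b
    rng = np.random.default_rng(seed)
    n_pos, n_neg = pos_a.size, neg_a.size
    diffs = np.empty(n_boot)
    chunk = max(1, int(5e6 // (n_pos * n_neg)))
    for start in range(0, n_boot, chunk):
        m = min(chunk, n_boot - start)
        pi = rng.integers(0, n_pos, size=(m, n_pos))
        ni = rng.integers(0, n_neg, size=(m, n_neg))
        if paired:
            pj, nj = pi, ni
        else:
            pj = rng.integers(0, n_pos, size=(m, n_pos))
            nj = rng.integers(0, n_neg, size=(m, n_neg))
        diffs[start : start + m] = _auc_matrix(pos_a[pi], neg_a[ni]) - _auc_matrix(
            pos_b[pj], neg_b[nj]
        )
    sd = float(np.std(diffs, ddof=1))
    if sd == 0.0:
        degenerate = bool(d0 != 0.0)
        return AucComparison(
            d_stat=np.inf if degenerate else 0.0,
            p_value=0.0 if degenerate else 1.0,
            auc_a=float(auc_a),
            auc_b=float(auc_b),
            n_boot=n_boot,
            seed=seed,
            paired=paired,
            degenerate=degenerate,
        )
    d = d0 / sd
    p = float(2 * sps.norm.sf(abs(d)))
    return AucComparison(
        d_stat=float(d),
        p_value=min(p, 1.0),
        auc_a=float(auc_a),
        auc_b=float(auc_b),
        n_boot=n_boot,
        seed=seed,
        paired=paired,
    )


class YoudenThresholdClassifier(ClassifierMixin, BaseEstimator):
    """Single-feature threshold classifier with a Youden-fitted cutoff.

    ``fit`` either scans for the Youden-optimal cutoff on the training
    scores or, when ``cutoff`` is given, uses that fixed clinical cutoff
    (e.g. "more than 24% FTB_high ⇒ progression"). ``predict`` applies
    the strict-inequality rule. Binary labels are whatever is passed as
    ``positive_class`` versus everything else.

    Parameters
    ----------
    positive_class : label of the positive outcome.
    direction : 'higher' if larger scores indicate the positive class.
    cutoff : float or None — fixed cutoff; None fits one by Youden's J.
    """

    def __init__(self, positive_class=1, direction: str = "higher", cutoff: float | None = None):
        self.positive_class = positive_class
        self.direction = direction
        self.cutoff = cutoff

    def _scores(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 2:
            if X.shape[1] != 1:
                raise ValueError("expects a single score feature")
            X = X[:, 0]
        return X

    def fit(self, X, y):
        s = self._scores(X)
        y = np.asarray(y)
        if self.cutoff is None:
            cutoff, sens, spec = youden_cutoff(s, y, self.positive_class, self.direction)
        else:
            cutoff = float(self.cutoff)
            pos = s[y == self.positive_class]
            neg = s[y != self.positive_class]
            if self.direction == "higher":
                sens, spec = float((pos > cutoff).mean()), float((neg <= cutoff).mean())
            else:
                sens, spec = float((pos < cutoff).mean()), float((neg >= cutoff).mean())
        self.cutoff_ = cutoff
        self.sensitivity_ = sens
        self.specificity_ = spec
        self.classes_ = np.unique(y)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self)
        s = self._scores(X)
        if self.direction == "higher":
            positive = s > self.cutoff_
        else:
            positive = s < self.cutoff_
        neg_label = next(
            (c for c in self.classes_ if c != self.positive_class), self.positive_class
        )
        out = np.where(positive, self.positive_class, neg_label)
        return out


def _confusion(scores, labels, positive_class, cutoff, direction="higher") -> dict:
    clf = YoudenThresholdClassifier(positive_class, direction, cutoff).fit(scores, labels)
    pred = clf.predict(scores)
    labels = np.asarray(labels)
    is_pos = labels == positive_class
    pred_pos = pred == positive_class
    return {
        "cutoff": float(cutoff),
        "rule": f"positive if score {'>' if direction == 'higher' else '<'} cutoff",
        "tp": int(np.sum(pred_pos & is_pos)),
        "fp": int(np.sum(pred_pos & ~is_pos)),
        "fn": int(np.sum(~pred_pos & is_pos)),
        "tn": int(np.sum(~pred_pos & ~is_pos)),
        "sensitivity": clf.sensitivity_,
        "specificity": clf.specificity_,
    }


def evaluate_cohort(
    table: pd.DataFrame,
    n_boot: int = 2000,
    n_boot_compare: int = 10_000,
    seed: int = 0,
    level: float = 0.95,
    fixed_cutoff_high: float = 24.0,
    fixed_cutoff_low: float = 59.0,
) -> dict:
    """Run the full cohort-level diagnostic analysis.

    ``table`` needs columns ``label`` (TP/TRA), ``pct_low``, ``pct_mid``,
    ``pct_high``. The report contains group mean fractions, per-class
    Mann-Whitney p-values, ROC analyses for FTB_high (positive class TP)
    and FTB_low (positive class TRA), their bootstrap AUROC comparison,
    and confusion matrices at the fixed clinical cutoffs. Raw p-values
    are reported without multiplicity adjustment. The report is a plain
    JSON-serialisable dict, byte-stable for a fixed table and seed.
    """
    required = {"label", "pct_low", "pct_mid", "pct_high"}
    if not required.issubset(table.columns):
        raise ValueError(f"cohort table must contain columns {sorted(required)}")
    labels = table["label"].to_numpy()
    for grp in ("TP", "TRA"):
        if np.sum(labels == grp) < 2:
            raise ValueError("need at least two patients per group")

    report: dict = {
        "n_tp": int(np.sum(labels == "TP")),
        "n_tra": int(np.sum(labels == "TRA")),
        "settings": {
            "n_boot": n_boot,
            "n_boot_compare": n_boot_compare,
            "seed": seed,
            "level": level,
            "fixed_cutoff_high_pct": fixed_cutoff_high,
            "fixed_cutoff_low_pct": fixed_cutoff_low,
            "multiple_testing": "none (raw p-values)",
        },
        "group_means": {},
        "mann_whitney": {},
    }
    for cls in ("pct_low", "pct_mid", "pct_high"):
        vals = table[cls].to_numpy(dtype=float)
        tp, tra = vals[labels == "TP"], vals[labels == "TRA"]
        report["group_means"][cls] = {"TP": float(tp.mean()), "TRA": float(tra.mean())}
        u, p = mann_whitney(tp, tra)
        report["mann_whitney"][cls] = {"U": u, "p_value": p}

    pct_high = table["pct_high"].to_numpy(dtype=float)
    pct_low = table["pct_low"].to_numpy(dtype=float)
    roc_high = roc_analysis(pct_high, labels, "TP", "higher", n_boot, seed, level)
    roc_low = roc_analysis(pct_low, labels, "TRA", "higher", n_boot, seed + 1, level)
    comparison = compare_auc_bootstrap(
        pct_high,
        pct_low,
        labels,
        positive_class="TP",
        direction_a="higher",
        direction_b="lower",  # high FTB_low argues against TP
        n_boot=n_boot_compare,
        seed=seed + 2,
    )
    report["roc_ftb_high"] = asdict(roc_high)
    report["roc_ftb_low"] = asdict(roc_low)
    report["auc_comparison"] = asdict(comparison)
    report["auc_comparison"]["convention"] = (
        "D = (AUC[FTB_high, TP-positive] - AUC[FTB_low, TRA-positive]) / bootstrap SD"
    )
    report["fixed_cutoffs"] = {
        "ftb_high_tp": _confusion(pct_high, labels, "TP", fixed_cutoff_high, "higher"),
        "ftb_low_tra": _confusion(pct_low, labels, "TRA", fixed_cutoff_low, "higher"),
    }
    return report
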