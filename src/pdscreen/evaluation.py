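"""Diagnostic performance, calibration, agreement, and subgroup statistics.

Covers the full reporting toolkit of a screening-model evaluation:
confusion-matrix metrics with percentile-bootstrap confidence intervals,
AUROC via the Mann-Whitney rank identity, AUPRC by step integration,
Brier score and expected calibration error, Mann-Whitney comparison of
bootstrapped metric distributions, two-proportion z tests with an explicit
applicability guard, Monte-Carlo chi-square tests for sparse contingency
tables, Benjamini-Hochberg FDR adjustment, Cohen's kappa and rater
majority votes, multivariable logistic regression of misclassification on
demographics, and the decomposition of fused-model accuracy by which task
models were correct.

Undefined ratios (zero denominators) are reported as NaN, never as 0.
Withheld predictions are the caller's concern: confusion metrics expect
them pre-removed, and coverage is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, cohen_kappa_score
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "confusion_metrics", "roc_auc", "pr_auc", "brier", "ece",
    "calibration_curve", "bootstrap_ci", "BootstrapResult",
    "compare_bootstrap_distributions", "two_proportion_z", "mc_chisquare",
    "bh_adjust", "cohens_kappa", "agreement_rate", "majority_vote",
    "misclassification_regression", "accuracy_by_agreement",
    "MetricReport", "evaluate_predictions",
]


def _binary(v, name):
    a = np.asarray(v)
    vals = set(np.unique(a).tolist())
    if not vals <= {0, 1}:
        raise ValueError(f"{name} must be binary 0/1, found values {sorted(vals)}")
    return a.astype(int)


def confusion_metrics(truth, predictions) -> dict:
    """Accuracy, sensitivity, specificity, PPV, NPV and F1 from the 2x2
    table.  Ratios with zero denominator are NaN."""
    t = _binary(truth, "truth")
    p = _binary(predictions, "predictions")
    if t.size == 0:
        raise ValueError("empty input")
    if t.shape != p.shape:
        raise ValueError("truth and predictions differ in length")
    tp = int(np.sum((t == 1) & (p == 1)))
    tn = int(np.sum((t == 0) & (p == 0)))
    fp = int(np.sum((t == 0) & (p == 1)))
    fn = int(np.sum((t == 1) & (p == 0)))

    def ratio(num, den):
        return num / den if den > 0 else float("nan")

    sens = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    ppv = ratio(tp, tp + fp)
    npv = ratio(tn, tn + fn)
    f1 = ratio(2 * tp, 2 * tp + fp + fn)
    return {"accuracy": (tp + tn) / t.size, "sensitivity": sens,
            "specificity": spec, "ppv": ppv, "npv": npv, "f1": f1}


def roc_auc(truth, scores) -> float:
    """AUROC via the Mann-Whitney identity; ties count one half."""
    t = _binary(truth, "truth")
    s = np.asarray(scores, dtype=float)
    n_pos = int(t.sum())
    n_neg = t.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUROC")
    ranks = stats.rankdata(s)
    u = ranks[t == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def pr_auc(truth, scores) -> float:
    """Area under the precision-recall curve by step integration
    (average precision)."""
    t = _binary(truth, "truth")
    if t.sum() == 0 or t.sum() == t.size:
        raise ValueError("both classes must be present to compute AUPRC")
    return float(average_precision_score(t, np.asarray(scores, dtype=float)))


def brier(probs, truth) -> float:
    """Mean squared error of predicted probabilities."""
    p = np.asarray(probs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    t = _binary(truth, "truth")
    return float(np.mean((p - t) ** 2))


def ece(probs, truth, bins: int = 10) -> float:
    """Expected calibration error over equal-width probability bins;
    empty bins are skipped."""
    curve = calibration_curve(probs, truth, bins)
    n = sum(row[2] for row in curve)
    return float(sum(nb / n * abs(conf - rate) for conf, rate, nb in curve))


def calibration_curve(probs, truth, bins: int = 10):
    """Per-bin (mean predicted probability, observed positive rate, n)
    over equal-width bins on [0, 1]; empty bins omitted."""
    if bins < 1:
        raise ValueError("bins must be >= 1")
    p = np.asarray(probs, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    t = _binary(truth, "truth")
    edges = np.linspace(0.0, 1.0, bins + 1)
    idx = np.clip(np.digitize(p, edges[1:-1], right=False), 0, bins - 1)
    out = []
    for b in range(bins):
        mask = idx == b
        nb = int(mask.sum())
        if nb == 0:
            continue
        out.append((float(p[mask].mean()), float(t[mask].mean()), nb))
    return out


@dataclass
class BootstrapResult:
    estimate: float
    ci_low: float
    ci_high: float
    distribution: np.ndarray
    level: float
    n_redrawn: int = 0


def bootstrap_ci(statistic, data, B: int = 1000, level: float = 0.95,
                 seed: int = 0, max_redraw: int = 1000) -> BootstrapResult:
    """Percentile bootstrap CI of ``statistic`` over resamples of ``data``.

    ``data`` is one array or a tuple of aligned arrays resampled jointly.
    Resamples on which the statistic is undefined (raises or returns NaN)
    are redrawn, up to ``max_redraw`` extra draws in total.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    arrays = data if isinstance(data, tuple) else (data,)
    arrays = tuple(np.asarray(a) for a in arrays)
    n = arrays[0].shape[0]
    if any(a.shape[0] != n for a in arrays):
        raise ValueError("data arrays must be aligned")
    rng = np.random.default_rng(seed)
    est = float(statistic(*arrays))
    dist = np.empty(B)
    redrawn = 0
    b = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        try:
            val = float(statistic(*(a[idx] for a in arrays)))
        except (ValueError, ZeroDivisionError):
            val = float("nan")
        if np.isnan(val):
            redrawn += 1
            if redrawn > max_redraw:
                raise RuntimeError(
                    "statistic undefined on too many bootstrap resamples")
            continue
        dist[b] = val
        b += 1
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(dist, [100 * alpha, 100 * (1 - alpha)])
    return BootstrapResult(est, float(lo), float(hi), dist, level, redrawn)


def compare_bootstrap_distributions(dist_a, dist_b):
    """Two-sided Mann-Whitney U with tie-corrected normal approximation,
    for comparing two bootstrapped metric distributions."""
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("distributions must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


class AssumptionError(ValueError):
    """A test's applicability conditions are not met."""


def two_proportion_z(x1: int, n1: int, x2: int, n2: int):
    """Pooled two-sided z test for two proportions.

    Refuses (rather than silently degrading) when the normal approximation
    is unjustified, i.e. unless n*p >= 5 and n*(1-p) >= 5 in both groups.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if not 0 <= x <= n or n == 0:
            raise ValueError("need 0 <= x <= n with n > 0")
        p = x / n
        if n * p < 5 or n * (1 - p) < 5:
            raise AssumptionError(
                f"z-test assumptions violated: np={n * p:.1f}, "
                f"n(1-p)={n * (1 - p):.1f} (both must be >= 5)")
    p1, p2 = x1 / n1, x2 / n2
    pool = (x1 + x2) / (n1 + n2)
    se = np.sqrt(pool * (1 - pool) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.0, 1.0
    z = (p1 - p2) / se
    return float(z), float(2 * stats.norm.sf(abs(z)))


def mc_chisquare(table, reps: int = 10000, seed: int = 0):
    """Pearson chi-square with a Monte-Carlo p-value.

    Null tables are drawn with the observed margins held fixed;
    p = (1 + #{chi2_sim >= chi2_obs}) / (reps + 1), so p is never zero.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    obs = np.asarray(table, dtype=int)
    if np.any(obs < 0):
        raise ValueError("counts must be nonnegative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise ValueError("zero marginal row or column")
    chi2_obs = float(stats.chi2_contingency(obs, correction=False)[0])
    expected = np.outer(rows, cols) / obs.sum()
    rng = np.random.default_rng(seed)
    sims = stats.random_table(rows, cols).rvs(reps, random_state=rng)
    sims = sims.reshape(reps, *obs.shape)
    chi2_sim = (((sims - expected) ** 2) / expected).sum(axis=(1, 2))
    p = (1 + int(np.sum(chi2_sim >= chi2_obs - 1e-12))) / (reps + 1)
    return chi2_obs, float(p)


def bh_adjust(p_values):
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def cohens_kappa(labels_a, labels_b) -> float:
    """Chance-corrected agreement; NaN when expected agreement is 1
    (both raters constant and identical)."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    if len(set(a.tolist())) == 1 and set(a.tolist()) == set(b.tolist()):
        return float("nan")
    return float(cohen_kappa_score(a, b))


def agreement_rate(labels_a, labels_b) -> float:
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors differ in length")
    return float(np.mean(a == b))


def majority_vote(ratings: pd.DataFrame, raters: list[str]):
    """Per-subject modal verdict over an odd number of binary raters."""
    if len(raters) % 2 == 0:
        raise ValueError("majority vote requires an odd number of raters")
    votes = ratings[list(raters)].to_numpy(dtype=int)
    return (votes.sum(axis=1) * 2 > len(raters)).astype(int)


class SeparationError(RuntimeError):
    """Perfect separation (or rank deficiency) in a logistic regression."""


def misclassification_regression(errors, covariates: pd.DataFrame):
    """Multivariable logistic regression of a misclassification indicator
    on demographic covariates, with BH-adjusted Wald p-values.

    Categorical covariates are dummy-coded (first level dropped).  Returns
    a DataFrame indexed by term with columns coefficient, p, adjusted_p.
    """
    y = _binary(errors, "errors")
    if covariates.shape[1] == 0:
        X = pd.DataFrame({"const": np.ones(len(y))})
    else:
        X = pd.get_dummies(covariates, drop_first=True, dtype=float)
        X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise SeparationError("design matrix is rank deficient")
    try:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")   # separation detected below
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as e:
        raise SeparationError(f"logistic fit failed: {e}") from e
    if np.any(np.abs(fit.params) > 30):
        raise SeparationError("coefficients diverged; data are separable")
    terms = [c for c in X.columns if c != "const"]
    pvals = fit.pvalues[terms].to_numpy()
    out = pd.DataFrame({
        "coefficient": fit.params[terms].to_numpy(),
        "p": pvals,
        "adjusted_p": bh_adjust(pvals),
    }, index=terms)
    out.loc["const"] = [fit.params["const"], fit.pvalues["const"], np.nan]
    return out


def accuracy_by_agreement(task_verdicts: dict, fused_verdicts, truth) -> pd.DataFrame:
    """Partition sessions by which task models were correct (8 regions)
    and report fused accuracy and n per region."""
    t = _binary(truth, "truth")
    fused = _binary(fused_verdicts, "fused_verdicts")
    names = list(task_verdicts)
    correct = {m: _binary(task_verdicts[m], m) == t for m in names}
    rows = []
    for key in range(8):
        bits = [(key >> (len(names) - 1 - i)) & 1 for i in range(len(names))]
        mask = np.ones(t.size, dtype=bool)
        for m, b in zip(names, bits):
            mask &= correct[m] == bool(b)
        n = int(mask.sum())
        acc = float(np.mean(fused[mask] == t[mask])) if n else float("nan")
        rows.append({**{f"{m}_correct": bool(b) for m, b in zip(names, bits)},
                     "n": n, "fused_accuracy": acc})
    return pd.DataFrame(rows)


@dataclass
class MetricReport:
    """Named diagnostic metrics with percentile-bootstrap intervals."""

    metrics: dict               # name -> (estimate, ci_low, ci_high)
    distributions: dict = field(default_factory=dict)
    coverage: float = 1.0
    n: int = 0
    B: int = 1000
    level: float = 0.95

    def to_dict(self) -> dict:
        return {
            "n": self.n, "coverage": self.coverage, "bootstrap_B": self.B,
            "ci_level": self.level,
            "metrics": {k: {"estimate": _j(v[0]), "ci_low": _j(v[1]),
                            "ci_high": _j(v[2])}
                        for k, v in self.metrics.items()},
        }


def _j(x):
    return None if (isinstance(x, float) and np.isnan(x)) else float(x)


def evaluate_predictions(truth, probs, verdicts=None, threshold: float = 0.5,
                         B: int = 1000, level: float = 0.95, seed: int = 0,
                         ece_bins: int = 10) -> MetricReport:
    """Full metric report for one prediction set.

    ``verdicts`` may contain ``"withheld"`` entries (or the strings
    positive/negative); withheld sessions are excluded from every metric
    and reported through coverage.  Without verdicts, predictions are
    thresholded at ``threshold``.
    """
    t = _binary(truth, "truth")
    p = np.asarray(probs, dtype=float)
    if verdicts is not None:
        v = np.asarray(verdicts)
        retained = v != "withheld"
        pred = np.where(v == "positive", 1, 0)
    else:
        retained = np.ones(t.size, dtype=bool)
        pred = (p > threshold).astype(int)
    coverage = float(np.mean(retained))
    t_r, p_r, pred_r = t[retained], p[retained], pred[retained]
    if t_r.size == 0:
        raise ValueError("no retained sessions to evaluate")

    def all_metrics(tt, pp, dd):
        out = dict(confusion_metrics(tt, dd))
        try:
            out["auroc"] = roc_auc(tt, pp)
            out["auprc"] = pr_auc(tt, pp)
        except ValueError:
            out["auroc"] = float("nan")
            out["auprc"] = float("nan")
        out["brier"] = brier(pp, tt)
        out["ece"] = ece(pp, tt, ece_bins)
        return out

    point = all_metrics(t_r, p_r, pred_r)
    rng = np.random.default_rng(seed)
    names = list(point)
    dists = {k: np.empty(B) for k in names}
    n = t_r.size
    b = 0
    guard = 0
    while b < B:
        idx = rng.integers(0, n, size=n)
        vals = all_metrics(t_r[idx], p_r[idx], pred_r[idx])
        if any(np.isnan(vals[k]) for k in names):
            guard += 1
            if guard > 10 * B:
                raise RuntimeError("metrics undefined on too many resamples")
            continue
        for k in names:
            dists[k][b] = vals[k]
        b += 1
    alpha = (1.0 - level) / 2.0
    metrics = {}
    for k in names:
        lo, hi = np.percentile(dists[k], [100 * alpha, 100 * (1 - alpha)])
        metrics[k] = (point[k], float(lo), float(hi))
    return MetricReport(metrics, dists, coverage, int(n), B, level)
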