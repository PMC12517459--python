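"""Agreement, diagnostic-accuracy and association statistics.

Implements the evaluation toolkit used around the risk grids: one-vs-rest
confusion metrics with likelihood ratios, unweighted Cohen kappa with a
large-sample significance test, Pearson chi-square (no continuity
correction), the linear-by-linear trend test, Pearson/Spearman
correlations, percentile bootstrap confidence intervals, Monte-Carlo
power for the two-predictor logistic model, and per-phenotype agreement
reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "ContingencyTable",
    "PowerResult",
    "BootstrapCI",
    "DegenerateTableError",
    "confusion_metrics",
    "cohen_kappa",
    "pearson_chi_square",
    "linear_trend_test",
    "correlations",
    "bootstrap_ci",
    "simulate_power",
    "phenotype_agreement_report",
    "events_per_variable",
]


class DegenerateTableError(ValueError):
    """A contingency table with an empty row or column margin."""


@dataclass(frozen=True)
class ConfusionCounts:
    """One-vs-rest confusion counts for a single phenotype label."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    """Diagnostic-accuracy metrics; LR+ may be the +infinity sentinel.

    Undefined ratios (e.g. PPV with no positive calls) are NaN rather
    than an exception; infinite LR+ serializes as the string "inf".
    """

    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    lr_pos: float
    lr_neg: float
    kappa: float
    kappa_p: float

    def as_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
            "lr_pos": "inf" if math.isinf(self.lr_pos) else self.lr_pos,
            "lr_neg": self.lr_neg,
            "kappa": self.kappa,
            "kappa_p": self.kappa_p,
        }
        return d


@dataclass(frozen=True)
class ContingencyTable:
    """An r x c count table with optional row/column labels."""

    counts: tuple
    row_labels: Optional[tuple] = None
    col_labels: Optional[tuple] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.ndim != 2:
            raise ValueError("counts must be a 2-D table")
        if (arr < 0).any():
            raise ValueError("counts must be nonnegative")
        if arr.sum() <= 0:
            raise ValueError("grand total must be positive")

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=float)


@dataclass(frozen=True)
class PowerResult:
    power: float
    ci_low: float
    ci_high: float
    reps: int
    alpha: float

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.power <= self.ci_high):
            raise ValueError("power must lie inside its confidence interval")


@dataclass(frozen=True)
class BootstrapCI:
    point: float
    low: float
    high: float
    iterations: int
    seed: int
    failures: int = 0

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ValueError("low must not exceed high")


def _safe_div(num: float, den: float) -> float:
    if den == 0:
        return math.nan
    return num / den


def confusion_metrics(counts: ConfusionCounts, alpha: float = 0.05) -> MetricSet:
    """Standard diagnostic-accuracy metrics from one-vs-rest counts.

    LR+ = Se/(1-Sp) becomes +infinity when specificity is exactly 1 with
    nonzero sensitivity; kappa and its p-value come from the implied 2x2
    agreement table.
    """
    if counts.total == 0:
        raise ValueError("all-zero confusion counts")
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    n = counts.total
    se = _safe_div(tp, tp + fn)
    sp = _safe_div(tn, tn + fp)
    ppv = _safe_div(tp, tp + fp)
    npv = _safe_div(tn, tn + fn)
    acc = (tp + tn) / n
    if not math.isnan(se) and not math.isnan(sp):
        if sp == 1.0:
            lr_pos = math.inf if se > 0 else math.nan
        else:
            lr_pos = se / (1.0 - sp)
        lr_neg = _safe_div(1.0 - se, sp)
    else:
        lr_pos = math.nan
        lr_neg = math.nan
    pred = [1] * tp + [0] * fn + [1] * fp + [0] * tn
    ref = [1] * tp + [1] * fn + [0] * fp + [0] * tn
    kappa, kappa_p = cohen_kappa(pred, ref)
    return MetricSet(
        accuracy=acc, sensitivity=se, specificity=sp, ppv=ppv, npv=npv,
        lr_pos=lr_pos, lr_neg=lr_neg, kappa=kappa, kappa_p=kappa_p,
    )


def cohen_kappa(labels_x: Sequence, labels_y: Sequence) -> tuple[float, float]:
    """Unweighted Cohen kappa and a two-sided large-sample p-value.

    The p-value tests kappa = 0 with the normal approximation z =
    kappa / SE0, SE0 being the null standard error from the marginal
    distributions (Fleiss). kappa is 1 exactly iff the sequences are
    identical; when both marginals are degenerate on the same single
    label, agreement is trivially perfect and (1.0, 1.0) is returned.
    """
    x = np.asarray(labels_x)
    y = np.asarray(labels_y)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("label sequences must be 1-D and of equal length")
    n = x.size
    if n < 2:
        raise ValueError("need at least two paired labels")
    cats = np.unique(np.concatenate([x, y]))
    k = cats.size
    index = {c: i for i, c in enumerate(cats)}
    table = np.zeros((k, k))
    for xi, yi in zip(x, y):
        table[index[xi], index[yi]] += 1
    table /= n
    po = float(np.trace(table))
    p_row = table.sum(axis=1)
    p_col = table.sum(axis=0)
    pe = float(np.dot(p_row, p_col))
    if pe >= 1.0:
        return (1.0, 1.0) if po == 1.0 else (0.0, 1.0)
    kappa = (po - pe) / (1.0 - pe)
    # Fleiss null SE of kappa
    num = pe + pe**2 - float(np.sum(p_row * p_col * (p_row + p_col)))
    se0 = math.sqrt(max(num, 0.0) / (n * (1.0 - pe) ** 2))
    if se0 == 0:
        p_value = 1.0 if kappa == 0 else 0.0
    else:
        z = kappa / se0
        p_value = float(2.0 * stats.norm.sf(abs(z)))
    p_value = min(max(p_value, math.ulp(0.0)), 1.0)
    return float(kappa), p_value


def pearson_chi_square(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction.

    chi2 = sum (O - E)^2 / E over all cells, df = (r-1)(c-1). Zero row or
    column margins raise a degenerate-table error.
    """
    arr = table.array
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateTableError("table has an empty row or column margin")
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=False)
    return float(chi2), int(df), float(p)


def linear_trend_test(
    table: ContingencyTable,
    row_scores: Optional[Sequence[float]] = None,
    col_scores: Optional[Sequence[float]] = None,
) -> tuple[float, float]:
    """Linear-by-linear (Mantel-Haenszel) trend test on an ordered table.

    Statistic (n-1)*r^2, with r the Pearson correlation between row and
    column scores over individual observations (integer ranks by
    default), referred to chi-square with 1 df. Requires >= 3 ordered
    rows.
    """
    arr = table.array
    r, c = arr.shape
    if r < 3:
        raise ValueError("trend test needs at least 3 ordered rows")
    u = np.asarray(row_scores if row_scores is not None else np.arange(1, r + 1),
                   dtype=float)
    v = np.asarray(col_scores if col_scores is not None else np.arange(1, c + 1),
                   dtype=float)
    n = arr.sum()
    pu = arr.sum(axis=1)
    pv = arr.sum(axis=0)
    mean_u = float(np.dot(u, pu) / n)
    mean_v = float(np.dot(v, pv) / n)
    cov = float(((u[:, None] - mean_u) * (v[None, :] - mean_v) * arr).sum())
    var_u = float(np.dot((u - mean_u) ** 2, pu))
    var_v = float(np.dot((v - mean_v) ** 2, pv))
    if var_u == 0 or var_v == 0:
        return 0.0, 1.0
    r_coef = cov / math.sqrt(var_u * var_v)
    statistic = (n - 1) * r_coef**2
    p = float(stats.chi2.sf(statistic, df=1))
    return float(statistic), p


class UndefinedCorrelationError(ValueError):
    """Correlation requested on a constant sequence."""


def correlations(x: Sequence[float], y: Sequence[float]):
    """Pearson and Spearman correlations with two-sided p-values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need equal-length 1-D sequences with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("constant input has no defined correlation")
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return (
        float(pr.statistic), float(pr.pvalue),
        float(sr.statistic), float(sr.pvalue),
    )


def bootstrap_ci(
    cohort: Sequence,
    statistic: Callable,
    iterations: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> BootstrapCI:
    """Percentile bootstrap CI for a cohort-level statistic.

    Resamples patients with replacement; a statistic that fails on a
    resample skips it (counted in ``failures``) rather than aborting.
    """
    if len(cohort) == 0:
        raise ValueError("cohort must be nonempty")
    rng = np.random.default_rng(seed)
    cohort = list(cohort)
    n = len(cohort)
    point = float(statistic(cohort))
    values = []
    failures = 0
    for _ in range(iterations):
        idx = rng.integers(0, n, size=n)
        sample = [cohort[i] for i in idx]
        try:
            values.append(float(statistic(sample)))
        except Exception:  # noqa: BLE001 - contract: skip and count
            failures += 1
    if not values:
        raise ValueError("statistic failed on every bootstrap resample")
    lo, hi = np.percentile(values, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return BootstrapCI(point=point, low=float(lo), high=float(hi),
                       iterations=iterations, seed=seed, failures=failures)


def _newton_logistic(X: np.ndarray, y: np.ndarray,
                     tol: float = 1e-9, max_iter: int = 40):
    """IRLS/Newton fit of a logistic model with intercept; returns
    (beta, covariance) or None when the iteration breaks down."""
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xd.shape[1])
    for _ in range(max_iter):
        eta = Xd @ beta
        mu = expit(eta)
        w = mu * (1 - mu)
        if np.max(w) < 1e-12:
            break
        H = Xd.T @ (Xd * w[:, None])
        g = Xd.T @ (y - mu)
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            return None
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
        if np.max(np.abs(beta)) > 40:  # separation guard
            break
    eta = Xd @ beta
    w = expit(eta) * (1 - expit(eta))
    H = Xd.T @ (Xd * w[:, None])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    return beta, cov


def simulate_power(
    truth,
    spec=None,
    n: int = 106,
    reps: int = 10000,
    alpha: float = 0.05,
    seed: int = 0,
) -> PowerResult:
    """Monte-Carlo power of the two-predictor logistic model.

    ``truth`` supplies the generating coefficients (any object with
    ``alpha``/``beta1``/``beta2`` or a 3-tuple); covariates (a, b) are
    drawn from the synthetic cohort spec's distribution (defaults to the
    reference-cohort spec in sampling mode). A replicate counts as a
    success when the model-level likelihood-ratio test of both slopes
    against the intercept-only model rejects at ``alpha`` in an
    unpenalized refit — a criterion whose size under the null equals the
    nominal level. The returned power carries an exact binomial
    confidence interval. Deterministic given ``seed``.
    """
    from dataclasses import replace as _replace

    from .cohort import CohortSpec, generate_cohort

    if reps < 1:
        raise ValueError("reps must be at least 1")
    if hasattr(truth, "beta1"):
        a0, b1, b2 = truth.alpha, truth.beta1, truth.beta2
    else:
        a0, b1, b2 = truth
    if spec is None:
        spec = CohortSpec(exact_quota=False)
    spec = _replace(spec, n=n, exact_quota=False)

    rng = np.random.default_rng(seed)
    # one covariate pool, resampled per replicate: cheap and stable
    pool = generate_cohort(_replace(spec, n=max(n * 4, 500)),
                           seed=int(rng.integers(2**31 - 1)))
    ab = np.asarray([[r.a_raw, r.b_raw] for r in pool], dtype=float)
    p_pool = expit(a0 + ab[:, 0] * b1 + ab[:, 1] * b2)
    if np.all(p_pool < 1e-12) or np.all(p_pool > 1 - 1e-12):
        raise ValueError("degenerate generator: outcome has no variance")

    hits = 0
    for _ in range(reps):
        idx = rng.integers(0, len(ab), size=n)
        X = ab[idx]
        p = expit(a0 + X[:, 0] * b1 + X[:, 1] * b2)
        y = (rng.random(n) < p).astype(float)
        if y.min() == y.max():
            continue
        fit = _newton_logistic(X, y)
        if fit is None:
            continue
        beta, _ = fit
        eta = beta[0] + X @ beta[1:]
        ll_full = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
        phat = y.mean()
        ll_null = float(n * (phat * math.log(phat)
                             + (1 - phat) * math.log(1 - phat)))
        lr = 2.0 * (ll_full - ll_null)
        if stats.chi2.sf(max(lr, 0.0), df=2) < alpha:
            hits += 1
    power = hits / reps
    ci = stats.binomtest(hits, reps).proportion_ci(confidence_level=0.95)
    return PowerResult(power=power, ci_low=float(ci.low), ci_high=float(ci.high),
                       reps=reps, alpha=alpha)


def phenotype_agreement_report(
    predicted: Sequence,
    reference: Sequence,
    labels: Optional[Sequence] = None,
):
    """Per-label one-vs-rest metrics plus overall multi-class kappa.

    Returns ``(table, overall_kappa, overall_kappa_p)`` where ``table``
    is a pandas DataFrame, one row per label in Table-style column order
    (accuracy, Se, Sp, PPV, NPV, LR+, LR-, kappa, kappa p). Labels absent
    from both sequences are marked not estimable.
    """
    import pandas as pd

    pred = np.asarray([str(p) for p in predicted])
    ref = np.asarray([str(r) for r in reference])
    if pred.shape != ref.shape:
        raise ValueError("label sequences must have equal length")
    if labels is None:
        labels = sorted(set(pred) | set(ref))
    labels = [str(l) for l in labels]
    rows = []
    for lab in labels:
        p = pred == lab
        r = ref == lab
        if not p.any() and not r.any():
            rows.append({"label": lab, "estimable": False})
            continue
        cc = ConfusionCounts(
            tp=int((p & r).sum()), fp=int((p & ~r).sum()),
            tn=int((~p & ~r).sum()), fn=int((~p & r).sum()),
        )
        ms = confusion_metrics(cc)
        rows.append({"label": lab, "estimable": True, **ms.as_dict()})
    kappa, kappa_p = cohen_kappa(pred, ref)
    cols = ["label", "estimable", "accuracy", "sensitivity", "specificity",
            "ppv", "npv", "lr_pos", "lr_neg", "kappa", "kappa_p"]
    table = pd.DataFrame(rows).reindex(columns=cols)
    return table, kappa, kappa_p


def events_per_variable(
    n: int, train_fraction: float, prevalence: float, n_predictors: int
) -> float:
    """Events-per-variable ratio for a planned logistic fit.

    The training-set size is rounded to the nearest patient, the event
    count to the nearest event, then divided by the predictor count —
    e.g. 106 patients, an 80% training split and 55.7% prevalence give
    round(round(84.8) * 0.557) = 47 events, 23.5 per predictor for two.
    """
    if n <= 0 or n_predictors <= 0:
        raise ValueError("n and n_predictors must be positive")
    if not (0 < train_fraction <= 1) or not (0 < prevalence <= 1):
        raise ValueError("train_fraction and prevalence must lie in (0, 1]")
    n_train = round(n * train_fraction)
    events = round(n_train * prevalence)
    return events / n_predictors
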