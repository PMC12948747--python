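"""Production-to-perception modelling: feature screening, sequential
regression, and Bayes-factor model evidence.

The participant-level feature table (production indices plus trait scores)
is screened with a shadow-feature random-forest wrapper: each iteration
augments the predictors with independently permuted "shadow" copies, fits
a random forest, and scores a hit for every real feature whose importance
exceeds the maximum shadow importance.  After all iterations each feature's
hit count is tested against the binomial(iterations, 1/2) reference
(two-sided): significantly above chance = confirmed, significantly below =
rejected, otherwise tentative.  This mirrors the Boruta all-relevant
selection scheme; permutation importance is the default metric (impurity
importance is available), and tentative features are left tentative.

Confirmed features then enter a forward sequential regression in order of
mean importance, stopping at the first step whose F-change is not
significant.  Finally, evidence for the selected model against the
intercept-only null is quantified with a Jeffreys-Zellner-Siow (Cauchy
g-prior) Bayes factor, labelled on the conventional ladder: BF10 in (1, 3]
weak, (3, 10] moderate, (10, 100] strong, > 100 extreme evidence (with the
reciprocal reading for BF10 < 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, special, stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

from .types import ConfigurationError, DataError


@dataclass
class SelectionResult:
    """Outcome of shadow-feature screening."""

    decisions: pd.DataFrame        # feature, decision, mean_importance, hits
    shadow_summary: dict[str, float]   # min / mean / max over iterations
    n_iterations: int

    def features(self, decision: str) -> list[str]:
        mask = self.decisions["decision"] == decision
        sub = self.decisions[mask]
        return list(sub.sort_values("mean_importance",
                                    ascending=False)["feature"])

    @property
    def confirmed(self) -> list[str]:
        return self.features("confirmed")

    @property
    def tentative(self) -> list[str]:
        return self.features("tentative")

    @property
    def rejected(self) -> list[str]:
        return self.features("rejected")


def shadow_feature_select(features: pd.DataFrame, outcome: np.ndarray,
                          n_iterations: int = 50, n_estimators: int = 100,
                          importance: str = "permutation",
                          n_permutation_repeats: int = 3,
                          alpha: float = 0.05, seed: int = 0,
                          ) -> SelectionResult:
    """All-relevant feature screening against shadow (permuted) copies.

    ``features`` is an (n, p) frame of candidate predictors (p >= 2,
    n >= 10); ``outcome`` the response.  Deterministic under ``seed``.
    """
    outcome = np.asarray(outcome, dtype=float)
    if features.shape[1] < 2:
        raise ConfigurationError("need at least 2 candidate features")
    if len(features) < 10:
        raise ConfigurationError("need at least 10 observations")
    if np.ptp(outcome) == 0:
        raise DataError("outcome is constant")
    if importance not in ("permutation", "impurity"):
        raise ConfigurationError(f"unknown importance metric {importance!r}")

    X = features.to_numpy(dtype=float)
    names = list(features.columns)
    p = X.shape[1]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 41]))
    hits = np.zeros(p, dtype=int)
    importance_sum = np.zeros(p)
    shadow_stats: list[tuple[float, float, float]] = []

    for it in range(n_iterations):
        shadow = np.column_stack([rng.permutation(X[:, j])
                                  for j in range(p)])
        X_aug = np.hstack([X, shadow])
        forest_seed = int(rng.integers(0, 2 ** 31 - 1))
        forest = RandomForestRegressor(
            n_estimators=n_estimators, random_state=forest_seed, n_jobs=1)
        forest.fit(X_aug, outcome)
        if importance == "permutation":
            perm_seed = int(rng.integers(0, 2 ** 31 - 1))
            imp = permutation_importance(
                forest, X_aug, outcome, n_repeats=n_permutation_repeats,
                random_state=perm_seed, n_jobs=1).importances_mean
        else:
            imp = forest.feature_importances_
        real, shad = imp[:p], imp[p:]
        hits += (real > shad.max()).astype(int)
        importance_sum += real
        shadow_stats.append((float(shad.min()), float(shad.mean()),
                             float(shad.max())))

    decisions = []
    for j, name in enumerate(names):
        pval = stats.binomtest(int(hits[j]), n_iterations, 0.5).pvalue
        if pval < alpha and hits[j] > n_iterations / 2:
            decision = "confirmed"
        elif pval < alpha and hits[j] < n_iterations / 2:
            decision = "rejected"
        else:
            decision = "tentative"
        decisions.append((name, decision, importance_sum[j] / n_iterations,
                          int(hits[j]), float(pval)))
    table = pd.DataFrame(decisions, columns=[
        "feature", "decision", "mean_importance", "hits", "p_value"])
    shadow_arr = np.asarray(shadow_stats)
    return SelectionResult(
        decisions=table,
        shadow_summary={"min": float(shadow_arr[:, 0].mean()),
                        "mean": float(shadow_arr[:, 1].mean()),
                        "max": float(shadow_arr[:, 2].mean())},
        n_iterations=n_iterations)


@dataclass
class RegressionStep:
    feature: str
    entered: bool
    f_change: float
    p_value: float
    r2_change: float
    r2: float


@dataclass
class SequentialRegressionResult:
    steps: list[RegressionStep]
    entered: list[str]
    r2: float
    coefficients: dict[str, float]
    n: int

    @property
    def r2_changes(self) -> dict[str, float]:
        return {s.feature: s.r2_change for s in self.steps if s.entered}


def sequential_regression(outcome: np.ndarray, predictors: pd.DataFrame,
                          alpha_entry: float = 0.05,
                          ) -> SequentialRegressionResult:
    """Forward stepwise OLS in the supplied predictor order.

    Predictors (ordered by mean importance, most important first) are added
    one at a time; entry stops at the first step whose nested-model
    F-change has p >= ``alpha_entry``.  A step whose column is collinear to
    singularity with the current model is skipped with a warning.  Reports
    F-change, its p-value and the R^2 increment for every attempted step.
    """
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    if n <= predictors.shape[1] + 2:
        raise DataError("too few observations for the candidate steps")
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        raise DataError("outcome is constant")

    X_cur = np.ones((n, 1))
    rss_cur = tss
    steps: list[RegressionStep] = []
    entered: list[str] = []
    for name in predictors.columns:
        col = predictors[name].to_numpy(dtype=float)
        X_new = np.column_stack([X_cur, col])
        if np.linalg.matrix_rank(X_new) < X_new.shape[1]:
            import warnings as _warnings
            _warnings.warn(
                f"predictor {name!r} is collinear with the current model; "
                "step skipped", stacklevel=2)
            continue
        beta, _, _, _ = np.linalg.lstsq(X_new, y, rcond=None)
        rss_new = ((y - X_new @ beta) ** 2).sum()
        df_new = n - X_new.shape[1]
        if df_new <= 0:
            break
        if rss_new == 0:
            f_change, pval = np.inf, 0.0
        else:
            f_change = (rss_cur - rss_new) / (rss_new / df_new)
            pval = float(stats.f.sf(f_change, 1, df_new))
        r2_new = 1 - rss_new / tss
        step = RegressionStep(feature=name, entered=pval < alpha_entry,
                              f_change=float(f_change), p_value=pval,
                              r2_change=float(r2_new - (1 - rss_cur / tss)),
                              r2=float(r2_new))
        steps.append(step)
        if not step.entered:
            break
        X_cur, rss_cur = X_new, rss_new
        entered.append(name)

    beta, _, _, _ = np.linalg.lstsq(X_cur, y, rcond=None)
    coefs = {"intercept": float(beta[0])}
    coefs.update({name: float(b) for name, b in zip(entered, beta[1:])})
    return SequentialRegressionResult(
        steps=steps, entered=entered, r2=float(1 - rss_cur / tss),
        coefficients=coefs, n=n)


# ---------------------------------------------------------------------------
# JZS Bayes factor for linear regression

def jzs_bf_regression(outcome: np.ndarray, predictors: pd.DataFrame | np.ndarray,
                      r_scale: float = math.sqrt(2) / 2) -> float:
    """JZS (Zellner-Siow Cauchy g-prior) Bayes factor of the regression of
    ``outcome`` on ``predictors`` against the intercept-only model.

    Computed as the one-dimensional integral over the g-prior mixing
    variable::

        BF10 = int_0^inf (1+g)^((n-p-1)/2) [1 + g(1-R^2)]^(-(n-1)/2)
               pi(g) dg

    with pi(g) the inverse-gamma(1/2, n r^2 / 2) density implied by the
    Cauchy prior of scale ``r_scale`` on the standardised coefficients.
    The default scale sqrt(2)/2 is the conventional "wide" setting; it is
    configurable because software defaults differ.
    """
    y = np.asarray(outcome, dtype=float)
    X = np.asarray(predictors, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if p < 1:
        raise ConfigurationError("need at least one predictor")
    if n <= p + 2:
        raise DataError("too few observations for the Bayes factor")
    Xc = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise DataError("singular design matrix")
    beta, _, _, _ = np.linalg.lstsq(Xc, y, rcond=None)
    rss = ((y - Xc @ beta) ** 2).sum()
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        raise DataError("outcome is constant")
    r2 = 1 - rss / tss

    a = n * r_scale ** 2 / 2.0
    log_norm = 0.5 * math.log(a) - special.gammaln(0.5)

    def log_integrand(log_g: float) -> float:
        g = math.exp(log_g)
        return ((n - p - 1) / 2 * math.log1p(g)
                - (n - 1) / 2 * math.log1p(g * (1 - r2))
                + log_norm - 1.5 * log_g - a / g
                + log_g)          # Jacobian of g = exp(u)

    # Integrate in log-g space; shift by the maximum for stability.
    grid = np.linspace(-12, 25, 400)
    values = np.array([log_integrand(u) for u in grid])
    shift = values.max()
    integral, _ = integrate.quad(
        lambda u: math.exp(log_integrand(u) - shift), -40, 40, limit=200)
    return float(math.exp(shift) * integral)


def classify_bf(bf10: float) -> str:
    """Evidence label for a BF10 on the conventional ladder.

    (1, 3] weak, (3, 10] moderate, (10, 100] strong, > 100 extreme evidence
    for the alternative; reciprocal values earn the mirrored label for the
    null; exactly 1 is no evidence.
    """
    if bf10 <= 0 or not np.isfinite(bf10):
        raise ValueError(f"BF10 must be positive and finite, got {bf10}")
    if bf10 == 1:
        return "no evidence"
    value, target = (bf10, "alternative") if bf10 > 1 else (1 / bf10, "null")
    if value > 100:
        strength = "extreme"
    elif value > 10:
        strength = "strong"
    elif value > 3:
        strength = "moderate"
    else:
        strength = "weak"
    suffix = "" if target == "alternative" else " for the null"
    return f"{strength} evidence{suffix}"


@dataclass
class BayesFactorResult:
    bf10: float
    label: str
    r_scale: float


def bayes_factor_model(outcome: np.ndarray,
                       predictors: pd.DataFrame | np.ndarray,
                       r_scale: float = math.sqrt(2) / 2) -> BayesFactorResult:
    """BF10 of the predictor model against the intercept-only null, with
    its evidence label."""
    bf10 = jzs_bf_regression(outcome, predictors, r_scale=r_scale)
    return BayesFactorResult(bf10=bf10, label=classify_bf(bf10),
                             r_scale=r_scale)


@dataclass
class GroupAnalysis:
    group: str
    selection: SelectionResult
    regression: SequentialRegressionResult | None
    bayes: BayesFactorResult | None


def run_production_perception(feature_table: pd.DataFrame,
                              outcome_col: str = "er_accuracy",
                              group_col: str = "group",
                              feature_cols: list[str] | None = None,
                              n_iterations: int = 50,
                              alpha_entry: float = 0.05,
                              seed: int = 0,
                              **select_kwargs) -> dict[str, GroupAnalysis]:
    """Screen, regress and weigh evidence separately per group.

    Confirmed features enter the sequential regression in descending mean
    importance; the Bayes factor compares the entered-predictor model to
    the intercept-only null.  Returns one analysis per group label.
    """
    if feature_cols is None:
        feature_cols = [c for c in feature_table.columns
                        if c not in (outcome_col, group_col, "participant_id")]
    out: dict[str, GroupAnalysis] = {}
    for group, sub in feature_table.groupby(group_col):
        X = sub[feature_cols]
        y = sub[outcome_col].to_numpy(dtype=float)
        selection = shadow_feature_select(
            X, y, n_iterations=n_iterations, seed=seed, **select_kwargs)
        ordered = selection.confirmed
        regression = None
        bayes = None
        if ordered:
            regression = sequential_regression(
                y, sub[ordered], alpha_entry=alpha_entry)
            if regression.entered:
                bayes = bayes_factor_model(y, sub[regression.entered])
        out[str(group)] = GroupAnalysis(group=str(group), selection=selection,
                                        regression=regression, bayes=bayes)
    return out
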