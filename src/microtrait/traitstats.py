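"""Trait-association statistics for microstate stability.

Covers the statistical layer of the analysis: scoring the 12-item short-form
Aggression Questionnaire (AQ-12; four subscales of three items each, 1-6
Likert, no reverse scoring), quantifying the consistency of stability metrics
across the four microstate classes (random-intercept mixed model vs. a fixed
model, likelihood-ratio test, and a one-way intraclass correlation), simple
standardized regressions of aggression on mean duration / mean occurrence,
and gender moderation with simple slopes (the classic "model 1" moderation:
``y ~ x + g + x:g`` with y and x z-scored over the whole sample and gender
coded 0/1).

Ordinary model fits go through statsmodels (OLS, MixedLM); this module owns
the conventions: standardization, ICC form, LRT reference distribution,
simple-slope definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

__all__ = [
    "AQScores",
    "AQ_SUBSCALES",
    "score_aq",
    "to_long_table",
    "ICCResult",
    "icc_oneway",
    "ModelComparisonResult",
    "compare_fixed_vs_random_intercept",
    "RegressionResult",
    "regress_standardized",
    "ModerationResult",
    "moderation_model1",
    "run_full_analysis",
    "AnalysisBundle",
    "TraitModerationModel",
    "TraitModerationResults",
]

#: Item -> subscale map of the short-form AQ (three consecutive items per
#: subscale, in the order physical, verbal, hostility, anger).
AQ_SUBSCALES: dict[str, tuple[int, int, int]] = {
    "physical": (0, 1, 2),
    "verbal": (3, 4, 5),
    "hostility": (6, 7, 8),
    "anger": (9, 10, 11),
}


@dataclass(frozen=True)
class AQScores:
    total: float
    physical: float
    verbal: float
    hostility: float
    anger: float

    def as_dict(self) -> dict[str, float]:
        return {
            "aq_total": self.total,
            "aq_physical": self.physical,
            "aq_verbal": self.verbal,
            "aq_hostility": self.hostility,
            "aq_anger": self.anger,
        }


def score_aq(item_responses) -> AQScores:
    """Score 12 AQ items: total = mean of all, subscale = mean of its three.

    Items must be integers in 1..6; anything missing or out of range raises
    (subjects with incomplete data are excluded, not imputed).
    """
    items = np.asarray(item_responses, dtype=float)
    if items.shape != (12,):
        raise ValueError(f"expected exactly 12 item responses, got shape {items.shape}")
    if np.any(~np.isfinite(items)):
        raise ValueError("missing AQ item response")
    if np.any((items < 1) | (items > 6)):
        raise ValueError("AQ item responses must lie in 1..6")
    subs = {name: float(items[list(ix)].mean()) for name, ix in AQ_SUBSCALES.items()}
    return AQScores(total=float(items.mean()), **subs)


def to_long_table(subject_table: pd.DataFrame, types=("A", "B", "C", "D")) -> pd.DataFrame:
    """Wide subject table -> long format (one row per subject x class)."""
    rows = []
    for _, r in subject_table.iterrows():
        for t in types:
            rows.append(
                {
                    "subject_id": r["subject_id"],
                    "microstate_type": t,
                    "duration_ms": r[f"duration_{t}_ms"],
                    "occurrence_hz": r[f"occurrence_{t}_hz"],
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# consistency across classes: ICC and mixed-model comparison
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ICCResult:
    icc: float
    variance_between: float
    variance_within: float


_METRIC_COLS = {"duration": "duration_ms", "occurrence": "occurrence_hz"}


def _metric_column(long_table: pd.DataFrame, metric: str) -> str:
    if metric not in _METRIC_COLS:
        raise ValueError(f"metric must be one of {sorted(_METRIC_COLS)}")
    return _METRIC_COLS[metric]


def icc_oneway(long_table: pd.DataFrame, metric: str = "duration") -> ICCResult:
    """One-way random-effects ICC of a stability metric across classes.

    Fits ``metric ~ 1`` with a subject random intercept (REML) and reports
    ``sigma2_between / (sigma2_between + sigma2_within)``. Negative
    component estimates are truncated at zero by the boundary of the
    optimizer.
    """
    col = _metric_column(long_table, metric)
    df = long_table[["subject_id", col]].rename(columns={col: "y"})
    if df["subject_id"].nunique() < 2:
        raise ValueError("ICC needs at least 2 subjects")
    if float(np.var(df["y"])) == 0:
        raise ValueError("metric has zero total variance")
    md = smf.mixedlm("y ~ 1", df, groups=df["subject_id"])
    with np.errstate(all="ignore"):
        fit = md.fit(reml=True)
    var_b = max(float(fit.cov_re.iloc[0, 0]), 0.0)
    var_w = float(fit.scale)
    return ICCResult(icc=var_b / (var_b + var_w), variance_between=var_b, variance_within=var_w)


@dataclass(frozen=True)
class ModelComparisonResult:
    loglik_fixed: float
    loglik_mixed: float
    lrt_statistic: float
    p_value: float


def compare_fixed_vs_random_intercept(
    long_table: pd.DataFrame,
    metric: str = "duration",
    boundary_mixture: bool = False,
) -> ModelComparisonResult:
    """LRT of a subject random intercept, over a fixed effect of class.

    Both models include microstate class as a categorical fixed effect and
    are fitted by maximum likelihood; the mixed model adds a random intercept
    per subject. The default p-value uses chi-square with df = 1
    (conservative at the variance boundary); ``boundary_mixture=True``
    switches to the 50:50 chi0/chi1 mixture.
    """
    import warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    col = _metric_column(long_table, metric)
    df = long_table[["subject_id", "microstate_type", col]].rename(columns={col: "y"})
    fixed = smf.ols("y ~ C(microstate_type)", df).fit()
    md = smf.mixedlm("y ~ C(microstate_type)", df, groups=df["subject_id"])
    with np.errstate(all="ignore"), warnings.catch_warnings():
        # at a zero variance component the gradient stalls on the boundary;
        # the profiled likelihood is still valid there
        warnings.simplefilter("ignore", ConvergenceWarning)
        mixed = md.fit(reml=False)
    if not np.isfinite(mixed.llf):
        raise RuntimeError(f"mixed model did not converge: {mixed.summary()}")
    ll_f, ll_m = float(fixed.llf), float(mixed.llf)
    lrt = max(0.0, 2.0 * (ll_m - ll_f))
    p = float(sps.chi2.sf(lrt, df=1))
    if boundary_mixture:
        p = 0.5 * p if lrt > 0 else 1.0
    return ModelComparisonResult(
        loglik_fixed=ll_f,
        loglik_mixed=max(ll_m, ll_f),
        lrt_statistic=lrt,
        p_value=p,
    )


# --------------------------------------------------------------------------
# regression and moderation
# --------------------------------------------------------------------------


def _zscore(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    sd = v.std(ddof=1)
    if sd == 0:
        raise ValueError("cannot z-score a constant variable")
    return (v - v.mean()) / sd


@dataclass(frozen=True)
class RegressionResult:
    beta_standardized: float
    p_value: float
    r_squared: float
    n: int


def regress_standardized(y, x) -> RegressionResult:
    """OLS of z-scored y on z-scored x; beta equals the Pearson correlation."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be 1-D and equally long")
    if y.size < 3:
        raise ValueError("need n >= 3")
    zy, zx = _zscore(y), _zscore(x)
    fit = sm.OLS(zy, sm.add_constant(zx)).fit()
    return RegressionResult(
        beta_standardized=float(fit.params[1]),
        p_value=float(fit.pvalues[1]),
        r_squared=float(fit.rsquared),
        n=int(y.size),
    )


@dataclass(frozen=True)
class ModerationResult:
    interaction_b: float
    t_value: float
    df: int
    p_value: float
    ci_low: float
    ci_high: float
    r_squared: float
    r_squared_change: float
    simple_slopes: dict[str, RegressionResult]
    interaction_b_raw: float
    n: int


def moderation_model1(y, x, g) -> ModerationResult:
    """Gender-moderated regression with simple slopes.

    Fits ``y = b0 + b1 x + b2 g + b3 (x * g)`` with y and x z-scored over the
    whole sample and the two-level moderator coded 0/1 (levels in sorted
    order; the reference level is the first). Reports the interaction
    coefficient with t, df = n - 4, two-sided p and 95% CI, the model R²
    and its change over the no-interaction model, plus the within-level
    standardized simple slopes. ``interaction_b_raw`` is the same
    coefficient from the fit on unstandardized y and x.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    g = np.asarray(g)
    if not (y.shape == x.shape == g.shape) or y.ndim != 1:
        raise ValueError("y, x, g must be 1-D and equally long")
    levels = sorted(pd.unique(g).tolist())
    if len(levels) != 2:
        raise ValueError(f"moderator must have exactly 2 levels, got {levels}")
    g01 = (g == levels[1]).astype(float)
    if min(g01.sum(), (1 - g01).sum()) < 3:
        raise ValueError("need n >= 3 in each moderator level")

    def _fit(yv, xv):
        X = np.column_stack([np.ones_like(xv), xv, g01, xv * g01])
        return sm.OLS(yv, X).fit()

    zy, zx = _zscore(y), _zscore(x)
    full = _fit(zy, zx)
    reduced = sm.OLS(zy, np.column_stack([np.ones_like(zx), zx, g01])).fit()
    raw = _fit(y, x)
    ci = full.conf_int()[3]
    slopes: dict[str, RegressionResult] = {}
    for lvl in levels:
        sel = g == lvl
        try:
            slopes[str(lvl)] = regress_standardized(y[sel], x[sel])
        except ValueError:
            # degenerate subgroup (constant outcome/predictor): slope undefined
            slopes[str(lvl)] = RegressionResult(
                beta_standardized=float("nan"),
                p_value=float("nan"),
                r_squared=float("nan"),
                n=int(sel.sum()),
            )
    return ModerationResult(
        interaction_b=float(full.params[3]),
        t_value=float(full.tvalues[3]),
        df=int(full.df_resid),
        p_value=float(full.pvalues[3]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        r_squared=float(full.rsquared),
        r_squared_change=float(max(0.0, full.rsquared - reduced.rsquared)),
        simple_slopes=slopes,
        interaction_b_raw=float(raw.params[3]),
        n=int(y.size),
    )


# --------------------------------------------------------------------------
# the full grid
# --------------------------------------------------------------------------

_OUTCOMES = ("aq_total", "aq_physical", "aq_verbal", "aq_hostility", "aq_anger")
_PREDICTORS = ("mean_duration_ms", "mean_occurrence_hz")


@dataclass
class AnalysisBundle:
    """Everything the full analysis produces: grid, ICCs, model comparisons."""

    grid: pd.DataFrame
    icc: dict[str, ICCResult]
    model_comparison: dict[str, ModelComparisonResult]
    metadata: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = ["Trait-association analysis", ""]
        for metric in self.icc:
            icc = self.icc[metric]
            cmp_ = self.model_comparison[metric]
            lines.append(
                f"  {metric}: ICC = {icc.icc:.3f} "
                f"(LRT = {cmp_.lrt_statistic:.1f}, p = {cmp_.p_value:.2g})"
            )
        lines.append("")
        cols = [
            "outcome", "predictor", "beta_pooled", "p_pooled",
            "beta_male", "beta_female", "interaction_b", "interaction_p",
            "r_squared", "r_squared_change",
        ]
        header = " ".join(f"{c:>16}" for c in cols)
        lines.append(header)
        for _, r in self.grid.iterrows():
            vals = []
            for c in cols:
                v = r[c]
                vals.append(f"{v:>16}" if isinstance(v, str) else f"{v:>16.3f}")
            lines.append(" ".join(vals))
        return "\n".join(lines)


def run_full_analysis(
    subject_table: pd.DataFrame,
    include_consistency: bool = True,
    types=("A", "B", "C", "D"),
) -> AnalysisBundle:
    """The complete statistical grid for one cohort table.

    For each outcome (AQ total plus the four subscales) and each predictor
    (mean duration, mean occurrence): the pooled standardized regression,
    the per-gender standardized simple slopes, and the gender-moderation
    model. With `include_consistency`, also the ICC and the fixed-vs-mixed
    comparison of the per-class metrics. No multiple-testing correction is
    applied; every cell is a two-sided test at its nominal level.
    """
    df = subject_table
    missing = [c for c in ("gender", *_PREDICTORS, *_OUTCOMES) if c not in df.columns]
    if missing:
        raise ValueError(f"subject table lacks required columns: {missing}")
    rows = []
    for outcome in _OUTCOMES:
        for pred in _PREDICTORS:
            pooled = regress_standardized(df[outcome], df[pred])
            mod = moderation_model1(df[outcome], df[pred], df["gender"].to_numpy())
            male = mod.simple_slopes.get("male")
            female = mod.simple_slopes.get("female")
            rows.append(
                {
                    "outcome": outcome,
                    "predictor": pred,
                    "n": pooled.n,
                    "beta_pooled": pooled.beta_standardized,
                    "p_pooled": pooled.p_value,
                    "beta_male": male.beta_standardized if male else np.nan,
                    "p_male": male.p_value if male else np.nan,
                    "beta_female": female.beta_standardized if female else np.nan,
                    "p_female": female.p_value if female else np.nan,
                    "interaction_b": mod.interaction_b,
                    "interaction_t": mod.t_value,
                    "interaction_df": mod.df,
                    "interaction_p": mod.p_value,
                    "ci_low": mod.ci_low,
                    "ci_high": mod.ci_high,
                    "r_squared": mod.r_squared,
                    "r_squared_change": mod.r_squared_change,
                }
            )
    grid = pd.DataFrame(rows)
    icc: dict[str, ICCResult] = {}
    cmps: dict[str, ModelComparisonResult] = {}
    if include_consistency:
        have_types = all(f"duration_{t}_ms" in df.columns for t in types)
        if have_types:
            long = to_long_table(df, types=types)
            for metric in ("duration", "occurrence"):
                icc[metric] = icc_oneway(long, metric)
                cmps[metric] = compare_fixed_vs_random_intercept(long, metric)
    return AnalysisBundle(
        grid=grid,
        icc=icc,
        model_comparison=cmps,
        metadata={
            "n_subjects": int(len(df)),
            "multiple_testing_correction": "none (each cell at nominal alpha = 0.05)",
        },
    )


# --------------------------------------------------------------------------
# model-object interface
# --------------------------------------------------------------------------


class TraitModerationModel:
    """Moderated association between one trait and one stability metric.

    A thin modelling object over :func:`regress_standardized` and
    :func:`moderation_model1`; build it from an analysis-ready subject table
    with :meth:`from_dataframe` and call :meth:`fit`.
    """

    def __init__(self, y: np.ndarray, x: np.ndarray, g: np.ndarray, names=None):
        self.y = np.asarray(y, dtype=float)
        self.x = np.asarray(x, dtype=float)
        self.g = np.asarray(g)
        self.names = names or {"outcome": "y", "predictor": "x", "moderator": "g"}

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str = "aq_total",
        predictor: str = "mean_duration_ms",
        moderator: str = "gender",
    ) -> "TraitModerationModel":
        return cls(
            df[outcome].to_numpy(),
            df[predictor].to_numpy(),
            df[moderator].to_numpy(),
            names={"outcome": outcome, "predictor": predictor, "moderator": moderator},
        )

    def fit(self) -> "TraitModerationResults":
        pooled = regress_standardized(self.y, self.x)
        moderation = moderation_model1(self.y, self.x, self.g)
        return TraitModerationResults(self, pooled, moderation)


@dataclass
class TraitModerationResults:
    model: TraitModerationModel
    pooled: RegressionResult
    moderation: ModerationResult

    def summary(self) -> str:
        n = self.model.names
        m = self.moderation
        lines = [
            f"{n['outcome']} ~ {n['predictor']} (moderated by {n['moderator']})",
            f"  pooled:      beta = {self.pooled.beta_standardized:+.3f}, "
            f"p = {self.pooled.p_value:.3g}, R2 = {self.pooled.r_squared:.3f}, "
            f"n = {self.pooled.n}",
        ]
        for lvl, s in m.simple_slopes.items():
            lines.append(
                f"  {lvl:>10}:  beta = {s.beta_standardized:+.3f}, "
                f"p = {s.p_value:.3g} (n = {s.n})"
            )
        lines.append(
            f"  interaction: b = {m.interaction_b:+.3f}, t({m.df}) = {m.t_value:.2f}, "
            f"p = {m.p_value:.3g}, 95% CI [{m.ci_low:.3f}, {m.ci_high:.3f}], "
            f"R2 = {m.r_squared:.3f}, dR2 = {m.r_squared_change:.3f}"
        )
        return "\n".join(lines)
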