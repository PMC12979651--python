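"""Group-screening statistics.

The screening funnel runs in two stages.  First, each behavioral or
oculomotor *indicator* (RT, saccade count, ...) is fitted with a
random-intercept linear mixed model over the participant x condition long
table: group, congruency, SOA and cue type (and their interactions) enter as
fixed effects, with z-scored demographic and clinical covariates (age, sex,
CARS, CDI, STAI-C).  Indicators with any fixed-effect or covariate p below
0.15 advance.  Second, the advancing indicators' condition-level columns are
compared between groups with Mann-Whitney U tests, corrected by
Benjamini-Hochberg within the candidate set; survivors feed the classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

COVARIATES = ("age", "cars", "cdi", "staic_state", "staic_trait")


@dataclass
class LmmResult:
    """Fixed-effect table and variance decomposition of one mixed model."""

    response: str
    table: pd.DataFrame  # index: effect name; columns: beta, z, p
    var_fixed: float
    var_random: float
    var_residual: float
    converged: bool
    singular: bool

    @property
    def r2_marginal(self) -> float:
        tot = self.var_fixed + self.var_random + self.var_residual
        return self.var_fixed / tot if tot > 0 else float("nan")

    @property
    def r2_conditional(self) -> float:
        tot = self.var_fixed + self.var_random + self.var_residual
        return (self.var_fixed + self.var_random) / tot if tot > 0 else float("nan")

    def min_p(self, exclude_intercept: bool = True) -> float:
        t = self.table
        if t.empty:
            return float("nan")
        if exclude_intercept:
            t = t[~t.index.str.contains("Intercept")]
        return float(t["p"].min()) if len(t) else float("nan")


def zscore_columns(df: pd.DataFrame, cols) -> pd.DataFrame:
    """Z-transform continuous predictor columns (constant columns untouched)."""
    out = df.copy()
    for c in cols:
        v = pd.to_numeric(out[c], errors="coerce")
        sd = v.std(ddof=0)
        if sd and np.isfinite(sd) and sd > 0:
            out[c] = (v - v.mean()) / sd
        else:
            out[c] = v - v.mean()
    return out


def fit_screening_lmm(
    long_table: pd.DataFrame,
    response: str,
    covariates=COVARIATES,
    include_sex: bool = True,
) -> LmmResult:
    """Random-intercept LMM for one indicator over the condition long table.

    ``long_table`` has one row per participant x condition with columns
    ``participant``, ``group``, ``congruency``, ``soa_ms``, ``cue_type``,
    the covariates, and the response.  Design factors with more than one
    level present enter as fixed effects with full interactions; continuous
    covariates are z-scored; fitting is by REML with z-tests on the fixed
    effects.  Marginal and conditional R-squared follow the variance
    partition of fixed, random-intercept and residual components.
    """
    data = long_table.dropna(subset=[response]).copy()
    data = zscore_columns(data, [c for c in covariates if c in data.columns])
    factors = []
    for fac, expr in (
        ("group", "C(group, Treatment('TD'))"),
        ("congruency", "C(congruency, Treatment('cong'))"),
        ("soa_ms", "C(soa_ms)"),
        ("cue_type", "C(cue_type, Treatment('nonsocial'))"),
    ):
        if fac in data.columns and data[fac].nunique() > 1:
            factors.append(expr)
    tail = [c for c in covariates if c in data.columns]
    if include_sex and "sex" in data.columns and data["sex"].nunique() > 1:
        tail.append("C(sex, Treatment('M'))")  # female as indicator level

    model = fit = None
    last_err: Exception | None = None
    # full factorial first; small samples may only support additive effects
    for joiner in (" * ", " + "):
        rhs = joiner.join(factors) if factors else "1"
        formula = f"Q('{response}') ~ " + " + ".join([rhs] + tail)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ConvergenceWarning)
                warnings.simplefilter("ignore", RuntimeWarning)
                warnings.simplefilter("ignore", UserWarning)
                model = smf.mixedlm(formula, data, groups=data["participant"])
                fit = model.fit(reml=True)
            break
        except (np.linalg.LinAlgError, ValueError) as err:
            last_err = err
            model = fit = None
    if fit is None:
        warnings.warn(
            f"mixed model for {response!r} is singular ({last_err}); "
            "indicator flagged and skipped", stacklevel=2)
        empty = pd.DataFrame(columns=["beta", "z", "p"])
        return LmmResult(response, empty, float("nan"), float("nan"),
                         float("nan"), converged=False, singular=True)

    fe = pd.DataFrame({
        "beta": fit.fe_params,
        "z": fit.tvalues[fit.fe_params.index],
        "p": fit.pvalues[fit.fe_params.index],
    })
    exog = pd.DataFrame(model.exog, columns=model.exog_names)
    pred_fixed = exog.to_numpy() @ fit.fe_params.to_numpy()
    var_fixed = float(np.var(pred_fixed))
    var_random = float(fit.cov_re.iloc[0, 0]) if fit.cov_re.size else 0.0
    var_residual = float(fit.scale)
    singular = var_random <= 1e-10 * max(var_residual, 1e-12)
    return LmmResult(
        response=response, table=fe, var_fixed=var_fixed, var_random=var_random,
        var_residual=var_residual, converged=bool(fit.converged), singular=singular,
    )


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test with midranks for ties.

    Exact p by enumeration for small samples without ties (at most 8 per
    group); the normal approximation with tie correction otherwise.  When
    every value in both samples is identical the test is vacuous and p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return float(x.size * y.size / 2.0), 1.0
    has_ties = len(np.unique(pooled)) < pooled.size
    small = max(x.size, y.size) <= 8
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=(method == "asymptotic"))
    return float(res.statistic), float(res.pvalue)


def cohens_d(x, y) -> float:
    """Cohen's d with the classic pooled standard deviation.

    Pooled variance weights each group's variance by its degrees of freedom:
    ``s_p^2 = ((n_x-1) s_x^2 + (n_y-1) s_y^2) / (n_x + n_y - 2)``.
    Undefined (NaN) when the pooled SD is zero.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    nx, ny = x.size, y.size
    sp2 = ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    if sp2 <= 0:
        return float("nan")
    return float((x.mean() - y.mean()) / np.sqrt(sp2))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ScreenReport:
    """Outcome of the two-stage screening funnel."""

    lmm_summary: pd.DataFrame        # indicator, min_p, r2m, r2c, advanced
    tests: pd.DataFrame              # column-level MWU results with d and BH p
    selected: list[str] = field(default_factory=list)


def group_feature_tests(
    matrix: pd.DataFrame, columns, group_col: str = "group",
    positive: str = "ADHD",
) -> pd.DataFrame:
    """Mann-Whitney U + Cohen's d per feature column, ADHD vs TD, complete cases."""
    rows = []
    for col in columns:
        v = pd.to_numeric(matrix[col], errors="coerce")
        x = v[(matrix[group_col] == positive) & v.notna()].to_numpy()
        y = v[(matrix[group_col] != positive) & v.notna()].to_numpy()
        if x.size < 2 or y.size < 2:
            continue
        u, p = mann_whitney(x, y)
        rows.append({
            "feature": col, "n_adhd": x.size, "n_td": y.size,
            "mean_adhd": x.mean(), "sd_adhd": x.std(ddof=1),
            "mean_td": y.mean(), "sd_td": y.std(ddof=1),
            "U": u, "p_raw": p, "cohens_d": cohens_d(x, y),
        })
    out = pd.DataFrame(rows, columns=[
        "feature", "n_adhd", "n_td", "mean_adhd", "sd_adhd", "mean_td", "sd_td",
        "U", "p_raw", "cohens_d"])
    if len(out):
        out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    else:
        out["p_adj"] = pd.Series(dtype=float)
    return out


def screen_features(
    lmm_results: dict[str, LmmResult],
    participant_matrix: pd.DataFrame,
    indicator_columns: dict[str, list[str]],
    alpha_screen: float = 0.15,
    alpha_final: float = 0.05,
) -> ScreenReport:
    """Two-stage funnel: LMM screen at ``alpha_screen``, then MWU + BH.

    ``indicator_columns`` maps each indicator to the participant-matrix
    columns (condition cells, GCE columns, totals) it owns.  Indicators whose
    mixed model shows no fixed-effect or covariate p below ``alpha_screen``
    are dropped before any group test; BH correction applies within the
    candidate column set, and columns with adjusted p below ``alpha_final``
    are selected.
    """
    lmm_rows = []
    candidates: list[str] = []
    for indicator, res in lmm_results.items():
        advanced = res.min_p() < alpha_screen
        lmm_rows.append({
            "indicator": indicator, "min_p": res.min_p(),
            "r2_marginal": res.r2_marginal, "r2_conditional": res.r2_conditional,
            "converged": res.converged, "singular": res.singular, "advanced": advanced,
        })
        if advanced:
            candidates.extend(c for c in indicator_columns.get(indicator, ())
                              if c in participant_matrix.columns)
    tests = group_feature_tests(participant_matrix, candidates)
    selected = tests.loc[tests["p_adj"] < alpha_final, "feature"].tolist() if len(tests) else []
    return ScreenReport(
        lmm_summary=pd.DataFrame(lmm_rows), tests=tests, selected=selected)
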