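"""Group-level behavioral statistics.

Covers the three analyses run on trial-level RT records:

* per-participant condition means (Structure x Target cells) and the NADs
  effect (mean Random RT minus mean NADs RT, both as unweighted averages of
  the two target cells, so the cohort NADs effect equals the Structure
  main-effect mean difference of the ANOVA);
* a 2x2 repeated-measures ANOVA on the cell means, optionally extended to a
  mixed design with block Order as a between-participants factor.  With
  2-level factors every effect has 1 numerator df, so each within effect is
  computed exactly from its participant-wise contrast score (paired-t
  algebra); the between factor enters through a groupwise linear model on
  the contrast / average scores.  Partial eta^2 = F / (F + df_den) for 1-df
  effects;
* learning slopes from the linear mixed model

      rt ~ condition + trial + condition:trial + TNT + (1 | participant)

  fitted by REML, with Random as the reference condition, trial 1-based and
  uncentered within block, and NoTarget as the TNT reference, so the
  condition:trial coefficient (beta4, "beta_diff", ms per trial) is the
  extra per-trial speed-up in the structured block.  Degrees of freedom for
  the fixed-effect t tests use the Satterthwaite approximation, computed
  from the closed-form random-intercept REML criterion.

Only included trials (correct responses under 1,000 ms) enter any of these.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import RT_MAX_MS, included_mask
from .paradigm import NADS, RANDOM

logger = logging.getLogger(__name__)

TARGET = "Target"
NOTARGET = "NoTarget"

REQUIRED_COLUMNS = ("participant", "condition", "trial_index", "tnt", "rt", "correct")


@dataclass
class AnovaResult:
    effects: pd.DataFrame  # effect, F, df_num, df_den, p, partial_eta_sq
    mean_differences: pd.DataFrame  # effect, mean_diff, se
    nads_effect: pd.Series | None = None  # per participant, ms

    def effect(self, name: str) -> pd.Series:
        rows = self.effects[self.effects["effect"] == name]
        if rows.empty:
            raise KeyError(name)
        return rows.iloc[0]


@dataclass
class SlopeResult:
    params: pd.Series  # beta0..beta4 by term name
    se: pd.Series
    t: pd.Series
    df: pd.Series  # Satterthwaite df per coefficient
    p: pd.Series
    sigma2_participant: float
    sigma2_resid: float
    df_method: str = "satterthwaite"
    singular: bool = False
    converged: bool = True

    @property
    def beta_diff(self) -> float:
        return float(self.params["condition_nads:trial"])


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing required columns: {missing}")
    bad_cond = set(records["condition"].unique()) - {NADS, RANDOM}
    if bad_cond:
        raise ValueError(f"unknown condition labels: {sorted(bad_cond)}")
    bad_tnt = set(records["tnt"].unique()) - {TARGET, NOTARGET}
    if bad_tnt:
        raise ValueError(f"unknown tnt labels: {sorted(bad_tnt)}")
    return records


def add_inclusion(records: pd.DataFrame, rt_max_ms: float = RT_MAX_MS) -> pd.DataFrame:
    records = records.copy()
    records["included"] = included_mask(records, rt_max_ms)
    return records


# ---------------------------------------------------------------------------
# condition means
# ---------------------------------------------------------------------------


def condition_means(records: pd.DataFrame) -> pd.DataFrame:
    """Per-participant Structure x Target cell means over included trials.

    Returns a frame indexed by participant with columns
    (NADs, Target), (NADs, NoTarget), (Random, Target), (Random, NoTarget)
    plus ``nads_effect`` (ms).  Participants with an empty cell are dropped
    with a warning.
    """
    records = validate_records(records)
    if "included" not in records.columns:
        records = add_inclusion(records)
    inc = records[records["included"]]
    cells = inc.groupby(["participant", "condition", "tnt"])["rt"].mean().unstack(["condition", "tnt"])
    cells.columns = cells.columns.to_flat_index()  # tuple-valued flat columns
    expected = [(c, t) for c in (NADS, RANDOM) for t in (TARGET, NOTARGET)]
    for col in expected:
        if col not in cells.columns:
            cells[col] = np.nan
    cells = cells[expected]
    incomplete = cells.index[cells.isna().any(axis=1)]
    if len(incomplete):
        msg = f"dropping participants with empty design cells: {list(incomplete)}"
        logger.warning(msg)
        warnings.warn(msg)
        cells = cells.drop(index=incomplete)
    out = cells.copy()
    out["nads_effect"] = (
        cells[[(RANDOM, TARGET), (RANDOM, NOTARGET)]].mean(axis=1)
        - cells[[(NADS, TARGET), (NADS, NOTARGET)]].mean(axis=1)
    )
    return out


# ---------------------------------------------------------------------------
# repeated-measures / mixed-design ANOVA via contrast scores
# ---------------------------------------------------------------------------


def _contrast_scores(cells: pd.DataFrame) -> pd.DataFrame:
    """Average and 1-df contrast scores per participant for the 2x2 design."""
    nt = cells[(NADS, TARGET)]
    nn = cells[(NADS, NOTARGET)]
    rt_ = cells[(RANDOM, TARGET)]
    rn = cells[(RANDOM, NOTARGET)]
    return pd.DataFrame(
        {
            "avg": (nt + nn + rt_ + rn) / 4.0,
            # Structure: NADs minus Random (negative diff = faster NADs)
            "d_structure": (nt + nn) / 2.0 - (rt_ + rn) / 2.0,
            "d_target": (nt + rt_) / 2.0 - (nn + rn) / 2.0,
            "d_interaction": (nt - nn) - (rt_ - rn),
        }
    )


def _one_sample_effect(d: pd.Series) -> tuple[float, int, float, float]:
    """F, df_den, p, partial eta^2 for a within effect from its contrast."""
    n = d.size
    mean = d.mean()
    var = d.var(ddof=1)
    if var == 0.0:
        f = np.inf if mean != 0 else 0.0
        return f, n - 1, 0.0 if mean != 0 else 1.0, 1.0 if mean != 0 else 0.0
    t = mean / np.sqrt(var / n)
    f = t**2
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(f), n - 1, float(p), float(f / (f + (n - 1)))


def _grouped_effects(d: pd.Series, groups: pd.Series) -> tuple[tuple, tuple]:
    """(within main effect, within x between interaction) from a contrast.

    The main effect tests the unweighted mean of group means; the
    interaction tests the group difference.  Error is the pooled
    within-group variance, df = n - 2.
    """
    levels = list(pd.unique(groups))
    g1 = d[groups == levels[0]]
    g2 = d[groups == levels[1]]
    n1, n2 = g1.size, g2.size
    df_den = n1 + n2 - 2
    ss_err = g1.var(ddof=1) * (n1 - 1) + g2.var(ddof=1) * (n2 - 1)
    mse = ss_err / df_den
    m1, m2 = g1.mean(), g2.mean()
    half = 0.25 * (1.0 / n1 + 1.0 / n2)

    def _f(contrast_mean: float, scale: float) -> tuple:
        if mse == 0.0:
            f = np.inf if contrast_mean != 0 else 0.0
            return f, df_den, 0.0 if contrast_mean != 0 else 1.0, 1.0 if contrast_mean != 0 else 0.0
        f = contrast_mean**2 / (mse * scale)
        p = stats.f.sf(f, 1, df_den)
        return float(f), df_den, float(p), float(f / (f + df_den))

    main = _f((m1 + m2) / 2.0, half)
    inter = _f(m1 - m2, 1.0 / n1 + 1.0 / n2)
    return main, inter


def rm_anova_2x2(cell_means: pd.DataFrame, between: pd.Series | None = None) -> AnovaResult:
    """2x2 within-participants ANOVA, optionally mixed with a between factor.

    ``cell_means`` is the output of :func:`condition_means` (the
    ``nads_effect`` column, if present, is ignored).  ``between`` maps
    participant to a 2-level factor such as block order.
    """
    cells = cell_means.drop(columns=["nads_effect"], errors="ignore")
    n = cells.shape[0]
    if n < 3:
        raise ValueError("need at least 3 participants")
    sc = _contrast_scores(cells)
    rows = []
    within = [
        ("Structure", "d_structure"),
        ("Target", "d_target"),
        ("Structure x Target", "d_interaction"),
    ]
    mean_rows = [
        {"effect": "Structure", "mean_diff": float(-sc["d_structure"].mean()),
         "se": float(sc["d_structure"].std(ddof=1) / np.sqrt(n))},
        {"effect": "Target", "mean_diff": float(-sc["d_target"].mean()),
         "se": float(sc["d_target"].std(ddof=1) / np.sqrt(n))},
    ]
    if between is None:
        for name, col in within:
            f, dfd, p, eta = _one_sample_effect(sc[col])
            rows.append({"effect": name, "F": f, "df_num": 1, "df_den": dfd,
                         "p": p, "partial_eta_sq": eta})
    else:
        between = between.reindex(cells.index)
        if between.isna().any():
            raise ValueError("between factor missing for some participants")
        if between.nunique() != 2:
            raise ValueError("between factor must have exactly 2 levels")
        # between main effect from participant averages
        levels = list(pd.unique(between))
        g1 = sc.loc[between == levels[0], "avg"]
        g2 = sc.loc[between == levels[1], "avg"]
        df_den = g1.size + g2.size - 2
        mse = (g1.var(ddof=1) * (g1.size - 1) + g2.var(ddof=1) * (g2.size - 1)) / df_den
        if mse == 0.0:
            f_b = np.inf if g1.mean() != g2.mean() else 0.0
            p_b = 0.0 if f_b else 1.0
        else:
            f_b = (g1.mean() - g2.mean()) ** 2 / (mse * (1.0 / g1.size + 1.0 / g2.size))
            p_b = stats.f.sf(f_b, 1, df_den)
        rows.append({"effect": "Order", "F": float(f_b), "df_num": 1, "df_den": df_den,
                     "p": float(p_b), "partial_eta_sq": float(f_b / (f_b + df_den))})
        for name, col in within:
            main, inter = _grouped_effects(sc[col], between)
            rows.append({"effect": name, "F": main[0], "df_num": 1,
                         "df_den": main[1], "p": main[2], "partial_eta_sq": main[3]})
            rows.append({"effect": f"{name} x Order", "F": inter[0], "df_num": 1,
                         "df_den": inter[1], "p": inter[2], "partial_eta_sq": inter[3]})
    nads = cell_means["nads_effect"] if "nads_effect" in cell_means.columns else None
    return AnovaResult(pd.DataFrame(rows), pd.DataFrame(mean_rows), nads)


def order_check(cell_means: pd.DataFrame, order: pd.Series) -> AnovaResult:
    """Mixed-design ANOVA returning the Order main effect and interactions."""
    if order.reindex(cell_means.index).nunique() < 2:
        raise ValueError("order factor must have 2 levels")
    return rm_anova_2x2(cell_means, between=order)


# ---------------------------------------------------------------------------
# linear mixed model learning slopes
# ---------------------------------------------------------------------------

SLOPE_TERMS = ("intercept", "condition_nads", "trial", "tnt_target", "condition_nads:trial")


def _slope_design(records: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    cond = (records["condition"] == NADS).to_numpy(dtype=float)
    trial = records["trial_index"].to_numpy(dtype=float)
    tnt = (records["tnt"] == TARGET).to_numpy(dtype=float)
    x = np.column_stack([np.ones(len(records)), cond, trial, tnt, cond * trial])
    y = records["rt"].to_numpy(dtype=float)
    groups = records["participant"].to_numpy()
    return x, y, groups


def _reml_terms(y, x, group_slices, s2b, s2e):
    """Woodbury accumulation of the REML pieces for a random-intercept model."""
    p = x.shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet_v = 0.0
    for sl in group_slices:
        xg = x[sl]
        yg = y[sl]
        ng = xg.shape[0]
        c = s2b / (s2e + ng * s2b)
        x1 = xg.sum(axis=0)
        y1 = yg.sum()
        xtvx += (xg.T @ xg - c * np.outer(x1, x1)) / s2e
        xtvy += (xg.T @ yg - c * x1 * y1) / s2e
        ytvy += (yg @ yg - c * y1 * y1) / s2e
        logdet_v += ng * np.log(s2e) + np.log1p(ng * s2b / s2e)
    return xtvx, xtvy, ytvy, logdet_v


def _reml_loglike(y, x, group_slices, s2b, s2e):
    xtvx, xtvy, ytvy, logdet_v = _reml_terms(y, x, group_slices, s2b, s2e)
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    beta = np.linalg.solve(xtvx, xtvy)
    ypy = ytvy - xtvy @ beta
    return -0.5 * (logdet_v + logdet_xtvx + ypy)


def _satterthwaite_df(y, x, group_slices, s2b, s2e, k: int) -> float:
    """Satterthwaite df for fixed-effect k of the random-intercept model.

    df = 2 f^2 / (g' A g) with f = Var(beta_k) as a function of the variance
    components, g its gradient (finite differences) and A the asymptotic
    covariance of the variance-component estimates (inverse observed REML
    information, also by finite differences).
    """
    theta = np.array([s2b, s2e], dtype=float)

    def var_beta(th):
        xtvx, _, _, _ = _reml_terms(y, x, group_slices, max(th[0], 0.0), th[1])
        return np.linalg.inv(xtvx)[k, k]

    def ll(th):
        return _reml_loglike(y, x, group_slices, max(th[0], 0.0), th[1])

    h = np.maximum(1e-4 * np.abs(theta), 1e-8)
    grad = np.empty(2)
    for i in range(2):
        e = np.zeros(2)
        e[i] = h[i]
        grad[i] = (var_beta(theta + e) - var_beta(theta - e)) / (2 * h[i])
    hess = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            ei = np.zeros(2)
            ej = np.zeros(2)
            ei[i] = h[i]
            ej[j] = h[j]
            hess[i, j] = (
                ll(theta + ei + ej) - ll(theta + ei - ej)
                - ll(theta - ei + ej) + ll(theta - ei - ej)
            ) / (4 * h[i] * h[j])
    try:
        a = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        return np.nan
    denom = grad @ a @ grad
    if denom <= 0:
        return np.nan
    return float(2.0 * var_beta(theta) ** 2 / denom)


def fit_learning_slopes(records: pd.DataFrame) -> SlopeResult:
    """Fit the learning-slope mixed model to included trial-level records."""
    import statsmodels.api as sm

    records = validate_records(records)
    if "included" not in records.columns:
        records = add_inclusion(records)
    records = records[records["included"]].sort_values(["participant", "condition", "trial_index"])
    if records["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants")
    if records["condition"].nunique() < 2:
        raise ValueError("both conditions must be present")
    x, y, groups = _slope_design(records)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, x, groups=groups)
        res = model.fit(reml=True)
    s2e = float(res.scale)
    s2b = float(np.asarray(res.cov_re)[0, 0])
    var_y = float(np.var(y))
    s2e_eff = max(s2e, 1e-10 * max(var_y, 1.0))  # guards noiseless fixtures
    singular = s2b < 1e-8 * s2e_eff or s2e <= 1e-10 * max(var_y, 1.0)
    # group index slices (records sorted by participant)
    starts = np.flatnonzero(np.r_[True, groups[1:] != groups[:-1]])
    bounds = np.r_[starts, len(groups)]
    slices = [slice(bounds[i], bounds[i + 1]) for i in range(len(starts))]
    s2b_eff = max(s2b, 1e-10 * s2e_eff)
    xtvx, xtvy, _, _ = _reml_terms(y, x, slices, s2b_eff, s2e_eff)
    cov_beta = np.linalg.inv(xtvx)
    beta = np.linalg.solve(xtvx, xtvy)
    se = np.sqrt(np.diag(cov_beta))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = beta / se
    n, p = x.shape
    if singular:
        dfs = np.full(p, float(n - p))
        method = "residual (singular random-intercept fit)"
    else:
        dfs = np.array(
            [_satterthwaite_df(y, x, slices, s2b, s2e, k) for k in range(p)]
        )
        fallback = ~np.isfinite(dfs)
        dfs[fallback] = n - p
        method = "satterthwaite"
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dfs)
    if singular:
        logger.warning("singular random-intercept fit; estimates returned with residual df")
    idx = pd.Index(SLOPE_TERMS)
    return SlopeResult(
        params=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        t=pd.Series(tvals, index=idx),
        df=pd.Series(dfs, index=idx),
        p=pd.Series(pvals, index=idx),
        sigma2_participant=s2b,
        sigma2_resid=s2e,
        df_method=method,
        singular=singular,
        converged=bool(res.converged),
    )
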