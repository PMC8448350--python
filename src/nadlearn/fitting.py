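"""Likelihood machinery: RT transform, trial fit, optimization, model comparison.

Reaction times are standardized within their scope (z-scored with the
sample standard deviation) and squashed to (0, 1) by

    xRT = 1 / (1 + exp(zRT)),

so faster-than-average responses map above 0.5.  A learner's trial-wise
prediction p is scored against the observed xRT by

    Delta_t = 1 - |xRT_t - p_t|,

which lies in [0, 1] and acts as a per-trial likelihood.  The block
log-likelihood is the sum of log Delta_t over included trials (correct
responses faster than 1,000 ms), with Delta floored at 1e-12.  Free
parameters (alpha, gamma for TD; alpha for RW) are fitted by Nelder-Mead
restarts from a fixed lattice of start points, clamped to the unit square.
Goodness of fit is summarized by the model-fit index

    1 - LLE_model / LLE_chance,

which is 1 for an exact fit and 0 for a model no better than the constant
chance prediction of 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .models import CHANCE, CHANCE_PREDICTION, TD, LearnerParams, ModelTrace, compact_design, predictions
from .paradigm import BlockDesign

DELTA_FLOOR = 1e-12
RT_MAX_MS = 1000.0
MIN_INCLUDED_TRIALS = 10

# deterministic Nelder-Mead start lattice on the unit square
TD_STARTS = tuple(
    (a, g) for a in (0.1, 0.3, 0.5, 0.7, 0.9) for g in (0.25, 0.75)
)
RW_STARTS = tuple((a,) for a in np.linspace(0.05, 0.95, 10))


@dataclass(frozen=True)
class FitConfig:
    rt_max_ms: float = RT_MAX_MS
    delta_floor: float = DELTA_FLOOR
    xatol: float = 1e-4
    fatol: float = 1e-7
    maxiter: int = 400


@dataclass
class FitResult:
    model_kind: str
    alpha: float
    gamma: float  # NaN for RW and chance fits
    lle: float
    lle_chance: float
    fit_index: float
    n_included: int
    n_restarts: int = 0
    converged: bool = True

    @property
    def params(self) -> LearnerParams | None:
        if self.model_kind == CHANCE:
            return None
        gamma = 0.0 if np.isnan(self.gamma) else self.gamma
        return LearnerParams(self.alpha, gamma)


@dataclass
class ModelComparison:
    n: int
    mean_diff: float
    se: float
    t: float
    df: int
    p: float
    d: float  # Cohen's d_z = mean of differences / sd of differences
    effect_size_convention: str = "cohen_dz"
    degenerate: bool = False


# ---------------------------------------------------------------------------
# transform and likelihood
# ---------------------------------------------------------------------------


def transform_rts(rts) -> pd.DataFrame:
    """Standardize RTs and map to (0, 1).

    The vector passed defines the standardization scope (one participant's
    included trials of one block, in the standard pipeline).  Returns a
    frame with columns ``zrt`` and ``xrt``.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size < 2 or np.unique(rts).size < 2:
        raise ValueError("need at least 2 distinct RT values to standardize")
    if np.any(~np.isfinite(rts)) or np.any(rts <= 0):
        raise ValueError("RTs must be finite and positive")
    zrt = (rts - rts.mean()) / rts.std(ddof=1)
    xrt = 1.0 / (1.0 + np.exp(zrt))
    return pd.DataFrame({"zrt": zrt, "xrt": xrt})


def trial_fit(xrt: float, p: float) -> float:
    """Per-trial agreement Delta = 1 - |xRT - p|, in [0, 1]."""
    return 1.0 - abs(xrt - p)


def log_likelihood(trace, xrts, included_mask=None, delta_floor: float = DELTA_FLOOR) -> float:
    """Sum of log Delta over included trials.

    ``trace`` may be a ModelTrace or a bare prediction vector aligned with
    ``xrts`` trial-by-trial.
    """
    p = trace.p_first if isinstance(trace, ModelTrace) else np.asarray(trace, dtype=float)
    xrts = np.asarray(xrts, dtype=float)
    if included_mask is not None:
        mask = np.asarray(included_mask, dtype=bool)
        p = p[mask]
        xrts = xrts[mask]
    if p.size == 0:
        raise ValueError("no included trials")
    delta = 1.0 - np.abs(xrts - p)
    return float(np.sum(np.log(np.maximum(delta, delta_floor))))


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _chance_lle(xrt_included: np.ndarray, config: FitConfig) -> float:
    p = np.full(xrt_included.size, CHANCE_PREDICTION)
    return log_likelihood(p, xrt_included, delta_floor=config.delta_floor)


def fit_to_xrt(
    design: BlockDesign,
    xrt_included: np.ndarray,
    included_trial_idx: np.ndarray,
    model_kind: str,
    config: FitConfig | None = None,
) -> FitResult:
    """Maximize the block log-likelihood over the learner's free parameters.

    ``xrt_included`` holds transformed RTs for the trials whose 1-based
    indices are ``included_trial_idx``; the learner itself is always run
    over the full block.
    """
    config = config or FitConfig()
    xrt_included = np.asarray(xrt_included, dtype=float)
    idx0 = np.asarray(included_trial_idx, dtype=int) - 1
    if xrt_included.size != idx0.size:
        raise ValueError("xrt and trial-index vectors must align")
    if xrt_included.size == 0:
        raise ValueError("no included trials")
    lle_chance = _chance_lle(xrt_included, config)

    if model_kind == CHANCE:
        return FitResult(CHANCE, np.nan, np.nan, lle_chance, lle_chance,
                         0.0, xrt_included.size)

    triples, n_words = compact_design(design)

    def neg_lle(theta: np.ndarray) -> float:
        theta = np.clip(theta, 0.0, 1.0)
        alpha = theta[0]
        gamma = theta[1] if model_kind == TD else 0.0
        p = predictions(triples, n_words, model_kind, alpha, gamma)[idx0]
        delta = 1.0 - np.abs(xrt_included - p)
        return -float(np.sum(np.log(np.maximum(delta, config.delta_floor))))

    starts = TD_STARTS if model_kind == TD else RW_STARTS
    best = None
    any_converged = False
    for start in starts:
        res = optimize.minimize(
            neg_lle,
            np.asarray(start, dtype=float),
            method="Nelder-Mead",
            options={
                "xatol": config.xatol,
                "fatol": config.fatol,
                "maxiter": config.maxiter,
            },
        )
        any_converged = any_converged or bool(res.success)
        theta = np.clip(res.x, 0.0, 1.0)
        val = neg_lle(theta)
        if best is None or val < best[0] - 0.0:  # strict improvement; first wins ties
            best = (val, theta)
    lle = -best[0]
    alpha = float(best[1][0])
    gamma = float(best[1][1]) if model_kind == TD else np.nan
    fit_index = 1.0 - lle / lle_chance if lle_chance != 0.0 else np.nan
    return FitResult(
        model_kind, alpha, gamma, lle, lle_chance, fit_index,
        xrt_included.size, n_restarts=len(starts), converged=any_converged,
    )


def included_mask(records: pd.DataFrame, rt_max_ms: float = RT_MAX_MS) -> pd.Series:
    """Inclusion filter: responded, correct, and RT under the cutoff."""
    responded = records["responded"] if "responded" in records else records["rt"].notna()
    return (
        responded.astype(bool)
        & records["correct"].astype(bool)
        & (records["rt"] < rt_max_ms)
        & records["rt"].notna()
    )


def fit_model(
    design: BlockDesign,
    rt_records: pd.DataFrame,
    model_kind: str,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit one learner to one participant-block of trial-level RT records.

    ``rt_records`` needs columns trial_index (1-based, aligned with the
    design), rt (ms), correct, and optionally responded.  Only correct
    responses faster than the cutoff enter the likelihood; the same trials
    define the z-scoring scope.
    """
    config = config or FitConfig()
    records = rt_records.sort_values("trial_index")
    inc = included_mask(records, config.rt_max_ms)
    n_inc = int(inc.sum())
    if n_inc < MIN_INCLUDED_TRIALS:
        raise ValueError(f"need >= {MIN_INCLUDED_TRIALS} included trials, got {n_inc}")
    rts = records.loc[inc, "rt"].to_numpy(dtype=float)
    xrt = transform_rts(rts)["xrt"].to_numpy()
    idx = records.loc[inc, "trial_index"].to_numpy(dtype=int)
    if idx.max() > design.n_trials or idx.min() < 1:
        raise ValueError("record trial indices do not match the design")
    return fit_to_xrt(design, xrt, idx, model_kind, config)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------


def compare_models(fits_a: list[FitResult], fits_b: list[FitResult]) -> ModelComparison:
    """Paired comparison of per-participant fit indices (A minus B)."""
    if len(fits_a) != len(fits_b):
        raise ValueError("fit lists must pair the same participants")
    n = len(fits_a)
    if n < 3:
        raise ValueError("need at least 3 participants")
    diffs = np.array([a.fit_index - b.fit_index for a, b in zip(fits_a, fits_b)])
    mean = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    se = sd / np.sqrt(n)
    df = n - 1
    if sd <= 1e-12 * max(1.0, abs(mean)):  # numerically constant differences
        if abs(mean) <= 1e-12:  # identical fits: a true zero effect, not a failure
            return ModelComparison(n, 0.0, 0.0, 0.0, df, 1.0, 0.0)
        return ModelComparison(n, mean, se, np.nan, df, np.nan, np.nan, degenerate=True)
    t = mean / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return ModelComparison(n, mean, se, t, df, p, mean / sd)


def fits_to_frame(fits: dict) -> pd.DataFrame:
    """Tidy table from {(participant, block, model): FitResult}."""
    rows = []
    for (pid, block, model), f in fits.items():
        rows.append(
            {
                "participant": pid,
                "block": block,
                "model": model,
                "alpha": f.alpha,
                "gamma": f.gamma,
                "lle": f.lle,
                "lle_chance": f.lle_chance,
                "fit_index": f.fit_index,
                "n_included": f.n_included,
                "converged": f.converged,
            }
        )
    return pd.DataFrame(rows)
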