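"""Synthetic cohorts and parameter-recovery experiments.

The generator is the exact inverse of the fitting machinery's assumptions:
a TD learner with participant-specific (alpha, gamma) is run over each
block, Gaussian noise is added to its trial-wise prediction on the
transformed-RT scale, and the logistic transform is inverted back to
milliseconds:

    xRT* = clamp(p_first + N(0, pred_noise_sd), eps, 1 - eps)
    zRT  = log(1 / xRT* - 1)
    RT   = rt_mean + rt_sd * zRT

Errors and timeouts are injected missing-at-random at configured rates;
those trials are later dropped by the inclusion filter but still drive
learning (exposure, not response, updates the learner).

Default conditions mirror the behavioral study: 19 participants
counterbalanced over block order x target word x language assignment, a
72-trial structured and a 96-trial unstructured block.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import fitting, paradigm
from .models import RW, TD, LearnerParams, run_model
from .paradigm import NADS, RANDOM, BlockDesign


@dataclass(frozen=True)
class SyntheticConfig:
    n_participants: int = 19
    alpha_range: tuple[float, float] = (0.05, 0.35)
    gamma_range: tuple[float, float] = (0.5, 0.9)
    rt_mean: float = 600.0  # ms
    rt_sd: float = 100.0  # ms
    pred_noise_sd: float = 0.1  # noise on the (0,1) prediction scale
    error_rate: float = 0.05
    timeout_rate: float = 0.02
    clamp_eps: float = 0.01  # keeps inverted RTs positive (rt_mean - 4.6 rt_sd)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.rt_sd <= 0:
            raise ValueError("rt_sd must be positive")
        for name in ("pred_noise_sd", "error_rate", "timeout_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if not (0.0 < self.clamp_eps < 0.5):
            raise ValueError("clamp_eps must be in (0, 0.5)")


@dataclass
class RecoveryReport:
    per_level: pd.DataFrame  # one row per noise level
    fits: pd.DataFrame  # per participant per model per level

    def to_dict(self) -> dict:
        return {"per_level": self.per_level.to_dict(orient="records")}


def simulate_participant(
    designs: tuple[BlockDesign, BlockDesign],
    params: LearnerParams,
    cfg: SyntheticConfig,
    seed: int,
    participant: str = "p01",
) -> pd.DataFrame:
    """Trial-level RT records for one participant over both blocks."""
    rng = np.random.default_rng(seed)
    eps = cfg.clamp_eps
    frames = []
    for design in designs:
        trace = run_model(design, TD, params)
        p = trace.p_first
        xstar = np.clip(p + rng.normal(0.0, cfg.pred_noise_sd, size=p.size), eps, 1.0 - eps)
        zrt = np.log(1.0 / xstar - 1.0)
        rt = cfg.rt_mean + cfg.rt_sd * zrt
        correct = rng.random(p.size) >= cfg.error_rate
        responded = rng.random(p.size) >= cfg.timeout_rate
        rt = np.where(responded, rt, np.nan)
        correct = correct & responded
        frames.append(
            pd.DataFrame(
                {
                    "participant": participant,
                    "condition": design.block_type,
                    "trial_index": np.arange(1, design.n_trials + 1),
                    "tnt": np.where(
                        [t.target_present for t in design.trials], "Target", "NoTarget"
                    ),
                    "rt": rt,
                    "correct": correct,
                    "responded": responded,
                }
            )
        )
    records = pd.concat(frames, ignore_index=True)
    records["included"] = fitting.included_mask(records)
    return records


def _participant_designs(
    cell: dict, languages: tuple, seed: int
) -> tuple[BlockDesign, BlockDesign]:
    """(NADs design, Random design) for one counterbalancing cell."""
    lang1, lang2 = languages
    nads_lang = lang1 if cell["nads_language"] == "lang1" else lang2
    rand_lang = lang2 if cell["nads_language"] == "lang1" else lang1
    nads = paradigm.generate_nads_block(nads_lang, cell["target_role"], seed)
    rand = paradigm.generate_random_block(rand_lang, cell["target_role"], seed + 1)
    return nads, rand


def simulate_cohort(
    cfg: SyntheticConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, tuple[BlockDesign, BlockDesign]]]:
    """Counterbalanced cohort: tidy records, truth table, per-participant designs."""
    ss = np.random.SeedSequence(cfg.seed)
    lang_seed, param_seed, *pseeds = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(2 + cfg.n_participants)
    )
    languages = paradigm.generate_language_pair(lang_seed)
    cells = paradigm.counterbalance(cfg.n_participants)
    prng = np.random.default_rng(param_seed)
    records_frames = []
    truth_rows = []
    designs: dict[str, tuple[BlockDesign, BlockDesign]] = {}
    for i, (cell, pseed) in enumerate(zip(cells, pseeds)):
        pid = f"p{i + 1:02d}"
        alpha = float(prng.uniform(*cfg.alpha_range))
        gamma = float(prng.uniform(*cfg.gamma_range))
        params = LearnerParams(alpha, gamma)
        dpair = _participant_designs(cell, languages, pseed)
        designs[pid] = dpair
        rec = simulate_participant(dpair, params, cfg, pseed + 2, pid)
        rec["order"] = cell["block_order"]
        records_frames.append(rec)
        truth_rows.append(
            {
                "participant": pid,
                "alpha": alpha,
                "gamma": gamma,
                "block_order": cell["block_order"],
                "target_role": cell["target_role"],
                "nads_language": cell["nads_language"],
            }
        )
    records = pd.concat(records_frames, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return records, truth, designs


def fit_cohort(
    records: pd.DataFrame,
    designs: dict[str, tuple[BlockDesign, BlockDesign]],
    model_kinds: tuple[str, ...] = (TD, RW),
    blocks: tuple[str, ...] = (NADS,),
    config: fitting.FitConfig | None = None,
) -> dict[tuple[str, str, str], fitting.FitResult]:
    """Fit each requested learner to each participant-block."""
    fits = {}
    for pid, (nads, rand) in designs.items():
        for block, design in ((NADS, nads), (RANDOM, rand)):
            if block not in blocks:
                continue
            rec = records[(records["participant"] == pid) & (records["condition"] == block)]
            for kind in model_kinds:
                fits[(pid, block, kind)] = fitting.fit_model(design, rec, kind, config)
    return fits


def recovery_experiment(
    cfg: SyntheticConfig, noise_grid: tuple[float, ...] | None = None
) -> RecoveryReport:
    """Simulate, refit TD and RW, and summarize recovery per noise level.

    Fitting uses the structured (NADs) block, whose prediction trajectory
    identifies both alpha and gamma.
    """
    noise_grid = noise_grid if noise_grid is not None else (cfg.pred_noise_sd,)
    level_rows = []
    fit_rows = []
    for noise in noise_grid:
        level_cfg = replace(cfg, pred_noise_sd=noise)
        records, truth, designs = simulate_cohort(level_cfg)
        fits = fit_cohort(records, designs, (TD, RW), blocks=(NADS,))
        td_fits = [fits[(pid, NADS, TD)] for pid in truth["participant"]]
        rw_fits = [fits[(pid, NADS, RW)] for pid in truth["participant"]]
        comparison = fitting.compare_models(td_fits, rw_fits)
        alpha_true = truth["alpha"].to_numpy()
        gamma_true = truth["gamma"].to_numpy()
        alpha_hat = np.array([f.alpha for f in td_fits])
        gamma_hat = np.array([f.gamma for f in td_fits])
        row = {"pred_noise_sd": noise, "n_participants": cfg.n_participants}
        for name, true, hat in (
            ("alpha", alpha_true, alpha_hat),
            ("gamma", gamma_true, gamma_hat),
        ):
            err = hat - true
            row[f"{name}_bias"] = float(err.mean())
            row[f"{name}_rmse"] = float(np.sqrt((err**2).mean()))
            row[f"{name}_corr"] = (
                float(np.corrcoef(true, hat)[0, 1]) if np.std(hat) > 0 else np.nan
            )
        row["td_mean_fit_index"] = float(np.mean([f.fit_index for f in td_fits]))
        row["rw_mean_fit_index"] = float(np.mean([f.fit_index for f in rw_fits]))
        row["td_rw_mean_diff"] = comparison.mean_diff
        row["td_rw_t"] = comparison.t
        row["td_rw_p"] = comparison.p
        level_rows.append(row)
        df = fitting.fits_to_frame(fits)
        df["pred_noise_sd"] = noise
        df = df.merge(truth[["participant", "alpha", "gamma"]], on="participant",
                      suffixes=("_hat", "_true"))
        fit_rows.append(df)
    return RecoveryReport(pd.DataFrame(level_rows), pd.concat(fit_rows, ignore_index=True))
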