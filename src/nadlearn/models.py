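"""Trial-sequence learners: temporal-difference (TD), Rescorla-Wagner (RW), chance.

Each learner walks through a block's phrases and maintains a value V per
word, starting from zero at block onset.  On an AXC (or XXC) trial with
first word w1, second word w2, final word w3 and reward R = +1 if w3 is the
monitored target word, else -1:

TD (two prediction errors per trial, with temporal discounting):

    pe1 = V(w2) - V(w1)           (at the second word)
    V(w1) <- V(w1) + alpha * pe1
    pe2 = R - V(w2)               (at the final word)
    V(w2) <- V(w2) + alpha * pe2
    V(w1) <- V(w1) + alpha * pe2 * gamma

The gamma-scaled pass-back of the outcome prediction error onto the initial
word is what lets TD bridge the nonadjacent A-C relation.

RW (one compound prediction per trial, no discounting):

    pe = R - (V(w1) + V(w2))
    V(w1) <- V(w1) + alpha * pe
    V(w2) <- V(w2) + alpha * pe

Chance: a constant prediction of 0.5 on the transformed-RT scale.

The trial-wise prediction strength is p_first = |V(w1)| *before* any update
on that trial (the value carried into the phrase onset); it is the quantity
fitted to transformed RTs and exported as the parametric modulator
(P(A) in structured blocks, P(X1) in unstructured ones).  p_first is clipped
to [0, 1]: TD values are provably bounded there, while RW compound updates
can transiently overshoot at extreme learning rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .paradigm import BlockDesign, Phrase

TD = "td"
RW = "rw"
CHANCE = "chance"
MODEL_KINDS = (TD, RW, CHANCE)

CHANCE_PREDICTION = 0.5


@dataclass(frozen=True)
class LearnerParams:
    """Learning rate and temporal discounting factor, both in [0, 1]."""

    alpha: float
    gamma: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")


@dataclass(frozen=True)
class TrialTrace:
    trial_index: int
    p_first: float  # |V(w1)| at phrase onset, pre-update, clipped to [0, 1]
    pe1: float
    pe2: float
    reward: float


@dataclass
class ModelTrace:
    model_kind: str
    params: LearnerParams | None
    trials: list[TrialTrace] = field(default_factory=list)

    @property
    def p_first(self) -> np.ndarray:
        return np.array([t.p_first for t in self.trials])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "trial_index": [t.trial_index for t in self.trials],
                "p_first": [t.p_first for t in self.trials],
                "pe1": [t.pe1 for t in self.trials],
                "pe2": [t.pe2 for t in self.trials],
                "reward": [t.reward for t in self.trials],
            }
        )
        df["model_kind"] = self.model_kind
        df["alpha"] = self.params.alpha if self.params else np.nan
        df["gamma"] = self.params.gamma if self.params else np.nan
        return df


ValueState = dict  # word identifier -> V


def _reward(phrase: Phrase, target_word: str) -> float:
    return 1.0 if phrase.w3 == target_word else -1.0


def td_step(
    state: ValueState,
    phrase: Phrase,
    target_word: str,
    params: LearnerParams,
    trial_index: int = 0,
) -> tuple[ValueState, TrialTrace]:
    """One TD trial.  Returns a new state; the input state is not mutated."""
    if phrase.w1 == phrase.w2:
        raise ValueError("first and second word must differ")
    v = dict(state)
    v1 = v.get(phrase.w1, 0.0)
    v2 = v.get(phrase.w2, 0.0)
    p_first = min(abs(v1), 1.0)
    pe1 = v2 - v1
    v1 += params.alpha * pe1
    r = _reward(phrase, target_word)
    pe2 = r - v2
    v2 += params.alpha * pe2
    v1 += params.alpha * pe2 * params.gamma
    v[phrase.w1] = v1
    v[phrase.w2] = v2
    return v, TrialTrace(trial_index, p_first, pe1, pe2, r)


def rw_step(
    state: ValueState,
    phrase: Phrase,
    target_word: str,
    params: LearnerParams,
    trial_index: int = 0,
) -> tuple[ValueState, TrialTrace]:
    """One RW trial: a single compound prediction V(w1) + V(w2).

    gamma is ignored; no prediction error arises at the second word.
    """
    if phrase.w1 == phrase.w2:
        raise ValueError("first and second word must differ")
    v = dict(state)
    v1 = v.get(phrase.w1, 0.0)
    v2 = v.get(phrase.w2, 0.0)
    p_first = min(abs(v1), 1.0)
    r = _reward(phrase, target_word)
    pe = r - (v1 + v2)
    v[phrase.w1] = v1 + params.alpha * pe
    v[phrase.w2] = v2 + params.alpha * pe
    return v, TrialTrace(trial_index, p_first, 0.0, pe, r)


_STEPS = {TD: td_step, RW: rw_step}


def run_model(
    design: BlockDesign, model_kind: str, params: LearnerParams | None = None
) -> ModelTrace:
    """Run a learner over a whole block from a fresh zero-value state.

    Every trial updates the learner (exposure drives learning), including
    trials that a behavioral inclusion filter would later drop from fitting.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}")
    trace = ModelTrace(model_kind, params)
    if model_kind == CHANCE:
        for i, p in enumerate(design.trials, start=1):
            trace.trials.append(
                TrialTrace(i, CHANCE_PREDICTION, 0.0, 0.0, _reward(p, design.target_word))
            )
        return trace
    if params is None:
        raise ValueError(f"{model_kind} model requires params")
    step = _STEPS[model_kind]
    state: ValueState = {}
    for i, phrase in enumerate(design.trials, start=1):
        state, t = step(state, phrase, design.target_word, params, trial_index=i)
        trace.trials.append(t)
    return trace


# ---------------------------------------------------------------------------
# compact fast path used by the likelihood optimizer (identical arithmetic,
# no per-trial object allocation); its equivalence to run_model is asserted
# in the test suite.
# ---------------------------------------------------------------------------


def compact_design(design: BlockDesign) -> tuple[list[tuple[int, int, float]], int]:
    """Integer-coded (w1, w2, reward) triples plus vocabulary size."""
    vocab: dict[str, int] = {}
    triples = []
    for p in design.trials:
        i1 = vocab.setdefault(p.w1, len(vocab))
        i2 = vocab.setdefault(p.w2, len(vocab))
        triples.append((i1, i2, _reward(p, design.target_word)))
    return triples, len(vocab)


def predictions(
    triples: list[tuple[int, int, float]],
    n_words: int,
    model_kind: str,
    alpha: float,
    gamma: float,
) -> np.ndarray:
    """Trial-wise p_first for a compact design (zero-initialized values)."""
    if model_kind == CHANCE:
        return np.full(len(triples), CHANCE_PREDICTION)
    v = [0.0] * n_words
    out = np.empty(len(triples))
    if model_kind == TD:
        for t, (i1, i2, r) in enumerate(triples):
            v1 = v[i1]
            v2 = v[i2]
            out[t] = a1 if (a1 := abs(v1)) < 1.0 else 1.0
            v1 += alpha * (v2 - v1)
            pe2 = r - v2
            v[i2] = v2 + alpha * pe2
            v[i1] = v1 + alpha * pe2 * gamma
    elif model_kind == RW:
        for t, (i1, i2, r) in enumerate(triples):
            v1 = v[i1]
            v2 = v[i2]
            out[t] = a1 if (a1 := abs(v1)) < 1.0 else 1.0
            pe = r - (v1 + v2)
            v[i1] = v1 + alpha * pe
            v[i2] = v2 + alpha * pe
    else:
        raise ValueError(f"unknown model kind {model_kind!r}")
    return out
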