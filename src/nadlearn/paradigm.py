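"""Artificial-language word-monitoring paradigm.

Builds the two-block nonadjacent-dependency (NAD) learning task: an
artificial language of 28 bisyllabic (CVCV) pseudowords with designated
roles, a structured "NADs" block of AXC phrases in which the initial word A
fully predicts the final word C, and an unstructured "Random" block of XXC
phrases carrying no predictive relation.  Participants monitor for one of
the two C words, so each trial is a target/no-target decision.

Roles
-----
A1, A2   initial words, each deterministically paired with C1, C2
C1, C2   phrase-final words; one of them is the participant's target
X        24 intervening words; 12 shared between the two dependencies and
         6 unique to each, so P(X | A) = 1/18 within the NADs block

Block combinatorics
-------------------
NADs block: 2 dependencies x 18 X words = 36 distinct AXC phrases, each
presented twice -> 72 trials.  Random block: 48 distinct XXC phrases (every
X word twice in first and twice in second position, never twice within a
phrase; C1/C2 each ending half the phrases), each presented twice -> 96
trials.  Trial order is pseudorandom under mild interleaving constraints.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

CONSONANTS = "bcdfgjlmnprstvz"
VOWELS = "aeiou"

NADS = "NADs"
RANDOM = "Random"

#: maximum run length of the same dependency (NADs) / final word (Random)
MAX_RUN = 3

# ---------------------------------------------------------------------------
# timing defaults (ms).  The phrase lasts 1,460 ms; the inter-trial interval
# is fixed at 1,000 ms for lab testing or jittered 1,500-3,000 ms for scanner
# testing.  These are configuration values, not derived quantities.
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimingConfig:
    phrase_duration_ms: float = 1460.0
    iti_mode: str = "fixed"  # "fixed" | "jitter"
    iti_ms: float = 1000.0
    iti_jitter_ms: tuple[float, float] = (1500.0, 3000.0)

    def __post_init__(self) -> None:
        if self.iti_mode not in ("fixed", "jitter"):
            raise ValueError(f"unknown iti_mode {self.iti_mode!r}")


@dataclass(frozen=True)
class Language:
    """A 28-word artificial language with role assignments."""

    words: tuple[str, ...]
    role_map: dict[str, str]  # word -> role in {A1, A2, C1, C2, X}
    shared_x: tuple[str, ...]
    unique_x: dict[int, tuple[str, ...]]  # dependency (1|2) -> 6 X words

    def word_for_role(self, role: str) -> str:
        for w, r in self.role_map.items():
            if r == role:
                return w
        raise KeyError(role)

    @property
    def x_words(self) -> tuple[str, ...]:
        return tuple(w for w in self.words if self.role_map[w] == "X")

    def x_for_dependency(self, dep: int) -> tuple[str, ...]:
        return self.shared_x + self.unique_x[dep]

    def validate(self) -> None:
        if len(self.words) != 28 or len(set(self.words)) != 28:
            raise ValueError("language must have 28 distinct words")
        roles = [self.role_map.get(w) for w in self.words]
        for role in ("A1", "A2", "C1", "C2"):
            if roles.count(role) != 1:
                raise ValueError(f"language must have exactly one {role} word")
        if roles.count("X") != 24:
            raise ValueError("language must have 24 X-role words")
        xs = set(self.x_words)
        if len(self.shared_x) != 12 or not set(self.shared_x) <= xs:
            raise ValueError("12 shared X words required")
        for dep in (1, 2):
            if len(self.unique_x[dep]) != 6 or not set(self.unique_x[dep]) <= xs:
                raise ValueError(f"6 unique X words required for dependency {dep}")
        pool = set(self.shared_x) | set(self.unique_x[1]) | set(self.unique_x[2])
        if pool != xs:
            raise ValueError("shared/unique X subsets must partition the X words")


@dataclass(frozen=True)
class Phrase:
    """One three-word phrase (a trial's stimulus)."""

    w1: str
    w2: str
    w3: str
    condition: str  # NADS | RANDOM
    dependency: int  # 1 or 2; 0 for Random phrases
    target_present: bool


@dataclass
class BlockDesign:
    """The ordered trial list of one block."""

    block_type: str  # NADS | RANDOM
    trials: list[Phrase]
    target_word: str
    seed: int
    timing: TimingConfig = field(default_factory=TimingConfig)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def onsets_s(self) -> np.ndarray:
        """Scheduled phrase onsets in seconds (phrase duration + ITI grid)."""
        n = self.n_trials
        dur = self.timing.phrase_duration_ms / 1000.0
        if self.timing.iti_mode == "fixed":
            itis = np.full(n, self.timing.iti_ms / 1000.0)
        else:
            lo, hi = self.timing.iti_jitter_ms
            rng = np.random.default_rng(int(self.seed) + 7_654_321)
            itis = rng.uniform(lo, hi, size=n) / 1000.0
        deltas = dur + itis
        onsets = np.concatenate([[0.0], np.cumsum(deltas[:-1])])
        return onsets

    def to_frame(self) -> pd.DataFrame:
        onsets = self.onsets_s()
        dur = self.timing.phrase_duration_ms / 1000.0
        return pd.DataFrame(
            {
                "trial_index": np.arange(1, self.n_trials + 1),
                "w1": [p.w1 for p in self.trials],
                "w2": [p.w2 for p in self.trials],
                "w3": [p.w3 for p in self.trials],
                "condition": [p.condition for p in self.trials],
                "dependency": [p.dependency for p in self.trials],
                "target_present": [p.target_present for p in self.trials],
                "onset_s": onsets,
                "duration_s": np.full(self.n_trials, dur),
            }
        )


def design_from_frame(df: pd.DataFrame, seed: int = -1) -> BlockDesign:
    """Rebuild a BlockDesign from its tidy-table form.

    The target word is inferred as the unique w3 of target-present trials.
    Timing is taken as the default configuration (the table's onsets are not
    re-used for scheduling).
    """
    df = df.sort_values("trial_index")
    trials = [
        Phrase(r.w1, r.w2, r.w3, r.condition, int(r.dependency), bool(r.target_present))
        for r in df.itertuples()
    ]
    targets = {p.w3 for p in trials if p.target_present}
    if len(targets) != 1:
        raise ValueError("cannot infer a unique target word from the design table")
    block_type = trials[0].condition
    return BlockDesign(block_type, trials, targets.pop(), seed)


# ---------------------------------------------------------------------------
# language generation
# ---------------------------------------------------------------------------


def generate_language(seed: int) -> Language:
    """Sample a 28-word CVCV language and assign roles, deterministically.

    Word forms are drawn from simple Spanish-legal consonant/vowel
    inventories; identity of the letter strings plays no role in any
    downstream computation.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    rng = np.random.default_rng(seed)
    forms = [
        c1 + v1 + c2 + v2
        for c1, v1, c2, v2 in itertools.product(CONSONANTS, VOWELS, CONSONANTS, VOWELS)
    ]
    idx = rng.choice(len(forms), size=28, replace=False)
    words = tuple(forms[i] for i in idx)
    role_map = {words[0]: "A1", words[1]: "A2", words[2]: "C1", words[3]: "C2"}
    xs = words[4:]
    role_map.update({w: "X" for w in xs})
    lang = Language(
        words=words,
        role_map=role_map,
        shared_x=tuple(xs[:12]),
        unique_x={1: tuple(xs[12:18]), 2: tuple(xs[18:24])},
    )
    lang.validate()
    return lang


def generate_language_pair(seed: int) -> tuple[Language, Language]:
    """Two word-disjoint languages (one per block)."""
    ss = np.random.SeedSequence(seed)
    s1, s2 = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(2))
    lang1 = generate_language(s1)
    for bump in range(100):
        lang2 = generate_language((s2 + bump) % (2**31))
        if not set(lang1.words) & set(lang2.words):
            return lang1, lang2
    raise RuntimeError("could not draw disjoint languages")


# ---------------------------------------------------------------------------
# pseudorandom ordering under interleaving constraints
# ---------------------------------------------------------------------------


def _violates(seq: list[Phrase], cand: Phrase, run_key, max_run: int) -> bool:
    if seq and (seq[-1].w1, seq[-1].w2, seq[-1].w3) == (cand.w1, cand.w2, cand.w3):
        return True  # identical phrase on consecutive trials
    if len(seq) >= max_run:
        k = run_key(cand)
        if all(run_key(p) == k for p in seq[-max_run:]):
            return True  # would extend a same-key run beyond max_run
    return False


def _pseudorandom_order(
    items: list[Phrase],
    rng: np.random.Generator,
    run_key,
    max_run: int = MAX_RUN,
    max_restarts: int = 500,
) -> list[Phrase]:
    """Greedy constrained shuffle with restart on dead ends."""
    for _ in range(max_restarts):
        order = rng.permutation(len(items))
        pool = [items[i] for i in order]
        seq: list[Phrase] = []
        while pool:
            for i, cand in enumerate(pool):
                if not _violates(seq, cand, run_key, max_run):
                    seq.append(pool.pop(i))
                    break
            else:
                break  # dead end -> restart
        if not pool:
            return seq
    raise RuntimeError("could not satisfy pseudorandomization constraints")


# ---------------------------------------------------------------------------
# block generation
# ---------------------------------------------------------------------------


def generate_nads_block(language: Language, target: str, seed: int) -> BlockDesign:
    """72-trial structured block: 36 distinct AXC phrases presented twice.

    Each dependency contributes 18 phrases (12 shared + 6 unique X), so the
    empirical transition probability from an A word to any particular X is
    1/18.  ``target`` selects which C role ("C1" or "C2") the participant
    monitors.
    """
    language.validate()
    if target not in ("C1", "C2"):
        raise ValueError("target must be 'C1' or 'C2'")
    target_word = language.word_for_role(target)
    distinct: list[Phrase] = []
    for dep in (1, 2):
        a = language.word_for_role(f"A{dep}")
        c = language.word_for_role(f"C{dep}")
        for x in language.x_for_dependency(dep):
            distinct.append(Phrase(a, x, c, NADS, dep, c == target_word))
    items = distinct * 2
    rng = np.random.default_rng(seed)
    trials = _pseudorandom_order(items, rng, run_key=lambda p: p.dependency)
    return BlockDesign(NADS, trials, target_word, seed)


def _pair_x_words(
    xs: tuple[str, ...], rng: np.random.Generator, max_restarts: int = 200
) -> list[tuple[str, str]]:
    """48 distinct (X, X) pairs; every X twice in each position, w1 != w2."""
    pos1 = [x for x in xs for _ in range(2)]
    pos2 = list(pos1)
    for _ in range(max_restarts):
        rng.shuffle(pos1)
        rng.shuffle(pos2)
        for _ in range(2000):  # local repair sweeps
            pairs = list(zip(pos1, pos2))
            seen: dict[tuple[str, str], int] = {}
            bad = []
            for i, pr in enumerate(pairs):
                if pr[0] == pr[1] or pr in seen:
                    bad.append(i)
                seen[pr] = i
            if not bad:
                return pairs
            i = bad[int(rng.integers(len(bad)))]
            j = int(rng.integers(len(pairs)))
            pos2[i], pos2[j] = pos2[j], pos2[i]
    raise RuntimeError("could not balance X positions in the Random block")


def generate_random_block(language: Language, target: str, seed: int) -> BlockDesign:
    """96-trial unstructured block: 48 distinct XXC phrases presented twice.

    C1 and C2 each terminate half the trials; each X word appears equally
    often in first and second position and never twice within a phrase, so
    the final word cannot be predicted from the preceding ones.
    """
    language.validate()
    if target not in ("C1", "C2"):
        raise ValueError("target must be 'C1' or 'C2'")
    target_word = language.word_for_role(target)
    rng = np.random.default_rng(seed)
    pairs = _pair_x_words(language.x_words, rng)
    c1 = language.word_for_role("C1")
    c2 = language.word_for_role("C2")
    cs = [c1] * 24 + [c2] * 24
    rng.shuffle(cs)
    distinct = [
        Phrase(w1, w2, c, RANDOM, 0, c == target_word)
        for (w1, w2), c in zip(pairs, cs)
    ]
    items = distinct * 2
    trials = _pseudorandom_order(items, rng, run_key=lambda p: p.w3)
    return BlockDesign(RANDOM, trials, target_word, seed)


# ---------------------------------------------------------------------------
# counterbalancing
# ---------------------------------------------------------------------------

_CELLS = tuple(
    {"block_order": bo, "target_role": tr, "nads_language": nl}
    for bo, tr, nl in itertools.product(
        ("nads_first", "random_first"), ("C1", "C2"), ("lang1", "lang2")
    )
)


def counterbalance(n_participants: int) -> list[dict]:
    """Assign participants round-robin to the 2x2x2 counterbalancing cells.

    Cells cross block order, monitored target word, and which of the two
    languages is heard in the NADs block.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    return [dict(_CELLS[i % len(_CELLS)]) for i in range(n_participants)]


def transition_probabilities(design: BlockDesign) -> pd.DataFrame:
    """Empirical P(w2 = x | w1 = a) over a block, as a tidy table."""
    df = design.to_frame()
    counts = df.groupby(["w1", "w2"]).size().rename("n").reset_index()
    totals = counts.groupby("w1")["n"].transform("sum")
    counts["p"] = counts["n"] / totals
    return counts


def with_timing(design: BlockDesign, timing: TimingConfig) -> BlockDesign:
    return replace(design, timing=timing)
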