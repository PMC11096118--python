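"""Triangle-test trial schedules, a Thurstonian observer, and test power.

The discrimination task is a triangle test: each trial presents three
textures, two rendered at the standard spatial frequency ``f_St`` and one at
a comparison frequency ``f_Co`` (or the St/Co roles swapped), and the
respondent must pick the odd one; chance performance is 1/3.

The schedule follows the method of constant stimuli: within every 20-trial
block each of the four comparison frequencies appears exactly five times in
randomized order, with the triplet arrangement drawn uniformly from the six
patterns St/Co/Co, Co/St/Co, Co/Co/St, St/St/Co, St/Co/St, Co/St/St.

The simulated participant is an equal-variance Gaussian (Thurstonian)
observer: each texture evokes a perceived magnitude x_i ~ N(f_i, sigma^2)
and the observer picks the sample farthest from the midpoint of the other
two — the classical triangle-test decision rule whose chance level and
power analysis the study design invokes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import stream
from .errors import ConfigurationError

#: The six admissible triplet patterns. "St" marks the standard stimulus.
ARRANGEMENTS = (
    ("St", "Co", "Co"),
    ("Co", "St", "Co"),
    ("Co", "Co", "St"),
    ("St", "St", "Co"),
    ("St", "Co", "St"),
    ("Co", "St", "St"),
)

PHASES = ("pre", "intervention", "post")
GROUPS = ("Sham", "WH-Stim")


def _odd_position(arrangement: tuple[str, str, str]) -> int:
    """1-based position of the odd texture (minority label) in a triplet."""
    n_st = arrangement.count("St")
    odd_label = "St" if n_st == 1 else "Co"
    return arrangement.index(odd_label) + 1


@dataclass(frozen=True)
class StimulusSet:
    """Standard and comparison spatial frequencies (1/m) of the gratings."""

    f_standard: float = 164.0
    f_comparisons: tuple[float, ...] = (120.0, 142.0, 186.0, 208.0)

    def __post_init__(self) -> None:
        if self.f_standard <= 0 or any(f <= 0 for f in self.f_comparisons):
            raise ConfigurationError("spatial frequencies must be positive")
        if self.f_standard in self.f_comparisons:
            raise ConfigurationError("standard frequency must not be a comparison")


@dataclass(frozen=True)
class TrialSpec:
    """One triangle-test trial."""

    trial_index: int
    phase: str  # pre | intervention | post | familiarization
    block_index: int
    arrangement: tuple[str, str, str]
    odd_position: int  # 1..3, the position whose texture differs
    f_comparison: float
    f_standard: float = 164.0

    def frequencies(self) -> tuple[float, float, float]:
        """Spatial frequency rendered at each of the three positions."""
        return tuple(
            self.f_standard if lab == "St" else self.f_comparison
            for lab in self.arrangement
        )


@dataclass(frozen=True)
class ObserverParams:
    """Equal-variance Gaussian observer; ``sigma`` in 1/m, on the physical scale.

    The perceived-magnitude mean equals the spatial frequency (identity
    perceptual scale): only differences matter under the equal-variance model.
    """

    sigma: float = 18.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ConfigurationError("sigma must be non-negative")


@dataclass
class SessionSchedule:
    """Full session: 8 familiarization + 20 pre + 60 intervention + 20 post.

    The randomized 20-trial order drawn at pre-intervention is repeated
    verbatim in each of the three intervention blocks and at post.
    """

    trials: list[TrialSpec] = field(default_factory=list)

    def phase_trials(self, phase: str) -> list[TrialSpec]:
        return [t for t in self.trials if t.phase == phase]


def generate_block(
    stimulus_set: StimulusSet, phase: str, seed: int | np.random.Generator
) -> list[TrialSpec]:
    """Generate one randomized 20-trial constant-stimuli block.

    Each comparison frequency appears exactly five times; arrangements are
    drawn uniformly from the six triplet patterns.
    """
    if len(stimulus_set.f_comparisons) != 4:
        raise ConfigurationError(
            f"expected 4 comparison frequencies, got {len(stimulus_set.f_comparisons)}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else stream(seed, "block", phase)
    f_co = np.repeat(stimulus_set.f_comparisons, 5)
    rng.shuffle(f_co)
    arr_idx = rng.integers(0, len(ARRANGEMENTS), size=20)
    trials = []
    for i in range(20):
        arrangement = ARRANGEMENTS[arr_idx[i]]
        trials.append(
            TrialSpec(
                trial_index=i,
                phase=phase,
                block_index=0,
                arrangement=arrangement,
                odd_position=_odd_position(arrangement),
                f_comparison=float(f_co[i]),
                f_standard=stimulus_set.f_standard,
            )
        )
    return trials


def generate_session(
    stimulus_set: StimulusSet = StimulusSet(),
    seed: int = 0,
    *,
    f_familiar: float = 100.0,
    familiar_odd_position: int = 1,
) -> SessionSchedule:
    """Generate a complete session schedule.

    Familiarization presents eight A/B/B triplets (f_A = 100, f_B = 164 per
    default) with a fixed odd position; the 20-trial order randomized at
    pre-intervention is reused in all three intervention blocks and at post.
    """
    rng = stream(seed, "schedule")
    trials: list[TrialSpec] = []
    # Familiarization: odd texture (A) at a fixed position, not randomized.
    fam_arr = ["Co", "Co", "Co"]
    fam_arr[familiar_odd_position - 1] = "St"
    fam_arrangement = tuple(fam_arr)
    for i in range(8):
        trials.append(
            TrialSpec(
                trial_index=i,
                phase="familiarization",
                block_index=0,
                arrangement=fam_arrangement,
                odd_position=familiar_odd_position,
                f_comparison=stimulus_set.f_standard,  # B textures: the standard
                f_standard=f_familiar,  # the odd A texture
            )
        )
    base = generate_block(stimulus_set, "pre", rng)
    trials.extend(base)
    for block in range(3):
        for t in base:
            trials.append(
                TrialSpec(
                    trial_index=t.trial_index,
                    phase="intervention",
                    block_index=block,
                    arrangement=t.arrangement,
                    odd_position=t.odd_position,
                    f_comparison=t.f_comparison,
                    f_standard=t.f_standard,
                )
            )
    for t in base:
        trials.append(
            TrialSpec(
                trial_index=t.trial_index,
                phase="post",
                block_index=0,
                arrangement=t.arrangement,
                odd_position=t.odd_position,
                f_comparison=t.f_comparison,
                f_standard=t.f_standard,
            )
        )
    return SessionSchedule(trials=trials)


def _triangle_pick(x: np.ndarray) -> np.ndarray:
    """Vectorized triangle rule: index of the sample farthest from the
    midpoint of the other two, for an (n, 3) array of perceived magnitudes."""
    x = np.atleast_2d(x)
    d = np.empty_like(x)
    for i in range(3):
        j, k = [m for m in range(3) if m != i]
        d[:, i] = np.abs(x[:, i] - 0.5 * (x[:, j] + x[:, k]))
    return np.argmax(d, axis=1)


def simulate_response(
    trial: TrialSpec,
    observer: ObserverParams,
    rng: np.random.Generator | None = None,
) -> int:
    """Simulate one trial; returns 1 if the odd texture was selected."""
    return int(simulate_responses([trial], observer, rng)[0])


def simulate_responses(
    trials: list[TrialSpec],
    observer: ObserverParams,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Vectorized observer simulation over a list of trials."""
    if rng is None:
        rng = stream(observer.seed, "observer")
    means = np.array([t.frequencies() for t in trials], dtype=float)
    x = means + observer.sigma * rng.standard_normal(means.shape)
    picked = _triangle_pick(x) + 1
    odd = np.array([t.odd_position for t in trials])
    return (picked == odd).astype(int)


def probability_correct(responses) -> float:
    """Proportion of correct responses (mean of 0/1 indicators)."""
    responses = np.asarray(responses)
    if responses.size == 0:
        raise ValueError("empty response list")
    return float(np.mean(responses))


def triangle_power(p_alt: float, n: int, alpha: float = 0.05) -> float:
    """Exact power of the one-sided binomial triangle test of H0: p = 1/3.

    The critical count k is the smallest count with
    P(X >= k | n, 1/3) <= alpha; the returned power is
    P(X >= k | n, p_alt).
    """
    if not (1 / 3 <= p_alt <= 1):
        raise ValueError("p_alt must lie in [1/3, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    k_grid = np.arange(0, n + 2)
    tail = stats.binom.sf(k_grid - 1, n, 1 / 3)  # P(X >= k)
    admissible = np.nonzero(tail <= alpha)[0]
    if admissible.size == 0 or k_grid[admissible[0]] > n:
        return 0.0
    k = k_grid[admissible[0]]
    return float(stats.binom.sf(k - 1, n, p_alt))


def schedule_to_frame(
    schedule: SessionSchedule,
    responses: np.ndarray | None = None,
    *,
    participant_id: str = "P00",
    group: str = "Sham",
) -> pd.DataFrame:
    """Tidy table of a schedule (optionally with scored responses)."""
    rows = []
    for i, t in enumerate(schedule.trials):
        rows.append(
            {
                "participant_id": participant_id,
                "group": group,
                "phase": t.phase,
                "block": t.block_index,
                "trial": t.trial_index,
                "arrangement": "/".join(t.arrangement),
                "odd_position": t.odd_position,
                "f_comparison": t.f_comparison,
                "correct": int(responses[i]) if responses is not None else pd.NA,
            }
        )
    return pd.DataFrame(rows)
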