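"""Formal model of the two-door probabilistic reward task ("Lucky Door").

The task presents two doors on every trial. One door delivers rare gains
(RareG: large gains with probability 0.3, small losses otherwise); the other
delivers rare losses (RareL: small gains with probability 0.7, large losses
otherwise). In the *experimental* block the payoff magnitudes make the RareG
door the higher expected-value option; in the *baseline* block both doors have
zero expected value, isolating any bias toward the frequent-gain door.

Expected values are reported over a 10-trial horizon by default so that the
conventional labels for the standard payoff sets come out as +40 / -40 / 0
coins rather than the per-trial +4 / -4 / 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np
import pandas as pd

DeckLabel = Literal["RareG", "RareL"]
BlockKind = Literal["experimental", "baseline"]

#: Horizon (in trials) over which expected values are reported by default.
DEFAULT_EV_HORIZON = 10

#: Trials per block.
DEFAULT_N_TRIALS = 40


@dataclass(frozen=True)
class DeckSpec:
    """One door's payoff process: gain with probability ``p_gain``, else loss.

    Parameters
    ----------
    label
        ``"RareG"`` (rare-gain door) or ``"RareL"`` (rare-loss door).
    p_gain
        Probability of a gain on any trial, in [0, 1]. The loss probability
        is the complement and is not stored.
    gain
        Coins won on a gain trial; must be positive.
    loss
        Coins lost on a loss trial; must be negative.
    """

    label: DeckLabel
    p_gain: float
    gain: int
    loss: int

    def __post_init__(self) -> None:
        if self.label not in ("RareG", "RareL"):
            raise ValueError(f"unknown deck label {self.label!r}")
        if not 0.0 <= self.p_gain <= 1.0:
            raise ValueError(f"p_gain must be in [0, 1], got {self.p_gain}")
        if not self.gain > 0:
            raise ValueError(f"gain must be > 0, got {self.gain}")
        if not self.loss < 0:
            raise ValueError(f"loss must be < 0, got {self.loss}")

    @property
    def p_loss(self) -> float:
        return 1.0 - self.p_gain


@dataclass(frozen=True)
class BlockSpec:
    """A block of the task: one RareG deck, one RareL deck, a trial count."""

    block_kind: BlockKind
    rare_gain: DeckSpec
    rare_loss: DeckSpec
    n_trials: int = DEFAULT_N_TRIALS

    def __post_init__(self) -> None:
        if self.block_kind not in ("experimental", "baseline"):
            raise ValueError(f"unknown block kind {self.block_kind!r}")
        if self.rare_gain.label != "RareG" or self.rare_loss.label != "RareL":
            raise ValueError("block needs exactly one RareG and one RareL deck")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")

    def deck(self, label: DeckLabel) -> DeckSpec:
        if label == "RareG":
            return self.rare_gain
        if label == "RareL":
            return self.rare_loss
        raise ValueError(f"unknown deck label {label!r}")


@dataclass(frozen=True)
class TrialRecord:
    """Outcome of one played trial."""

    trial_index: int  # 1-based
    choice: DeckLabel
    outcome: int  # signed coins
    cumulative: int  # running total including this trial

    @property
    def is_win(self) -> bool:
        return self.outcome > 0


def deck_ev(deck: DeckSpec, horizon: int = DEFAULT_EV_HORIZON) -> float:
    """Expected cumulative coins from playing ``deck`` for ``horizon`` trials.

    ``horizon * (p_gain * gain + (1 - p_gain) * loss)``. The default 10-trial
    horizon reproduces the conventional EV labels for the standard payoff
    sets (+40 for RareG, -40 for RareL in the experimental block; 0 in the
    baseline block).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    # factored form p*(gain-loss)+loss avoids the rounding of 1-p, so the
    # standard integer payoff sets give exact integer EVs
    return horizon * (deck.p_gain * (deck.gain - deck.loss) + deck.loss)


def make_block(block_kind: BlockKind, n_trials: int = DEFAULT_N_TRIALS) -> BlockSpec:
    """Standard block definitions.

    experimental: RareG gains +60 with p=0.3 / loses -20 (EV +40 over 10
    trials); RareL gains +20 with p=0.7 / loses -60 (EV -40).
    baseline: RareG +70/-30, RareL +30/-70 -- both EV 0 at every horizon.
    """
    if block_kind == "experimental":
        rare_gain = DeckSpec("RareG", p_gain=0.3, gain=60, loss=-20)
        rare_loss = DeckSpec("RareL", p_gain=0.7, gain=20, loss=-60)
    elif block_kind == "baseline":
        rare_gain = DeckSpec("RareG", p_gain=0.3, gain=70, loss=-30)
        rare_loss = DeckSpec("RareL", p_gain=0.7, gain=30, loss=-70)
    else:
        raise ValueError(f"unknown block kind {block_kind!r}")
    return BlockSpec(block_kind, rare_gain, rare_loss, n_trials=n_trials)


def sample_outcome(deck: DeckSpec, rng: np.random.Generator) -> int:
    """Draw one i.i.d. Bernoulli payoff from ``deck``."""
    return deck.gain if rng.random() < deck.p_gain else deck.loss


def fixed_ratio_outcomes(
    deck: DeckSpec, n_trials: int, rng: np.random.Generator
) -> np.ndarray:
    """Pre-generated payoff schedule with the gain count fixed at
    ``round(p_gain * n_trials)`` and the order permuted.

    Alternative to per-trial i.i.d. sampling for sensitivity checks; the
    realized gain frequency is exact rather than binomial.
    """
    n_gain = int(round(deck.p_gain * n_trials))
    outcomes = np.array([deck.gain] * n_gain + [deck.loss] * (n_trials - n_gain))
    return rng.permutation(outcomes)


def play_block(
    block: BlockSpec,
    choices: Iterable[DeckLabel],
    rng: np.random.Generator,
    schedule: Literal["iid", "fixed_ratio"] = "iid",
) -> list[TrialRecord]:
    """Realize outcomes for a pre-decided choice sequence.

    With the default ``"iid"`` schedule each trial's payoff is an independent
    Bernoulli draw from the chosen deck. With ``"fixed_ratio"`` each deck's
    payoff sequence is pre-generated (exact gain counts, permuted order) and
    consumed in choice order.
    """
    choices = list(choices)
    if len(choices) != block.n_trials:
        raise ValueError(
            f"expected {block.n_trials} choices, got {len(choices)}"
        )
    pregen: dict[DeckLabel, list[int]] = {}
    if schedule == "fixed_ratio":
        for label in ("RareG", "RareL"):
            pregen[label] = list(fixed_ratio_outcomes(block.deck(label), block.n_trials, rng))
    elif schedule != "iid":
        raise ValueError(f"unknown schedule {schedule!r}")

    records: list[TrialRecord] = []
    cumulative = 0
    for t, choice in enumerate(choices, start=1):
        deck = block.deck(choice)
        if schedule == "iid":
            outcome = sample_outcome(deck, rng)
        else:
            outcome = int(pregen[choice].pop(0))
        cumulative += outcome
        records.append(TrialRecord(t, choice, outcome, cumulative))
    return records


def trials_to_frame(
    records: Iterable[TrialRecord], subject_id: str, block: BlockKind
) -> pd.DataFrame:
    """Serialize trial records to the tidy per-trial schema
    (subject_id, block, trial, choice, outcome, cumulative)."""
    rows = [
        {
            "subject_id": subject_id,
            "block": block,
            "trial": r.trial_index,
            "choice": r.choice,
            "outcome": r.outcome,
            "cumulative": r.cumulative,
        }
        for r in records
    ]
    return pd.DataFrame(rows)
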