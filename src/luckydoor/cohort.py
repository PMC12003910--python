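"""Synthetic cohort generation: covariates, behavioral agents, trial tables.

The generator emulates a three-group wildfire-exposure study cohort
(directly exposed / indirectly exposed / non-exposed, default sizes
27/21/27): demographics and self-reported mental-health scores with
configurable group shifts (elevated anxiety, depression and recent-trauma
rates in the exposed groups), and task behavior produced by parameterized
agents whose Win-Stay tendency is under experimental control, so that the
downstream behavioral and neural analyses can be exercised against known
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .task_model import (
    BlockSpec,
    DeckLabel,
    TrialRecord,
    make_block,
    sample_outcome,
    trials_to_frame,
)

GROUPS = ("directly_exposed", "indirectly_exposed", "non_exposed")

ETHNICITY_LEVELS = ("caucasian", "black", "asian", "multiple", "other")

#: Instrument ranges for the self-report scores.
SCORE_RANGES = {"ses": (0, 9), "gad7": (0, 21), "phq9": (0, 27)}


@dataclass(frozen=True)
class CovariateEffectConfig:
    """Group-wise covariate distributions.

    Means/SDs per group, in the order (directly_exposed, indirectly_exposed,
    non_exposed). Defaults qualitatively follow the study cohort: matched age
    and gender across groups, lower affluence and markedly higher anxiety
    (GAD7), depression (PHQ9) and recent-trauma rates in the exposed groups.
    Magnitudes are configuration, not claims about the real sample.
    """

    age_mean: tuple[float, float, float] = (24.4, 25.7, 23.9)
    age_sd: tuple[float, float, float] = (5.9, 7.0, 5.9)
    male_rate: tuple[float, float, float] = (0.148, 0.19, 0.148)
    ses_mean: tuple[float, float, float] = (4.0, 4.0, 4.9)
    ses_sd: tuple[float, float, float] = (1.7, 1.7, 2.0)
    gad7_mean: tuple[float, float, float] = (10.1, 9.7, 3.2)
    gad7_sd: tuple[float, float, float] = (6.6, 5.2, 2.1)
    phq9_mean: tuple[float, float, float] = (8.9, 11.8, 2.6)
    phq9_sd: tuple[float, float, float] = (6.5, 6.1, 2.1)
    recent_trauma_rate: tuple[float, float, float] = (0.667, 0.143, 0.0)
    #: Per-group ethnicity probabilities over ETHNICITY_LEVELS.
    ethnicity_probs: tuple[tuple[float, ...], ...] = (
        (0.78, 0.04, 0.0, 0.14, 0.04),
        (0.57, 0.0, 0.10, 0.24, 0.09),
        (0.30, 0.0, 0.40, 0.22, 0.08),
    )

    def __post_init__(self) -> None:
        for name in ("age_sd", "ses_sd", "gad7_sd", "phq9_sd"):
            if any(s < 0 for s in getattr(self, name)):
                raise ValueError(f"{name} must be non-negative")
        for name in ("male_rate", "recent_trauma_rate"):
            if any(not 0 <= r <= 1 for r in getattr(self, name)):
                raise ValueError(f"{name} must be in [0, 1]")
        for probs in self.ethnicity_probs:
            if len(probs) != len(ETHNICITY_LEVELS) or abs(sum(probs) - 1) > 1e-9:
                raise ValueError("ethnicity_probs rows must sum to 1")

    @classmethod
    def null(cls) -> "CovariateEffectConfig":
        """No group differences: every covariate pooled across groups."""

        def pool(vals: tuple[float, float, float]) -> tuple[float, float, float]:
            m = float(np.mean(vals))
            return (m, m, m)

        probs = tuple(
            tuple(float(np.mean([row[i] for row in cls.ethnicity_probs]))
                  for i in range(len(ETHNICITY_LEVELS)))
            for _ in range(3)
        )
        base = cls()
        return replace(
            base,
            age_mean=pool(base.age_mean),
            age_sd=pool(base.age_sd),
            male_rate=pool(base.male_rate),
            ses_mean=pool(base.ses_mean),
            ses_sd=pool(base.ses_sd),
            gad7_mean=pool(base.gad7_mean),
            gad7_sd=pool(base.gad7_sd),
            phq9_mean=pool(base.phq9_mean),
            phq9_sd=pool(base.phq9_sd),
            recent_trauma_rate=pool(base.recent_trauma_rate),
            ethnicity_probs=probs,
        )


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, n: int
) -> np.ndarray:
    """Sample N(mean, sd) clipped to [lo, hi]; degenerate sd gives constants."""
    x = rng.normal(mean, sd, size=n) if sd > 0 else np.full(n, float(mean))
    return np.clip(x, lo, hi)


def generate_covariates(
    group_sizes: Sequence[int] = (27, 21, 27),
    effect_config: CovariateEffectConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Generate a per-subject covariate table.

    Returns one row per subject with columns subject_id, group, age, gender,
    ethnicity, ses, gad7, phq9, recent_trauma. Scores are truncated to their
    instrument ranges (SES 0-9, GAD7 0-21, PHQ9 0-27).
    """
    if len(group_sizes) != 3 or any(n < 1 for n in group_sizes):
        raise ValueError("need three group sizes, each >= 1")
    cfg = effect_config or CovariateEffectConfig()
    rng = np.random.default_rng(rng)

    frames = []
    sid = 0
    for gi, (group, n) in enumerate(zip(GROUPS, group_sizes)):
        age = np.round(
            _truncated_normal(rng, cfg.age_mean[gi], cfg.age_sd[gi], 18, 60, n)
        ).astype(int)
        gender = np.where(rng.random(n) < cfg.male_rate[gi], "male", "female")
        ethnicity = rng.choice(ETHNICITY_LEVELS, size=n, p=cfg.ethnicity_probs[gi])
        ses = np.round(
            _truncated_normal(rng, cfg.ses_mean[gi], cfg.ses_sd[gi], *SCORE_RANGES["ses"], n)
        ).astype(int)
        gad7 = np.round(
            _truncated_normal(rng, cfg.gad7_mean[gi], cfg.gad7_sd[gi], *SCORE_RANGES["gad7"], n)
        ).astype(int)
        phq9 = np.round(
            _truncated_normal(rng, cfg.phq9_mean[gi], cfg.phq9_sd[gi], *SCORE_RANGES["phq9"], n)
        ).astype(int)
        trauma = rng.random(n) < cfg.recent_trauma_rate[gi]
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": [f"S{sid + i:03d}" for i in range(n)],
                    "group": group,
                    "age": age,
                    "gender": gender,
                    "ethnicity": ethnicity,
                    "ses": ses,
                    "gad7": gad7,
                    "phq9": phq9,
                    "recent_trauma": trauma,
                }
            )
        )
        sid += n
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class AgentParams:
    """Parameters of a generative choice agent.

    ``wsls`` agents implement a stochastic Win-Stay/Lose-Shift policy: after a
    win on the rare-gain door they stay with probability ``p_stay_win_rareG``;
    after a win on the rare-loss door they stay with probability
    ``p_stay_win_rareL``; after any loss they shift with probability
    ``p_shift_loss``. ``delta_rule`` agents learn deck values with a delta
    rule V <- V + lr * (r - V) (losses scaled by ``loss_aversion_weight``) and
    choose by softmax with ``inverse_temperature``.
    """

    agent_kind: Literal["wsls", "delta_rule"] = "wsls"
    p_stay_win_rareG: float = 0.65
    p_stay_win_rareL: float = 0.5
    p_shift_loss: float = 0.5
    learning_rate: float = 0.3
    inverse_temperature: float = 5.0
    loss_aversion_weight: float = 1.0

    def __post_init__(self) -> None:
        for name in ("p_stay_win_rareG", "p_stay_win_rareL", "p_shift_loss", "learning_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.inverse_temperature < 0 or self.loss_aversion_weight < 0:
            raise ValueError("inverse_temperature and loss_aversion_weight must be >= 0")


def _other(label: DeckLabel) -> DeckLabel:
    return "RareL" if label == "RareG" else "RareG"


def simulate_agent(
    block: BlockSpec, params: AgentParams, rng: np.random.Generator | int | None = None
) -> list[TrialRecord]:
    """Play one block with the given agent; first-trial choice is uniform."""
    rng = np.random.default_rng(rng)
    records: list[TrialRecord] = []
    cumulative = 0
    values = {"RareG": 0.0, "RareL": 0.0}

    choice: DeckLabel = "RareG" if rng.random() < 0.5 else "RareL"
    for t in range(1, block.n_trials + 1):
        if t > 1:
            prev = records[-1]
            if params.agent_kind == "wsls":
                if prev.is_win:
                    p_stay = (
                        params.p_stay_win_rareG
                        if prev.choice == "RareG"
                        else params.p_stay_win_rareL
                    )
                    choice = prev.choice if rng.random() < p_stay else _other(prev.choice)
                else:
                    choice = _other(prev.choice) if rng.random() < params.p_shift_loss else prev.choice
            elif params.agent_kind == "delta_rule":
                dv = params.inverse_temperature * (values["RareG"] - values["RareL"])
                p_rareg = 1.0 / (1.0 + np.exp(-dv))
                choice = "RareG" if rng.random() < p_rareg else "RareL"
            else:
                raise ValueError(f"unknown agent kind {params.agent_kind!r}")
        outcome = sample_outcome(block.deck(choice), rng)
        cumulative += outcome
        records.append(TrialRecord(t, choice, outcome, cumulative))
        if params.agent_kind == "delta_rule":
            r = float(outcome)
            if r < 0:
                r *= params.loss_aversion_weight
            # scale rewards to keep softmax arguments moderate
            r /= 60.0
            values[choice] += params.learning_rate * (r - values[choice])
    return records


@dataclass(frozen=True)
class BehaviorEffectConfig:
    """Group-wise Win-Stay tendency injected into the experimental block.

    ``p_stay_mean`` maps group name to the mean of the between-subject
    distribution of ``p_stay_win_rareG`` in the experimental block. In the
    baseline block every group uses ``baseline_p_stay`` (no group effect, the
    null the baseline-block control analysis expects). Default: a 0.2 deficit
    in the directly exposed group, between-subject SD 0.1.
    """

    p_stay_mean: Mapping[str, float] = field(
        default_factory=lambda: {
            "directly_exposed": 0.45,
            "indirectly_exposed": 0.65,
            "non_exposed": 0.65,
        }
    )
    p_stay_sd: float = 0.1
    baseline_p_stay: float = 0.65

    def __post_init__(self) -> None:
        if self.p_stay_sd < 0:
            raise ValueError("p_stay_sd must be >= 0")
        for g, m in self.p_stay_mean.items():
            if not 0 <= m <= 1:
                raise ValueError(f"p_stay_mean[{g!r}] must be in [0, 1]")

    @classmethod
    def null(cls, p_stay: float = 0.65, sd: float = 0.1) -> "BehaviorEffectConfig":
        return cls(p_stay_mean={g: p_stay for g in GROUPS}, p_stay_sd=sd)


def generate_cohort_behavior(
    covariates: pd.DataFrame,
    behavior_effect: BehaviorEffectConfig | None = None,
    rng: np.random.Generator | int | None = None,
    n_trials: int = 40,
) -> pd.DataFrame:
    """Simulate one experimental and one baseline block per subject.

    Each subject's experimental-block ``p_stay_win_rareG`` is drawn from its
    group's distribution (clipped to [0.01, 0.99]); baseline-block agents use
    a common mean for all groups, so no group effect exists in baseline
    behavior by construction. Block order alternates with subject index
    parity (counterbalancing); rows are emitted in presentation order.

    Returns the tidy trial table with columns
    (subject_id, block, block_order, trial, choice, outcome, cumulative).
    """
    eff = behavior_effect or BehaviorEffectConfig()
    rng = np.random.default_rng(rng)
    blocks = {k: make_block(k, n_trials=n_trials) for k in ("experimental", "baseline")}

    frames = []
    for i, row in enumerate(covariates.itertuples(index=False)):
        p_expt = float(
            np.clip(rng.normal(eff.p_stay_mean[row.group], eff.p_stay_sd), 0.01, 0.99)
        )
        p_base = float(np.clip(rng.normal(eff.baseline_p_stay, eff.p_stay_sd), 0.01, 0.99))
        order = ("experimental", "baseline") if i % 2 == 0 else ("baseline", "experimental")
        for pos, kind in enumerate(order, start=1):
            p = p_expt if kind == "experimental" else p_base
            params = AgentParams(agent_kind="wsls", p_stay_win_rareG=p)
            recs = simulate_agent(blocks[kind], params, rng)
            frame = trials_to_frame(recs, row.subject_id, kind)
            frame.insert(2, "block_order", pos)
            frames.append(frame)
    return pd.concat(frames, ignore_index=True)
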