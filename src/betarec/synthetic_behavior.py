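"""Generative dual-process signal-detection (DPSD) response simulator.

Each match (old) trial is recollected with probability ``R_eff``; a
recollected item is reported old at the highest confidence.  Otherwise the
item's familiarity strength is drawn from Normal(d', 1) and binned by five
ordered decision criteria into one of six confidence levels.  Nonmatch
(new) trials draw strength from Normal(0, 1) and are binned the same way.
Stimulation effects enter as decrements to recollection (and optionally
familiarity) on trials whose sample was targeted by rTMS.

Confidence levels run 1..6 from *absolutely certain old* to *absolutely
certain new*; levels 1-3 are "old" decisions, 4-6 "new".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from betarec.task_design import SessionDesign

__all__ = [
    "ParticipantModel",
    "ResponseRecord",
    "confidence_to_level",
    "level_to_confidence",
    "simulate_responses",
    "records_frame",
]

_LEVELS = {("old", 3): 1, ("old", 2): 2, ("old", 1): 3,
           ("new", 1): 4, ("new", 2): 5, ("new", 3): 6}


def confidence_to_level(decision: str, rating: int) -> int:
    """Map an old/new decision plus a 1-3 confidence rating to a 1-6 level.

    Level 1 is *absolutely certain old* (old, rating 3); level 6 is
    *absolutely certain new* (new, rating 3).
    """
    if decision not in ("old", "new"):
        raise ValueError(f"decision must be 'old' or 'new', got {decision!r}")
    if rating not in (1, 2, 3):
        raise ValueError(f"rating must be 1, 2 or 3, got {rating!r}")
    return _LEVELS[(decision, rating)]


def level_to_confidence(level: int) -> tuple:
    """Inverse of :func:`confidence_to_level`."""
    for (decision, rating), lv in _LEVELS.items():
        if lv == level:
            return decision, rating
    raise ValueError(f"level must be 1..6, got {level!r}")


@dataclass
class ParticipantModel:
    """DPSD generative parameters for one simulated participant.

    ``criteria`` are five strictly decreasing thresholds on the strength
    axis (c1 strictest/highest); strength above ``criteria[i-1]`` maps to
    confidence level i, below the lowest to level 6.  ``delta_R`` is the
    recollection decrement applied to rTMS-targeted match trials in
    beta-stimulation blocks; ``delta_R_random`` the analogue for random
    stimulation; ``delta_d`` an optional familiarity decrement.  ``spillover``
    applies that fraction of the block's delta to untargeted match trials in
    the same block.  ``lapse`` replaces the response with a uniform level.
    """

    R_base: float = 0.3
    dprime_base: float = 1.2
    criteria: tuple = (1.2, 0.6, 0.0, -0.6, -1.2)
    delta_R: float = 0.0
    delta_R_random: float = 0.0
    delta_d: float = 0.0
    site: str = "dlPFC"
    lapse: float = 0.0
    spillover: float = 0.0
    recollection_levels: tuple = (1,)
    participant: int = 0

    def __post_init__(self):
        if not 0.0 <= self.R_base <= 1.0:
            raise ValueError("R_base must lie in [0, 1]")
        c = np.asarray(self.criteria, dtype=float)
        if len(c) != 5 or np.any(np.diff(c) >= 0):
            raise ValueError("criteria must be 5 strictly decreasing thresholds")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError("lapse must lie in [0, 1]")

    def effective_R(self, condition: str, targeted: bool) -> float:
        delta = {"beta": self.delta_R, "random": self.delta_R_random}.get(condition, 0.0)
        if not targeted:
            delta *= self.spillover
        return float(np.clip(self.R_base - delta, 0.0, 1.0))

    def effective_d(self, condition: str, targeted: bool) -> float:
        delta = self.delta_d if condition in ("beta", "random") else 0.0
        if not targeted:
            delta *= self.spillover
        return self.dprime_base - delta


@dataclass(frozen=True)
class ResponseRecord:
    participant: int
    site: str
    condition: str
    block: int
    trial_type: str  # match | nonmatch
    targeted: bool
    decision: str  # old | new
    rating: int  # 1..3
    level: int  # 1..6
    correct: bool


def _bin_strength(strength, criteria: np.ndarray):
    # strength above criteria[0] -> level 1, below criteria[-1] -> level 6
    return 1 + np.searchsorted(-criteria, -np.atleast_1d(strength), side="right")


def _draw_levels(
    model: ParticipantModel,
    is_match: np.ndarray,
    r_eff: np.ndarray,
    d_eff: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized DPSD response process for a batch of trials."""
    criteria = np.asarray(model.criteria, dtype=float)
    n = len(is_match)
    recollected = is_match & (rng.random(n) < r_eff)
    strength = rng.normal(np.where(is_match, d_eff, 0.0), 1.0)
    levels = _bin_strength(strength, criteria)
    if len(model.recollection_levels) == 1:
        levels[recollected] = model.recollection_levels[0]
    else:
        levels[recollected] = rng.choice(
            model.recollection_levels, size=int(recollected.sum())
        )
    if model.lapse:
        lapsed = rng.random(n) < model.lapse
        levels[lapsed] = rng.integers(1, 7, size=int(lapsed.sum()))
    return levels


def simulate_levels(
    model: ParticipantModel,
    n_match: int,
    n_nonmatch: int,
    condition: str = "none",
    targeted: bool = False,
    rng: np.random.Generator | int | None = None,
) -> tuple:
    """Draw confidence levels for flat batches of match and nonmatch trials.

    Convenience sampler for calibration studies that need raw level
    distributions without a session design.  Returns
    ``(match_levels, nonmatch_levels)`` as integer arrays in 1..6.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    is_match = np.concatenate([np.ones(n_match, bool), np.zeros(n_nonmatch, bool)])
    r = model.effective_R(condition, targeted)
    d = model.effective_d(condition, targeted)
    levels = _draw_levels(
        model, is_match, np.full(len(is_match), r), np.full(len(is_match), d), rng
    )
    return levels[:n_match], levels[n_match:]


def simulate_responses(
    model: ParticipantModel,
    design: SessionDesign,
    rng: np.random.Generator | int | None = None,
) -> list:
    """Simulate one participant's responses over a full session design."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    trials = []
    for bi, block in enumerate(design.blocks):
        for trial in block.test_trials:
            trials.append((bi, block.condition, trial))
    is_match = np.array([t.trial_type == "match" for _, _, t in trials])
    r_eff = np.array(
        [model.effective_R(cond, t.targeted) for _, cond, t in trials]
    )
    d_eff = np.array(
        [model.effective_d(cond, t.targeted) for _, cond, t in trials]
    )
    levels = _draw_levels(model, is_match, r_eff, d_eff, rng)

    records = []
    for (bi, condition, trial), level, match in zip(trials, levels, is_match):
        decision, rating = level_to_confidence(int(level))
        records.append(
            ResponseRecord(
                participant=model.participant,
                site=model.site,
                condition=condition,
                block=bi,
                trial_type=trial.trial_type,
                targeted=trial.targeted,
                decision=decision,
                rating=rating,
                level=int(level),
                correct=(match and decision == "old")
                or (not match and decision == "new"),
            )
        )
    return records


def records_frame(records) -> pd.DataFrame:
    """Tidy DataFrame view of a list of :class:`ResponseRecord`."""
    if isinstance(records, pd.DataFrame):
        return records
    return pd.DataFrame([r.__dict__ for r in records])
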