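"""Experiment design: block/session structure and rTMS pulse schedules.

The recognition-memory session consists of three subsessions of 15 blocks
each.  Every block presents a list of 12 trial-unique sample images followed
by 12 test trials (6 match, 6 nonmatch).  Blocks come in three stimulation
conditions — beta (fixed inter-pulse interval, 12.5 Hz), random (same pulse
count scattered over non-adjacent 30-ms bins) and none — each occurring five
times per subsession in random order.  In stimulated blocks four of the 12
samples are targeted, with at least two non-targeted samples between any two
targeted ones (a TMS safety constraint).

Both the target-position schedules and the random pulse trains are drawn
uniformly from the exhaustively enumerated set of configurations satisfying
their constraints.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict
from functools import lru_cache

import numpy as np
import pandas as pd

__all__ = [
    "PulseTrain",
    "StimulationSchedule",
    "TestTrial",
    "Block",
    "SessionDesign",
    "DesignConfig",
    "beta_pulse_train",
    "random_pulse_train",
    "sample_target_schedule",
    "build_session",
]

CONDITIONS = ("beta", "random", "none")


@dataclass(frozen=True)
class PulseTrain:
    """Pulse onset times for one targeted sample presentation.

    Parameters
    ----------
    epoch_ms : float
        Duration of the sample presentation epoch in milliseconds.
    times_ms : tuple of float
        Ordered pulse onsets, as offsets from sample onset.
    kind : {"beta", "random"}
    """

    epoch_ms: float
    times_ms: tuple
    kind: str

    def __post_init__(self):
        times = self.times_ms
        if any(not (0 <= t < self.epoch_ms) for t in times):
            raise ValueError("pulse times must lie in [0, epoch_ms)")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("pulse times must be strictly increasing")

    @property
    def n_pulses(self) -> int:
        return len(self.times_ms)

    @property
    def rate_hz(self) -> float:
        """Implied pulse rate (pulses per second) for an evenly spaced train."""
        if self.n_pulses < 2:
            raise ValueError("rate undefined for fewer than two pulses")
        isi = np.diff(self.times_ms)
        if not np.allclose(isi, isi[0]):
            raise ValueError("rate undefined for unevenly spaced train")
        return 1000.0 / isi[0]


@dataclass(frozen=True)
class StimulationSchedule:
    """Which samples of a block are targeted and with what pulse train."""

    condition: str
    targeted_samples: frozenset
    pulse_trains: dict = field(default_factory=dict)  # sample position -> PulseTrain

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.condition == "none":
            if self.targeted_samples:
                raise ValueError("no-stimulation schedule cannot target samples")
        else:
            pos = sorted(self.targeted_samples)
            if any(b - a < 3 for a, b in zip(pos, pos[1:])):
                raise ValueError("targeted positions must differ by >= 3")
            if set(self.pulse_trains) != set(self.targeted_samples):
                raise ValueError("one pulse train per targeted sample required")


@dataclass(frozen=True)
class TestTrial:
    trial_index: int
    stimulus_id: int
    trial_type: str  # match | nonmatch
    targeted: bool
    sample_position: int | None  # position in the sample list, match trials only
    circle_side: str  # left | right placement of the nonmatch button


@dataclass(frozen=True)
class Block:
    subsession: int
    index: int  # position within the subsession
    condition: str
    sample_ids: tuple
    schedule: StimulationSchedule
    test_trials: tuple


@dataclass(frozen=True)
class SessionDesign:
    """Complete session layout: subsessions of blocks, trials and schedules."""

    subsessions: tuple  # tuple of tuples of Block
    seed: int

    @property
    def blocks(self):
        return tuple(b for sub in self.subsessions for b in sub)

    def trials_table(self) -> pd.DataFrame:
        """Long-format test-trial table (one row per test trial)."""
        rows = []
        for bi, block in enumerate(self.blocks):
            for t in block.test_trials:
                rows.append(
                    {
                        "block": bi,
                        "condition": block.condition,
                        "trial_index": t.trial_index,
                        "stimulus_id": t.stimulus_id,
                        "trial_type": t.trial_type,
                        "targeted": t.targeted,
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        def _ser(obj):
            if isinstance(obj, (frozenset, set)):
                return sorted(obj)
            if isinstance(obj, tuple):
                return [_ser(o) for o in obj]
            if isinstance(obj, dict):
                return {str(k): _ser(v) for k, v in obj.items()}
            if hasattr(obj, "__dataclass_fields__"):
                return {k: _ser(v) for k, v in asdict(obj).items()}
            return obj

        return {"seed": self.seed, "subsessions": _ser(self.subsessions)}

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass
class DesignConfig:
    """Session-design parameters.  Defaults reproduce the published protocol."""

    n_subsessions: int = 3
    blocks_per_condition: int = 5  # per subsession
    n_samples: int = 12
    n_match: int = 6
    n_nonmatch: int = 6
    n_targets: int = 4
    min_between: int = 2  # non-stimulated samples between targeted ones
    epoch_ms: float = 480.0
    isi_ms: float = 350.0  # interstimulus interval (metadata only)
    pulse_isi_ms: float = 80.0
    n_pulses: int = 6
    bin_ms: float = 30.0
    # Optional forcing of per-session targeted-match counts per condition,
    # e.g. {"beta": 36, "random": 33}; None leaves counts emergent.
    force_targeted_match: dict | None = None

    def validate(self):
        if self.n_match > self.n_samples:
            raise ValueError("cannot have more match trials than samples")
        for name in ("n_subsessions", "blocks_per_condition", "n_samples",
                     "n_match", "n_nonmatch", "n_targets", "n_pulses"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def beta_pulse_train(
    epoch_ms: float, isi_ms: float, n_pulses: int, first_offset_ms: float = 0.0
) -> PulseTrain:
    """Evenly spaced pulse train: ``n_pulses`` pulses every ``isi_ms`` ms.

    The default protocol (480-ms epoch, 80-ms interval, 6 pulses) implies a
    12.5-Hz stimulation rate.  The first pulse is at sample onset unless
    ``first_offset_ms`` shifts the whole train.
    """
    if epoch_ms <= 0 or isi_ms <= 0 or n_pulses <= 0:
        raise ValueError("epoch_ms, isi_ms and n_pulses must all be positive")
    span = first_offset_ms + (n_pulses - 1) * isi_ms
    if span >= epoch_ms:
        raise ValueError(
            f"train does not fit: last pulse at {span} ms >= epoch {epoch_ms} ms"
        )
    times = tuple(first_offset_ms + k * isi_ms for k in range(n_pulses))
    return PulseTrain(epoch_ms=epoch_ms, times_ms=times, kind="beta")


@lru_cache(maxsize=None)
def _nonadjacent_bin_sets(n_bins: int, k: int) -> tuple:
    """All k-subsets of range(n_bins) with no two adjacent members."""
    return tuple(
        c
        for c in itertools.combinations(range(n_bins), k)
        if all(b - a >= 2 for a, b in zip(c, c[1:]))
    )


def random_pulse_train(
    epoch_ms: float, bin_ms: float, n_pulses: int, rng: np.random.Generator
) -> PulseTrain:
    """Pulse train scattered over non-adjacent fixed-width bins.

    The epoch is divided into ``epoch_ms / bin_ms`` intervals; ``n_pulses``
    of them are chosen uniformly from all subsets in which no two chosen
    intervals are adjacent.  Each pulse fires at the start of its bin.
    """
    if epoch_ms <= 0 or bin_ms <= 0:
        raise ValueError("durations must be positive")
    n_bins_f = epoch_ms / bin_ms
    n_bins = round(n_bins_f)
    if abs(n_bins_f - n_bins) > 1e-9:
        raise ValueError(f"epoch {epoch_ms} ms not divisible by bin {bin_ms} ms")
    if n_pulses > (n_bins + 1) // 2:
        raise ValueError(
            f"{n_pulses} non-adjacent pulses do not fit in {n_bins} bins"
        )
    valid = _nonadjacent_bin_sets(n_bins, n_pulses)
    bins = valid[int(rng.integers(len(valid)))]
    return PulseTrain(
        epoch_ms=epoch_ms, times_ms=tuple(b * bin_ms for b in bins), kind="random"
    )


@lru_cache(maxsize=None)
def _target_schedules(n_samples: int, n_targets: int, min_between: int) -> tuple:
    """All target-position subsets with >= min_between untargeted in between."""
    gap = min_between + 1
    return tuple(
        c
        for c in itertools.combinations(range(n_samples), n_targets)
        if all(b - a >= gap for a, b in zip(c, c[1:]))
    )


def sample_target_schedule(
    n_samples: int, n_targets: int, min_between: int, rng: np.random.Generator
) -> frozenset:
    """Uniformly draw which sample positions receive stimulation.

    Enumerates every subset of ``n_targets`` positions out of ``n_samples``
    with at least ``min_between`` non-stimulated samples between consecutive
    targets, and samples one uniformly.  With the default 4-of-12 list and a
    2-sample gap there are exactly 15 valid schedules.
    """
    valid = _target_schedules(n_samples, n_targets, min_between)
    if not valid:
        raise ValueError(
            f"no valid schedule: {n_targets} targets with gap >= "
            f"{min_between + 1} do not fit in {n_samples} positions"
        )
    return frozenset(valid[int(rng.integers(len(valid)))])


def _make_schedule(
    condition: str, config: DesignConfig, rng: np.random.Generator
) -> StimulationSchedule:
    if condition == "none":
        return StimulationSchedule("none", frozenset())
    targets = sample_target_schedule(
        config.n_samples, config.n_targets, config.min_between, rng
    )
    trains = {}
    for pos in sorted(targets):
        if condition == "beta":
            trains[pos] = beta_pulse_train(
                config.epoch_ms, config.pulse_isi_ms, config.n_pulses
            )
        else:
            trains[pos] = random_pulse_train(
                config.epoch_ms, config.bin_ms, config.n_pulses, rng
            )
    return StimulationSchedule(condition, targets, trains)


def _allocate_forced_counts(
    total: int, n_blocks: int, n_targets: int, n_match: int, rng: np.random.Generator
) -> list:
    """Split a forced session-level targeted-match count across blocks."""
    lo, hi = 0, min(n_targets, n_match)
    if not n_blocks * lo <= total <= n_blocks * hi:
        raise ValueError(f"cannot allocate {total} targeted match trials "
                         f"over {n_blocks} blocks (max {hi} each)")
    counts = [total // n_blocks] * n_blocks
    for i in rng.choice(n_blocks, size=total - sum(counts), replace=False):
        counts[i] += 1
    return counts


def build_session(
    config: DesignConfig | None = None, rng: np.random.Generator | int | None = None
) -> SessionDesign:
    """Generate a full randomized session design.

    With defaults: 3 subsessions x 15 blocks x 12 test trials = 540 trials,
    each condition 15 times per session, 90 nonmatch trials per condition.
    Stimulus ids are unique across the whole session; match-test stimuli are
    drawn from their own block's sample list, nonmatch stimuli are novel.
    """
    config = config or DesignConfig()
    config.validate()
    if isinstance(rng, np.random.Generator):
        seed = -1
    else:
        seed = 0 if rng is None else int(rng)
        rng = np.random.default_rng(seed)

    n_blocks_sub = config.blocks_per_condition * len(CONDITIONS)
    next_id = itertools.count()

    # Optional forced targeted-match allocation per stimulated condition.
    forced: dict[str, list] = {}
    if config.force_targeted_match:
        nb = config.n_subsessions * config.blocks_per_condition
        for cond, total in config.force_targeted_match.items():
            forced[cond] = _allocate_forced_counts(
                total, nb, config.n_targets, config.n_match, rng
            )

    subsessions = []
    for sub in range(config.n_subsessions):
        order = np.repeat(CONDITIONS, config.blocks_per_condition)
        rng.shuffle(order)
        blocks = []
        for bi in range(n_blocks_sub):
            condition = str(order[bi])
            schedule = _make_schedule(condition, config, rng)
            sample_ids = tuple(next(next_id) for _ in range(config.n_samples))

            positions = np.arange(config.n_samples)
            targeted_pos = np.isin(positions, sorted(schedule.targeted_samples))
            if condition in forced:
                n_plus = forced[condition].pop(0)
                plus = rng.choice(positions[targeted_pos], n_plus, replace=False)
                minus = rng.choice(
                    positions[~targeted_pos], config.n_match - n_plus, replace=False
                )
                match_pos = np.concatenate([plus, minus])
            else:
                match_pos = rng.choice(positions, config.n_match, replace=False)

            trials = []
            for pos in match_pos:
                trials.append(
                    TestTrial(
                        trial_index=-1,
                        stimulus_id=sample_ids[pos],
                        trial_type="match",
                        targeted=bool(pos in schedule.targeted_samples),
                        sample_position=int(pos),
                        circle_side="",
                    )
                )
            for _ in range(config.n_nonmatch):
                trials.append(
                    TestTrial(
                        trial_index=-1,
                        stimulus_id=next(next_id),
                        trial_type="nonmatch",
                        targeted=False,
                        sample_position=None,
                        circle_side="",
                    )
                )
            perm = rng.permutation(len(trials))
            sides = rng.choice(["left", "right"], size=len(trials))
            ordered = tuple(
                TestTrial(
                    trial_index=i,
                    stimulus_id=trials[j].stimulus_id,
                    trial_type=trials[j].trial_type,
                    targeted=trials[j].targeted,
                    sample_position=trials[j].sample_position,
                    circle_side=str(sides[i]),
                )
                for i, j in enumerate(perm)
            )
            blocks.append(
                Block(
                    subsession=sub,
                    index=bi,
                    condition=condition,
                    sample_ids=sample_ids,
                    schedule=schedule,
                    test_trials=ordered,
                )
            )
        subsessions.append(tuple(blocks))
    return SessionDesign(subsessions=tuple(subsessions), seed=seed)
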