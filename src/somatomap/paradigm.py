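"""Task timing for phase-encoded (travelling-wave) and block-design digit mapping.

The travelling-wave paradigm cycles movement through the five digits in a set
order (forward D1..D5 or backward D5..D1), one block per digit, so that each
cortical locus responds at a characteristic phase of the cycle.  The block
design presents each digit (plus rest) in a counterbalanced order and is used
for the multivoxel-pattern similarity analysis.  Both the simulator and the
analysis build their regressors from these schedules, which keeps the two
sides of every round-trip test commensurate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MovementEvent",
    "MovementSchedule",
    "BlockSchedule",
    "make_travelling_wave_schedule",
    "make_bimanual_schedule",
    "make_block_schedule",
    "schedule_duration",
    "events_table",
    "schedule_from_events_table",
    "write_events",
    "read_events",
]

HANDS = ("left", "right")
DIRECTIONS = ("forward", "backward", "none")

REST_LABEL = "rest"


@dataclass(frozen=True)
class MovementEvent:
    """A single timed digit-movement block.

    digit: 1 = thumb (D1) ... 5 = little finger (D5).
    """

    digit: int
    hand: str
    onset: float
    duration: float

    def __post_init__(self) -> None:
        if not (isinstance(self.digit, (int, np.integer)) and 1 <= self.digit <= 5):
            raise ValueError(f"digit must be an integer in 1..5, got {self.digit!r}")
        if self.hand not in HANDS:
            raise ValueError(f"hand must be one of {HANDS}, got {self.hand!r}")
        if self.onset < 0:
            raise ValueError(f"onset must be >= 0, got {self.onset}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")

    @property
    def offset(self) -> float:
        return self.onset + self.duration

    @property
    def label(self) -> str:
        return f"D{self.digit}"


def _check_events(events: list[MovementEvent]) -> None:
    by_hand: dict[str, list[MovementEvent]] = {}
    for ev in events:
        by_hand.setdefault(ev.hand, []).append(ev)
    if any(events[i].onset > events[i + 1].onset for i in range(len(events) - 1)):
        raise ValueError("events must be sorted by onset")
    for hand_events in by_hand.values():
        for a, b in zip(hand_events, hand_events[1:]):
            if b.onset < a.offset - 1e-9:
                raise ValueError(
                    f"overlapping events within one hand: {a} and {b}"
                )


@dataclass(frozen=True)
class MovementSchedule:
    """An ordered travelling-wave run: ``n_cycles`` repetitions of a digit cycle."""

    events: tuple[MovementEvent, ...]
    cycle_duration: float
    n_cycles: int
    lead_in: float = 0.0
    direction: str = "none"

    def __post_init__(self) -> None:
        if self.direction not in DIRECTIONS:
            raise ValueError(f"direction must be one of {DIRECTIONS}")
        if self.lead_in < 0:
            raise ValueError("lead_in must be >= 0")
        _check_events(list(self.events))

    @property
    def hand(self) -> str | None:
        hands = {ev.hand for ev in self.events}
        return hands.pop() if len(hands) == 1 else None

    @property
    def digit_sequence(self) -> tuple[int, ...]:
        return tuple(ev.digit for ev in self.events)


@dataclass(frozen=True)
class BlockSchedule:
    """A counterbalanced block-design run over digit conditions plus rest.

    ``blocks`` is an ordered list of ``(label, onset, duration)`` with labels
    "D1".."D5" or "rest"; blocks tile the run with no gaps.
    """

    blocks: tuple[tuple[str, float, float], ...]
    block_duration: float
    n_conditions: int
    reps_per_condition: int
    order_seed: int
    hand: str = "left"
    lead_in: float = 0.0

    def __post_init__(self) -> None:
        labels = [b[0] for b in self.blocks]
        from collections import Counter

        counts = Counter(labels)
        for lab, n in counts.items():
            if n != self.reps_per_condition:
                raise ValueError(
                    f"condition {lab!r} appears {n} times, "
                    f"expected {self.reps_per_condition}"
                )
        t = self.lead_in
        for lab, onset, dur in self.blocks:
            if abs(onset - t) > 1e-9:
                raise ValueError("blocks must tile the run with no gaps")
            t = onset + dur

    @property
    def condition_order(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.blocks)

    def digit_events(self) -> list[MovementEvent]:
        """Movement events for the non-rest blocks."""
        return [
            MovementEvent(int(lab[1]), self.hand, onset, dur)
            for lab, onset, dur in self.blocks
            if lab != REST_LABEL
        ]


def make_travelling_wave_schedule(
    direction: str,
    n_digits: int = 5,
    block_duration: float = 9.0,
    n_cycles: int = 8,
    lead_in: float = 0.0,
    hand: str = "left",
) -> MovementSchedule:
    """Build a forward (D1..Dn) or backward (Dn..D1) travelling-wave run.

    The canonical high-field protocol uses five 9 s digit blocks per 45 s
    cycle and 8 cycles per run; the standard-field variant uses 9.1 s blocks
    (45.5 s cycles).
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    if n_digits < 2:
        raise ValueError("n_digits must be >= 2")
    if block_duration <= 0:
        raise ValueError("block_duration must be > 0")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if n_digits > 5:
        raise ValueError("at most 5 digits are supported")

    digits = list(range(1, n_digits + 1))
    if direction == "backward":
        digits = digits[::-1]
    cycle = n_digits * block_duration
    events = []
    for c in range(n_cycles):
        for k, d in enumerate(digits):
            onset = lead_in + c * cycle + k * block_duration
            events.append(MovementEvent(d, hand, onset, block_duration))
    return MovementSchedule(
        events=tuple(events),
        cycle_duration=cycle,
        n_cycles=n_cycles,
        lead_in=lead_in,
        direction=direction,
    )


def make_bimanual_schedule(
    n_digits: int = 5,
    block_duration: float = 9.0,
    n_cycles: int = 8,
    direction_left: str = "forward",
    lead_in: float = 0.0,
) -> tuple[MovementSchedule, MovementSchedule]:
    """Paired bimanual runs with reversed digit cycles between the hands.

    At every block the left and right digits are complementary
    (left + right = n_digits + 1), i.e. one hand cycles D1->Dn while the
    other simultaneously cycles Dn->D1.
    """
    left = make_travelling_wave_schedule(
        direction_left, n_digits, block_duration, n_cycles, lead_in, hand="left"
    )
    direction_right = "backward" if direction_left == "forward" else "forward"
    right = make_travelling_wave_schedule(
        direction_right, n_digits, block_duration, n_cycles, lead_in, hand="right"
    )
    return left, right


def make_block_schedule(
    n_conditions: int = 6,
    reps: int = 7,
    block_duration: float = 12.0,
    order_seed: int = 0,
    hand: str = "left",
    lead_in: float = 0.0,
) -> BlockSchedule:
    """Counterbalanced block design: ``n_conditions`` (digits + rest) x ``reps``.

    The order is a seeded permutation constrained so that no condition
    immediately repeats itself.  The canonical protocol is 6 conditions
    (5 digits + rest) x 7 reps x 12 s = 8 min 24 s.
    """
    if n_conditions < 1:
        raise ValueError("n_conditions must be >= 1")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if block_duration <= 0:
        raise ValueError("block_duration must be > 0")
    if n_conditions == 1 and reps > 1:
        raise ValueError(
            "no-immediate-repeat order impossible with a single condition"
        )
    if n_conditions > 6:
        raise ValueError("at most 6 conditions (5 digits + rest) are supported")

    labels = [f"D{d}" for d in range(1, n_conditions)] + [REST_LABEL]
    rng = np.random.default_rng(order_seed)
    pool = labels * reps
    for _ in range(10_000):
        order = list(rng.permutation(pool))
        if all(a != b for a, b in zip(order, order[1:])):
            break
    else:  # pragma: no cover - rejection sampling essentially always succeeds
        raise RuntimeError("could not find a no-immediate-repeat order")

    blocks = tuple(
        (lab, lead_in + i * block_duration, block_duration)
        for i, lab in enumerate(order)
    )
    return BlockSchedule(
        blocks=blocks,
        block_duration=block_duration,
        n_conditions=n_conditions,
        reps_per_condition=reps,
        order_seed=order_seed,
        hand=hand,
        lead_in=lead_in,
    )


def schedule_duration(schedule: MovementSchedule | BlockSchedule) -> float:
    """Total run duration in seconds (lead-in + active blocks)."""
    if isinstance(schedule, MovementSchedule):
        if not schedule.events:
            return schedule.lead_in
        return schedule.lead_in + schedule.n_cycles * schedule.cycle_duration
    if isinstance(schedule, BlockSchedule):
        return schedule.lead_in + len(schedule.blocks) * schedule.block_duration
    raise TypeError(f"unsupported schedule type: {type(schedule)!r}")


# ---------------------------------------------------------------------------
# BIDS-style 3-column events tables


def events_table(
    schedule: MovementSchedule | BlockSchedule, prefix_hand: bool = False
) -> pd.DataFrame:
    """Serialize a schedule to a (onset, duration, trial_type) table."""
    rows = []
    if isinstance(schedule, MovementSchedule):
        for ev in schedule.events:
            lab = ev.label
            if prefix_hand:
                lab = ("L_" if ev.hand == "left" else "R_") + lab
            rows.append((ev.onset, ev.duration, lab))
    else:
        for lab, onset, dur in schedule.blocks:
            if prefix_hand and lab != REST_LABEL:
                lab = ("L_" if schedule.hand == "left" else "R_") + lab
            rows.append((onset, dur, lab))
    return pd.DataFrame(rows, columns=["onset", "duration", "trial_type"])


def schedule_from_events_table(
    table: pd.DataFrame,
    cycle_duration: float,
    n_cycles: int,
    lead_in: float = 0.0,
    direction: str = "none",
    default_hand: str = "left",
) -> MovementSchedule:
    """Rebuild a travelling-wave schedule from a 3-column events table."""
    events = []
    for _, row in table.iterrows():
        lab = str(row["trial_type"])
        hand = default_hand
        if lab.startswith(("L_", "R_")):
            hand = "left" if lab[0] == "L" else "right"
            lab = lab[2:]
        if lab == REST_LABEL:
            continue
        events.append(
            MovementEvent(int(lab[1]), hand, float(row["onset"]), float(row["duration"]))
        )
    return MovementSchedule(
        events=tuple(events),
        cycle_duration=cycle_duration,
        n_cycles=n_cycles,
        lead_in=lead_in,
        direction=direction,
    )


def write_events(schedule, path, prefix_hand: bool = False) -> None:
    events_table(schedule, prefix_hand=prefix_hand).to_csv(
        path, sep="\t", index=False
    )


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
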