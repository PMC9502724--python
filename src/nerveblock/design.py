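"""Balanced-incomplete-block measurement schedules.

Latency readings are destructive of time, not of animals: the analgesia meter
measures one mouse at a time, so a group of n mice sharing one 270-min
post-injection horizon is interleaved on a 1.5-min slot grid.  Each mouse is
read exactly once per 13.5-min window (9 slots); with n < 9 mice per group
only n of the 9 slots in each window are occupied, which makes the block
design incomplete.  Slot assignment rotates the group through the grid so the
same animal is never measured twice in quick succession.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["DesignSpec", "ScheduleEntry", "generate_schedule", "validate_schedule"]


def _is_multiple(a: float, b: float, tol: float = 1e-9) -> bool:
    r = a / b
    return abs(r - round(r)) < tol


@dataclass(frozen=True)
class DesignSpec:
    """Grid geometry of the sampling design.

    Defaults give the 180-point grid: 270 min / 1.5-min slots, windows of
    13.5 min (9 slots, 20 windows).
    """

    n_mice_per_group: int
    slot_spacing_min: float = 1.5
    window_min: float = 13.5
    total_min: float = 270.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice_per_group < 1:
            raise ValueError("n_mice_per_group must be >= 1")
        if not _is_multiple(self.window_min, self.slot_spacing_min):
            raise ValueError("window_min must be an integer multiple of slot_spacing_min")
        if not _is_multiple(self.total_min, self.window_min):
            raise ValueError("total_min must be an integer multiple of window_min")
        if self.n_mice_per_group > self.slots_per_window:
            raise ValueError(
                f"{self.n_mice_per_group} mice cannot fit the "
                f"{self.slots_per_window} slots of one window"
            )

    @property
    def slots_per_window(self) -> int:
        return round(self.window_min / self.slot_spacing_min)

    @property
    def n_windows(self) -> int:
        return round(self.total_min / self.window_min)

    @property
    def n_grid_points(self) -> int:
        return round(self.total_min / self.slot_spacing_min)


@dataclass(frozen=True)
class ScheduleEntry:
    window_index: int
    slot_time_min: float
    mouse_id: str


def generate_schedule(spec: DesignSpec, mouse_ids: Sequence[str]) -> list[ScheduleEntry]:
    """Assign each mouse one slot per window, rotating across windows.

    A seeded shuffle fixes the group's base slot order; within window w every
    base slot advances by 2*w (mod slots-per-window).  Stepping by two slots
    guarantees consecutive readings of the same animal are at least two slot
    spacings (3 min) apart whenever the window holds three or more slots.
    Deterministic given (spec.seed, mouse order).
    """
    if len(mouse_ids) != spec.n_mice_per_group:
        raise ValueError("len(mouse_ids) must equal spec.n_mice_per_group")
    if len(set(mouse_ids)) != len(mouse_ids):
        raise ValueError("mouse_ids must be unique")
    s = spec.slots_per_window
    rng = np.random.default_rng(spec.seed)
    base = rng.permutation(s)[: len(mouse_ids)]  # distinct base slots
    step = 2 % s
    entries = []
    for w in range(spec.n_windows):
        for mouse, b in zip(mouse_ids, base):
            slot = (int(b) + step * w) % s
            t = w * spec.window_min + slot * spec.slot_spacing_min
            entries.append(ScheduleEntry(window_index=w, slot_time_min=t, mouse_id=mouse))
    entries.sort(key=lambda e: (e.slot_time_min, e.mouse_id))
    return entries


def validate_schedule(entries: Sequence[ScheduleEntry], spec: DesignSpec) -> list[str]:
    """Check a schedule against the grid; returns a list of violations.

    An empty list means the schedule is valid.  Violations are data, not
    exceptions: the checker is idempotent and reports every problem found
    (slot collisions, off-grid times, slots outside their window, missing or
    duplicated mouse-window pairs).
    """
    violations: list[str] = []
    seen_times: dict[float, str] = {}
    pairs: dict[tuple[str, int], int] = {}
    for e in entries:
        r = e.slot_time_min / spec.slot_spacing_min
        if abs(r - round(r)) > 1e-9:
            violations.append(f"off-grid time {e.slot_time_min} for mouse {e.mouse_id}")
        lo = e.window_index * spec.window_min
        if not (lo <= e.slot_time_min < lo + spec.window_min):
            violations.append(
                f"slot {e.slot_time_min} outside window {e.window_index} for mouse {e.mouse_id}"
            )
        if e.slot_time_min in seen_times:
            violations.append(
                f"slot collision at t={e.slot_time_min} ({seen_times[e.slot_time_min]} vs {e.mouse_id})"
            )
        else:
            seen_times[e.slot_time_min] = e.mouse_id
        pairs[(e.mouse_id, e.window_index)] = pairs.get((e.mouse_id, e.window_index), 0) + 1
    mice = {e.mouse_id for e in entries}
    for mouse in sorted(mice):
        for w in range(spec.n_windows):
            count = pairs.get((mouse, w), 0)
            if count == 0:
                violations.append(f"mouse {mouse} missing in window {w}")
            elif count > 1:
                violations.append(f"mouse {mouse} measured {count} times in window {w}")
    return violations


def schedule_to_frame(entries: Sequence[ScheduleEntry]) -> pd.DataFrame:
    """Schedule as a DataFrame (window_index, slot_time_min, mouse_id)."""
    return pd.DataFrame(
        {
            "window_index": [e.window_index for e in entries],
            "slot_time_min": [e.slot_time_min for e in entries],
            "mouse_id": [e.mouse_id for e in entries],
        }
    )
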