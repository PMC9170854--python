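"""Disjoint-interval frame schedules.

A full acquisition of length T is partitioned into ``floor(T/RL)``
contiguous half-open intervals ``[k*RL, (k+1)*RL)``.  Because the
intervals are disjoint, frames reconstructed from them are statistically
independent — the property the variation estimator depends on.  Remainder
seconds (e.g. 150 mod 4 = 2 s) are dropped so every frame in a subset
shares the same reconstruction length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "FrameSchedule",
    "make_schedule",
    "default_schedules",
    "DEFAULT_RLS_S",
    "DEFAULT_TOTAL_S",
]

#: The fourteen default reconstruction lengths (s).
DEFAULT_RLS_S: tuple[float, ...] = (4, 6, 8, 10, 12, 15, 17, 19, 20, 22, 24, 26, 28, 30)

#: Default full acquisition length per bed position (s).
DEFAULT_TOTAL_S = 150.0


@dataclass(frozen=True)
class FrameSchedule:
    """One subset: a reconstruction length and its disjoint time intervals."""

    rl_s: float
    intervals: tuple[tuple[float, float], ...]
    total_s: float

    @property
    def n_frames(self) -> int:
        return len(self.intervals)


def make_schedule(total_s: float, rl_s: float) -> FrameSchedule:
    """Partition ``[0, total_s)`` into frames of length ``rl_s``.

    Raises
    ------
    ValueError
        If ``rl_s`` is not in ``(0, total_s]``.
    """
    if rl_s <= 0:
        raise ValueError(f"reconstruction length must be > 0, got {rl_s}")
    if rl_s > total_s:
        raise ValueError(f"reconstruction length {rl_s} exceeds acquisition length {total_s}")
    n = int(total_s // rl_s)
    intervals = tuple((k * rl_s, (k + 1) * rl_s) for k in range(n))
    return FrameSchedule(rl_s=float(rl_s), intervals=intervals, total_s=float(total_s))


def default_schedules(total_s: float = DEFAULT_TOTAL_S) -> list[FrameSchedule]:
    """The fourteen standard subsets (RL = 4 ... 30 s) of a 150 s acquisition."""
    return [make_schedule(total_s, rl) for rl in DEFAULT_RLS_S]
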