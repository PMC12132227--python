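"""Flash-schedule protocols for pulse-amplitude-modulation NPQ measurements.

A measurement run applies a sequence of saturating flashes to a dark-adapted
sample: first under actinic light (NPQ induction), then in darkness (NPQ
relaxation), optionally repeated over several light/dark cycles (fluctuating
light).  The protocol is specified as *inter-flash intervals* in seconds; the
absolute time of flash k is the cumulative sum of the first k intervals, with
t = 0 at actinic-light onset.  Fo and Fm are taken before illumination and are
not part of the flash list.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import yaml


class ProtocolError(ValueError):
    """Raised when a flash schedule is structurally invalid."""


LIGHT = "light"
DARK = "dark"


@dataclass(frozen=True)
class FlashSchedule:
    """A validated flash protocol.

    Attributes
    ----------
    intervals_s:
        Positive inter-flash intervals in seconds, one per flash.
    phase_labels:
        ``"light"`` or ``"dark"`` per flash.  Within a cycle every light
        flash precedes every dark flash.
    cycle_index:
        Non-negative cycle number per flash (all zero for single-cycle
        protocols).
    actinic_ppfd, pulse_ppfd:
        Actinic-light and saturating-pulse intensities in µmol m⁻² s⁻¹
        (metadata only; they do not enter any computation).
    nominal_light_duration_s, nominal_dark_duration_s:
        Optional declared phase lengths from the protocol description.  They
        may disagree with the interval sums; the flash partition is the
        operational definition of the phases.
    name:
        Optional preset name, carried into output headers.
    """

    intervals_s: tuple[float, ...]
    phase_labels: tuple[str, ...]
    cycle_index: tuple[int, ...]
    actinic_ppfd: float = 1000.0
    pulse_ppfd: float = 3200.0
    nominal_light_duration_s: float | None = None
    nominal_dark_duration_s: float | None = None
    name: str = "custom"

    def __post_init__(self) -> None:
        n = len(self.intervals_s)
        if n == 0:
            raise ProtocolError("schedule must contain at least one flash")
        if len(self.phase_labels) != n or len(self.cycle_index) != n:
            raise ProtocolError(
                f"flash count mismatch: {n} intervals, "
                f"{len(self.phase_labels)} labels, {len(self.cycle_index)} cycle indices"
            )
        if any(dt <= 0 for dt in self.intervals_s):
            raise ProtocolError("all inter-flash intervals must be positive")
        bad = set(self.phase_labels) - {LIGHT, DARK}
        if bad:
            raise ProtocolError(f"unknown phase labels: {sorted(bad)}")
        if any(c < 0 for c in self.cycle_index):
            raise ProtocolError("cycle indices must be non-negative")
        if list(self.cycle_index) != sorted(self.cycle_index):
            raise ProtocolError("cycle indices must be non-decreasing")
        for c in set(self.cycle_index):
            labels = [p for p, ci in zip(self.phase_labels, self.cycle_index) if ci == c]
            seen_dark = False
            for p in labels:
                if p == DARK:
                    seen_dark = True
                elif seen_dark:
                    raise ProtocolError(
                        f"cycle {c}: light flash after a dark flash; within a "
                        "cycle all light flashes must precede all dark flashes"
                    )

    @property
    def n_flashes(self) -> int:
        return len(self.intervals_s)

    @property
    def n_cycles(self) -> int:
        return max(self.cycle_index) + 1

    def times(self) -> np.ndarray:
        """Absolute flash times in seconds since actinic-light onset."""
        return np.cumsum(np.asarray(self.intervals_s, dtype=float))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "intervals_s": list(self.intervals_s),
            "phase_labels": list(self.phase_labels),
            "cycle_index": list(self.cycle_index),
            "actinic_ppfd": self.actinic_ppfd,
            "pulse_ppfd": self.pulse_ppfd,
            "nominal_light_duration_s": self.nominal_light_duration_s,
            "nominal_dark_duration_s": self.nominal_dark_duration_s,
        }


@dataclass(frozen=True)
class PhaseSegment:
    """One contiguous light or dark stretch of a schedule.

    ``local_times_s`` re-zeroes the clock at the segment boundary: the first
    flash of the segment sits at its own interval.  For a dark segment this is
    time since light-off, the clock relaxation kinetics are fit against
    (light-off is taken to coincide with the final light-phase flash).
    """

    cycle_index: int
    phase: str
    flash_slice: slice
    local_times_s: np.ndarray = field(repr=False)

    @property
    def duration_s(self) -> float:
        return float(self.local_times_s[-1])

    @property
    def n_flashes(self) -> int:
        return len(self.local_times_s)


def make_schedule(
    intervals_s: Sequence[float],
    n_light: int,
    n_dark: int,
    n_cycles: int = 1,
    actinic_ppfd: float = 1000.0,
    pulse_ppfd: float = 3200.0,
    nominal_light_duration_s: float | None = None,
    nominal_dark_duration_s: float | None = None,
    name: str = "custom",
) -> FlashSchedule:
    """Build a schedule by assigning phase labels cycle-wise.

    The first ``n_light`` flashes of each cycle are labelled light, the next
    ``n_dark`` dark.  ``len(intervals_s)`` must equal
    ``n_cycles * (n_light + n_dark)``.
    """
    intervals_s = [float(x) for x in intervals_s]
    if not intervals_s:
        raise ProtocolError("empty interval list")
    if n_light < 0 or n_dark < 0 or n_cycles < 1:
        raise ProtocolError("n_light, n_dark must be >= 0 and n_cycles >= 1")
    per_cycle = n_light + n_dark
    if len(intervals_s) != n_cycles * per_cycle:
        raise ProtocolError(
            f"{len(intervals_s)} intervals cannot partition into "
            f"{n_cycles} cycle(s) of {n_light} light + {n_dark} dark flashes"
        )
    labels: list[str] = []
    cycles: list[int] = []
    for c in range(n_cycles):
        labels.extend([LIGHT] * n_light + [DARK] * n_dark)
        cycles.extend([c] * per_cycle)
    return FlashSchedule(
        intervals_s=tuple(intervals_s),
        phase_labels=tuple(labels),
        cycle_index=tuple(cycles),
        actinic_ppfd=actinic_ppfd,
        pulse_ppfd=pulse_ppfd,
        nominal_light_duration_s=nominal_light_duration_s,
        nominal_dark_duration_s=nominal_dark_duration_s,
        name=name,
    )


def flash_times(schedule: FlashSchedule) -> tuple[np.ndarray, list[PhaseSegment]]:
    """Absolute flash times plus the light/dark segmentation.

    Returns ``(t_abs, segments)`` where ``t_abs[k]`` is the cumulative sum of
    intervals 1..k+1 and each :class:`PhaseSegment` carries a local clock that
    restarts at its phase transition.
    """
    t_abs = schedule.times()
    intervals = np.asarray(schedule.intervals_s, dtype=float)
    segments: list[PhaseSegment] = []
    start = 0
    n = schedule.n_flashes
    for k in range(1, n + 1):
        boundary = (
            k == n
            or schedule.phase_labels[k] != schedule.phase_labels[start]
            or schedule.cycle_index[k] != schedule.cycle_index[start]
        )
        if boundary:
            local = np.cumsum(intervals[start:k])
            segments.append(
                PhaseSegment(
                    cycle_index=schedule.cycle_index[start],
                    phase=schedule.phase_labels[start],
                    flash_slice=slice(start, k),
                    local_times_s=local,
                )
            )
            start = k
    return t_abs, segments


def local_times(schedule: FlashSchedule) -> np.ndarray:
    """Per-flash local time (seconds since the current segment started)."""
    out = np.empty(schedule.n_flashes, dtype=float)
    for seg in flash_times(schedule)[1]:
        out[seg.flash_slice] = seg.local_times_s
    return out


# ---------------------------------------------------------------------------
# Presets: the two protocols used by the source study.
#
# Crop protocol (tobacco/soybean at 1000, sorghum/teosinte/maize at 2000
# µmol m⁻² s⁻¹): one induction/relaxation cycle, flashes at intervals
# 15, 30, 30, then ten of 60 s in the light and 9, 15, 30, 60, 180, 300 s in
# the dark.  Note the light intervals sum to 675 s although the nominal light
# period is 10 min; the 13-light/6-dark flash partition is the operational
# phase definition.
#
# Arabidopsis fluctuating-light protocol: three cycles of 3 min light
# (intervals 10, 10, 20, 20, 60, 60) followed by 2 min dark (10, 20, 30, 60).
# ---------------------------------------------------------------------------

CROP_INTERVALS = (15, 30, 30, 60, 60, 60, 60, 60, 60, 60, 60, 60, 60, 9, 15, 30, 60, 180, 300)
ARABIDOPSIS_CYCLE_INTERVALS = (10, 10, 20, 20, 60, 60, 10, 20, 30, 60)


def crop_default(actinic_ppfd: float = 1000.0) -> FlashSchedule:
    """Single-cycle crop protocol: 13 light + 6 dark flashes."""
    return make_schedule(
        CROP_INTERVALS,
        n_light=13,
        n_dark=6,
        n_cycles=1,
        actinic_ppfd=actinic_ppfd,
        pulse_ppfd=3200.0,
        nominal_light_duration_s=600.0,
        nominal_dark_duration_s=600.0,
        name="crop_default",
    )


def arabidopsis_fluctuating(n_cycles: int = 3) -> FlashSchedule:
    """Fluctuating-light protocol: n_cycles of 6 light + 4 dark flashes."""
    return make_schedule(
        ARABIDOPSIS_CYCLE_INTERVALS * n_cycles,
        n_light=6,
        n_dark=4,
        n_cycles=n_cycles,
        actinic_ppfd=1000.0,
        pulse_ppfd=2400.0,
        nominal_light_duration_s=180.0,
        nominal_dark_duration_s=120.0,
        name="arabidopsis_fluctuating",
    )


PRESETS = {
    "crop_default": crop_default,
    "arabidopsis_fluctuating": arabidopsis_fluctuating,
}


def get_schedule(name_or_path: str) -> FlashSchedule:
    """Resolve a preset name or a YAML/JSON schedule file."""
    if name_or_path in PRESETS:
        return PRESETS[name_or_path]()
    return load_schedule(name_or_path)


def load_schedule(path: str) -> FlashSchedule:
    """Read a schedule config (YAML or JSON) with keys ``intervals_s``,
    ``n_light``, ``n_dark``, ``n_cycles``, ``actinic_ppfd``, ``pulse_ppfd``."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return make_schedule(
        cfg["intervals_s"],
        n_light=int(cfg["n_light"]),
        n_dark=int(cfg["n_dark"]),
        n_cycles=int(cfg.get("n_cycles", 1)),
        actinic_ppfd=float(cfg.get("actinic_ppfd", 1000.0)),
        pulse_ppfd=float(cfg.get("pulse_ppfd", 3200.0)),
        nominal_light_duration_s=cfg.get("nominal_light_duration_s"),
        nominal_dark_duration_s=cfg.get("nominal_dark_duration_s"),
        name=str(cfg.get("name", "custom")),
    )
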