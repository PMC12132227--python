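"""Stern-Volmer NPQ and Fv/Fm from raw fluorescence traces.

NPQ at each flash is ``Fm/Fm' - 1`` (Stern-Volmer quenching) and the maximum
PSII quantum yield is ``Fv/Fm = (Fm - Fo)/Fm``, both from the dark-adapted
Fo/Fm pair and the per-flash Fm' readings.  Marginally negative NPQ (Fm'
slightly above Fm, a real measurement artifact) is retained rather than
clipped; the QC layer screens it later, because clipping would bias kinetic
fits near zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import FlashSchedule, local_times


class TraceDataError(ValueError):
    """Raised when a fluorescence trace violates its physical invariants."""


@dataclass
class FluorescenceTrace:
    """One sample's raw fluorescence signal.

    ``fo``/``fm`` are the dark-adapted minimum and maximum fluorescence
    (instrument units); ``fm_prime`` holds the per-flash maximum fluorescence
    under illumination, ordered as in ``schedule``.  ``fs`` is the
    steady-state fluorescence, carried through for completeness but consumed
    by no downstream computation.
    """

    sample_id: str
    fo: float
    fm: float
    fm_prime: np.ndarray
    schedule: FlashSchedule
    fs: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fm_prime = np.asarray(self.fm_prime, dtype=float)
        if self.fs is not None:
            self.fs = np.asarray(self.fs, dtype=float)
        if self.fo <= 0 or self.fm <= 0:
            raise TraceDataError(f"{self.sample_id}: Fo and Fm must be positive")
        if self.fm <= self.fo:
            # Physically Fm > Fo; a violation is a measurement defect that the
            # QC layer flags (Fv/Fm <= 0) rather than a hard parse error.
            self.meta.setdefault("warnings", []).append("fm_not_above_fo")
        if self.fm_prime.ndim != 1 or len(self.fm_prime) != self.schedule.n_flashes:
            raise TraceDataError(
                f"{self.sample_id}: {len(self.fm_prime)} Fm' values for a "
                f"{self.schedule.n_flashes}-flash schedule"
            )
        bad = np.flatnonzero(self.fm_prime <= 0)
        if bad.size:
            raise TraceDataError(
                f"{self.sample_id}: non-positive Fm' at flash index {bad[0]}"
            )

    @property
    def n_flashes(self) -> int:
        return len(self.fm_prime)

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-flash table (one row per flash)."""
        sched = self.schedule
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "flash": np.arange(self.n_flashes),
                "cycle": list(sched.cycle_index),
                "phase": list(sched.phase_labels),
                "t_abs_s": sched.times(),
                "t_local_s": local_times(sched),
                "Fs": self.fs if self.fs is not None else np.nan,
                "Fm_prime": self.fm_prime,
            }
        )


@dataclass
class NPQSeries:
    """Derived Stern-Volmer NPQ values with phase/cycle annotation."""

    sample_id: str
    t_abs_s: np.ndarray
    t_local_s: np.ndarray
    cycle: np.ndarray
    phase: np.ndarray
    npq: np.ndarray
    fvfm: float | None = None
    schedule: FlashSchedule | None = None

    def __len__(self) -> int:
        return len(self.npq)

    def segment(self, cycle: int, phase: str) -> tuple[np.ndarray, np.ndarray]:
        """(local times, NPQ) of one light or dark segment."""
        m = (self.cycle == cycle) & (self.phase == phase)
        return self.t_local_s[m], self.npq[m]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_id,
                "flash": np.arange(len(self.npq)),
                "cycle": self.cycle,
                "phase": self.phase,
                "t_abs_s": self.t_abs_s,
                "t_local_s": self.t_local_s,
                "NPQ": self.npq,
            }
        )


def npq_series(trace: FluorescenceTrace) -> NPQSeries:
    """Stern-Volmer NPQ per flash: ``NPQ_k = Fm / Fm'_k - 1``."""
    sched = trace.schedule
    npq = trace.fm / trace.fm_prime - 1.0
    return NPQSeries(
        sample_id=trace.sample_id,
        t_abs_s=sched.times(),
        t_local_s=local_times(sched),
        cycle=np.asarray(sched.cycle_index),
        phase=np.asarray(sched.phase_labels),
        npq=npq,
        fvfm=fvfm(trace)[0],
        schedule=sched,
    )


def fvfm(trace: FluorescenceTrace) -> tuple[float, list[str]]:
    """Maximum PSII quantum yield ``(Fm - Fo)/Fm`` plus QC warnings.

    Values outside the physically plausible range are returned as-is with a
    warning rather than clipped; the QC layer decides whether to flag the
    sample.
    """
    value = (trace.fm - trace.fo) / trace.fm
    warnings: list[str] = []
    if value <= 0:
        warnings.append("fvfm_nonpositive")
    return value, warnings
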