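"""Synthetic NPQ kinetics: ground truth, noisy traces, factorial studies,
paired measurement approaches, and rendered plate stacks.

The generator produces Stern-Volmer NPQ curves from the same model family the
fitter assumes — hyperbolic induction in the light, offset-minus-hyperbola
relaxation in the dark — then inverts ``NPQ = Fm/Fm' - 1`` to emit raw
fluorescence traces.  Noise is multiplicative on the fluorescence channel
(Fm', Fo, Fm), not additive on NPQ, so NPQ noise is heteroscedastic the way
real Stern-Volmer ratios are.

For fluctuating-light protocols an incomplete dark relaxation leaves a
residual that carries into the next cycle as an additive offset; the
``residual_gain`` parameter grows that residual geometrically across cycles
(gain 1 means identical cycles with no carry-over).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .imaging import LayoutError, PlateLayout
from .npq import FluorescenceTrace
from .protocol import DARK, LIGHT, FlashSchedule, PhaseSegment, flash_times

HYPERBOLIC = "hyperbolic"
EXPONENTIAL = "exponential"

#: Kinetic parameters that genotype/treatment multipliers and replicate noise
#: may act on.
KINETIC_PARAMS = ("A_L", "K_L", "tau_L", "A_D", "K_D")


@dataclass(frozen=True)
class GroundTruth:
    """Generative kinetic parameters for one sample.

    Induction amplitude ``A_L`` (dimensionless NPQ units) with half-saturation
    time ``K_L`` (s) for the hyperbolic form, or time constant ``tau_L`` (s)
    for the exponential form (``light_model`` selects which).  Relaxation has
    amplitude ``A_D`` and half-saturation ``K_D``; ``N0`` is NPQ at light-off
    (derived from the induction curve at the end of the light segment when
    ``None``, which keeps the curve continuous at the phase transition).
    """

    A_L: float = 2.5
    K_L: float = 90.0
    tau_L: float = 60.0
    A_D: float = 1.8
    K_D: float = 120.0
    N0: float | None = None
    Fo_true: float = 0.5
    Fm_true: float = 3.0
    residual_gain: float = 1.0
    light_model: str = HYPERBOLIC

    def __post_init__(self) -> None:
        if min(self.A_L, self.K_L, self.tau_L, self.K_D) <= 0:
            raise ValueError("A_L, K_L, tau_L, K_D must all be positive")
        if self.A_D < 0:
            raise ValueError("A_D must be non-negative")
        if self.N0 is not None and self.A_D > self.N0:
            raise ValueError("A_D must not exceed N0")
        if not self.Fm_true > self.Fo_true > 0:
            raise ValueError("need Fm_true > Fo_true > 0")
        if self.residual_gain < 1:
            raise ValueError("residual_gain must be >= 1")
        if self.light_model not in (HYPERBOLIC, EXPONENTIAL):
            raise ValueError(f"unknown light model {self.light_model!r}")

    def induction(self, t):
        """Noise-free induction NPQ at time ``t`` since light-on (no offset)."""
        t = np.asarray(t, dtype=float)
        if self.light_model == HYPERBOLIC:
            return self.A_L * t / (self.K_L + t)
        return self.A_L * (1.0 - np.exp(-t / self.tau_L))

    def n0_at(self, light_duration_s: float) -> float:
        """NPQ at light-off for a light phase of the given length."""
        if self.N0 is not None:
            return self.N0
        return float(self.induction(light_duration_s))

    def relaxation(self, t, n0: float):
        """Noise-free dark-phase NPQ at ``t`` seconds since light-off."""
        t = np.asarray(t, dtype=float)
        return n0 - self.A_D * t / (self.K_D + t)


def _cycle_offset(
    params: GroundTruth,
    cycle: int,
    light_duration_s: float,
    dark_duration_s: float,
) -> float:
    """Additive NPQ offset carried into ``cycle`` from incomplete relaxation.

    The base cycle's dark-end residual rho = N0 - A_D*T_D/(K_D+T_D) grows
    geometrically: the dark-end value of cycle c is residual_gain**c * rho,
    so the offset at the start of cycle c is (residual_gain**c - 1) * rho.
    """
    if cycle == 0 or params.residual_gain == 1.0:
        return 0.0
    n0 = params.n0_at(light_duration_s)
    rho = float(params.relaxation(dark_duration_s, n0))
    rho = max(rho, 0.0)
    return (params.residual_gain**cycle - 1.0) * rho


def npq_truth_at(
    params: GroundTruth,
    segment: PhaseSegment,
    local_t,
    light_duration_s: float | None = None,
    dark_duration_s: float | None = None,
) -> np.ndarray | float:
    """Ground-truth NPQ at ``local_t`` seconds into a phase segment.

    For multi-cycle schedules with carry-over (``residual_gain > 1``) the
    light/dark segment durations of a cycle are needed to place the offset;
    they default from the segment itself where possible and must be given
    otherwise (cycles are assumed uniform, as built by ``make_schedule``).
    """
    local_t = np.asarray(local_t, dtype=float)
    if (local_t < 0).any():
        raise ValueError("local_t must be non-negative")
    if segment.phase == LIGHT and light_duration_s is None:
        light_duration_s = segment.duration_s
    if segment.phase == DARK and dark_duration_s is None:
        dark_duration_s = segment.duration_s

    needs_offset = segment.cycle_index > 0 and params.residual_gain != 1.0
    needs_n0 = segment.phase == DARK and params.N0 is None
    if (needs_offset or needs_n0) and light_duration_s is None:
        raise ValueError("light_duration_s required for this evaluation")
    if needs_offset and dark_duration_s is None:
        raise ValueError("dark_duration_s required for cross-cycle carry-over")

    offset = (
        _cycle_offset(params, segment.cycle_index, light_duration_s, dark_duration_s)
        if needs_offset
        else 0.0
    )
    if segment.phase == LIGHT:
        value = offset + params.induction(local_t)
    else:
        n0 = offset + params.n0_at(light_duration_s)
        value = params.relaxation(local_t, n0)
    return value if value.ndim else float(value)


def npq_truth_series(params: GroundTruth, schedule: FlashSchedule) -> np.ndarray:
    """Ground-truth NPQ at every flash of a schedule."""
    _, segments = flash_times(schedule)
    light_dur = {s.cycle_index: s.duration_s for s in segments if s.phase == LIGHT}
    dark_dur = {s.cycle_index: s.duration_s for s in segments if s.phase == DARK}
    out = np.empty(schedule.n_flashes, dtype=float)
    for seg in segments:
        out[seg.flash_slice] = npq_truth_at(
            params,
            seg,
            seg.local_times_s,
            light_duration_s=light_dur.get(seg.cycle_index),
            dark_duration_s=dark_dur.get(seg.cycle_index),
        )
    return out


_FS_FRACTION = 0.6  # dummy Fs proportionality; nothing downstream consumes Fs


def trace_from_truth(
    params: GroundTruth,
    schedule: FlashSchedule,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    sample_id: str = "synthetic",
    npq_scale: float = 1.0,
) -> FluorescenceTrace:
    """Render a noisy fluorescence trace from kinetic ground truth.

    ``Fm'_k = Fm_true / (1 + NPQ_k) * (1 + eps_k)`` with
    ``eps_k ~ Normal(0, noise_sd)`` truncated so Fm' stays positive; Fo and
    Fm get independent noise of the same sd.  ``npq_scale`` multiplies the
    whole truth curve before inversion (used to impose an approach bias on
    the NPQ scale).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    npq = npq_scale * npq_truth_series(params, schedule)

    def jitter(n):
        eps = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
        return np.maximum(1.0 + eps, 1e-6)

    fm_prime = params.Fm_true / (1.0 + npq) * jitter(len(npq))
    fo = params.Fo_true * float(jitter(1)[0])
    fm = params.Fm_true * float(jitter(1)[0])
    return FluorescenceTrace(
        sample_id=sample_id,
        fo=fo,
        fm=fm,
        fm_prime=fm_prime,
        schedule=schedule,
        fs=_FS_FRACTION * fm_prime,
        meta={"synthetic": True},
    )


@dataclass(frozen=True)
class StudyDesign:
    """Factorial genotype x treatment x replicate structure of a simulation.

    ``genotype_effects`` and ``treatment_effects`` map level name to a dict
    of multiplicative effects on kinetic parameters (keys from
    :data:`KINETIC_PARAMS`; missing keys mean multiplier 1).  Replicates draw
    each kinetic parameter lognormally around the cell value with log-sd
    ``replicate_sd``; ``noise_sd`` is the multiplicative measurement noise on
    the fluorescence channel.
    """

    genotype_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"WT": {}}
    )
    treatment_effects: dict[str, dict[str, float]] = field(
        default_factory=lambda: {"control": {}}
    )
    n_replicates: int = 4
    replicate_sd: float = 0.05
    noise_sd: float = 0.03
    approach_bias: float = 1.0
    base: GroundTruth = field(default_factory=GroundTruth)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.replicate_sd < 0 or self.noise_sd < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.approach_bias <= 0:
            raise ValueError("approach_bias must be positive")
        for effects in (self.genotype_effects, self.treatment_effects):
            for level, mult in effects.items():
                for key, m in mult.items():
                    if key not in KINETIC_PARAMS:
                        raise ValueError(f"unknown kinetic parameter {key!r}")
                    if m <= 0:
                        raise ValueError(f"{level}: multiplier for {key} must be > 0")


def _apply_effects(params: GroundTruth, *effect_dicts: dict[str, float]) -> GroundTruth:
    values = {k: getattr(params, k) for k in KINETIC_PARAMS}
    for eff in effect_dicts:
        for k, m in eff.items():
            values[k] *= m
    return replace(params, **values)


def simulate_study(
    design: StudyDesign, schedule: FlashSchedule
) -> tuple[list[FluorescenceTrace], pd.DataFrame]:
    """One trace per genotype x treatment x replicate, plus the truth table.

    The truth table records every realized kinetic parameter (after genotype,
    treatment and replicate effects) for parameter-recovery testing, keyed by
    ``sample_id`` with ``genotype``, ``treatment``, ``replicate`` columns.
    """
    rng = np.random.default_rng(design.seed)
    traces: list[FluorescenceTrace] = []
    rows = []
    for genotype, g_eff in design.genotype_effects.items():
        for treatment, t_eff in design.treatment_effects.items():
            cell = _apply_effects(design.base, g_eff, t_eff)
            for rep in range(design.n_replicates):
                if design.replicate_sd > 0:
                    mult = {
                        k: float(np.exp(rng.normal(0.0, design.replicate_sd)))
                        for k in KINETIC_PARAMS
                    }
                else:
                    mult = {k: 1.0 for k in KINETIC_PARAMS}
                realized = _apply_effects(cell, mult)
                sid = f"{genotype}:{treatment}:r{rep}"
                traces.append(
                    trace_from_truth(
                        realized, schedule, design.noise_sd, rng, sample_id=sid
                    )
                )
                rows.append(
                    {
                        "sample_id": sid,
                        "genotype": genotype,
                        "treatment": treatment,
                        "replicate": rep,
                        **{k: getattr(realized, k) for k in KINETIC_PARAMS},
                        "Fo_true": realized.Fo_true,
                        "Fm_true": realized.Fm_true,
                    }
                )
    return traces, pd.DataFrame(rows)


def simulate_paired_approaches(
    params: GroundTruth,
    schedule: FlashSchedule,
    disc_noise: float = 0.03,
    plant_noise: float = 0.03,
    approach_bias: float = 1.0,
    seed: int | np.random.Generator | None = None,
    n_replicates: int = 1,
) -> tuple[list[FluorescenceTrace], list[FluorescenceTrace]]:
    """Paired leaf-disc / whole-plant traces sharing one kinetic truth.

    The disc readings see the same underlying kinetics scaled by
    ``approach_bias`` on the NPQ scale (bias 1 = unbiased, matching the
    near one-to-one disc/plant relationship); noise draws are independent
    between approaches and replicates.  Returns
    ``(disc_traces, plant_traces)`` of length ``n_replicates`` each.
    """
    if approach_bias <= 0:
        raise ValueError("approach_bias must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    discs, plants = [], []
    for rep in range(n_replicates):
        discs.append(
            trace_from_truth(
                params,
                schedule,
                disc_noise,
                rng,
                sample_id=f"disc:r{rep}",
                npq_scale=approach_bias,
            )
        )
        plants.append(
            trace_from_truth(
                params, schedule, plant_noise, rng, sample_id=f"plant:r{rep}"
            )
        )
    return discs, plants


def render_plate_stack(
    layout: PlateLayout,
    traces: list[FluorescenceTrace],
    wells: list[int] | None = None,
    pixel_noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Render traces as a multi-frame plate image stack.

    Each trace occupies one well (by default wells 0, 1, ... row-major);
    frame 0 holds every trace's Fo, frame 1 its Fm, frames ``2+k`` the k-th
    flash's Fm'.  Disc pixels are set to the reading (mean disc intensity
    equals the trace value exactly at zero noise); the rest of the frame is
    the layout's background constant, with optional Gaussian pixel noise over
    the whole frame.
    """
    if len(traces) > layout.n_wells:
        raise LayoutError(f"{len(traces)} traces for {layout.n_wells} wells")
    if wells is None:
        wells = list(range(len(traces)))
    if len(wells) != len(traces) or len(set(wells)) != len(wells):
        raise LayoutError("wells must assign one distinct well per trace")
    n_flashes = {t.n_flashes for t in traces}
    if len(n_flashes) > 1:
        raise LayoutError("all traces must share one schedule length")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n_frames = 2 + (n_flashes.pop() if n_flashes else 0)
    stack = np.full((n_frames, *layout.image_shape), float(layout.background))
    for trace, w in zip(traces, wells):
        mask = layout.disc_mask(w)
        values = np.concatenate([[trace.fo, trace.fm], trace.fm_prime])
        for frame, v in enumerate(values):
            stack[frame][mask] = v
    if pixel_noise_sd > 0:
        stack += rng.normal(0.0, pixel_noise_sd, size=stack.shape)
    return stack
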