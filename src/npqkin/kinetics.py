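"""Kinetics fitting and trait extraction for NPQ induction/relaxation curves.

Three model families, fit by bounded nonlinear least squares:

* ``hyperbolic_light``:  NPQ(t)  = A_L * t / (K_L + t)
* ``hyperbolic_dark``:   NPQ(t') = N0 - A_D * t' / (K_D + t'),  0 <= A_D <= N0
* ``exponential_light``: NPQ(t)  = A_E * (1 - exp(-t / tau))

with amplitudes bounded in (0, 20] and time parameters in (0, 1e4] s (NPQ in
this assay is O(0.1-4); the bounds prevent runaway asymptotes on short
series).  Fitting is deterministic multi-start: 5 starts from a log-spaced
grid on the time parameter crossed with the amplitude initialized at the
last observed value; best residual sum of squares wins, ties broken by the
smallest time parameter.

The trait panel per sample: the induction fit's asymptote (steady state) and
initial slope A_L/K_L, the relaxation fit's amplitude and initial slope
A_D/K_D, the exponential induction time constant, the *observed* NPQ at the
last light flash (NPQ_max) and last dark flash (NPQ_end), goodness of fit
(coefficient of determination) per phase, and Fv/Fm.  Slope traits are the
fitted curve's derivative at t = 0, not a finite difference — robust to
flash spacing.  The dark-phase A_D <= N0 constraint is imposed by fitting
the fraction A_D/N0 in [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .npq import NPQSeries
from .protocol import DARK, LIGHT

HYPERBOLIC_LIGHT = "hyperbolic_light"
HYPERBOLIC_DARK = "hyperbolic_dark"
EXPONENTIAL_LIGHT = "exponential_light"

AMP_MAX = 20.0
TIME_MAX = 1e4
_EPS = 1e-9
N_STARTS = 5


class InsufficientDataError(ValueError):
    """Raised when a phase has too few points to fit (< 3)."""


@dataclass
class FitResult:
    """Outcome of one nonlinear least-squares kinetics fit."""

    model: str
    params: dict[str, float]
    gof: float | None
    converged: bool
    n_points: int
    rss: float
    flags: list[str] = field(default_factory=list)

    def __getitem__(self, key: str) -> float:
        return self.params[key]


def r_squared(observed, predicted) -> float | None:
    """Coefficient of determination 1 - SS_res/SS_tot; may be negative.

    Returns None (flagged undefined) when the observations carry no variance.
    """
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape or observed.size < 2:
        raise ValueError("observed and predicted must be equal-length, n >= 2")
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        return None
    ss_res = float(np.sum((observed - predicted) ** 2))
    return 1.0 - ss_res / ss_tot


def _multistart_ls(residual_fn, starts, bounds):
    """Deterministic multi-start bounded least squares.

    Ties on RSS broken by the smallest time parameter (assumed last in the
    parameter vector).
    """
    best = None
    for x0 in starts:
        x0 = np.clip(x0, bounds[0], bounds[1])
        sol = least_squares(residual_fn, x0, bounds=bounds, method="trf")
        rss = float(np.sum(sol.fun**2))
        if (
            best is None
            or rss < best[1] - 1e-12
            or (abs(rss - best[1]) <= 1e-12 and sol.x[-1] < best[0].x[-1])
        ):
            best = (sol, rss)
    return best


def _time_grid(t: np.ndarray) -> np.ndarray:
    lo = max(float(t[t > 0].min()) / 2.0 if (t > 0).any() else 1.0, _EPS * 10)
    hi = min(float(t.max()) * 2.0, TIME_MAX)
    if hi <= lo:
        hi = lo * 10
    return np.geomspace(lo, hi, N_STARTS)


def _check_points(t, y, phase: str):
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("time and NPQ arrays must be 1-D and equal length")
    if len(t) < 3:
        raise InsufficientDataError(
            f"{phase} fit needs >= 3 points, got {len(t)}"
        )
    if not np.all(np.diff(t) > 0):
        raise ValueError("times must be strictly increasing")
    return t, y


def fit_induction_hyperbolic(t_local, npq) -> FitResult:
    """Fit NPQ(t) = A_L * t / (K_L + t) to light-phase points."""
    t, y = _check_points(t_local, npq, "induction")
    flags: list[str] = []
    if np.allclose(y, 0.0):
        return FitResult(
            HYPERBOLIC_LIGHT,
            {"A_L": 0.0, "K_L": float("nan")},
            gof=None,
            converged=False,
            n_points=len(y),
            rss=float(np.sum(y**2)),
            flags=["no_signal"],
        )
    a0 = float(np.clip(y[-1], _EPS * 10, AMP_MAX))
    starts = [np.array([a0, k0]) for k0 in _time_grid(t)]
    bounds = (np.array([_EPS, _EPS]), np.array([AMP_MAX, TIME_MAX]))
    sol, rss = _multistart_ls(lambda p: p[0] * t / (p[1] + t) - y, starts, bounds)
    a, k = sol.x
    gof = r_squared(y, a * t / (k + t))
    converged = bool(sol.success) and np.isfinite(sol.x).all()
    if gof is not None and gof < 0.5:
        flags.append("poor_fit")
    return FitResult(
        HYPERBOLIC_LIGHT,
        {"A_L": float(a), "K_L": float(k)},
        gof=gof,
        converged=converged,
        n_points=len(y),
        rss=rss,
        flags=flags,
    )


def fit_relaxation_hyperbolic(t_local, npq, n_at_light_off: float | None = None) -> FitResult:
    """Fit NPQ(t') = N0 - A_D * t' / (K_D + t') to dark-phase points.

    N0 is initialized at the observed NPQ at light-off (or the maximum dark
    value) and fit as a free parameter; the physical constraint
    0 <= A_D <= N0 is enforced by parameterizing A_D = frac * N0 with
    frac in [0, 1].
    """
    t, y = _check_points(t_local, npq, "relaxation")
    flags: list[str] = []
    n0_init = float(n_at_light_off) if n_at_light_off is not None else float(y.max())
    n0_init = float(np.clip(n0_init, _EPS * 10, AMP_MAX))
    drop = max(float(y[0] - y[-1]), 0.0)
    frac0 = float(np.clip(drop / n0_init if n0_init > 0 else 0.5, 0.05, 1.0))
    starts = [np.array([n0_init, frac0, k0]) for k0 in _time_grid(t)]
    bounds = (np.array([_EPS, 0.0, _EPS]), np.array([AMP_MAX, 1.0, TIME_MAX]))

    def resid(p):
        n0, frac, k = p
        return n0 - frac * n0 * t / (k + t) - y

    sol, rss = _multistart_ls(resid, starts, bounds)
    n0, frac, k = sol.x
    a_d = frac * n0
    converged = bool(sol.success) and np.isfinite(sol.x).all()
    # parsimony tie-break: tiny A_D with huge K_D traces the same flat line
    # as A_D = 0; collapse the degenerate ridge to the boundary solution
    rss_flat = float(np.sum((y - y.mean()) ** 2))
    if rss_flat <= rss + 1e-12:
        n0, a_d, k = float(y.mean()), 0.0, float("nan")
        rss = rss_flat
        pred = np.full_like(y, n0)
    else:
        pred = n0 - a_d * t / (k + t)
    gof = r_squared(y, pred)
    if a_d <= _EPS * 10:
        flags.append("amplitude_at_lower_bound")
        # an increasing dark series pushes A_D to 0: model mismatch
        if y[-1] > y[0]:
            converged = False
    if gof is not None and gof < 0.5:
        flags.append("poor_fit")
    return FitResult(
        HYPERBOLIC_DARK,
        {"N0": float(n0), "A_D": float(a_d), "K_D": float(k)},
        gof=gof,
        converged=converged,
        n_points=len(y),
        rss=rss,
        flags=flags,
    )


def fit_induction_exponential(t_local, npq) -> FitResult:
    """Fit NPQ(t) = A_E * (1 - exp(-t/tau)); tau is the induction time constant."""
    t, y = _check_points(t_local, npq, "induction")
    flags: list[str] = []
    if np.allclose(y, 0.0):
        return FitResult(
            EXPONENTIAL_LIGHT,
            {"A_E": 0.0, "tau": float("nan")},
            gof=None,
            converged=False,
            n_points=len(y),
            rss=float(np.sum(y**2)),
            flags=["no_signal"],
        )
    a0 = float(np.clip(y[-1], _EPS * 10, AMP_MAX))
    starts = [np.array([a0, k0]) for k0 in _time_grid(t)]
    bounds = (np.array([_EPS, _EPS]), np.array([AMP_MAX, TIME_MAX]))
    sol, rss = _multistart_ls(
        lambda p: p[0] * (1.0 - np.exp(-t / p[1])) - y, starts, bounds
    )
    a, tau = sol.x
    gof = r_squared(y, a * (1.0 - np.exp(-t / tau)))
    converged = bool(sol.success) and np.isfinite(sol.x).all()
    if gof is not None and gof < 0.5:
        flags.append("poor_fit")
    return FitResult(
        EXPONENTIAL_LIGHT,
        {"A_E": float(a), "tau": float(tau)},
        gof=gof,
        converged=converged,
        n_points=len(y),
        rss=rss,
        flags=flags,
    )


#: Columns of the wide trait table, one row per sample.
TRAIT_COLUMNS = [
    "NPQslope_lightH",
    "NPQasymptote_lightH",
    "NPQamplitude_darkH",
    "NPQslope_darkH",
    "NPQ_max",
    "NPQ_end",
    "NPQtime_constant_light",
    "NPQgof_light",
    "NPQgof_dark",
    "FvFm",
]


@dataclass
class KineticTraits:
    """The per-sample trait panel.

    NPQ_max / NPQ_end are *observed* values at the last light / last dark
    flash; everything else derives from the fits.  Missing fits leave
    explicit None fields.  ``cycles`` holds per-cycle sub-records for
    fluctuating-light protocols.
    """

    sample_id: str
    NPQslope_lightH: float | None = None  # s^-1, A_L/K_L
    NPQasymptote_lightH: float | None = None
    NPQamplitude_darkH: float | None = None
    NPQslope_darkH: float | None = None  # s^-1, A_D/K_D
    NPQ_max: float | None = None
    NPQ_end: float | None = None
    NPQtime_constant_light: float | None = None  # s
    NPQgof_light: float | None = None
    NPQgof_dark: float | None = None
    FvFm: float | None = None
    fits: dict[str, FitResult] = field(default_factory=dict)
    cycles: list["KineticTraits"] = field(default_factory=list)
    cycle_index: int | None = None

    def to_dict(self) -> dict:
        d = {"sample_id": self.sample_id}
        if self.cycle_index is not None:
            d["cycle"] = self.cycle_index
        d.update({c: getattr(self, c) for c in TRAIT_COLUMNS})
        return d


def extract_traits(
    series: NPQSeries,
    light_fit: FitResult | None = None,
    dark_fit: FitResult | None = None,
    exp_fit: FitResult | None = None,
    cycle: int = 0,
) -> KineticTraits:
    """Derive the trait panel for one cycle of an NPQ series.

    Fits not supplied are computed from the series' light/dark segments of
    the requested cycle.  Observed traits (NPQ_max, NPQ_end) come straight
    from the series and survive missing fits.
    """
    t_l, y_l = series.segment(cycle, LIGHT)
    t_d, y_d = series.segment(cycle, DARK)
    traits = KineticTraits(sample_id=series.sample_id, FvFm=series.fvfm)
    if len(y_l):
        traits.NPQ_max = float(y_l[-1])
    if len(y_d):
        traits.NPQ_end = float(y_d[-1])

    if light_fit is None and len(y_l) >= 3:
        try:
            light_fit = fit_induction_hyperbolic(t_l, y_l)
        except InsufficientDataError:
            light_fit = None
    if exp_fit is None and len(y_l) >= 3:
        try:
            exp_fit = fit_induction_exponential(t_l, y_l)
        except InsufficientDataError:
            exp_fit = None
    if dark_fit is None and len(y_d) >= 3:
        try:
            dark_fit = fit_relaxation_hyperbolic(t_d, y_d, n_at_light_off=traits.NPQ_max)
        except InsufficientDataError:
            dark_fit = None

    if light_fit is not None:
        traits.fits["light"] = light_fit
        traits.NPQasymptote_lightH = light_fit.params.get("A_L")
        k = light_fit.params.get("K_L")
        if traits.NPQasymptote_lightH is not None and k and math.isfinite(k):
            traits.NPQslope_lightH = traits.NPQasymptote_lightH / k
        traits.NPQgof_light = light_fit.gof
    if dark_fit is not None:
        traits.fits["dark"] = dark_fit
        traits.NPQamplitude_darkH = dark_fit.params.get("A_D")
        k = dark_fit.params.get("K_D")
        if traits.NPQamplitude_darkH is not None and k and math.isfinite(k):
            traits.NPQslope_darkH = traits.NPQamplitude_darkH / k
        traits.NPQgof_dark = dark_fit.gof
    if exp_fit is not None:
        traits.fits["exp"] = exp_fit
        tau = exp_fit.params.get("tau")
        traits.NPQtime_constant_light = tau if tau is None or math.isfinite(tau) else None
    return traits


def fit_cycles(series: NPQSeries) -> list[KineticTraits]:
    """Per-cycle trait extraction for fluctuating-light protocols.

    Induction fits run per light segment on the segment's local clock; a
    cycle whose segment is too short gets null fitted traits but keeps the
    observed NPQ_max/NPQ_end.
    """
    cycles = sorted(set(series.cycle.tolist()))
    if len(cycles) < 2:
        raise ValueError("fit_cycles needs a schedule with >= 2 cycles")
    out = []
    for c in cycles:
        tr = extract_traits(series, cycle=c)
        tr.cycle_index = c
        out.append(tr)
    return out


def traits_for_sample(series: NPQSeries) -> KineticTraits:
    """Full trait panel for one sample; per-cycle sub-records when the
    schedule has multiple cycles (whole-series traits from cycle 0)."""
    traits = extract_traits(series, cycle=0)
    n_cycles = len(set(series.cycle.tolist()))
    if n_cycles > 1:
        traits.cycles = fit_cycles(series)
    return traits


def traits_table(all_traits: list[KineticTraits]) -> pd.DataFrame:
    """Wide table: one row per sample (or per sample-cycle sub-record)."""
    rows = []
    for tr in all_traits:
        rows.append(tr.to_dict())
        for sub in tr.cycles:
            rows.append(sub.to_dict())
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Quality-integrity screening
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QCThresholds:
    """Defaults for the data-integrity screen (all config-exposed)."""

    min_gof: float = 0.90
    fvfm_max: float = 0.90
    npq_floor: float = -0.05
    mad_multiplier: float = 3.0
    outlier_trait: str = "NPQasymptote_lightH"


@dataclass
class QCReport:
    """Pass/flag verdicts with one row per triggered rule."""

    records: pd.DataFrame

    def passed(self, sample_id: str) -> bool:
        r = self.records[self.records["sample_id"] == sample_id]
        return bool(r.empty or (~r["flagged"]).all())

    @property
    def flagged_samples(self) -> list[str]:
        f = self.records[self.records["flagged"]]
        return sorted(f["sample_id"].unique().tolist())


def qc_assess(
    all_traits: list[KineticTraits],
    series_by_sample: dict[str, NPQSeries] | None = None,
    groups: dict[str, tuple] | None = None,
    thresholds: QCThresholds = QCThresholds(),
) -> QCReport:
    """Screen fitted samples for integrity problems.

    Rules: goodness of fit below ``min_gof`` in either phase; non-converged
    fits; Fv/Fm outside (0, ``fvfm_max``]; any NPQ below ``npq_floor``
    (needs the series); trait beyond ``mad_multiplier`` * MAD from the
    cohort median within a genotype x treatment cell (needs ``groups``
    mapping sample_id -> cell key).  Every triggered rule is listed.
    """
    rows = []

    def add(sid, rule, value, flagged=True):
        rows.append({"sample_id": sid, "rule": rule, "value": value, "flagged": flagged})

    for tr in all_traits:
        sid = tr.sample_id
        for phase, gof in (("light", tr.NPQgof_light), ("dark", tr.NPQgof_dark)):
            if gof is not None and gof < thresholds.min_gof:
                add(sid, f"gof_{phase}_below_threshold", gof)
        for name, fit in tr.fits.items():
            if not fit.converged:
                add(sid, f"fit_{name}_not_converged", fit.rss)
        if tr.FvFm is not None and not (0.0 < tr.FvFm <= thresholds.fvfm_max):
            add(sid, "fvfm_out_of_range", tr.FvFm)
        if series_by_sample is not None and sid in series_by_sample:
            m = float(series_by_sample[sid].npq.min())
            if m < thresholds.npq_floor:
                add(sid, "negative_npq", m)

    if groups is not None:
        trait_name = thresholds.outlier_trait
        by_cell: dict[tuple, list[tuple[str, float]]] = {}
        for tr in all_traits:
            v = getattr(tr, trait_name, None)
            if v is not None and tr.sample_id in groups:
                by_cell.setdefault(groups[tr.sample_id], []).append((tr.sample_id, v))
        for cell, pairs in by_cell.items():
            vals = np.array([v for _, v in pairs])
            med = np.median(vals)
            mad = np.median(np.abs(vals - med))
            if mad == 0:
                continue
            for sid, v in pairs:
                if abs(v - med) > thresholds.mad_multiplier * mad:
                    add(sid, f"{trait_name}_cohort_outlier", v)

    cols = ["sample_id", "rule", "value", "flagged"]
    return QCReport(records=pd.DataFrame(rows, columns=cols))
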