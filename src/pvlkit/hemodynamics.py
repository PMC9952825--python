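"""Bulk-flow hydrodynamic performance metrics for prosthetic aortic valves.

Given a transvalvular pressure-gradient waveform (ventricular minus aortic,
mmHg) and the corresponding volumetric flow waveform (mL/s, positive =
ventricle → aorta), this module segments the cardiac cycle into systole and
diastole, and computes the standard pulse-duplicator performance metrics:

* stroke volume (SV) and cardiac output (CO);
* effective orifice area ``EOA = Q_RMS / (51.6 * sqrt(dP_avg / rho))`` with
  Q_RMS in mL/s, dP_avg in mmHg and rho in g/cm³, giving cm²;
* the effective regurgitant orifice area (EROA), the same formula applied
  to the diastolic reverse flow;
* the regurgitant decomposition of the diastolic reverse volume into a
  closing transient and a steady paravalvular leak, and the regurgitant
  fraction RF = 100 * (|closing| + |leak|) / SV.

Waveforms are columnar time series; all integrals are composite trapezoids
on the native sampling grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class WaveformError(ValueError):
    """Raised for waveforms that violate the sampling/shape contract."""


@dataclass
class PressureWaveform:
    """Ventricular-minus-aortic pressure gradient, mmHg, over ≥1 cycle."""

    t: np.ndarray  # s, strictly increasing
    dp: np.ndarray  # mmHg
    period: float  # s (= 60 / BPM)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.dp = np.asarray(self.dp, dtype=float)
        _check_series(self.t, self.dp, self.period)

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        """Linear interpolation with periodic extension."""
        return _interp_periodic(t, self.t, self.dp, self.period)


@dataclass
class FlowWaveform:
    """Volumetric flow, mL/s, positive = forward (ventricle → aorta)."""

    t: np.ndarray
    q: np.ndarray  # mL/s
    period: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        _check_series(self.t, self.q, self.period)

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        return _interp_periodic(t, self.t, self.q, self.period)


@dataclass
class PhaseSegmentation:
    """Disjoint [t_start, t_end) intervals covering one analyzed cycle."""

    systole: list[tuple[float, float]]
    diastole: list[tuple[float, float]]

    def phase_at(self, t: float) -> str:
        for a, b in self.systole:
            if a <= t < b:
                return "systole"
        return "diastole"


@dataclass
class FluidProperties:
    """Newtonian blood-analog fluid (glycerin solution at 37 °C)."""

    mu: float = 3.5e-3  # Pa·s
    rho: float = 1120.0  # kg/m³

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.rho <= 0:
            raise ValueError("mu and rho must be positive")

    @property
    def rho_g_cm3(self) -> float:
        return self.rho / 1000.0


@dataclass
class HemodynamicMetrics:
    co: float  # L/min (net forward volume per beat × beats/min / 1000)
    sv: float  # mL/beat
    eoa: float  # cm²
    eroa: float  # cm²
    closing_volume: float  # mL/beat, signed ≤ 0
    leak_volume: float  # mL/beat, signed ≤ 0
    rf: float  # % of SV
    dp_avg_sys: float = np.nan  # mmHg
    dp_avg_dia: float = np.nan  # mmHg
    co_mean_forward: float = np.nan  # L/min, forward-volume convention

    def as_dict(self) -> dict[str, float]:
        return {
            "co_l_min": self.co,
            "sv_ml": self.sv,
            "eoa_cm2": self.eoa,
            "eroa_cm2": self.eroa,
            "closing_volume_ml": self.closing_volume,
            "leak_volume_ml": self.leak_volume,
            "rf_pct_sv": self.rf,
            "dp_avg_sys_mmhg": self.dp_avg_sys,
            "dp_avg_dia_mmhg": self.dp_avg_dia,
            "co_mean_forward_l_min": self.co_mean_forward,
        }


# ---------------------------------------------------------------------------
# helpers

def _check_series(t: np.ndarray, y: np.ndarray, period: float) -> None:
    if t.ndim != 1 or y.shape != t.shape:
        raise WaveformError("t and values must be 1-D arrays of equal length")
    if len(t) < 2:
        raise WaveformError("waveform needs at least two samples")
    if not np.all(np.diff(t) > 0):
        raise WaveformError("time must be strictly increasing")
    if period <= 0:
        raise WaveformError("period must be positive")
    if t[-1] - t[0] < period * (1 - 1e-9):
        raise WaveformError("waveform must cover at least one full period")


def _interp_periodic(tq, t, y, period):
    tq = np.asarray(tq, dtype=float)
    # query points inside the covered span are interpolated directly (so the
    # exact endpoint is not wrapped back to the start); only points outside
    # use the periodic extension
    tm = np.where((tq >= t[0]) & (tq <= t[-1]),
                  tq, t[0] + np.mod(tq - t[0], period))
    return np.interp(tm, t, y)


def _interp_linear(tq, t, y):
    return np.interp(np.asarray(tq, dtype=float), t, y)


def _resample_union(t: np.ndarray, extra: Sequence[float],
                    lo: float, hi: float) -> np.ndarray:
    """Sample points of t within [lo, hi] plus the interval endpoints."""
    pts = t[(t > lo) & (t < hi)]
    grid = np.concatenate(([lo], pts, [hi], np.asarray(extra, dtype=float)))
    return np.unique(grid)


# ---------------------------------------------------------------------------
# phase segmentation

def segment_phases(dp: PressureWaveform, *, min_phase_s: float = 0.020,
                   t_start: float | None = None) -> PhaseSegmentation:
    """Segment one cycle into systole (dp > 0) and diastole (dp ≤ 0).

    Zero crossings are located by linear interpolation between samples.
    Intervals shorter than ``min_phase_s`` are merged into their
    neighbours to suppress chatter near the crossings.
    """
    t0 = dp.t[0] if t_start is None else t_start
    t1 = t0 + dp.period
    tt = _resample_union(dp.t, [], t0, t1)
    vv = dp(tt)

    pos = vv > 0
    if pos.all() or not pos.any():
        raise WaveformError("monophasic gradient: cannot segment")

    # refine crossing locations by linear interpolation
    bounds = [t0]
    for i in range(len(tt) - 1):
        if pos[i] != pos[i + 1]:
            a, b = tt[i], tt[i + 1]
            ya, yb = vv[i], vv[i + 1]
            tc = a if yb == ya else a + (0.0 - ya) * (b - a) / (yb - ya)
            bounds.append(float(np.clip(tc, a, b)))
    bounds.append(t1)
    bounds = sorted(set(bounds))

    intervals: list[tuple[float, float, bool]] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        mid = 0.5 * (a + b)
        intervals.append((a, b, bool(dp(mid) > 0)))

    # merge chatter: absorb sub-threshold intervals into the previous phase
    merged: list[list] = []
    for a, b, p in intervals:
        if merged and (p == merged[-1][2] or (b - a) < min_phase_s):
            merged[-1][1] = b
        else:
            merged.append([a, b, p])
    # a leading runt joins its successor
    if len(merged) > 1 and (merged[0][1] - merged[0][0]) < min_phase_s:
        merged[1][0] = merged[0][0]
        merged.pop(0)

    systole = [(a, b) for a, b, p in merged if p]
    diastole = [(a, b) for a, b, p in merged if not p]
    if not systole:
        raise WaveformError("monophasic gradient: cannot segment")
    return PhaseSegmentation(systole=systole, diastole=diastole)


# ---------------------------------------------------------------------------
# Eq.-1 style metrics

def q_rms(q: FlowWaveform, interval: tuple[float, float]) -> float:
    """Root-mean-square flow over an interval (trapezoidal time average)."""
    lo, hi = interval
    if hi <= lo:
        raise WaveformError("empty interval")
    tt = _resample_union(q.t, [], lo, hi) if hi <= q.t[-1] and lo >= q.t[0] \
        else np.linspace(lo, hi, 2049)
    vv = q(tt)
    mean_sq = np.trapezoid(vv ** 2, tt) / (hi - lo)
    return float(np.sqrt(mean_sq))


def mean_gradient(dp: PressureWaveform, interval: tuple[float, float]) -> float:
    """Time-average pressure gradient (mmHg) over an interval."""
    lo, hi = interval
    if hi <= lo:
        raise WaveformError("empty interval")
    tt = _resample_union(dp.t, [], lo, hi) if hi <= dp.t[-1] and lo >= dp.t[0] \
        else np.linspace(lo, hi, 2049)
    return float(np.trapezoid(dp(tt), tt) / (hi - lo))


def effective_orifice_area(q_rms_ml_s: float, dp_avg_mmhg: float,
                           rho_g_cm3: float) -> float:
    """EOA (cm²) from RMS flow (mL/s), mean gradient (mmHg), density (g/cm³).

    The identical formula serves the effective regurgitant orifice area
    (EROA) when fed the diastolic RMS reverse flow and the magnitude of the
    mean diastolic gradient.
    """
    if dp_avg_mmhg <= 0:
        raise ValueError("non-positive mean gradient")
    if rho_g_cm3 <= 0:
        raise ValueError("non-positive density")
    return float(q_rms_ml_s / (51.6 * np.sqrt(dp_avg_mmhg / rho_g_cm3)))


# ---------------------------------------------------------------------------
# regurgitant decomposition

def _integrate_negative(q: FlowWaveform, lo: float, hi: float) -> float:
    tt = _resample_union(q.t, [], lo, hi)
    # insert zero-crossing refinement for accurate clipped integration
    vv = q(tt)
    sgn = vv < 0
    extra = []
    for i in range(len(tt) - 1):
        if sgn[i] != sgn[i + 1] and vv[i + 1] != vv[i]:
            extra.append(tt[i] - vv[i] * (tt[i + 1] - tt[i]) / (vv[i + 1] - vv[i]))
    if extra:
        tt = np.unique(np.concatenate([tt, extra]))
        vv = q(tt)
    return float(np.trapezoid(np.minimum(vv, 0.0), tt))


def regurgitant_volumes(q: FlowWaveform, seg: PhaseSegmentation, *,
                        plateau_frac: float = 0.25) -> tuple[float, float]:
    """Split diastolic reverse flow into (closing_volume, leak_volume), mL.

    The closing transient is the initial burst of reverse flow at valve
    closure; the leak is the quasi-steady paravalvular portion that
    persists through diastole.  The split point is the first time after
    diastole onset at which the reverse-flow magnitude falls to within
    ``plateau_frac`` of the leak-plateau level, estimated as the median
    reverse-flow magnitude over the final two-thirds of diastole.  Both
    volumes are signed (≤ 0) and sum to the total reverse diastolic volume.
    """
    if not seg.diastole:
        return 0.0, 0.0
    closing = 0.0
    leak = 0.0
    for lo, hi in seg.diastole:
        total = _integrate_negative(q, lo, hi)
        if total == 0.0:
            continue
        # plateau level from the final two-thirds of this diastolic interval
        p_lo = lo + (hi - lo) / 3.0
        tt = _resample_union(q.t, [], p_lo, hi)
        vv = q(tt)
        rev = -np.minimum(vv, 0.0)
        plateau = float(np.median(rev[rev > 0])) if np.any(rev > 0) else 0.0

        # walk forward from diastole onset: the closing transient must first
        # rise above the plateau band, then the split lands where the
        # reverse-flow magnitude first falls back to within it
        tt_all = _resample_union(q.t, [], lo, hi)
        vv_all = -np.minimum(q(tt_all), 0.0)
        thresh = plateau * (1.0 + plateau_frac)
        above = np.nonzero(vv_all > thresh)[0]
        if len(above) == 0:
            t_split = lo  # plateau-only reverse flow: no closing transient
        else:
            back = np.nonzero(vv_all[above[0]:] <= thresh)[0]
            t_split = float(tt_all[above[0] + back[0]]) if len(back) else hi
        closing += _integrate_negative(q, lo, t_split)
        leak += _integrate_negative(q, t_split, hi)
    return closing, leak


# ---------------------------------------------------------------------------
# case summary

def _integrate_positive(q: FlowWaveform, lo: float, hi: float) -> float:
    return -_integrate_negative(
        FlowWaveform(q.t, -q.q, q.period), lo, hi)


def regurgitant_fraction(closing_ml: float, leak_ml: float, sv_ml: float) -> float:
    """RF (% of SV) from signed closing and leak volumes."""
    if sv_ml <= 0:
        raise ValueError("stroke volume must be positive")
    return 100.0 * (abs(closing_ml) + abs(leak_ml)) / sv_ml


def summarize_case(q: FlowWaveform, dp: PressureWaveform,
                   fluid: FluidProperties | None = None, *,
                   plateau_frac: float = 0.25,
                   min_phase_s: float = 0.020) -> HemodynamicMetrics:
    """Full Table-of-metrics summary for one aligned (flow, pressure) pair.

    CO uses the net-volume convention by default (net forward volume per
    beat × beats/min); the mean-forward-volume convention is reported
    alongside since measurement practice varies between rigs.
    """
    fluid = fluid or FluidProperties()
    seg = segment_phases(dp, min_phase_s=min_phase_s)
    bpm = 60.0 / dp.period

    sv = sum(_integrate_positive(q, lo, hi) for lo, hi in seg.systole)
    if sv <= 0:
        raise WaveformError("no forward systolic volume")

    t0, t1 = dp.t[0], dp.t[0] + dp.period
    tt = _resample_union(q.t, [], t0, t1)
    net = float(np.trapezoid(q(tt), tt))
    co_net = net * bpm / 1000.0
    fwd_total = sum(_integrate_positive(q, lo, hi)
                    for lo, hi in seg.systole + seg.diastole)
    co_fwd = fwd_total * bpm / 1000.0

    dp_sys = mean_gradient(dp, seg.systole[0]) if len(seg.systole) == 1 else \
        float(np.average([mean_gradient(dp, iv) for iv in seg.systole],
                         weights=[iv[1] - iv[0] for iv in seg.systole]))
    dp_dia = float(np.average([mean_gradient(dp, iv) for iv in seg.diastole],
                              weights=[iv[1] - iv[0] for iv in seg.diastole]))

    qr_sys = float(np.sqrt(np.average(
        [q_rms(q, iv) ** 2 for iv in seg.systole],
        weights=[iv[1] - iv[0] for iv in seg.systole])))
    qr_dia = float(np.sqrt(np.average(
        [q_rms(q, iv) ** 2 for iv in seg.diastole],
        weights=[iv[1] - iv[0] for iv in seg.diastole])))

    eoa = effective_orifice_area(qr_sys, dp_sys, fluid.rho_g_cm3) \
        if dp_sys > 0 else 0.0
    eroa = effective_orifice_area(qr_dia, -dp_dia, fluid.rho_g_cm3) \
        if dp_dia < 0 else 0.0

    closing, leak = regurgitant_volumes(q, seg, plateau_frac=plateau_frac)
    rf = regurgitant_fraction(closing, leak, sv)

    return HemodynamicMetrics(
        co=co_net, sv=sv, eoa=eoa, eroa=eroa,
        closing_volume=closing, leak_volume=leak, rf=rf,
        dp_avg_sys=dp_sys, dp_avg_dia=dp_dia, co_mean_forward=co_fwd)
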