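"""Hydrodynamic summary metrics.

Aqueductal stroke volume is read off the flow-rate diagram's areas
above (A+) and below (A-) the time axis over one cycle.  Two
conventions exist in the literature and both are provided:

* ``difference``  -> A+ - A-  (the net volume per cycle; equals the
  cycle-mean flow times the period, i.e. the production volume);
* ``oscillatory`` -> (A+ + A-)/2  (the volume shuttled back and forth,
  the quantity MRI studies usually call aqueductal stroke volume).

``oscillatory`` is the default for group comparisons: the net volume
is pinned to the constant production rate, so only the oscillatory
convention can differ by a large factor between groups.

Quadrature is trapezoidal with the positive/negative parts split at
linear zero crossings, which is exact for piecewise-linear samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .constitutive import FluidProperties
from .fixtures_io import ML_PER_M3, Waveform
from .solver import SimulationResult, peak_aqueduct_velocity

#: Conventional laminar-turbulent threshold for the Reynolds number.
LAMINAR_RE = 2000.0


@dataclass
class HydroMetrics:
    stroke_volume_difference_ml: float
    stroke_volume_oscillatory_ml: float
    reynolds_max: float
    peak_pressure_Pa: float
    peak_pressure_phase: float
    min_pressure_Pa: float
    min_pressure_phase: float
    peak_velocity_m_s: float
    peak_velocity_phase: float
    laminar: bool


def _signed_areas(times: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """(A+, A-): trapezoidal areas above/below zero, crossing-exact."""
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    pos = neg = 0.0
    for i in range(t.size - 1):
        t0, t1, v0, v1 = t[i], t[i + 1], v[i], v[i + 1]
        if v0 * v1 < 0:  # linear zero crossing splits the panel
            tc = t0 + (t1 - t0) * v0 / (v0 - v1)
            a0 = 0.5 * v0 * (tc - t0)
            a1 = 0.5 * v1 * (t1 - tc)
        else:
            a0 = 0.5 * (v0 + v1) * (t1 - t0)
            a1 = 0.0
        for a in (a0, a1):
            if a >= 0:
                pos += a
            else:
                neg -= a
    return pos, neg


def stroke_volume(flow: Waveform, convention: str = "oscillatory") -> float:
    """Stroke volume over one cycle of an aqueductal flow waveform, ml."""
    if flow.values.size < 4:
        raise ValueError("need at least 4 samples of the flow cycle")
    t, v = flow.closed_cycle()
    pos, neg = _signed_areas(t, v)
    if convention == "difference":
        vol = pos - neg
    elif convention == "oscillatory":
        vol = 0.5 * (pos + neg)
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return vol * ML_PER_M3


def reynolds(u_max: float, D: float, fluid: FluidProperties) -> float:
    """Re = rho u D / mu with D the aqueduct diameter."""
    if D <= 0:
        raise ValueError("diameter must be positive")
    if u_max < 0:
        raise ValueError("velocity magnitude must be non-negative")
    return fluid.density * u_max * D / fluid.dynamic_viscosity


def peak_phase(series: Waveform, which: str = "max") -> tuple[float, float]:
    """(extreme value, phase fraction in [0, 1)); ties -> earliest phase."""
    if series.values.size == 0:
        raise ValueError("empty series")
    if which == "max":
        idx = int(np.argmax(series.values))
    elif which == "min":
        idx = int(np.argmin(series.values))
    else:
        raise ValueError(f"which must be 'max' or 'min', got {which!r}")
    return float(series.values[idx]), float(series.times[idx] / series.period) % 1.0


def _last_cycle_waveform(result: SimulationResult, series: np.ndarray) -> Waveform:
    t, v = result.last_cycle(series)
    return Waveform(period=result.period, times=t, values=v, units="SI")


def compare_runs(a: SimulationResult, b: SimulationResult, node: str = "sas") -> tuple[float, float]:
    """Compare last-cycle pressures at a node between two runs.

    Returns (max relative peak difference in %, peak-phase difference
    as % of the cycle).  Grids must match exactly.
    """
    if a.dt != b.dt or a.period != b.period or a.times.size != b.times.size:
        raise ValueError("simulation results are on different time grids")
    wa = _last_cycle_waveform(a, a.pressures[node])
    wb = _last_cycle_waveform(b, b.pressures[node])
    peak_a, phase_a = peak_phase(wa, "max")
    peak_b, phase_b = peak_phase(wb, "max")
    rel = 100.0 * abs(peak_b - peak_a) / max(abs(peak_a), 1e-30)
    dphase = abs(phase_b - phase_a)
    dphase = min(dphase, 1.0 - dphase)  # cyclic distance
    return rel, 100.0 * dphase


def summarize(result: SimulationResult, a: float, fluid: FluidProperties,
              node: str = "sas", velocity_method: str = "poiseuille") -> HydroMetrics:
    """All hydrodynamic metrics of one simulation's last cycle."""
    flow = _last_cycle_waveform(result, result.flows["aqueduct"])
    pressure = _last_cycle_waveform(result, result.pressures[node])
    sv_diff = stroke_volume(flow, "difference")
    sv_osc = stroke_volume(flow, "oscillatory")
    u_max = peak_aqueduct_velocity(result, a, fluid, method=velocity_method)
    re_max = reynolds(u_max, 2.0 * a, fluid)
    p_max, ph_max = peak_phase(pressure, "max")
    p_min, ph_min = peak_phase(pressure, "min")
    u_series = Waveform(period=flow.period, times=flow.times,
                        values=2.0 * flow.values / (math.pi * a**2), units="m/s")
    _, ph_u = peak_phase(
        Waveform(period=flow.period, times=flow.times, values=np.abs(u_series.values), units="m/s"),
        "max",
    )
    return HydroMetrics(
        stroke_volume_difference_ml=sv_diff,
        stroke_volume_oscillatory_ml=sv_osc,
        reynolds_max=re_max,
        peak_pressure_Pa=p_max,
        peak_pressure_phase=ph_max,
        min_pressure_Pa=p_min,
        min_pressure_phase=ph_min,
        peak_velocity_m_s=u_max,
        peak_velocity_phase=ph_u,
        laminar=bool(re_max < LAMINAR_RE),
    )
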