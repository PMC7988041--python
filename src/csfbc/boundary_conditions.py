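"""The three inlet/outlet boundary-condition schemes.

Scheme "A": sinusoidal gauge pressure 80 + 160 sin(2 pi t) Pa at the
inlet, constant outlet pressure (500 Pa healthy, 2700 Pa patient).
Scheme "B": pulsatile inlet flow with cycle mean 0.35 ml/min, same
constant-pressure outlet as "A".  Scheme "C": the same pulsatile inlet
flow, with pulsatile outlet flows of means 0.18 ml/min (sagittal
sinus) and 0.17 ml/min (spinal canal); the outlets reuse the inlet's
waveform scaled by their mean-flow fractions, so mean mass balance
holds exactly by construction.

The cardiac period defaults to 1 s; pulsatile shapes are normalized to
zero cycle mean and unit peak magnitude before scaling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .fixtures_io import GROUPS, ML_MIN_TO_M3_S, SCHEMES, Waveform

#: Constant CSF production rate, m3/s (0.35 ml/min).
MEAN_PRODUCTION = 0.35 * ML_MIN_TO_M3_S
#: Mean outlet flows (sagittal sinus, spinal canal), m3/s.
OUTLET_MEANS = (0.18 * ML_MIN_TO_M3_S, 0.17 * ML_MIN_TO_M3_S)
OUTLET_LOCATIONS = ("sagittal_sinus", "spinal_canal")

_OUTLET_PRESSURE = {"healthy": 500.0, "patient": 2700.0}


def bc_a_inlet_pressure(t, period: float = 1.0):
    """Scheme "A" inlet pressure, Pa (gauge, rides on the node baseline)."""
    t = np.asarray(t, dtype=float)
    out = 80.0 + 160.0 * np.sin(2.0 * math.pi * t / period)
    return float(out) if out.shape == () else out


def outlet_pressure(group: str) -> float:
    """Baseline sagittal-sinus pressure, Pa: 500 healthy, 2700 patient."""
    try:
        return _OUTLET_PRESSURE[group]
    except KeyError:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}") from None


def harmonic_shape(
    harmonic_amplitudes=(1.0, 0.5, 0.25),
    phase_of_peak: float = 0.175,
    period: float = 1.0,
    n_samples: int = 200,
) -> Waveform:
    """Deterministic normalized pulsatile shape from a cosine series.

    s(t) = sum_n c_n cos(2 pi n (t - t_peak)/T): every harmonic peaks at
    ``phase_of_peak`` (default 17.5% of the cycle, where the aqueductal
    velocity peak is observed in vivo), so the sum's global maximum
    sits there; the series has no DC term, so the cycle mean is zero.
    The result is scaled to unit peak magnitude.
    """
    if len(harmonic_amplitudes) < 1:
        raise ValueError("need at least one harmonic")
    if not 0.0 <= phase_of_peak < 1.0:
        raise ValueError("phase_of_peak must lie in [0, 1)")
    t = np.arange(n_samples) * (period / n_samples)
    phase = (t / period - phase_of_peak) * 2.0 * math.pi
    values = sum(c * np.cos((n + 1) * phase) for n, c in enumerate(harmonic_amplitudes))
    return normalize_shape(Waveform(period=period, times=t, values=values, units="dimensionless"))


def normalize_shape(shape: Waveform) -> Waveform:
    """Return the shape with zero cycle mean and unit peak magnitude."""
    if shape.values.size == 0:
        raise ValueError("empty shape waveform")
    values = shape.values - shape.cycle_mean()
    # re-subtract after trapezoid mean: the closed-cycle mean of the shifted
    # samples is already zero to roundoff
    peak = np.max(np.abs(values))
    if peak == 0:
        raise ValueError("shape waveform is identically zero after mean removal")
    return Waveform(
        period=shape.period,
        times=shape.times.copy(),
        values=values / peak,
        units="dimensionless",
    )


def superpose_flow(normalized_shape: Waveform, mean_flow: float, pulsatile_amplitude: float) -> Waveform:
    """mean + amplitude * shape(t); both flows in m3/s.

    The shape is (re)normalized first, so the cycle mean of the result
    equals ``mean_flow`` to quadrature accuracy.
    """
    shape = normalize_shape(normalized_shape)
    return Waveform(
        period=shape.period,
        times=shape.times.copy(),
        values=mean_flow + pulsatile_amplitude * shape.values,
        units="m3/s",
    )


@dataclass
class BCSpec:
    """One inlet/outlet scheme instance for one subject.

    ``inlet_pressure`` is a callable t -> Pa for scheme "A";
    ``inlet_flow`` is a Waveform (m3/s) for schemes "B"/"C".
    ``outlets`` holds (location, constant pressure Pa) for "A"/"B" and
    (location, Waveform) for "C".
    """

    scheme: str
    group: str
    period: float = 1.0
    inlet_pressure: Optional[object] = None
    inlet_flow: Optional[Waveform] = None
    outlets: list = field(default_factory=list)

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {set(SCHEMES)}, got {self.scheme!r}")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.scheme == "A":
            if self.inlet_pressure is None or self.inlet_flow is not None:
                raise ValueError("scheme A requires a pressure inlet")
            if len(self.outlets) != 1 or not isinstance(self.outlets[0][1], float):
                raise ValueError("scheme A requires a single constant-pressure outlet")
        else:
            if self.inlet_flow is None:
                raise ValueError(f"scheme {self.scheme} requires a flow inlet")
            if self.scheme == "B":
                if len(self.outlets) != 1 or not isinstance(self.outlets[0][1], float):
                    raise ValueError("scheme B requires a single constant-pressure outlet")
            else:
                if len(self.outlets) != 2 or not all(
                    isinstance(o[1], Waveform) for o in self.outlets
                ):
                    raise ValueError("scheme C requires two flow outlets")
                inlet_mean = self.inlet_flow.cycle_mean()
                outlet_mean = sum(o[1].cycle_mean() for o in self.outlets)
                if not math.isclose(inlet_mean, outlet_mean, rel_tol=1e-9, abs_tol=1e-18):
                    raise ValueError(
                        "scheme C outlet means must sum to the inlet mean "
                        f"({outlet_mean:.6e} vs {inlet_mean:.6e} m3/s)"
                    )

    def total_outlet_flow(self, t):
        """Prescribed total outlet flow at time t (scheme C only), m3/s."""
        if self.scheme != "C":
            raise ValueError("prescribed outlet flow exists only for scheme C")
        return sum(o[1](t) for o in self.outlets)


def build_bc(
    scheme: str,
    group: str,
    subject_waveform: Optional[Waveform] = None,
    mean_inflow: float = MEAN_PRODUCTION,
    pulsatile_amplitude: float = None,
    outlet_means: tuple = OUTLET_MEANS,
    period: float = 1.0,
) -> BCSpec:
    """Construct a validated BCSpec for the given scheme and group.

    ``subject_waveform`` is the subject's normalized pulsatile shape
    (required for schemes B and C); ``pulsatile_amplitude`` (m3/s) is
    the subject-level amplitude of the oscillatory component.  Scheme C
    inlets are identical to scheme B inlets; its outlets reuse the
    inlet waveform scaled by the fractions outlet_means / mean_inflow,
    so the instantaneous and mean mass balances track the inlet by
    construction.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"scheme must be one of {set(SCHEMES)}, got {scheme!r}")
    p_out = outlet_pressure(group)
    if scheme == "A":
        return BCSpec(
            scheme="A",
            group=group,
            period=period,
            inlet_pressure=lambda t: bc_a_inlet_pressure(t, period),
            outlets=[("sagittal_sinus", p_out)],
        )
    if subject_waveform is None:
        raise ValueError(f"scheme {scheme} requires a subject waveform")
    if pulsatile_amplitude is None:
        raise ValueError(f"scheme {scheme} requires a pulsatile amplitude")
    inlet = superpose_flow(subject_waveform, mean_inflow, pulsatile_amplitude)
    if scheme == "B":
        return BCSpec(scheme="B", group=group, period=period, inlet_flow=inlet,
                      outlets=[("sagittal_sinus", p_out)])
    if not math.isclose(sum(outlet_means), mean_inflow, rel_tol=1e-9, abs_tol=1e-18):
        raise ValueError(
            f"scheme C outlet means {outlet_means} do not sum to the inlet mean {mean_inflow}"
        )
    outlets = []
    for loc, m in zip(OUTLET_LOCATIONS, outlet_means):
        frac = m / mean_inflow
        outlets.append(
            (loc, Waveform(period=period, times=inlet.times.copy(),
                           values=frac * inlet.values, units="m3/s"))
        )
    return BCSpec(scheme="C", group=group, period=period, inlet_flow=inlet, outlets=outlets)
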