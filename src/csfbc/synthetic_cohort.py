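"""Seeded synthetic cohort generator.

Generates healthy and hydrocephalus subjects whose compartment-volume
distributions, baseline pressures and aqueductal stroke-volume ratio
match the statistical structure the analysis pipeline assumes:
truncated-normal volumes anchored to the bundled cohort tables'
group means and SDs, baseline pressures near 500 Pa (healthy) /
2700 Pa (patient), and cardiac waveforms whose oscillatory aqueductal
stroke volume differs ~7.9-fold between groups.  Each subject's
pulsatile amplitude is calibrated by running the network solver under
scheme "C" (compliant walls) and rescaling — the oscillatory response
is linear in the amplitude, so one pilot run suffices.

Absolute stroke-volume levels are conventions (0.04 ml per cycle for
healthy subjects, in the range MRI studies report; patients at 7.9x
that); only the group ratio is anchored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .boundary_conditions import build_bc, normalize_shape
from .fixtures_io import CohortTable, Waveform
from .metrics import stroke_volume
from .solver import NetworkModel, simulate


@dataclass
class SubjectRecord:
    id: str
    group: str
    ventricular_volume_ml: float
    brain_volume_ml: float
    sas_volume_ml: float
    aqueduct_radius: float  # m
    aqueduct_length: float  # m
    baseline_pressure: float  # Pa
    waveform: Waveform  # normalized pulsatile shape
    pulsatile_amplitude: float  # m3/s
    measured_icp: Optional[float] = None  # Pa

    def __post_init__(self):
        for v in (self.ventricular_volume_ml, self.brain_volume_ml, self.sas_volume_ml):
            if v <= 0:
                raise ValueError("volumes must be positive")
        if not 0.5e-3 <= self.aqueduct_radius <= 3e-3:
            raise ValueError("aqueduct radius must lie in [0.5, 3] mm")


#: (mean, sd) volume anchors per group, ml — the bundled tables' summaries.
VOLUME_ANCHORS = {
    "healthy": {"ventricular_volume_ml": (20.3, 0.8), "brain_volume_ml": (1297.0, 52.1),
                "sas_volume_ml": (105.9, 4.8)},
    "patient": {"ventricular_volume_ml": (281.6, 11.5), "brain_volume_ml": (1071.7, 48.6),
                "sas_volume_ml": (108.4, 4.7)},
}


@dataclass
class CohortSpec:
    seed: int  # mandatory: every stochastic draw derives from it
    n_healthy: int = 8
    n_patients: int = 11
    volume_distributions: dict = field(default_factory=lambda: {
        g: dict(v) for g, v in VOLUME_ANCHORS.items()
    })
    #: oscillatory aqueductal stroke-volume targets per group, ml/cycle
    stroke_volume_targets_ml: dict = field(default_factory=lambda: {
        "healthy": 0.04, "patient": 0.316  # ratio 7.9
    })
    aqueduct_radius_m: dict = field(default_factory=lambda: {
        "healthy": (1.0e-3, 0.05e-3), "patient": (1.5e-3, 0.1e-3)
    })
    aqueduct_length_m: float = 0.015
    baseline_pressure_Pa: dict = field(default_factory=lambda: {
        "healthy": (500.0, 0.0), "patient": (2700.0, 0.0)
    })
    #: measured ICP anchor (patients), Pa — the cohort table's summary
    measured_icp_Pa: tuple = (2638.5, 118.8)
    harmonic_amplitudes: tuple = (1.0, 0.5, 0.25)
    phase_of_peak: float = 0.175
    waveform_noise: float = 0.05
    period: float = 1.0
    n_waveform_samples: int = 200
    calibrate_amplitudes: bool = True

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for g, dists in self.volume_distributions.items():
            for var, (m, s) in dists.items():
                if s < 0 or m <= 0:
                    raise ValueError(f"invalid distribution for {g}/{var}: mean {m}, sd {s}")


def _truncated_normal(rng, mean, sd, lo=-math.inf, hi=math.inf, n_sigma=3.0):
    """Normal draw re-drawn until within ±n_sigma SD and [lo, hi]."""
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if abs(x - mean) <= n_sigma * sd and lo <= x <= hi:
            return x
    raise RuntimeError("truncated normal failed to accept a draw")


def generate_waveform(
    harmonics=(1.0, 0.5, 0.25),
    phase_of_peak: float = 0.175,
    seed: int = 0,
    noise: float = 0.05,
    period: float = 1.0,
    n_samples: int = 200,
) -> Waveform:
    """Normalized (zero-mean, unit-peak) pulsatile waveform.

    A cosine series with every harmonic peaked at ``phase_of_peak`` and
    seeded multiplicative amplitude perturbations; because all
    perturbed harmonics still peak together, the global maximum stays
    exactly at ``phase_of_peak``.
    """
    if len(harmonics) < 1:
        raise ValueError("need at least one harmonic")
    if not 0.0 <= phase_of_peak < 1.0:
        raise ValueError("phase_of_peak must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    amps = np.asarray(harmonics, dtype=float)
    perturbed = amps * np.clip(1.0 + noise * rng.standard_normal(amps.size), 0.1, None)
    t = np.arange(n_samples) * (period / n_samples)
    phase = (t / period - phase_of_peak) * 2.0 * math.pi
    values = sum(c * np.cos((k + 1) * phase) for k, c in enumerate(perturbed))
    return normalize_shape(Waveform(period=period, times=t, values=values, units="dimensionless"))


def subject_network(subject: SubjectRecord, scheme: str = "C", mode: str = "FSI",
                    **overrides) -> NetworkModel:
    """Default NetworkModel for a synthetic subject under one scheme."""
    bc = build_bc(
        scheme=scheme,
        group=subject.group,
        subject_waveform=subject.waveform if scheme != "A" else None,
        pulsatile_amplitude=subject.pulsatile_amplitude if scheme != "A" else None,
        period=subject.waveform.period,
    )
    kwargs = dict(
        bc=bc,
        mode=mode,
        V0=subject.ventricular_volume_ml * 1e-6,
        aqueduct_radius=subject.aqueduct_radius,
        aqueduct_length=subject.aqueduct_length,
        baseline_pressure=subject.baseline_pressure,
    )
    kwargs.update(overrides)
    return NetworkModel(**kwargs)


def _oscillatory_sv_ml(subject: SubjectRecord, n_cycles: int = 5) -> float:
    result = simulate(subject_network(subject, scheme="C", mode="FSI"), n_cycles=n_cycles)
    t, q = result.last_cycle(result.flows["aqueduct"])
    return stroke_volume(
        Waveform(period=result.period, times=t, values=q, units="m3/s"), "oscillatory"
    )


def generate_cohort(spec: CohortSpec) -> list[SubjectRecord]:
    """Draw a reproducible synthetic cohort from a CohortSpec."""
    rng = np.random.default_rng(spec.seed)
    cohort = []
    for group, n in (("healthy", spec.n_healthy), ("patient", spec.n_patients)):
        dists = spec.volume_distributions[group]
        r_mean, r_sd = spec.aqueduct_radius_m[group]
        p_mean, p_sd = spec.baseline_pressure_Pa[group]
        target_sv = spec.stroke_volume_targets_ml[group]
        for i in range(n):
            vols = {var: _truncated_normal(rng, m, s, lo=1e-9)
                    for var, (m, s) in dists.items()}
            radius = _truncated_normal(rng, r_mean, r_sd, lo=0.5e-3, hi=3e-3)
            baseline = _truncated_normal(rng, p_mean, p_sd, lo=1.0)
            wf_seed = int(rng.integers(0, 2**31 - 1))
            waveform = generate_waveform(
                harmonics=spec.harmonic_amplitudes,
                phase_of_peak=spec.phase_of_peak,
                seed=wf_seed,
                noise=spec.waveform_noise,
                period=spec.period,
                n_samples=spec.n_waveform_samples,
            )
            icp = None
            if group == "patient":
                icp = _truncated_normal(rng, *spec.measured_icp_Pa, lo=1.0)
            # amplitude guess: a pure sinusoid of amplitude A has
            # oscillatory stroke volume A*T/pi
            amplitude = target_sv * 1e-6 * math.pi / spec.period
            subject = SubjectRecord(
                id=f"{group[0].upper()}{i + 1:03d}",
                group=group,
                aqueduct_radius=radius,
                aqueduct_length=spec.aqueduct_length_m,
                baseline_pressure=baseline,
                waveform=waveform,
                pulsatile_amplitude=amplitude,
                measured_icp=icp,
                **vols,
            )
            if spec.calibrate_amplitudes:
                sv0 = _oscillatory_sv_ml(subject)
                subject.pulsatile_amplitude = amplitude * target_sv / sv0
            cohort.append(subject)
    return cohort


def cohort_to_tables(cohort: list[SubjectRecord], extra_variables: dict = None) -> dict:
    """Pack a cohort into fixture-shaped CohortTables, one per group.

    ``extra_variables`` optionally maps group -> {variable: (unit,
    per-subject vector)} to append simulated quantities (e.g. maximum
    pressures) in the fixtures' schema.
    """
    if not cohort:
        raise ValueError("empty cohort")
    tables = {}
    for group in ("healthy", "patient"):
        members = [s for s in cohort if s.group == group]
        if not members:
            continue
        variables = {
            "ventricular_volume_ml": np.array([s.ventricular_volume_ml for s in members]),
            "brain_volume_ml": np.array([s.brain_volume_ml for s in members]),
            "sas_volume_ml": np.array([s.sas_volume_ml for s in members]),
        }
        units = {k: "ml" for k in variables}
        if group == "patient":
            icps = [s.measured_icp for s in members]
            if any(v is None for v in icps) and any(v is not None for v in icps):
                raise ValueError("mixed schemas: some patients lack measured ICP")
            if all(v is not None for v in icps):
                variables["experimental_ICP_SAS_Pa"] = np.array(icps, dtype=float)
                units["experimental_ICP_SAS_Pa"] = "Pa"
        for var, (unit, vec) in ((extra_variables or {}).get(group) or {}).items():
            vec = np.asarray(vec, dtype=float)
            if vec.size != len(members):
                raise ValueError(f"extra variable {var!r} has wrong length for group {group}")
            variables[var] = vec
            units[var] = unit
        tables[group] = CohortTable(
            group=group,
            subject_ids=[s.id for s in members],
            variables=variables,
            units=units,
        )
    return tables
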