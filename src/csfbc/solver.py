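"""Reduced-order transient CSF pathway solver and Womersley oracle.

The circulation is reduced to a two-node hydraulic network:

    inlet -> [ventricle node] -> aqueduct (R, L) -> [SAS node] -> outlets

The ventricle node carries volume V_V and, in FSI mode, the
poro-viscoelastic cavity compliance of the surrounding brain tissue;
in CFD mode its walls are rigid (V_V constant).  The aqueduct is a
Poiseuille resistance R = 8 mu l / (pi a^4) in series with an
inertance L = rho l / (pi a^2).  The SAS node carries a small constant
compliance C_S and drains through a constant-pressure outlet
resistance (schemes A/B) or prescribed outlet flow waveforms
(scheme C).  Time integration is backward (implicit) Euler; because
the network is linear, each step is one 3x3 solve with a constant
matrix, prefactored once.

The classical Womersley solution for oscillatory flow in a rigid tube
is provided as an independent analytic oracle and as the profile
reconstruction behind the "womersley" peak-velocity method.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.special import jv

from .boundary_conditions import BCSpec, outlet_pressure
from .constitutive import FluidProperties, MaterialModel, PronyCavity


class SolverError(RuntimeError):
    pass


@dataclass
class NetworkModel:
    """Lumped network for one subject under one BC scheme."""

    bc: BCSpec
    fluid: FluidProperties = field(default_factory=FluidProperties)
    material: MaterialModel = field(default_factory=MaterialModel)
    mode: str = "FSI"
    V0: float = 20.3e-6  # reference ventricular volume, m3
    aqueduct_radius: float = 1.0e-3  # m
    aqueduct_length: float = 0.015  # m
    sas_compliance: float = 1e-9  # m3/Pa
    outlet_resistance: float = 8e9  # Pa s/m3 (schemes A/B)
    production_resistance: float = 1e9  # Pa s/m3 (scheme A inlet)
    leak_conductance: float = 0.0  # m3/(s Pa); 0 = Darcy pathway off
    baseline_pressure: Optional[float] = None  # Pa; defaults to outlet pressure

    def __post_init__(self):
        if self.mode not in ("FSI", "CFD"):
            raise ValueError(f"mode must be 'FSI' or 'CFD', got {self.mode!r}")
        if self.aqueduct_radius <= 0 or self.aqueduct_length <= 0 or self.V0 <= 0:
            raise ValueError("geometry must be positive")
        if self.baseline_pressure is None:
            self.baseline_pressure = outlet_pressure(self.bc.group)
        if self.bc.scheme == "C" and self.sas_compliance <= 0:
            raise SolverError(
                "scheme C with zero SAS compliance leaves the pressure level undefined"
            )

    @property
    def resistance(self) -> float:
        """Poiseuille resistance of the aqueduct, Pa s/m3."""
        mu = self.fluid.dynamic_viscosity
        return 8.0 * mu * self.aqueduct_length / (math.pi * self.aqueduct_radius**4)

    @property
    def inertance(self) -> float:
        """Fluid inertance of the aqueduct, Pa s^2/m3."""
        return self.fluid.density * self.aqueduct_length / (math.pi * self.aqueduct_radius**2)

    def mean_inflow(self) -> float:
        """Cycle-mean inlet flow, m3/s (closed form for scheme A)."""
        if self.bc.scheme == "A":
            # mean gauge inlet pressure 80 Pa drives flow through
            # R_prod + R_aq + R_out at quasi-steady state
            return 80.0 / (self.production_resistance + self.resistance + self.outlet_resistance)
        return self.bc.inlet_flow.cycle_mean()


@dataclass
class SimulationResult:
    """Uniform-grid time series for all five cycles plus derived flags."""

    dt: float
    period: float
    n_cycles: int
    times: np.ndarray
    pressures: dict  # node -> Pa series
    flows: dict  # element -> m3/s series
    volume: np.ndarray  # ventricular volume, m3
    mode: str
    scheme: str
    mass_residual: float = 0.0  # max |dV/dt - net inflow| over accepted steps
    cycle_periodicity: float = float("nan")

    def __post_init__(self):
        n = self.times.size
        for name, s in {**self.pressures, **self.flows, "volume": self.volume}.items():
            if np.asarray(s).size != n:
                raise ValueError(f"series {name!r} length mismatch")

    def _cycle_slice(self, cycle: int) -> slice:
        """Half-open sample window of the 1-indexed cycle [(c-1)T, cT)."""
        per = int(round(self.period / self.dt))
        return slice((cycle - 1) * per, cycle * per)

    def last_cycle(self, series: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(times within [.,.) normalized to cycle start, values)."""
        sl = self._cycle_slice(self.n_cycles)
        return self.times[sl] - self.times[sl.start], np.asarray(series)[sl]

    def compute_periodicity(self) -> float:
        """Max over the reported series (node pressures, aqueduct flow,
        ventricular volume) of max|cycle5 - cycle4| / max|cycle5|.
        Prescribed inlet and slaved outlet series are excluded: they
        carry no independent state."""
        worst = 0.0
        for s in [*self.pressures.values(), self.flows["aqueduct"], self.volume]:
            s = np.asarray(s)
            a = s[self._cycle_slice(self.n_cycles - 1)]
            b = s[self._cycle_slice(self.n_cycles)]
            scale = np.max(np.abs(b))
            if scale > 0:
                worst = max(worst, float(np.max(np.abs(b - a)) / scale))
        self.cycle_periodicity = worst
        return worst

    def to_dict(self) -> dict:
        return {
            "dt": self.dt,
            "period": self.period,
            "n_cycles": self.n_cycles,
            "times": self.times.tolist(),
            "pressures": {k: np.asarray(v).tolist() for k, v in self.pressures.items()},
            "flows": {k: np.asarray(v).tolist() for k, v in self.flows.items()},
            "volume": self.volume.tolist(),
            "mode": self.mode,
            "scheme": self.scheme,
            "mass_residual": self.mass_residual,
            "cycle_periodicity": self.cycle_periodicity,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationResult":
        return cls(
            dt=d["dt"],
            period=d["period"],
            n_cycles=d["n_cycles"],
            times=np.asarray(d["times"]),
            pressures={k: np.asarray(v) for k, v in d["pressures"].items()},
            flows={k: np.asarray(v) for k, v in d["flows"].items()},
            volume=np.asarray(d["volume"]),
            mode=d["mode"],
            scheme=d["scheme"],
            mass_residual=d["mass_residual"],
            cycle_periodicity=d["cycle_periodicity"],
        )


def simulate(network: NetworkModel, dt: float = 0.01, n_cycles: int = 5) -> SimulationResult:
    """Backward-Euler integration over ``n_cycles`` cardiac cycles.

    Initial state is the quasi-steady operating point (mean flow through
    the resistive chain, reference cavity volume), so start-up
    transients carry only the oscillatory mismatch.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    bc = network.bc
    T = bc.period
    steps_per_cycle = int(round(T / dt))
    if abs(steps_per_cycle * dt - T) > 1e-9 * T:
        raise ValueError("dt must divide the cardiac period")
    n_steps = steps_per_cycle * n_cycles

    R, L = network.resistance, network.inertance
    C_S = network.sas_compliance
    G_l = network.leak_conductance
    R_out = network.outlet_resistance
    R_prod = network.production_resistance
    P0 = network.baseline_pressure
    scheme = bc.scheme
    fsi = network.mode == "FSI"

    q_mean = network.mean_inflow()
    if scheme in ("A", "B"):
        p_out = bc.outlets[0][1]
        p_sas0 = p_out + R_out * q_mean
    else:
        p_sas0 = P0
    p_ref_v = p_sas0 + R * q_mean  # ventricle operating pressure

    cavity = PronyCavity(material=network.material, V0=network.V0, dt=dt) if fsi else None

    times = np.linspace(0.0, n_steps * dt, n_steps + 1)
    P_V = np.empty(n_steps + 1)
    P_S = np.empty(n_steps + 1)
    Q_aq = np.empty(n_steps + 1)
    Q_in = np.empty(n_steps + 1)
    Q_out = np.empty(n_steps + 1)
    Vol = np.empty(n_steps + 1)

    P_V[0], P_S[0], Q_aq[0] = p_ref_v, p_sas0, q_mean
    Vol[0] = network.V0
    if scheme == "A":
        Q_in[0] = (P0 + bc.inlet_pressure(0.0) - P_V[0]) / R_prod
    else:
        Q_in[0] = bc.inlet_flow(0.0)
    Q_out[0] = (P_S[0] - p_out) / R_out if scheme in ("A", "B") else bc.total_outlet_flow(0.0)

    # ----- constant step matrix ------------------------------------------
    # FSI unknowns [V, Q, P_S];  CFD unknowns [P_V, Q, P_S]
    b_cav = cavity.stiffness_per_volume if fsi else 0.0
    M = np.zeros((3, 3))
    if fsi:
        dQin_dV = -b_cav / R_prod if scheme == "A" else 0.0
        M[0] = [1.0 - dt * dQin_dV + dt * G_l * b_cav, dt, -dt * G_l]
        M[1] = [-b_cav, L / dt + R, 1.0]
        M[2] = [-G_l * b_cav, -1.0, C_S / dt + G_l + (1.0 / R_out if scheme in ("A", "B") else 0.0)]
    else:
        if scheme == "A":
            M[0] = [-1.0 / R_prod - G_l, -1.0, G_l]
        else:
            M[0] = [-G_l, -1.0, G_l]
        M[1] = [-1.0, L / dt + R, 1.0]
        M[2] = [-G_l, -1.0, C_S / dt + G_l + (1.0 / R_out if scheme in ("A", "B") else 0.0)]
    Minv = np.linalg.inv(M)

    # precompute boundary forcing on the step grid
    t_grid = times[1:]
    if scheme == "A":
        p_in_series = P0 + bc.inlet_pressure(t_grid)
    else:
        q_in_series = bc.inlet_flow(t_grid)
    if scheme == "C":
        q_out_series = bc.total_outlet_flow(t_grid)

    mass_residual = 0.0
    rhs = np.empty(3)
    for n in range(n_steps):
        i = n + 1
        if fsi:
            a_cav, _ = cavity.affine_step()
            p_v_const = p_ref_v + a_cav  # P_V = p_v_const + b_cav * V
            if scheme == "A":
                q_in_const = (p_in_series[n] - p_v_const) / R_prod
            else:
                q_in_const = q_in_series[n]
            rhs[0] = Vol[n] + dt * q_in_const - dt * G_l * p_v_const
            rhs[1] = (L / dt) * Q_aq[n] + p_v_const
            rhs[2] = (C_S / dt) * P_S[n] + G_l * p_v_const
            if scheme in ("A", "B"):
                rhs[2] += p_out / R_out
            else:
                rhs[2] -= q_out_series[n]
            x = Minv @ rhs
            x += Minv @ (rhs - M @ x)  # one refinement pass keeps the
            # discrete mass balance at machine precision
            V_new, q_new, p_s_new = x
            p_v_new = cavity.advance(V_new) + p_ref_v
            if scheme == "A":
                q_in_new = (p_in_series[n] - p_v_new) / R_prod
            else:
                q_in_new = q_in_series[n]
            q_leak = G_l * (p_v_new - p_s_new)
            mass_residual = max(
                mass_residual,
                abs((V_new - Vol[n]) / dt - (q_in_new - q_new - q_leak)),
            )
            Vol[i] = V_new
        else:
            if scheme == "A":
                rhs[0] = -p_in_series[n] / R_prod
            else:
                rhs[0] = -q_in_series[n]
            rhs[1] = (L / dt) * Q_aq[n]
            rhs[2] = (C_S / dt) * P_S[n]
            if scheme in ("A", "B"):
                rhs[2] += p_out / R_out
            else:
                rhs[2] -= q_out_series[n]
            x = Minv @ rhs
            x += Minv @ (rhs - M @ x)
            p_v_new, q_new, p_s_new = x
            if scheme == "A":
                q_in_new = (p_in_series[n] - p_v_new) / R_prod
            else:
                q_in_new = q_in_series[n]
            q_leak = G_l * (p_v_new - p_s_new)
            mass_residual = max(mass_residual, abs(q_in_new - q_new - q_leak))
            Vol[i] = network.V0
        if not (np.isfinite(q_new) and np.isfinite(p_s_new) and np.isfinite(p_v_new)):
            raise SolverError(f"solver diverged (non-finite state) at step {i}")
        P_V[i], P_S[i], Q_aq[i], Q_in[i] = p_v_new, p_s_new, q_new, q_in_new
        Q_out[i] = (p_s_new - p_out) / R_out if scheme in ("A", "B") else q_out_series[n]

    result = SimulationResult(
        dt=dt,
        period=T,
        n_cycles=n_cycles,
        times=times,
        pressures={"ventricle": P_V, "sas": P_S},
        flows={"inlet": Q_in, "aqueduct": Q_aq, "outlet": Q_out},
        volume=Vol,
        mode=network.mode,
        scheme=scheme,
        mass_residual=mass_residual / max(float(np.max(np.abs(Q_in))), 1e-30),
    )
    result.compute_periodicity()
    return result


def run_mode_pair(network: NetworkModel, dt: float = 0.01, n_cycles: int = 5):
    """Simulate the same subject/BC with compliant and rigid walls.

    Returns (fsi_result, cfd_result) on identical grids."""
    fsi = simulate(dataclasses.replace(network, mode="FSI"), dt=dt, n_cycles=n_cycles)
    cfd = simulate(dataclasses.replace(network, mode="CFD"), dt=dt, n_cycles=n_cycles)
    return fsi, cfd


# ---------------------------------------------------------------------------
# Womersley analytic solution
# ---------------------------------------------------------------------------

def womersley_number(a: float, omega: float, fluid: FluidProperties) -> float:
    return a * math.sqrt(omega * fluid.density / fluid.dynamic_viscosity)


def womersley_velocity(r, t, a: float, omega: float, pressure_gradient_amplitude: float,
                       fluid: FluidProperties):
    """Axial velocity of oscillatory laminar flow in a rigid tube, m/s.

    Driving pressure gradient is -dp/dx = G cos(omega t) with
    G = ``pressure_gradient_amplitude`` (Pa/m).  Satisfies no-slip
    u(a, t) = 0 exactly; for Womersley number alpha -> 0 it reduces to
    the quasi-static Poiseuille profile G (a^2 - r^2)/(4 mu) cos(wt).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0) or np.any(r > a):
        raise ValueError("radial position must satisfy 0 <= r <= a")
    if omega <= 0:
        raise ValueError("omega must be positive")
    alpha = womersley_number(a, omega, fluid)
    lam = 1j ** 1.5 * alpha
    G = pressure_gradient_amplitude
    profile = 1.0 - jv(0, lam * r / a) / jv(0, lam)
    u = (G / (1j * fluid.density * omega)) * profile * np.exp(1j * omega * np.asarray(t))
    out = np.real(u)
    return float(out) if out.shape == () else out


def womersley_flow_amplitude(a: float, omega: float, pressure_gradient_amplitude: float,
                             fluid: FluidProperties) -> complex:
    """Complex flow-rate phasor of the Womersley solution, m3/s."""
    alpha = womersley_number(a, omega, fluid)
    lam = 1j ** 1.5 * alpha
    G = pressure_gradient_amplitude
    bulk = 1.0 - 2.0 * jv(1, lam) / (lam * jv(0, lam))
    return (G * math.pi * a**2 / (1j * fluid.density * omega)) * bulk


def _womersley_profile_factor(r_over_a: np.ndarray, alpha: float) -> np.ndarray:
    """Velocity/flow transfer u_hat(r) / (Q_hat / (pi a^2)) at one harmonic."""
    lam = 1j ** 1.5 * alpha
    return (1.0 - jv(0, lam * r_over_a) / jv(0, lam)) / (1.0 - 2.0 * jv(1, lam) / (lam * jv(0, lam)))


def peak_aqueduct_velocity(result: SimulationResult, a: float, fluid: FluidProperties,
                           method: str = "poiseuille", n_harmonics: int = 16) -> float:
    """Peak axial CSF velocity in the aqueduct over the last cycle, m/s.

    "poiseuille": centreline of a parabolic profile, 2 |Q|_max/(pi a^2).
    "womersley": rebuild the oscillatory profile from the flow's Fourier
    harmonics and take the maximum over radius and time.
    """
    t, q = result.last_cycle(result.flows["aqueduct"])
    if method == "poiseuille":
        return float(2.0 * np.max(np.abs(q)) / (math.pi * a**2))
    if method != "womersley":
        raise ValueError(f"unknown method {method!r}; use 'poiseuille' or 'womersley'")
    n = q.size
    coeffs = np.fft.rfft(q) / n
    omega0 = 2.0 * math.pi / result.period
    r_over_a = np.linspace(0.0, 1.0, 41)
    u = np.zeros((r_over_a.size, n))
    phase = np.exp(1j * omega0 * np.outer(np.arange(1, min(n_harmonics, coeffs.size - 1) + 1), t))
    u += 2.0 * coeffs[0].real / (math.pi * a**2) * (1.0 - r_over_a[:, None] ** 2)
    for k in range(1, min(n_harmonics, coeffs.size - 1) + 1):
        alpha_k = womersley_number(a, k * omega0, fluid)
        prof = _womersley_profile_factor(r_over_a, alpha_k)
        u += 2.0 * np.real(np.outer(prof, phase[k - 1]) * coeffs[k]) / (math.pi * a**2)
    return float(np.max(np.abs(u)))


def build_network(config, waveform=None) -> NetworkModel:
    """Assemble a NetworkModel from a validated RunConfig.

    ``waveform`` (a normalized shape Waveform) overrides any
    bc.waveform_csv; if neither is given, the canonical three-harmonic
    shape with its peak at 17.5% of the cycle is used.
    """
    from .boundary_conditions import build_bc, harmonic_shape
    from .constitutive import darcy_leak_conductance
    from .fixtures_io import ML_MIN_TO_M3_S, read_waveform

    subject, bc_cfg, sol = config.subject, config.bc, config.solver
    material = MaterialModel(
        E=config.material["E_Pa"],
        nu=config.material["nu"],
        prony_g=tuple(config.material["prony_g"]),
        prony_tau=tuple(config.material["prony_tau_s"]),
        void_ratio=config.material["void_ratio"],
        permeability=config.material["permeability"],
    )
    if waveform is None:
        if bc_cfg.get("waveform_csv"):
            waveform = read_waveform(bc_cfg["waveform_csv"])
        else:
            waveform = harmonic_shape(period=bc_cfg["period_s"])
    bc = build_bc(
        scheme=bc_cfg["scheme"],
        group=subject["group"],
        subject_waveform=waveform if bc_cfg["scheme"] != "A" else None,
        mean_inflow=bc_cfg["mean_inflow_ml_min"] * ML_MIN_TO_M3_S,
        pulsatile_amplitude=(
            bc_cfg["pulsatile_amplitude_ml_min"] * ML_MIN_TO_M3_S
            if bc_cfg["scheme"] != "A" else None
        ),
        period=bc_cfg["period_s"],
    )
    leak = 0.0
    if sol["darcy_leak"]:
        leak = darcy_leak_conductance(
            material, sol["darcy_leak_length_m"], sol["darcy_leak_area_m2"]
        )
    return NetworkModel(
        bc=bc,
        material=material,
        mode=sol["mode"],
        V0=subject["ventricular_volume_ml"] * 1e-6,
        aqueduct_radius=subject["aqueduct_radius_m"],
        aqueduct_length=subject["aqueduct_length_m"],
        sas_compliance=sol["sas_compliance_m3_Pa"],
        outlet_resistance=sol["outlet_resistance_Pa_s_m3"],
        production_resistance=sol["production_resistance_Pa_s_m3"],
        leak_conductance=leak,
        baseline_pressure=subject["baseline_pressure_Pa"],
    )
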