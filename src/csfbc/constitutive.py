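"""Brain-tissue poro-viscoelastic model and CSF fluid properties.

The tissue is a linear viscoelastic solid whose shear relaxation
modulus is a Prony series

    Gr(t) = G0 * (1 - sum_k g_k * (1 - exp(-t / tau_k))),

with instantaneous shear modulus G0 = E / (2(1+nu)).  The ventricular
compartment is mapped to a pressurized spherical cavity in an unbounded
medium: elastically dV/V0 = 3 dP / (4 G), extended to viscoelasticity
by the correspondence principle, giving the hereditary integral

    P_tm(t) = 4/(3 V0) * int_0^t Gr(t - s) dV/ds ds.

The integral is evaluated by an exact exponential-integrator recursion
per Prony branch (piecewise-linear volume history), which is
unconditionally stable and needs O(1) memory per step.  A Darcy leak
pathway through the parenchyma is available as a lumped conductance but
is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class FluidProperties:
    """Newtonian CSF: water at body temperature by default."""

    density: float = 998.2  # kg/m3
    dynamic_viscosity: float = 0.001  # kg/(m s)
    newtonian: bool = True

    def __post_init__(self):
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("density and viscosity must be positive")


def shear_from_elastic(E: float, nu: float) -> float:
    """Instantaneous shear modulus of an isotropic solid, G0 = E/(2(1+nu))."""
    if E < 0:
        raise ValueError("elastic modulus must be non-negative")
    if not -1.0 < nu < 0.5:
        raise ValueError("Poisson ratio must lie in (-1, 0.5); the incompressible limit is unsupported")
    return E / (2.0 * (1.0 + nu))


@dataclass(frozen=True)
class MaterialModel:
    """Poro-viscoelastic brain tissue parameters.

    The relaxation amplitude g = 0.285 applies to each of the three
    branches (the convention of the source material data), so the
    long-time modulus is G0 * (1 - 3*0.285) = 0.145 * G0.  Permeability
    is in m4/(N s).
    """

    E: float = 584.4  # Pa
    nu: float = 0.35
    prony_g: tuple = (0.285, 0.285, 0.285)
    prony_tau: tuple = (3.1, 27.0, 410.0)  # s
    void_ratio: float = 0.2
    permeability: float = 4.08e-12  # m4/(N s)

    def __post_init__(self):
        shear_from_elastic(self.E, self.nu)  # validates E, nu
        if not 0.0 <= self.nu < 0.5:
            raise ValueError("Poisson ratio must lie in [0, 0.5)")
        g = np.asarray(self.prony_g, dtype=float)
        tau = np.asarray(self.prony_tau, dtype=float)
        if g.shape != tau.shape:
            raise ValueError("prony_g and prony_tau must have equal length")
        if np.any(g < 0) or g.sum() >= 1.0:
            raise ValueError("require g_k >= 0 and sum(g_k) < 1 so that Gr(inf) > 0")
        if np.any(tau <= 0) or np.any(np.diff(tau) <= 0):
            raise ValueError("relaxation times must be positive and strictly increasing")

    @property
    def G0(self) -> float:
        return shear_from_elastic(self.E, self.nu)

    @property
    def G_inf(self) -> float:
        return self.G0 * (1.0 - float(np.sum(self.prony_g)))


def relaxation_modulus(t, material: MaterialModel):
    """Time-dependent shear relaxation modulus Gr(t), Pa.

    Monotone non-increasing, bounded in [G_inf, G0].
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("relaxation modulus is defined for t >= 0")
    g = np.asarray(material.prony_g)[:, None]
    tau = np.asarray(material.prony_tau)[:, None]
    gr = material.G0 * (1.0 - np.sum(g * (1.0 - np.exp(-t.ravel()[None, :] / tau)), axis=0))
    return gr.reshape(t.shape) if t.shape else float(gr[0])


def darcy_leak_conductance(material: MaterialModel, path_length: float, path_area: float) -> float:
    """Lumped conductance of a porous pathway, Q = k A / L * dP, in m3/(s Pa).

    Zero area is allowed (degenerate closed pathway)."""
    if path_length <= 0 or path_area < 0:
        raise ValueError("pathway needs positive length and non-negative area")
    return material.permeability * path_area / path_length


@dataclass
class PronyCavity:
    """Incremental viscoelastic spherical-cavity response.

    Maintains one internal stress-like variable per Prony branch and
    maps a sampled cavity-volume history to transmural pressure.  The
    per-step update is exact for piecewise-linear V(t):

        h_k(t+dt) = e^(-dt/tau_k) h_k(t)
                    + G0 g_k (dV/dt) tau_k (1 - e^(-dt/tau_k))

        P_tm = 4/(3 V0) * ( G_inf (V - V0) + sum_k h_k )
    """

    material: MaterialModel
    V0: float  # reference cavity volume, m3
    dt: float
    _h: np.ndarray = field(init=False)
    _V_prev: float = field(init=False)

    def __post_init__(self):
        if self.V0 <= 0:
            raise ValueError("reference volume must be positive")
        if self.dt <= 0:
            raise ValueError("time step must be positive")
        self._h = np.zeros(len(self.material.prony_g))
        self._V_prev = self.V0
        tau = np.asarray(self.material.prony_tau)
        g = np.asarray(self.material.prony_g)
        self._decay = np.exp(-self.dt / tau)
        # exact ramp-response weight: G0 g_k tau_k (1 - e^(-dt/tau_k)) / dt
        self._ramp = self.material.G0 * g * tau * (1.0 - self._decay) / self.dt

    @property
    def stiffness_per_volume(self) -> float:
        """dP_tm/dV of one implicit step (used by the network solver)."""
        return (4.0 / (3.0 * self.V0)) * (self.material.G_inf + float(np.sum(self._ramp)))

    def affine_step(self) -> tuple[float, float]:
        """Coefficients (a, b) such that the next-step transmural
        pressure is P_tm(V_next) = a + b * V_next, given the current
        internal state.  Lets an implicit network solver treat the
        viscoelastic cavity as a linear element within each step."""
        b = self.stiffness_per_volume
        a = (4.0 / (3.0 * self.V0)) * (
            -self.material.G_inf * self.V0
            + float(np.sum(self._decay * self._h))
            - float(np.sum(self._ramp)) * self._V_prev
        )
        return a, b

    def advance(self, V_new: float) -> float:
        """Accept the next volume sample; return transmural pressure, Pa."""
        dV = V_new - self._V_prev
        self._h = self._decay * self._h + self._ramp * dV
        self._V_prev = V_new
        p = (4.0 / (3.0 * self.V0)) * (
            self.material.G_inf * (V_new - self.V0) + float(np.sum(self._h))
        )
        return p


def cavity_transmural_pressure(volume_history, material: MaterialModel, V0: float, dt: float = None, times=None):
    """Transmural pressure history for a sampled cavity-volume history.

    ``volume_history`` is sampled on a uniform grid with spacing ``dt``
    (or pass ``times``; uniformity is checked).  V(0) must equal V0.
    """
    v = np.asarray(volume_history, dtype=float)
    if times is not None:
        times = np.asarray(times, dtype=float)
        steps = np.diff(times)
        if steps.size and not np.allclose(steps, steps[0], rtol=1e-9, atol=0.0):
            raise ValueError("volume history must be sampled on a uniform time grid")
        dt = float(steps[0])
    if dt is None or dt <= 0:
        raise ValueError("a positive dt (or a uniform times grid) is required")
    if V0 <= 0:
        raise ValueError("reference volume must be positive")
    if abs(v[0] - V0) > 1e-12 * max(abs(V0), 1.0):
        raise ValueError("volume history must start at the reference volume V0")
    cavity = PronyCavity(material=material, V0=V0, dt=dt)
    out = np.empty_like(v)
    out[0] = 0.0
    for i in range(1, v.size):
        out[i] = cavity.advance(v[i])
    return out
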