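"""Biophysical mechanism models for chondroitin-proteinoid interaction.

Four building blocks of the proposed mechanism by which chondroitin
sulfate (CS) modulates microsphere electrical activity:

1. Surface electrostatics: the Poisson-Boltzmann equation reduced to
   spherical symmetry around a charged microsphere, solved by damped
   Newton iteration on a finite-difference grid
   (:func:`solve_pb_radial`). In the small-potential limit it reproduces
   the Debye-Hueckel screened-Coulomb profile.
2. Channel gating: Boltzmann open probability
   P = 1 / (1 + exp(dG / kT)) (:func:`channel_open_probability`).
3. Membrane dynamics: a multi-conductance (Hodgkin-Huxley-type) membrane
   ODE C dV/dt = -sum_i g_i (V - E_i) + I_ext with each conductance scaled
   by its gating probability (:func:`simulate_membrane`, exact
   exponential-Euler stepping).
4. Plasticity: a CS-dependent Hebbian rule dw_ij/dt = eta(CS_ij) x_i y_j
   with a saturating Michaelis-type learning rate
   (:func:`hebbian_step`, :func:`michaelis_learning_rate`).

The source framework states these equations without geometry, boundary
conditions or parameter values; the defaults here (1 um sphere, 0.1 M 1:1
electrolyte, 298.15 K) are configuration, not claims. SI units internally;
mV and mg/ml at the interfaces. Note the electrostatic potential is NOT
coupled into dG here — dG is an input, since the source framework leaves
that coupling unspecified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.constants import Avogadro as N_A
from scipy.constants import Boltzmann as K_B
from scipy.constants import elementary_charge as E_CHARGE
from scipy.constants import epsilon_0 as EPS0
from scipy.linalg import solve_banded

__all__ = [
    "ElectrolyteSystem",
    "MembraneModel",
    "Channel",
    "PlasticNetwork",
    "solve_pb_radial",
    "debye_length",
    "debye_huckel_profile",
    "channel_open_probability",
    "simulate_membrane",
    "membrane_steady_state",
    "michaelis_learning_rate",
    "hebbian_step",
]


# ---------------------------------------------------------------------------
# Poisson-Boltzmann electrostatics


@dataclass(frozen=True)
class ElectrolyteSystem:
    """Spherical microsphere of radius ``a`` in an electrolyte shell out to ``R``.

    ions: sequence of (valence z_i, bulk concentration c_i0 in mol/m^3);
    the bulk must be electroneutral. ``permittivity`` and
    ``fixed_charge`` may be constants or callables of r (m); fixed charge
    density in C/m^3. ``surface_charge`` sigma in C/m^2 sets the Neumann
    inner boundary -eps dpsi/dr|_a = sigma; psi(R) = 0 (Dirichlet).
    """

    ions: Sequence[tuple[float, float]] = ((1.0, 100.0), (-1.0, 100.0))  # 0.1 M 1:1
    temperature: float = 298.15  # K
    inner_radius: float = 1e-6  # m
    outer_radius: float = 1e-6 + 1e-8  # m; ~10 Debye lengths at 0.1 M
    surface_charge: float = 1e-4  # C/m^2
    permittivity: float | Callable[[np.ndarray], np.ndarray] = 78.5
    fixed_charge: float | Callable[[np.ndarray], np.ndarray] = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.inner_radius < self.outer_radius:
            raise ValueError("need 0 < inner radius < outer radius")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        net = sum(z * c for z, c in self.ions)
        scale = sum(abs(z) * c for z, c in self.ions) or 1.0
        if abs(net) > 1e-9 * scale:
            raise ValueError("bulk electrolyte must be electroneutral")

    def eps_at(self, r: np.ndarray) -> np.ndarray:
        p = self.permittivity
        return np.asarray(p(r) if callable(p) else np.full_like(r, float(p)))

    def rho_fixed_at(self, r: np.ndarray) -> np.ndarray:
        p = self.fixed_charge
        return np.asarray(p(r) if callable(p) else np.full_like(r, float(p)))


def debye_length(system: ElectrolyteSystem) -> float:
    """Debye screening length 1/kappa (m) at the mean relative permittivity."""
    r = np.asarray([0.5 * (system.inner_radius + system.outer_radius)])
    eps_r = float(system.eps_at(r)[0])
    ionic = sum(c * N_A * z**2 for z, c in system.ions)
    kappa2 = E_CHARGE**2 * ionic / (EPS0 * eps_r * K_B * system.temperature)
    return 1.0 / math.sqrt(kappa2)


def debye_huckel_profile(system: ElectrolyteSystem, r: np.ndarray) -> np.ndarray:
    """Linearized (Debye-Hueckel) closed form: screened Coulomb decay (V)."""
    a = system.inner_radius
    eps_r = float(system.eps_at(np.asarray([a]))[0])
    kappa = 1.0 / debye_length(system)
    pref = system.surface_charge * a**2 / (EPS0 * eps_r * (1.0 + kappa * a))
    return pref * np.exp(-kappa * (r - a)) / r


def _ionic_charge(system: ElectrolyteSystem, psi: np.ndarray) -> np.ndarray:
    """Mobile charge density (C/m^3) at potential psi; exponent clipped at 50."""
    kt = K_B * system.temperature
    rho = np.zeros_like(psi)
    for z, c in system.ions:
        x = np.clip(-z * E_CHARGE * psi / kt, -50.0, 50.0)
        rho += z * E_CHARGE * c * N_A * np.exp(x)
    return rho


def _ionic_charge_dpsi(system: ElectrolyteSystem, psi: np.ndarray) -> np.ndarray:
    kt = K_B * system.temperature
    d = np.zeros_like(psi)
    for z, c in system.ions:
        x = np.clip(-z * E_CHARGE * psi / kt, -50.0, 50.0)
        d += -(z * E_CHARGE) ** 2 * c * N_A * np.exp(x) / kt
    return d


def solve_pb_radial(
    system: ElectrolyteSystem,
    n_grid: int = 2000,
    *,
    tol: float = 1e-10,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the spherically symmetric Poisson-Boltzmann problem.

    (1/r^2) d/dr(eps_r r^2 dpsi/dr) = -[rho_f + rho_ion(psi)] / eps_0 on
    [a, R], Neumann flux condition at a (surface charge sigma), psi(R)=0.
    Damped Newton iteration until the residual max-norm falls below
    ``tol`` relative to the initial (psi=0) residual. Returns ``(r, psi)``
    in m and V.
    """
    if n_grid < 10:
        raise ValueError("n_grid must be >= 10")
    a, R = system.inner_radius, system.outer_radius
    r = np.linspace(a, R, n_grid)
    h = r[1] - r[0]
    r_half = 0.5 * (r[:-1] + r[1:])
    eps_half = system.eps_at(r_half)
    rho_f = system.rho_fixed_at(r)

    def residual(psi: np.ndarray) -> np.ndarray:
        F = np.zeros_like(psi)
        flux = eps_half * r_half**2 * np.diff(psi) / h  # eps_r r^2 psi'
        rho = (rho_f + _ionic_charge(system, psi)) / EPS0
        # interior nodes: divergence of flux + rho = 0
        F[1:-1] = (flux[1:] - flux[:-1]) / (h * r[1:-1] ** 2) + rho[1:-1]
        # inner node: half-cell flux balance with the surface-charge flux
        F[0] = (flux[0] + a**2 * system.surface_charge / EPS0) / (
            0.5 * h * a**2
        ) + rho[0]
        F[-1] = psi[-1]  # Dirichlet
        return F

    def jacobian_banded(psi: np.ndarray) -> np.ndarray:
        drho = _ionic_charge_dpsi(system, psi) / EPS0
        ab = np.zeros((3, psi.size))
        w = eps_half * r_half**2 / h
        # interior
        for j in range(1, psi.size - 1):
            ab[0, j + 1] = w[j] / (h * r[j] ** 2)  # super: dF_j/dpsi_{j+1}
            ab[1, j] = -(w[j] + w[j - 1]) / (h * r[j] ** 2) + drho[j]
            ab[2, j - 1] = w[j - 1] / (h * r[j] ** 2)  # sub: dF_j/dpsi_{j-1}
        ab[0, 1] = w[0] / (0.5 * h * a**2)
        ab[1, 0] = -w[0] / (0.5 * h * a**2) + drho[0]
        ab[1, -1] = 1.0
        ab[2, -2] = 0.0
        return ab

    psi = np.zeros(n_grid)
    F = residual(psi)
    norm0 = float(np.max(np.abs(F)))
    if norm0 == 0.0:
        return r, psi
    norm = norm0
    for _ in range(max_iter):
        step = solve_banded((1, 1), jacobian_banded(psi), -F)
        damp = 1.0
        while damp > 1e-8:
            trial = psi + damp * step
            F_trial = residual(trial)
            norm_trial = float(np.max(np.abs(F_trial)))
            if norm_trial < norm:
                psi, F, norm = trial, F_trial, norm_trial
                break
            damp *= 0.5
        else:
            raise RuntimeError("PB Newton: damping failed to reduce residual")
        if norm < tol * norm0:
            return r, psi
    raise RuntimeError(f"PB Newton did not converge in {max_iter} iterations")


# ---------------------------------------------------------------------------
# channel gating


def channel_open_probability(delta_g: float, temperature: float) -> float:
    """Boltzmann open probability P = 1 / (1 + exp(dG / kT)).

    delta_g is the open-minus-closed Gibbs free energy difference in J;
    strictly decreasing in delta_g, saturating at 1 (dG -> -inf) and 0
    (dG -> +inf).
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    x = delta_g / (K_B * temperature)
    if x > 700:
        return 0.0
    return 1.0 / (1.0 + math.exp(x))


# ---------------------------------------------------------------------------
# multi-conductance membrane


@dataclass(frozen=True)
class Channel:
    """One conductance: density (mS/cm^2), reversal (mV), gating dG (J).

    ``delta_g=None`` means constitutively open (P = 1).
    """

    g_max: float
    reversal: float
    delta_g: float | None = None

    def __post_init__(self) -> None:
        if self.g_max < 0:
            raise ValueError("g_max must be >= 0")


@dataclass(frozen=True)
class MembraneModel:
    """Membrane with capacitance C_m (uF/cm^2), channels, drive (uA/cm^2)."""

    c_m: float = 1.0
    channels: Sequence[Channel] = field(default_factory=tuple)
    i_ext: float = 0.0
    temperature: float = 298.15  # K, used by channel gating

    def __post_init__(self) -> None:
        if self.c_m <= 0:
            raise ValueError("capacitance must be positive")

    def effective_conductances(self) -> np.ndarray:
        return np.asarray(
            [
                ch.g_max
                * (
                    1.0
                    if ch.delta_g is None
                    else channel_open_probability(ch.delta_g, self.temperature)
                )
                for ch in self.channels
            ]
        )


def membrane_steady_state(model: MembraneModel) -> float:
    """Algebraic steady state: conductance-weighted reversals plus drive (mV)."""
    g = model.effective_conductances()
    g_tot = float(g.sum())
    if g_tot == 0:
        raise ValueError("no conductance: steady state undefined")
    e = np.asarray([ch.reversal for ch in model.channels])
    return float((g @ e + model.i_ext) / g_tot)


def simulate_membrane(
    model: MembraneModel, v0: float, duration: float, dt: float
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate C dV/dt = -sum g_i (V - E_i) + I_ext; returns (t, V) in ms/mV.

    Effective conductances are the channel densities scaled by their
    Boltzmann open probabilities. With constant conductances the equation
    is linear, so the exponential-Euler step is exact per step; with zero
    total conductance V ramps linearly at I_ext / C_m.
    """
    if dt <= 0 or duration < dt:
        raise ValueError("need dt > 0 and duration >= dt")
    g = model.effective_conductances()
    g_tot = float(g.sum()) if g.size else 0.0
    n = int(round(duration / dt)) + 1
    t = np.arange(n) * dt
    if g_tot == 0:
        return t, v0 + (model.i_ext / model.c_m) * t
    v_inf = membrane_steady_state(model)
    decay = np.exp(-g_tot * t / model.c_m)
    v = v_inf + (v0 - v_inf) * decay
    if np.any(~np.isfinite(v)):
        raise FloatingPointError("membrane state diverged")
    return t, v


# ---------------------------------------------------------------------------
# CS-dependent Hebbian plasticity


def michaelis_learning_rate(eta0: float, k_half: float) -> Callable[[np.ndarray], np.ndarray]:
    """Saturating learning rate eta(CS) = eta0 * CS / (K + CS).

    Bounded above by eta0, consistent with the stabilising effect of high
    CS concentrations; K is the half-saturation concentration (mg/ml).
    """
    if eta0 < 0 or k_half <= 0:
        raise ValueError("need eta0 >= 0 and K > 0")

    def eta(cs):
        cs = np.asarray(cs, dtype=float)
        return eta0 * cs / (k_half + cs)

    return eta


@dataclass(frozen=True)
class PlasticNetwork:
    """Microsphere network with CS-dependent Hebbian plasticity.

    weights[i, j] couples presynaptic unit i (activity x[i]) to
    postsynaptic unit j (activity y[j]); cs[i, j] is the local CS
    concentration (mg/ml) and ``learning_rate`` maps it to eta >= 0.
    """

    weights: np.ndarray
    cs: np.ndarray  # mg/ml, same shape as weights (or scalar broadcast)
    x: np.ndarray
    y: np.ndarray
    learning_rate: Callable = field(
        default_factory=lambda: michaelis_learning_rate(0.1, 1.0)
    )
    clip: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "cs", np.broadcast_to(
            np.asarray(self.cs, dtype=float), w.shape))
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if w.shape != (self.x.size, self.y.size):
            raise ValueError("weights must be (len(x), len(y))")
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")


def hebbian_step(network: PlasticNetwork, dt: float) -> np.ndarray:
    """One forward-Euler step of dw_ij/dt = eta(CS_ij) x_i y_j.

    Returns the updated weight matrix (the network is not mutated);
    optional clipping to ``network.clip`` bounds.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if not (np.all(np.isfinite(network.x)) and np.all(np.isfinite(network.y))):
        raise ValueError("activities must be finite")
    eta = np.asarray(network.learning_rate(network.cs), dtype=float)
    if np.any(eta < 0):
        raise ValueError("learning rate must be >= 0")
    w = network.weights + dt * eta * np.outer(network.x, network.y)
    if network.clip is not None:
        w = np.clip(w, *network.clip)
    return w
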