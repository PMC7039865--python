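"""Self-contained well-tempered metadynamics engine on analytic toy potentials.

The collective variable (CV) is the distance between a mobile ion and the
center of mass of a fixed anchor group (unit masses; the anchors in the
source system are four Cα atoms, so mass weighting is immaterial).  The CV
is confined by half-harmonic walls (defaults 5–20 Å) and the ion is kept in
the region of interest by a three-point angle restraint: the angle at the
upper-leaflet phosphorus COM, between the rays to the lower-leaflet COM and
to the ion, must stay below a maximum (default 80°).

Gaussian hills are deposited on the CV every ``stride`` steps with the
well-tempered height schedule

    h_t = h0 · exp(−V(s_t) / (k_B ΔT)),   ΔT = (γ − 1) T,

so heights decay where the bias has accumulated and the free energy is
estimated as F(s) = −(γ/(γ−1)) V(s).  Dynamics are overdamped Langevin:

    x ← x + (dt/ξ) F + sqrt(2 k_B T dt/ξ) η,

with ξ the friction and η unit Gaussian noise.  Hill defaults
(h0 = 1.2 kJ/mol, σ = 0.35 Å, stride = 500 steps, γ = 10) are conventional
choices; energies are kJ/mol, lengths Å, temperatures K.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .exceptions import (
    AnalysisError,
    ConfigurationError,
    GeometryError,
    IntegrationError,
)

KB = 0.008314462618  # kJ/mol/K


# ---------------------------------------------------------------------------
# Collective variable
# ---------------------------------------------------------------------------

def cv_value(
    ion_position: np.ndarray, anchor_coordinates: np.ndarray
) -> tuple[float, np.ndarray]:
    """Distance CV: s = |r_ion − r_COM| with unit-mass anchor COM.

    Returns (s, components) where components = r_ion − r_COM.
    """
    anchors = np.atleast_2d(np.asarray(anchor_coordinates, dtype=float))
    if anchors.size == 0:
        raise ConfigurationError("empty anchor group for the CV")
    com = anchors.mean(axis=0)
    components = np.asarray(ion_position, dtype=float) - com
    s = float(np.linalg.norm(components))
    return s, components


def distance_cv(anchor_coordinates: np.ndarray) -> Callable:
    """CV callable for the integrator: position → (s, components, ds/dx)."""
    anchors = np.atleast_2d(np.asarray(anchor_coordinates, dtype=float))
    com = anchors.mean(axis=0)

    def cv(position: np.ndarray):
        components = position - com
        s = float(np.linalg.norm(components))
        grad = components / s if s > 1e-12 else np.zeros_like(components)
        return s, components, grad

    return cv


# ---------------------------------------------------------------------------
# Restraints
# ---------------------------------------------------------------------------

@dataclass
class WallRestraint:
    """Half-harmonic walls on the CV: E = k·Δ² outside [lower, upper]."""

    lower: float = 5.0
    upper: float = 20.0
    force_constant: float = 10.0  # kJ/mol/Å²

    def __post_init__(self) -> None:
        if self.lower >= self.upper:
            raise ConfigurationError("wall lower bound must be < upper bound")

    def energy(self, s: float) -> float:
        if s > self.upper:
            return self.force_constant * (s - self.upper) ** 2
        if s < self.lower:
            return self.force_constant * (self.lower - s) ** 2
        return 0.0

    def dE_ds(self, s: float) -> float:
        if s > self.upper:
            return 2.0 * self.force_constant * (s - self.upper)
        if s < self.lower:
            return -2.0 * self.force_constant * (self.lower - s)
        return 0.0


@dataclass
class AngleRestraint:
    """Keep the angle at vertex A (between rays A→B and A→C) below a maximum.

    A is the extracellular-leaflet P COM, B the intracellular-leaflet P COM
    and C the mobile ion; the vertex sits at the first of the three points
    in that order.  E = k·(θ − θ_max)² for θ > θ_max, θ in radians.
    """

    point_a: np.ndarray
    point_b: np.ndarray
    max_angle_deg: float = 80.0
    force_constant: float = 50.0  # kJ/mol/rad²

    def angle(self, ion_position: np.ndarray) -> float:
        u = np.asarray(self.point_b, dtype=float) - np.asarray(self.point_a, dtype=float)
        v = np.asarray(ion_position, dtype=float) - np.asarray(self.point_a, dtype=float)
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        if nu < 1e-12 or nv < 1e-12:
            raise GeometryError("angle undefined: coincident restraint points")
        cos_t = np.clip(u @ v / (nu * nv), -1.0, 1.0)
        return float(np.arccos(cos_t))

    def energy_force(self, ion_position: np.ndarray) -> tuple[float, np.ndarray]:
        """Energy and the force on the ion (−∂E/∂C); A and B are fixed."""
        theta = self.angle(ion_position)
        theta_max = np.deg2rad(self.max_angle_deg)
        if theta <= theta_max:
            return 0.0, np.zeros(3)
        u = np.asarray(self.point_b, dtype=float) - np.asarray(self.point_a, dtype=float)
        v = np.asarray(ion_position, dtype=float) - np.asarray(self.point_a, dtype=float)
        nu, nv = np.linalg.norm(u), np.linalg.norm(v)
        cos_t = np.clip(u @ v / (nu * nv), -1.0, 1.0)
        sin_t = np.sqrt(max(1.0 - cos_t**2, 1e-12))
        # dθ/dv = −1/sinθ · d(cosθ)/dv
        dcos_dv = u / (nu * nv) - cos_t * v / nv**2
        dtheta_dv = -dcos_dv / sin_t
        energy = self.force_constant * (theta - theta_max) ** 2
        grad = 2.0 * self.force_constant * (theta - theta_max) * dtheta_dv
        return float(energy), -grad


# ---------------------------------------------------------------------------
# Well-tempered bias
# ---------------------------------------------------------------------------

@dataclass
class BiasState:
    """Deposited Gaussian hills on the CV plus the well-tempered schedule."""

    sigma: float = 0.35  # Å
    h0: float = 1.2  # kJ/mol
    bias_factor: float = 10.0  # γ, dimensionless
    temperature: float = 310.0  # K
    stride: int = 500  # steps between depositions
    centers: list[float] = field(default_factory=list)
    heights: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.bias_factor <= 1.0:
            raise ConfigurationError("bias factor γ must be > 1")
        if self.sigma <= 0 or self.h0 <= 0:
            raise ConfigurationError("hill width and height must be > 0")
        self._centers = np.array(self.centers, dtype=float)
        self._heights = np.array(self.heights, dtype=float)

    @property
    def delta_t(self) -> float:
        return (self.bias_factor - 1.0) * self.temperature

    @property
    def n_hills(self) -> int:
        return self._centers.size

    def bias_energy(self, s) -> np.ndarray | float:
        """V(s) = Σ_k h_k exp(−(s−s_k)²/(2σ²)); vectorized over s."""
        s_arr = np.atleast_1d(np.asarray(s, dtype=float))
        if self._centers.size == 0:
            out = np.zeros_like(s_arr)
        else:
            out = (
                self._heights[None, :]
                * np.exp(
                    -((s_arr[:, None] - self._centers[None, :]) ** 2)
                    / (2.0 * self.sigma**2)
                )
            ).sum(axis=1)
        return out if np.ndim(s) else float(out[0])

    def bias_dV_ds(self, s: float) -> float:
        if self._centers.size == 0:
            return 0.0
        d = s - self._centers
        g = self._heights * np.exp(-(d**2) / (2.0 * self.sigma**2))
        return float((g * (-d / self.sigma**2)).sum())

    def deposit_hill(self, s: float) -> float:
        """Append a hill at s with the tempered height; returns that height."""
        v_here = self.bias_energy(s)
        height = self.h0 * np.exp(-v_here / (KB * self.delta_t))
        self.centers.append(float(s))
        self.heights.append(float(height))
        self._centers = np.append(self._centers, s)
        self._heights = np.append(self._heights, height)
        return float(height)

    def hills_table(self) -> np.ndarray:
        """(n_hills, 3) array: hill index, center, height."""
        return np.column_stack(
            [np.arange(self.n_hills), self._centers, self._heights]
        )


def bias_energy(s, state: BiasState):
    return state.bias_energy(s)


def deposit_hill(s: float, state: BiasState) -> float:
    return state.deposit_hill(s)


# ---------------------------------------------------------------------------
# Overdamped Langevin integrator
# ---------------------------------------------------------------------------

@dataclass
class MetadRun:
    """Sampled output of a biased (or unbiased) Langevin run."""

    positions: np.ndarray  # (n_samples, dim)
    cv_values: np.ndarray  # (n_samples,)
    cv_components: np.ndarray  # (n_samples, dim)
    bias: BiasState | None
    sample_stride: int
    dt: float
    temperature: float
    friction: float


def run_langevin_metad(
    potential: Callable[[np.ndarray], float],
    grad_potential: Callable[[np.ndarray], np.ndarray],
    x0: np.ndarray,
    n_steps: int,
    dt: float,
    temperature: float,
    friction: float,
    seed: int,
    cv: Callable | None = None,
    bias: BiasState | None = None,
    wall: WallRestraint | None = None,
    angle: AngleRestraint | None = None,
    sample_stride: int = 10,
    position_cap: float = 1e4,
) -> MetadRun:
    """Overdamped Langevin dynamics with optional metadynamics bias.

    Total force = −∇(potential + bias(s) + wall(s) + angle); hills are
    deposited every ``bias.stride`` steps.  Fully reproducible under a
    fixed seed.  Positions beyond ``position_cap`` abort with an
    integration error (the step size is too large for the potential).
    """
    rng = np.random.default_rng(seed)
    x = np.array(x0, dtype=float).ravel()
    dim = x.size
    noise_scale = np.sqrt(2.0 * KB * temperature * dt / friction)
    mobility = dt / friction

    n_samples = n_steps // sample_stride + 1
    positions = np.empty((n_samples, dim))
    cv_values = np.empty(n_samples)
    cv_components = np.empty((n_samples, dim))
    k = 0

    for step in range(n_steps + 1):
        if cv is not None:
            s, components, ds_dx = cv(x)
        else:
            s, components, ds_dx = float(np.linalg.norm(x)), x.copy(), (
                x / max(np.linalg.norm(x), 1e-12)
            )
        if step % sample_stride == 0:
            positions[k] = x
            cv_values[k] = s
            cv_components[k] = components
            k += 1
        if step == n_steps:
            break

        force = -np.asarray(grad_potential(x), dtype=float).ravel()
        dV_ds = 0.0
        if bias is not None:
            if step % bias.stride == 0:
                bias.deposit_hill(s)
            dV_ds += bias.bias_dV_ds(s)
        if wall is not None:
            dV_ds += wall.dE_ds(s)
        if dV_ds != 0.0:
            force -= dV_ds * ds_dx
        if angle is not None and dim == 3:
            _, f_angle = angle.energy_force(x)
            force += f_angle

        x = x + mobility * force + noise_scale * rng.standard_normal(dim)
        if not np.all(np.isfinite(x)) or np.any(np.abs(x) > position_cap):
            raise IntegrationError(
                f"integration diverged at step {step}; reduce the step size"
            )

    return MetadRun(
        positions=positions[:k],
        cv_values=cv_values[:k],
        cv_components=cv_components[:k],
        bias=bias,
        sample_stride=sample_stride,
        dt=dt,
        temperature=temperature,
        friction=friction,
    )


# ---------------------------------------------------------------------------
# Free-energy reconstruction
# ---------------------------------------------------------------------------

def reconstruct_fes_1d(
    state: BiasState, grid: np.ndarray, average_from: float = 0.5
) -> np.ndarray:
    """F(s) = −(γ/(γ−1))·V(s), shifted so the minimum is 0.

    ``average_from`` enables the standard time-averaged estimator: the
    free-energy snapshots after each hill in the last (1 − average_from)
    fraction of the deposition history are aligned to zero minimum and
    averaged, damping the raggedness of the instantaneous bias.  Set it to
    1.0 to use the final bias only.
    """
    if state.n_hills == 0:
        raise AnalysisError("no hills deposited; nothing to reconstruct")
    grid = np.asarray(grid, dtype=float)
    scale = state.bias_factor / (state.bias_factor - 1.0)
    if average_from >= 1.0 or state.n_hills < 4:
        F = -scale * np.asarray(state.bias_energy(grid))
        return F - F.min()
    start = int(np.floor(average_from * state.n_hills))
    # cumulative bias on the grid after each hill
    gaussians = np.exp(
        -((grid[:, None] - state._centers[None, :]) ** 2)
        / (2.0 * state.sigma**2)
    ) * state._heights[None, :]
    cumulative = np.cumsum(gaussians, axis=1)
    snapshots = -scale * cumulative[:, start:]
    snapshots -= snapshots.min(axis=0, keepdims=True)
    F = snapshots.mean(axis=1)
    return F - F.min()


def project_fes_2d(
    run: MetadRun,
    component_pair: tuple[int, int],
    bins: int | tuple[int, int] = 40,
    ranges=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2D free-energy projection of the CV separation vector.

    The 1D bias acts on s only, so samples are reweighted with the final
    bias, w_t = exp(V_final(s_t)/k_B T), and the projected surface is
    F(a, b) = −k_B T ln Σ w_t; empty cells are masked (NaN), the minimum is
    shifted to 0.  Returns (F, a_edges, b_edges).
    """
    if run.bias is None:
        weights = np.ones_like(run.cv_values)
    else:
        v = np.asarray(run.bias.bias_energy(run.cv_values))
        v = v - v.max()  # overflow guard; constant shifts cancel in F
        weights = np.exp(v / (KB * run.temperature))
    a = run.cv_components[:, component_pair[0]]
    b = run.cv_components[:, component_pair[1]]
    hist, a_edges, b_edges = np.histogram2d(
        a, b, bins=bins, range=ranges, weights=weights
    )
    with np.errstate(divide="ignore"):
        F = -KB * run.temperature * np.log(hist)
    F[hist <= 0] = np.nan
    F -= np.nanmin(F)
    return F, a_edges, b_edges


def boltzmann_reference_fes(
    potential_1d: Callable[[np.ndarray], np.ndarray],
    grid: np.ndarray,
    temperature: float,
    oversample: int = 50,
) -> np.ndarray:
    """Numerically exact reference: per-bin −k_B T ln ∫ exp(−βU) dx.

    Independent of the metadynamics machinery; used as the oracle for
    recovered barrier heights.
    """
    beta = 1.0 / (KB * temperature)
    F = np.empty(grid.size - 1)
    for i in range(grid.size - 1):
        xs = np.linspace(grid[i], grid[i + 1], oversample)
        u = np.asarray(potential_1d(xs))
        F[i] = -np.log(np.trapezoid(np.exp(-beta * u), xs)) / beta
    return F - F.min()


def barrier_height(F: np.ndarray, grid: np.ndarray) -> float:
    """Barrier between the two deepest minima of a 1D profile.

    Locates the two lowest local minima and returns the highest point
    between them minus the deeper minimum.
    """
    finite = np.isfinite(F)
    idx = np.flatnonzero(finite)
    f = F[idx]
    minima = [
        k
        for k in range(1, len(f) - 1)
        if f[k] <= f[k - 1] and f[k] <= f[k + 1]
    ]
    if len(minima) < 2:
        raise AnalysisError("profile has fewer than two local minima")
    minima.sort(key=lambda k: f[k])
    a, b = sorted(minima[:2])
    return float(f[a : b + 1].max() - min(f[a], f[b]))


def double_well(center_a: float, center_b: float, barrier: float) -> tuple[
    Callable[[np.ndarray], np.ndarray], Callable[[np.ndarray], np.ndarray]
]:
    """Analytic 1D double well: minima at the two centers (U = 0), a barrier
    of the given height at the midpoint.  Returns (U, dU/dx)."""
    c = (center_a + center_b) / 2.0
    w = abs(center_b - center_a) / 2.0

    def u(x):
        return barrier * ((np.asarray(x, dtype=float) - c) ** 2 - w**2) ** 2 / w**4

    def du(x):
        x = np.asarray(x, dtype=float)
        return 4.0 * barrier * ((x - c) ** 2 - w**2) * (x - c) / w**4

    return u, du
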