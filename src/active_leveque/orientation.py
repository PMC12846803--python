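"""Swimmer orientation in shear: Jeffery drift, steady angle distribution,
far-field order tensors and the moment-closure source terms.

Orientation is represented by a single angle ``theta`` measured
counterclockwise from the +x (flow) axis; motion is restricted to the flow
plane.  In shear ``u = gamma_dot * y * x_hat`` a spheroid rotates clockwise
with angular velocity (in shear-rate units)

    omega(theta) = (1/2) * (beta * cos(2 theta) - 1),

the tangential projection of ``(beta*E + W) s`` for ``s = (cos, sin)`` with
the unit-shear strain and rotation tensors

    E = [[0, 1/2], [1/2, 0]],   W = [[0, 1/2], [-1/2, 0]].

The steady angular distribution solves the periodic Fokker-Planck balance

    d/dtheta [omega p] = (1/Per) d²p/dtheta²,

which we solve by Fourier spectral collocation; it feeds the agent-based
simulator's inlet orientation sampling and cross-checks the far-field
nematic order tensor of the moment-closure model.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np

from .parameters import ParameterError

__all__ = [
    "ClosureAccuracyWarning",
    "SolverError",
    "OrientationPDF",
    "OrderTensors",
    "FlowTensors",
    "unit_shear_tensors",
    "jeffery_drift",
    "steady_orientation_pdf",
    "sample_orientations",
    "far_field_Q",
    "closure_tensors",
    "moment_source_residual",
    "check_closure_validity",
]


class ClosureAccuracyWarning(UserWarning):
    """The (beta, Per) pair lies outside the stated closure accuracy envelope."""


class SolverError(RuntimeError):
    """The steady orientation solver failed to reach the requested residual."""


IDENTITY2 = np.eye(2)


@dataclass(frozen=True)
class FlowTensors:
    """Strain (symmetric) and rotation (antisymmetric) tensors of the flow."""

    strain: np.ndarray
    rotation: np.ndarray

    def __post_init__(self) -> None:
        E, W = np.asarray(self.strain), np.asarray(self.rotation)
        if not np.allclose(E, E.T, atol=1e-12):
            raise ParameterError("strain tensor must be symmetric")
        if not np.allclose(W, -W.T, atol=1e-12):
            raise ParameterError("rotation tensor must be antisymmetric")


def unit_shear_tensors() -> FlowTensors:
    """E and W for simple shear of unit rate, off-diagonal magnitude 1/2."""
    E = np.array([[0.0, 0.5], [0.5, 0.0]])
    W = np.array([[0.0, 0.5], [-0.5, 0.0]])
    return FlowTensors(strain=E, rotation=W)


@dataclass(frozen=True)
class OrderTensors:
    """Continuum order parameters: density, polar order n, nematic order Q."""

    polar: np.ndarray
    nematic: np.ndarray
    density: float = 1.0

    def __post_init__(self) -> None:
        n = np.asarray(self.polar, dtype=float)
        Q = np.asarray(self.nematic, dtype=float)
        object.__setattr__(self, "polar", n)
        object.__setattr__(self, "nematic", Q)
        if self.density < 0:
            raise ParameterError("density must be >= 0")
        if abs(np.trace(Q)) > 1e-12:
            raise ParameterError(f"nematic tensor must be traceless, trace={np.trace(Q)}")
        if not np.allclose(Q, Q.T, atol=1e-12):
            raise ParameterError("nematic tensor must be symmetric")
        if np.linalg.norm(n) > 1.0 + 1e-12:
            raise ParameterError("|polar| must not exceed 1")


def jeffery_drift(theta, beta: float):
    """Angular velocity of a spheroid in unit shear, (1/2)(beta cos 2θ − 1).

    Always <= 0 (clockwise), strictly negative for beta < 1.  Vectorised over
    ``theta``.
    """
    if not 0.0 <= beta < 1.0:
        raise ParameterError(f"beta must lie in [0, 1), got {beta}")
    return 0.5 * (beta * np.cos(2.0 * np.asarray(theta, dtype=float)) - 1.0)


# ---------------------------------------------------------------------------
# Steady orientation distribution (diffusive Jeffery orbits)
# ---------------------------------------------------------------------------


@dataclass
class OrientationPDF:
    """Steady angular probability density on [0, 2π).

    ``grid`` holds equispaced angles (endpoint excluded), ``density`` the
    matching probability densities (1/radian).  The density is π-periodic and
    integrates to one over the circle.
    """

    grid: np.ndarray
    density: np.ndarray
    beta: float
    rot_peclet: float
    residual: float = 0.0
    _coeffs: dict = field(default_factory=dict, repr=False)

    def integral(self) -> float:
        """Periodic trapezoid of the density over [0, 2π)."""
        dtheta = 2.0 * np.pi / len(self.grid)
        return float(np.sum(self.density) * dtheta)

    def moments(self) -> tuple[np.ndarray, np.ndarray]:
        """Polar vector ⟨s⟩ and nematic tensor ⟨ss⟩ − I/2 by quadrature."""
        th, p = self.grid, self.density
        dtheta = 2.0 * np.pi / len(th)
        c1 = float(np.sum(np.cos(th) * p) * dtheta)
        s1 = float(np.sum(np.sin(th) * p) * dtheta)
        c2 = float(np.sum(np.cos(2 * th) * p) * dtheta)
        s2 = float(np.sum(np.sin(2 * th) * p) * dtheta)
        polar = np.array([c1, s1])
        Q = 0.5 * np.array([[c2, s2], [s2, -c2]])
        return polar, Q

    def cdf(self) -> tuple[np.ndarray, np.ndarray]:
        """(angles, cumulative probability) on a closed grid [0, 2π]."""
        dtheta = 2.0 * np.pi / len(self.grid)
        # midpoint rule on the periodic grid: exact mass, monotone cdf
        cum = np.concatenate([[0.0], np.cumsum(self.density) * dtheta])
        cum /= cum[-1]
        ang = np.concatenate([self.grid, [2.0 * np.pi]])
        return ang, cum

    def to_table(self, path) -> None:
        """Write a two-column text table (angle, density) with a header."""
        header = (
            f"steady diffusive-Jeffery orientation distribution\n"
            f"beta = {self.beta}\nrot_peclet = {self.rot_peclet}\n"
            f"resolution = {len(self.grid)}\ncolumns: theta_rad density_per_rad"
        )
        np.savetxt(path, np.column_stack([self.grid, self.density]), header=header)

    @classmethod
    def from_table(cls, path) -> "OrientationPDF":
        with open(path) as fh:
            text = fh.read()
        meta = {}
        for line in text.splitlines():
            if line.startswith("#") and "=" in line:
                key, val = line.lstrip("# ").split("=", 1)
                meta[key.strip()] = val.strip()
        data = np.loadtxt(io.StringIO(text))
        return cls(
            grid=data[:, 0],
            density=data[:, 1],
            beta=float(meta.get("beta", np.nan)),
            rot_peclet=float(meta.get("rot_peclet", np.nan)),
        )


def _solve_fourier_modes(beta: float, per: float, n_modes: int) -> np.ndarray:
    """Complex Fourier coefficients c_k (even k, |k| <= n_modes) of the
    steady distribution, with c_0 = 1/(2π)."""
    ks = np.arange(-n_modes, n_modes + 1, 2)
    idx = {k: i for i, k in enumerate(ks)}
    m = len(ks)
    A = np.zeros((m, m), dtype=complex)
    rhs = np.zeros(m, dtype=complex)
    for k in ks:
        i = idx[k]
        if k == 0:
            A[i, i] = 1.0
            rhs[i] = 1.0 / (2.0 * np.pi)
            continue
        # ik[-(1/2) c_k + (beta/4)(c_{k-2} + c_{k+2})] + (k^2/Per) c_k = 0
        A[i, i] = -0.5j * k + k * k / per
        for kk in (k - 2, k + 2):
            if kk in idx:
                A[i, idx[kk]] += 0.25j * k * beta
    c = np.linalg.solve(A, rhs)
    return ks, c


def steady_orientation_pdf(
    beta: float,
    rot_peclet: float,
    resolution: int = 512,
    tol: float = 1e-8,
) -> OrientationPDF:
    """Steady diffusive Jeffery-orbit distribution on the circle.

    Solves ∂θ[omega(θ) p] = (1/Per) ∂²θ p by Fourier spectral collocation
    (only even harmonics are active: the distribution is π-periodic), with
    unit normalisation.  The number of retained modes is doubled until the
    max-norm residual of the discrete balance drops below ``tol``.
    """
    if resolution < 64:
        raise ParameterError(f"resolution must be >= 64, got {resolution}")
    if not 0.0 <= beta < 1.0:
        raise ParameterError(f"beta must lie in [0, 1), got {beta}")
    if rot_peclet <= 0:
        raise ParameterError(f"rot_peclet must be > 0, got {rot_peclet}")

    grid = np.linspace(0.0, 2.0 * np.pi, resolution, endpoint=False)
    n_modes = 16
    while True:
        ks, c = _solve_fourier_modes(beta, rot_peclet, n_modes)
        # interior mode equations are satisfied exactly; the residual is the
        # truncated coupling of the outermost retained modes to |k|+2
        k_edge = n_modes + 2
        res = abs(0.25 * k_edge * beta * c[-1]) * 2.0  # e^{±i k_edge θ} pair
        if res < tol:
            break
        if n_modes >= 4096:
            raise SolverError(
                f"steady orientation solver: residual {res:.3e} > tol {tol:.3e} "
                f"at {n_modes} Fourier modes (beta={beta}, Per={rot_peclet})"
            )
        n_modes *= 2

    phases = np.exp(1j * np.outer(grid, ks))
    density = np.real(phases @ c)
    min_d = density.min()
    if min_d < -1e-8:
        raise SolverError(
            f"steady orientation solver produced negative density {min_d:.3e}"
        )
    density = np.maximum(density, 0.0)
    return OrientationPDF(
        grid=grid,
        density=density,
        beta=beta,
        rot_peclet=rot_peclet,
        residual=float(res),
        _coeffs={int(k): complex(v) for k, v in zip(ks, c)},
    )


def sample_orientations(pdf: OrientationPDF, n: int, seed=None) -> np.ndarray:
    """Draw ``n`` i.i.d. angles from ``pdf`` by inverse-transform sampling.

    ``seed`` may be an int, a ``numpy.random.Generator`` or ``SeedSequence``.
    Reproducible for a fixed seed.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ang, cum = pdf.cdf()
    u = rng.random(n)
    return np.interp(u, cum, ang)


# ---------------------------------------------------------------------------
# Far-field order and moment closures
# ---------------------------------------------------------------------------


def check_closure_validity(beta: float, rot_peclet: float) -> bool:
    """Warn (do not raise) when (beta, Per) leave the closure accuracy envelope.

    The moment closure tracks the agent-based model well for Per ≲ 1 when
    beta ∈ (0.5, 1), Per ≲ 10 when beta ∈ (0, 0.5], and Per ≲ 100 for circular
    swimmers.  Returns True when inside the envelope.
    """
    if beta > 0.5:
        limit = 1.0
    elif beta > 0.0:
        limit = 10.0
    else:
        limit = 100.0
    if rot_peclet > limit:
        warnings.warn(
            f"moment closure accuracy degrades for Per={rot_peclet:g} > {limit:g} "
            f"at beta={beta:g}",
            ClosureAccuracyWarning,
            stacklevel=3,
        )
        return False
    return True


def far_field_Q(beta: float, rot_peclet: float) -> np.ndarray:
    """Far-field nematic order tensor in shear (leading order in beta).

    Q = [beta*Per / (4*(16+Per²))] * [[Per, 4], [4, -Per]] — symmetric and
    traceless; zero for spherical swimmers.
    """
    if not 0.0 <= beta < 1.0:
        raise ParameterError(f"beta must lie in [0, 1), got {beta}")
    if rot_peclet <= 0:
        raise ParameterError(f"rot_peclet must be > 0, got {rot_peclet}")
    check_closure_validity(beta, rot_peclet)
    per = rot_peclet
    pref = beta * per / (4.0 * (16.0 + per * per))
    return pref * np.array([[per, 4.0], [4.0, -per]])


def closure_tensors(state: OrderTensors) -> tuple[np.ndarray, np.ndarray]:
    """Rank-3 and rank-4 closure tensors from (rho, n, Q).

    T_ijk = rho/4 (δij n_k + δik n_j + δjk n_i)
    G_ijkl = rho/8 (δij δkl + δik δjl + δil δjk)
           + rho/6 (δij Q_kl + δik Q_jl + δil Q_jk + δjk Q_il + δjl Q_ik + δkl Q_ij)

    Both are fully symmetric under index permutation.
    """
    rho, n, Q = state.density, state.polar, state.nematic
    d = IDENTITY2
    T = (rho / 4.0) * (
        np.einsum("ij,k->ijk", d, n)
        + np.einsum("ik,j->ijk", d, n)
        + np.einsum("jk,i->ijk", d, n)
    )
    G = (rho / 8.0) * (
        np.einsum("ij,kl->ijkl", d, d)
        + np.einsum("ik,jl->ijkl", d, d)
        + np.einsum("il,jk->ijkl", d, d)
    ) + (rho / 6.0) * (
        np.einsum("ij,kl->ijkl", d, Q)
        + np.einsum("ik,jl->ijkl", d, Q)
        + np.einsum("il,jk->ijkl", d, Q)
        + np.einsum("jk,il->ijkl", d, Q)
        + np.einsum("jl,ik->ijkl", d, Q)
        + np.einsum("kl,ij->ijkl", d, Q)
    )
    return T, G


def moment_source_residual(
    state: OrderTensors, beta: float, rot_peclet: float
) -> tuple[np.ndarray, np.ndarray]:
    """Source terms of the far-field polar and nematic moment equations.

    With the flow tensors fixed to unit shear, returns

    * polar residual  (ρ I n − T):(βE + W) − ρn/Per   (a 2-vector), and
    * nematic residual βρ[E M + M E] + ρ(W Q − Q W) − 2β G:E − 4ρQ/Per with
      M = Q + I/2   (a 2×2 tensor).

    A spatially uniform state is a steady far-field solution iff both vanish.
    """
    if rot_peclet <= 0:
        raise ParameterError(f"rot_peclet must be > 0, got {rot_peclet}")
    check_closure_validity(beta, rot_peclet)
    ft = unit_shear_tensors()
    E, W = ft.strain, ft.rotation
    A = beta * E + W
    rho, n, Q = state.density, state.polar, state.nematic
    T, G = closure_tensors(state)

    res_n = A @ (rho * n) - np.einsum("ijk,jk->i", T, A) - rho * n / rot_peclet

    M = Q + 0.5 * IDENTITY2
    res_Q = (
        beta * rho * (E @ M + M @ E)
        + rho * (W @ Q - Q @ W)
        - 2.0 * beta * np.einsum("ijkl,kl->ij", G, E)
        - 4.0 * rho * Q / rot_peclet
    )
    return res_n, res_Q
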