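"""Closed-form active Lévêque theory of bacterial adhesion in shear flow.

Adhesion of motile bacteria to an absorbing surface under shear is controlled
by a depletion boundary layer in which a small orientation anisotropy,
produced by the balance of shear alignment, rotational diffusion and swimming
down density gradients, drives a wall-ward swimming flux.  The reduced
density equation has classic Lévêque form,

    y ∂ρ/∂x − (1/Pe_eff) ∂²ρ/∂y² = 0,

with an *effective* Péclet number

    Pe_eff = (16+Per²)(16+(4−β²)Per²) / [4 Per Vs² (32+(2−β)(1−β)Per²)],

where ``Vs`` is the relative swimming speed and ``Per`` the rotational
Péclet number.  The similarity solution gives the density field as a lower
incomplete gamma function, a local adhesion rate decaying as x^(−1/3) with
Lévêque prefactor 3^(1/3)/Γ(1/3) ≈ 0.538, and — in dimensional form — an
adhesion rate proportional to Deff^(2/3) γ̇^(1/3) whose nonmonotone shear
dependence produces a critical shear rate of maximal adhesion.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special

from .orientation import check_closure_validity
from .parameters import (
    BacteriumParams,
    DimensionlessGroups,
    FlowParams,
    ParameterError,
)

__all__ = [
    "LEVEQUE_PREFACTOR",
    "BoundaryLayerScales",
    "TheoryCurve",
    "RegimeLabel",
    "effective_peclet",
    "effective_diffusivity",
    "boundary_layer_orientation",
    "density_field",
    "adhesion_rate",
    "dimensional_adhesion_rate",
    "critical_shear",
    "net_adhesion",
    "collapsed_net_adhesion",
    "scaling_factor",
    "scaled_net_adhesion",
    "classify_regime",
    "theory_curve",
    "halfdensity_contour",
]

#: Lévêque wall-flux prefactor 3^(1/3)/Γ(1/3) ≈ 0.538.
LEVEQUE_PREFACTOR = 3.0 ** (1.0 / 3.0) / special.gamma(1.0 / 3.0)

GAMMA_THIRD = special.gamma(1.0 / 3.0)


def effective_peclet(groups: DimensionlessGroups, beta: float) -> float:
    """Effective Péclet number of the active Lévêque boundary layer.

    Diverges as the flow stops (Per → 0 with fixed Vs) toward the quiescent
    Péclet number 2/(Vs² Per); raises for degenerate inputs.
    """
    vs, per = groups.rel_swim_speed, groups.rot_peclet
    if per <= 0 or vs <= 0:
        raise ParameterError(
            "effective_peclet requires Per > 0 and Vs > 0; the Per→0 or Vs→0 "
            "(quiescent / nonmotile) limit has divergent Peclet number"
        )
    if not 0.0 <= beta < 1.0:
        raise ParameterError(f"beta must lie in [0, 1), got {beta}")
    check_closure_validity(beta, per)
    num = (16.0 + per**2) * (16.0 + (4.0 - beta**2) * per**2)
    den = 4.0 * per * vs**2 * (32.0 + (2.0 - beta) * (1.0 - beta) * per**2)
    return num / den


def quiescent_peclet(groups: DimensionlessGroups) -> float:
    """Classic Péclet number 2/(Vs² Per) = U L / Dquies (motility only)."""
    vs, per = groups.rel_swim_speed, groups.rot_peclet
    if per <= 0 or vs <= 0:
        raise ParameterError("quiescent_peclet requires Per > 0 and Vs > 0")
    return 2.0 / (vs**2 * per)


@dataclass(frozen=True)
class BoundaryLayerScales:
    """Effective and quiescent Péclet numbers and the depletion-layer
    thickness (x/Pe_eff)^(1/3) as a function of downstream position."""

    eff_peclet: float
    quies_peclet: float

    def thickness_at(self, x) -> np.ndarray:
        """Dimensionless boundary-layer thickness at downstream position x."""
        return (np.asarray(x, dtype=float) / self.eff_peclet) ** (1.0 / 3.0)


def boundary_layer_scales(groups: DimensionlessGroups, beta: float) -> BoundaryLayerScales:
    return BoundaryLayerScales(
        eff_peclet=effective_peclet(groups, beta),
        quies_peclet=quiescent_peclet(groups),
    )


def effective_diffusivity(b: BacteriumParams, shear_rate: float) -> float:
    """Shear-dependent effective diffusivity Deff (+ thermal DT), in µm²/s.

    Deff = 4 Dr Vs² (32 Dr² + (2−β)(1−β) γ̇²)
           / [(16 Dr² + (4−β²) γ̇²)(16 Dr² + γ̇²)]  +  DT.

    Reduces to the quiescent value Vs²/(2 Dr) + DT as γ̇ → 0 and decays as
    γ̇⁻² at high shear (shear-induced alignment suppresses wall-ward
    dispersion).
    """
    if shear_rate <= 0:
        raise ParameterError(f"shear_rate must be > 0, got {shear_rate}")
    vs, dr, beta = b.swim_speed, b.rot_diffusion, b.bretherton
    g2, dr2 = shear_rate**2, dr**2
    num = 4.0 * dr * vs**2 * (32.0 * dr2 + (2.0 - beta) * (1.0 - beta) * g2)
    den = (16.0 * dr2 + (4.0 - beta**2) * g2) * (16.0 * dr2 + g2)
    return num / den + b.thermal_diffusivity


def boundary_layer_orientation(
    density_gradient: float,
    groups: DimensionlessGroups,
    beta: float,
    epsilon: float,
) -> tuple[float, float]:
    """Leading-order mean-orientation flux (ρñx, ρñy) in the boundary layer.

    Both components are linear in the supplied vertical density gradient
    ∂ρ̃/∂ỹ.  A positive gradient (density increasing away from the wall)
    yields ρñy < 0: net swimming toward the wall; the streamwise component is
    negative as well (upstream swimming bias).
    """
    if epsilon <= 0:
        raise ParameterError(f"epsilon must be > 0, got {epsilon}")
    vs, per = groups.rel_swim_speed, groups.rot_peclet
    den = epsilon * (16.0 + per**2) * (16.0 + (4.0 - beta**2) * per**2)
    cy = -4.0 * per * vs * (32.0 + (2.0 - beta) * (1.0 - beta) * per**2) / den
    cx = -(per**2) * vs * (64.0 + 46.0 * beta + (4.0 - beta**2) * per**2) / den
    return cx * density_gradient, cy * density_gradient


def density_field(x, y, eff_peclet: float):
    """Similarity solution for the depleted density, in [0, 1].

    ρ(x, y) = γ(1/3, Pe_eff y³ / 9x) / Γ(1/3) using the regularised lower
    incomplete gamma function; 0 at the absorbing wall, → 1 in the far field,
    monotone increasing in y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.any(x <= 0):
        raise ParameterError("density_field requires x > 0")
    if np.any(y < 0):
        raise ParameterError("density_field requires y >= 0")
    return special.gammainc(1.0 / 3.0, eff_peclet * y**3 / (9.0 * x))


def adhesion_rate(x, eff_peclet: float):
    """Dimensionless local adhesion rate J(x) = 0.538 / (Pe_eff^(2/3) x^(1/3)).

    Equals the diffusive wall flux (1/Pe_eff) ∂ρ/∂y at y=0 of
    :func:`density_field`.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ParameterError("adhesion_rate requires x > 0")
    return LEVEQUE_PREFACTOR / (eff_peclet ** (2.0 / 3.0) * x ** (1.0 / 3.0))


def dimensional_adhesion_rate(
    x_dim,
    b: BacteriumParams,
    shear_rate: float,
    inlet_density: float = 1.0,
) -> np.ndarray:
    """Dimensional local adhesion rate Ĵ(x̂) in cells µm⁻¹ s⁻¹.

    Ĵ(x̂) = 3^(1/3) ρ∞ Deff^(2/3) γ̇^(1/3) / (Γ(1/3) x̂^(1/3)) with x̂ in µm
    and ρ∞ the inlet (bulk) cell density.  Linear in ρ∞; nonmonotone in γ̇
    through Deff.
    """
    x_dim = np.asarray(x_dim, dtype=float)
    if np.any(x_dim <= 0):
        raise ParameterError("dimensional_adhesion_rate requires x > 0")
    deff = effective_diffusivity(b, shear_rate)
    return (
        LEVEQUE_PREFACTOR
        * inlet_density
        * deff ** (2.0 / 3.0)
        * shear_rate ** (1.0 / 3.0)
        / x_dim ** (1.0 / 3.0)
    )


def critical_shear(
    b: BacteriumParams,
    tol: float = 1e-10,
    bracket_decades: float = 3.0,
) -> float:
    """Shear rate maximising the dimensional adhesion rate, in 1/s.

    Maximises Deff^(2/3) γ̇^(1/3) (the γ̇-dependence of the adhesion rate at
    fixed position) over log γ̇ on [Dr·10^-d, Dr·10^d] by Brent bracketed
    minimisation; the objective is unimodal.  For spherical swimmers without
    thermal diffusion the maximiser is 2 Dr / √3.
    """
    if tol <= 0:
        raise ParameterError(f"tol must be > 0, got {tol}")
    dr = b.rot_diffusion
    lo, hi = math.log(dr) - bracket_decades * math.log(10), math.log(
        dr
    ) + bracket_decades * math.log(10)

    def neg_obj(lng: float) -> float:
        g = math.exp(lng)
        return -(effective_diffusivity(b, g) ** (2.0 / 3.0) * g ** (1.0 / 3.0))

    res = optimize.minimize_scalar(
        neg_obj, bounds=(lo, hi), method="bounded", options={"xatol": tol}
    )
    if not res.success:
        raise RuntimeError(f"critical_shear optimisation failed: {res.message}")
    if res.x - lo < 1e-6 or hi - res.x < 1e-6:
        raise RuntimeError(
            "critical_shear: maximum not bracketed by "
            f"[{math.exp(lo):g}, {math.exp(hi):g}] 1/s"
        )
    return math.exp(res.x)


def net_adhesion(surface_length: float, eff_peclet: float) -> float:
    """Net dimensionless adhesion ∫₀ˡ J dx = (3/2)·0.538·l^(2/3)·Pe_eff^(−2/3)."""
    if surface_length <= 0:
        raise ParameterError(f"surface_length must be > 0, got {surface_length}")
    return (
        1.5 * LEVEQUE_PREFACTOR * surface_length ** (2.0 / 3.0) * eff_peclet ** (-2.0 / 3.0)
    )


def scaling_factor(beta: float, groups: DimensionlessGroups) -> float:
    """Shape/speed scaling S(β, Per, Vs) used for the net-adhesion collapse.

    S = (16+(4−β²)Per²)^(2/3) / [Vs^(4/3) (32+(2−β)(1−β)Per²)^(2/3)].
    """
    vs, per = groups.rel_swim_speed, groups.rot_peclet
    if vs <= 0 or per <= 0:
        raise ParameterError("scaling_factor requires Vs > 0 and Per > 0")
    return (16.0 + (4.0 - beta**2) * per**2) ** (2.0 / 3.0) / (
        vs ** (4.0 / 3.0) * (32.0 + (2.0 - beta) * (1.0 - beta) * per**2) ** (2.0 / 3.0)
    )


def scaled_net_adhesion(
    net_rate: float,
    beta: float,
    groups: DimensionlessGroups,
    inlet_density: float = 1.0,
) -> float:
    """Scaled net adhesion J̄ = S(β, Per, Vs) · net_rate / ρ∞.

    Applied to the theoretical :func:`net_adhesion` this collapses onto a
    function of (Per, l) alone — see :func:`collapsed_net_adhesion`.
    """
    return scaling_factor(beta, groups) * net_rate / inlet_density


def collapsed_net_adhesion(surface_length: float, rot_peclet: float) -> float:
    """Theory value of J̄: (3/2)·0.538·l^(2/3)·(4 Per/(16+Per²))^(2/3).

    Independent of shape and swimming speed; maximal at Per = 4; vanishes in
    both the Per → 0 and Per → ∞ limits.
    """
    if surface_length <= 0 or rot_peclet <= 0:
        raise ParameterError("surface_length and rot_peclet must be > 0")
    return (
        1.5
        * LEVEQUE_PREFACTOR
        * surface_length ** (2.0 / 3.0)
        * (4.0 * rot_peclet / (16.0 + rot_peclet**2)) ** (2.0 / 3.0)
    )


# ---------------------------------------------------------------------------
# Validity-regime classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RegimeLabel:
    """Validity-regime label with the thresholds used at evaluation.

    ``VALID`` marks the region where the boundary-layer analysis formally
    holds.  The failure regions, checked in this fixed precedence order, are

    * ``A`` — swimming comparable to the flow speed (Vs ≥ 1);
    * ``B`` — boundary layer thinner than a cell body
      (computed ε = Pe_eff^(−1/3) ≤ eps_threshold);
    * ``C`` — shear-induced reorientation dominant (Per ≥ 1/eps_threshold);
    * ``D`` — swimming weak relative to the flow to the point that active
      stresses matter (Vs ≤ eps_threshold).
    """

    label: str
    rel_swim_speed: float
    rot_peclet: float
    epsilon: float
    eps_threshold: float


def classify_regime(
    groups: DimensionlessGroups,
    beta: float,
    eps_threshold: float = 5e-4,
    x_eval: float = 1.0,
) -> RegimeLabel:
    """Classify (Vs, Per, β) into VALID or failure regions A–D.

    The boundary-layer thickness ε is evaluated as (x_eval/Pe_eff)^(1/3) at
    the O(1) downstream position ``x_eval`` (default 1).  The fixed
    ``eps_threshold`` (default 5×10⁻⁴, a 5 µm cell body over a 1 cm flow
    lengthscale) sets the B, C and D thresholds.
    """
    if eps_threshold <= 0 or x_eval <= 0:
        raise ParameterError("eps_threshold and x_eval must be > 0")
    vs, per = groups.rel_swim_speed, groups.rot_peclet
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")  # classification is meaningful everywhere
        pe_eff = effective_peclet(groups, beta)
    eps = (x_eval / pe_eff) ** (1.0 / 3.0)
    if vs >= 1.0:
        label = "A"
    elif eps <= eps_threshold:
        label = "B"
    elif per >= 1.0 / eps_threshold:
        label = "C"
    elif vs <= eps_threshold:
        label = "D"
    else:
        label = "VALID"
    return RegimeLabel(
        label=label,
        rel_swim_speed=vs,
        rot_peclet=per,
        epsilon=eps,
        eps_threshold=eps_threshold,
    )


# ---------------------------------------------------------------------------
# Theory curves and export
# ---------------------------------------------------------------------------


@dataclass
class TheoryCurve:
    """Analytic local adhesion-rate profile and its net integral.

    ``dimensional`` flags whether positions are in µm and rates in
    cells µm⁻¹ s⁻¹ (True) or everything is dimensionless (False).
    """

    positions: np.ndarray
    local_rate: np.ndarray
    net_rate: float
    beta: float
    groups: DimensionlessGroups
    dimensional: bool = False
    meta: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            fh.write(f"# active Leveque theory curve\n")
            fh.write(
                f"# beta = {self.beta}; Vs = {self.groups.rel_swim_speed}; "
                f"Per = {self.groups.rot_peclet}\n"
            )
            fh.write(f"# dimensional = {self.dimensional}\n")
            fh.write(f"# net_rate = {self.net_rate!r}\n")
            writer = csv.writer(fh)
            writer.writerow(["x", "local_rate"])
            for xx, jj in zip(self.positions, self.local_rate):
                writer.writerow([repr(float(xx)), repr(float(jj))])


def theory_curve(
    groups: DimensionlessGroups,
    beta: float,
    surface_length: float = 3.0,
    n_points: int = 200,
) -> TheoryCurve:
    """Dimensionless J(x) on a grid over (0, l] plus the closed-form net rate."""
    pe_eff = effective_peclet(groups, beta)
    x = np.linspace(surface_length / n_points, surface_length, n_points)
    return TheoryCurve(
        positions=x,
        local_rate=adhesion_rate(x, pe_eff),
        net_rate=net_adhesion(surface_length, pe_eff),
        beta=beta,
        groups=groups,
        dimensional=False,
        meta={"eff_peclet": pe_eff},
    )


def halfdensity_contour(x, eff_peclet: float):
    """y(x) along which the similarity density equals 1/2.

    y = (9x/Pe_eff)^(1/3) z½^(1/3) with z½ the root of γ(1/3, z) = Γ(1/3)/2.
    """
    z_half = special.gammaincinv(1.0 / 3.0, 0.5)
    return (9.0 * np.asarray(x, dtype=float) / eff_peclet) ** (1.0 / 3.0) * z_half ** (
        1.0 / 3.0
    )


def regime_records_to_json(records: list[dict], path) -> None:
    """Write regime-map records ({Vs, Per, Peeff, label}) as JSON."""
    with open(path, "w") as fh:
        json.dump(records, fh, indent=1)


def dimensionalize_net_rate(
    net_rate: float, flow: FlowParams, inlet_density: float = 1.0
) -> float:
    """Convert the dimensionless net adhesion ∫ J dx to cells/s (per unit
    depth): multiply by ρ∞ γ̇ L² (flux scale ρ∞·U times length scale L)."""
    return net_rate * inlet_density * flow.shear_rate * flow.lengthscale**2


def nondimensionalize_net_rate(
    dimensional_net_rate: float, flow: FlowParams, inlet_density: float = 1.0
) -> float:
    """Inverse of :func:`dimensionalize_net_rate`."""
    return dimensional_net_rate / (
        inlet_density * flow.shear_rate * flow.lengthscale**2
    )
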