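"""Dimensional motility and flow parameters, and their dimensionless groups.

Canonical internal units are micrometres and seconds throughout the package.
A swimmer is characterised by its swimming speed ``Vs`` (µm/s), rotational
diffusion coefficient ``Dr`` (1/s), Bretherton shape parameter ``beta``
(0 for a sphere, approaching 1 for an infinitely elongated spheroid) and an
optional thermal (Brownian) diffusivity ``DT`` (µm²/s).  A flow is
characterised by its shear rate ``gamma_dot`` (1/s) and a lengthscale ``L``
(µm); the reference velocity scale is ``U = gamma_dot * L``.

The nondimensional model is controlled by two groups:

* the relative swimming speed ``Vs / (gamma_dot * L)`` — swimmer speed over
  flow speed, and
* the rotational Péclet number ``gamma_dot / Dr`` — fluid rotation over
  rotational diffusion.

Run-and-tumble species are represented by substituting the tumble rate for
``Dr``; no separate tumble process is modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

__all__ = [
    "ParameterError",
    "BacteriumParams",
    "FlowParams",
    "DimensionlessGroups",
    "Scenario",
    "dimensionless_groups",
    "quiescent_diffusivity",
    "E_COLI",
    "P_AERUGINOSA",
    "SPECIES",
    "SCENARIOS",
    "get_species",
    "get_scenario",
    "load_config",
]


class ParameterError(ValueError):
    """A physical parameter is outside its admissible range."""


@dataclass(frozen=True)
class BacteriumParams:
    """Dimensional motility parameters of a bacterial species.

    Parameters
    ----------
    swim_speed : float
        Swimming speed ``Vs`` in µm/s; must be >= 0.
    rot_diffusion : float
        Rotational diffusion coefficient ``Dr`` in 1/s (tumble rate for
        run-and-tumble species); must be > 0.
    bretherton : float
        Shape parameter ``beta`` in [0, 1).
    thermal_diffusivity : float, optional
        Brownian translational diffusivity ``DT`` in µm²/s, default 0.
    """

    swim_speed: float
    rot_diffusion: float
    bretherton: float
    thermal_diffusivity: float = 0.0

    def __post_init__(self) -> None:
        if self.swim_speed < 0:
            raise ParameterError(f"swim_speed must be >= 0, got {self.swim_speed}")
        if self.rot_diffusion <= 0:
            raise ParameterError(
                f"rot_diffusion must be > 0, got {self.rot_diffusion}"
            )
        if not 0.0 <= self.bretherton < 1.0:
            raise ParameterError(
                f"bretherton must lie in [0, 1), got {self.bretherton}"
            )
        if self.thermal_diffusivity < 0:
            raise ParameterError(
                f"thermal_diffusivity must be >= 0, got {self.thermal_diffusivity}"
            )


@dataclass(frozen=True)
class FlowParams:
    """Shear rate ``gamma_dot`` (1/s) and flow lengthscale ``L`` (µm)."""

    shear_rate: float
    lengthscale: float

    def __post_init__(self) -> None:
        if self.shear_rate <= 0:
            raise ParameterError(f"shear_rate must be > 0, got {self.shear_rate}")
        if self.lengthscale <= 0:
            raise ParameterError(
                f"lengthscale must be > 0, got {self.lengthscale}"
            )

    @property
    def velocity_scale(self) -> float:
        """Reference velocity ``U = gamma_dot * L`` in µm/s (derived)."""
        return self.shear_rate * self.lengthscale


@dataclass(frozen=True)
class DimensionlessGroups:
    """Relative swimming speed and rotational Péclet number."""

    rel_swim_speed: float
    rot_peclet: float

    def __post_init__(self) -> None:
        if self.rel_swim_speed < 0:
            raise ParameterError(
                f"rel_swim_speed must be >= 0, got {self.rel_swim_speed}"
            )
        if self.rot_peclet <= 0:
            raise ParameterError(f"rot_peclet must be > 0, got {self.rot_peclet}")


def dimensionless_groups(b: BacteriumParams, f: FlowParams) -> DimensionlessGroups:
    """Form the dimensionless groups for a swimmer in a given flow.

    Returns the relative swimming speed ``Vs/(gamma_dot*L)`` and the
    rotational Péclet number ``gamma_dot/Dr``.
    """
    return DimensionlessGroups(
        rel_swim_speed=b.swim_speed / (f.shear_rate * f.lengthscale),
        rot_peclet=f.shear_rate / b.rot_diffusion,
    )


def quiescent_diffusivity(b: BacteriumParams) -> float:
    """Emergent diffusivity ``Vs²/(2 Dr)`` of a swimmer in quiescent fluid (µm²/s).

    This is the isotropic, motility-generated dispersion coefficient of a
    persistent random walker in 2D, valid in the absence of flow.
    """
    return b.swim_speed**2 / (2.0 * b.rot_diffusion)


# ---------------------------------------------------------------------------
# Built-in parameter sets
# ---------------------------------------------------------------------------

#: E. coli (strains HCB437 / RP437): Vs = 22 µm/s, tumble rate 1/s standing in
#: for Dr, beta = 0.88, thermal diffusivity 0.2 µm²/s.
E_COLI = BacteriumParams(
    swim_speed=22.0, rot_diffusion=1.0, bretherton=0.88, thermal_diffusivity=0.2
)

#: P. aeruginosa (PAO1): Vs = 23 µm/s, Dr = 0.036 1/s, beta = 0.88.
P_AERUGINOSA = BacteriumParams(
    swim_speed=23.0, rot_diffusion=0.036, bretherton=0.88
)

SPECIES: dict[str, BacteriumParams] = {
    "e_coli": E_COLI,
    "p_aeruginosa": P_AERUGINOSA,
}


@dataclass(frozen=True)
class Scenario:
    """A flow setting prone to biofilm formation: wall-shear-rate range (1/s)
    and flow lengthscale (µm)."""

    name: str
    shear_min: float
    shear_max: float
    lengthscale: float

    def flow(self, shear_rate: float | None = None) -> FlowParams:
        """FlowParams at the given shear rate (geometric mid-range default)."""
        if shear_rate is None:
            shear_rate = (self.shear_min * self.shear_max) ** 0.5
        return FlowParams(shear_rate=shear_rate, lengthscale=self.lengthscale)


SCENARIOS: dict[str, Scenario] = {
    "small_catheter": Scenario("small_catheter", 0.12, 5.09, 1.0e3),
    "large_catheter": Scenario("large_catheter", 0.038, 1.51, 1.5e3),
    "small_intestine": Scenario("small_intestine", 0.2, 80.0, 1.25e4),
    "river": Scenario("river", 5.9, 21.7, 1.0e4),
    "coronary_artery": Scenario("coronary_artery", 100.0, 350.0, 2.6e3),
}


def get_species(name: str) -> BacteriumParams:
    """Resolve a built-in species by string identifier."""
    try:
        return SPECIES[name]
    except KeyError:
        raise ParameterError(
            f"unknown species {name!r}; available: {sorted(SPECIES)}"
        ) from None


def get_scenario(name: str) -> Scenario:
    """Resolve a built-in flow scenario by string identifier."""
    try:
        return SCENARIOS[name]
    except KeyError:
        raise ParameterError(
            f"unknown scenario {name!r}; available: {sorted(SCENARIOS)}"
        ) from None


def load_config(path: str | Path) -> dict:
    """Load parameter sets from a YAML config file.

    Recognised top-level sections:

    ``bacterium``
        Either a mapping of :class:`BacteriumParams` fields or a string naming
        a built-in species.
    ``flow``
        Mapping of :class:`FlowParams` fields, or a string naming a built-in
        scenario (evaluated at its mid-range shear rate).
    ``sim``
        Mapping passed through unchanged (consumed by the simulator module).

    Returns a dict with the parsed objects under the same keys.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict = {}
    if "bacterium" in raw:
        spec = raw["bacterium"]
        out["bacterium"] = (
            get_species(spec) if isinstance(spec, str) else BacteriumParams(**spec)
        )
    if "flow" in raw:
        spec = raw["flow"]
        out["flow"] = (
            get_scenario(spec).flow() if isinstance(spec, str) else FlowParams(**spec)
        )
    if "sim" in raw:
        out["sim"] = dict(raw["sim"])
    return out


def dump_params(b: BacteriumParams, f: FlowParams | None = None) -> dict:
    """Plain-dict echo of parameter sets (for manifests and file headers)."""
    out = {"bacterium": asdict(b)}
    if f is not None:
        out["flow"] = asdict(f)
    return out
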