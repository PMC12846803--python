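"""Agent-based Langevin simulator of motile spheroids in shear with an
absorbing wall.

Each agent carries a position (x, y) and an orientation angle theta and obeys,
in shear-rate units (Euler–Maruyama, fixed timestep dt):

    x     += (y + Vs cos theta) dt
    y     += Vs sin theta dt
    theta += (1/2)(beta cos 2theta - 1) dt + sqrt(2 dt / Per) xi

with xi standard normal.  Agents are injected at x = 0 with heights drawn
from the flux-weighted inlet density p(y) = 2y/H² and orientations from the
steady diffusive-Jeffery distribution, are absorbed by the wall at y = 0
(adhesion event, position interpolated to the crossing), leave through
x = l (outflow), and are reflected specularly at the top boundary y = H.

Measurement follows a windowed protocol: events before a burn-in time are
discarded, the remainder is split into equal windows and the net adhesion
rate is reported as mean and SD over windows.  Occupancy histograms are
normalised by the expected passive (motility-free) count per bin so the far
field reads one.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from . import orientation as _orient
from .parameters import DimensionlessGroups, ParameterError


__all__ = [
    "ConfigError",
    "SimConfig",
    "AgentState",
    "AdhesionSummary",
    "DensityField",
    "sample_inlet_positions",
    "step_agents",
    "run_simulation",
    "net_adhesion_rate",
    "density_histogram",
    "simulate_orientation_samples",
]


class ConfigError(ValueError):
    """Simulation configuration violates its invariants."""


@dataclass
class SimConfig:
    """Full protocol configuration for one simulation run.

    All quantities are dimensionless (shear-rate time units, flow
    lengthscale).  ``n_inject`` may be fractional: a deterministic
    accumulator injects whole agents at the exact average rate.
    """

    rel_swim_speed: float
    rot_peclet: float
    beta: float
    domain_height: float
    t_end: float
    dt: float = 1e-2
    domain_length: float = 3.0
    n_inject: float = 1.0
    t_burnin: float = 300.0
    window_length: float | None = None
    seed: int = 0
    top_boundary: str = "reflect"  # or "absorb"
    inlet_orientation: str = "jeffery"  # or "uniform"
    disable_noise: bool = False
    record_density: bool = True
    density_bins: tuple[int, int] = (30, 80)
    sample_every: int = 10

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigError(f"dt must be > 0, got {self.dt}")
        if self.domain_height <= 0 or self.domain_length <= 0:
            raise ConfigError("domain dimensions must be > 0")
        if self.rot_peclet <= 0:
            raise ConfigError(f"rot_peclet must be > 0, got {self.rot_peclet}")
        if self.rel_swim_speed < 0:
            raise ConfigError("rel_swim_speed must be >= 0")
        if not 0.0 <= self.beta < 1.0:
            raise ConfigError(f"beta must lie in [0, 1), got {self.beta}")
        if not self.t_burnin < self.t_end:
            raise ConfigError("t_burnin must be < t_end")
        if self.window_length is None:
            self.window_length = self.t_end - self.t_burnin
        if self.n_windows < 1:
            raise ConfigError(
                "(t_end - t_burnin) must contain at least one whole window"
            )
        if self.top_boundary not in ("reflect", "absorb"):
            raise ConfigError(f"unknown top_boundary policy {self.top_boundary!r}")
        if self.inlet_orientation not in ("jeffery", "uniform"):
            raise ConfigError(
                f"unknown inlet_orientation policy {self.inlet_orientation!r}"
            )
        if min(self.density_bins) < 2:
            raise ConfigError("density_bins must be >= 2 per axis")

    @property
    def n_windows(self) -> int:
        return int((self.t_end - self.t_burnin) / self.window_length + 1e-9)

    @property
    def groups(self) -> DimensionlessGroups:
        return DimensionlessGroups(
            rel_swim_speed=self.rel_swim_speed, rot_peclet=self.rot_peclet
        )

    @property
    def inlet_density_equiv(self) -> float:
        """Continuum inlet density equivalent to the injection rate.

        Equates the agent inlet number flux n_inject/dt to the continuum
        inlet flux ∫₀ᴴ ρ∞ y dy = ρ∞ H²/2, giving ρ∞ = (n_inject/dt)/(H²/2).
        Divides the measured event rate to give the dimensionless net
        adhesion ∫ J dx.
        """
        return (self.n_inject / self.dt) / (self.domain_height**2 / 2.0)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "density_bins" in raw:
            raw["density_bins"] = tuple(raw["density_bins"])
        return cls(**raw)


@dataclass
class AgentState:
    """Positions and orientations of the live agents (parallel arrays)."""

    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray

    @classmethod
    def empty(cls) -> "AgentState":
        z = np.empty(0, dtype=float)
        return cls(x=z.copy(), y=z.copy(), theta=z.copy())

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class StepResult:
    """Outcome of one Euler–Maruyama step over the live population."""

    state: AgentState
    adhered_t: np.ndarray  # sub-step interpolated event times
    adhered_x: np.ndarray  # event positions on the surface, in [0, l]
    n_exited: int


@dataclass
class AdhesionSummary:
    """Adhesion event log and windowed net-adhesion-rate estimate."""

    events_t: np.ndarray
    events_x: np.ndarray
    rate_mean: float
    rate_sd: float
    n_windows: int
    single_window: bool
    window_rates: np.ndarray
    inlet_density_equiv: float
    n_injected: int = 0
    n_adhered: int = 0
    n_exited: int = 0
    n_live: int = 0

    @property
    def net_adhesion(self) -> float:
        """Dimensionless net adhesion ∫ J dx (rate over inlet density)."""
        return self.rate_mean / self.inlet_density_equiv

    @property
    def net_adhesion_sd(self) -> float:
        return self.rate_sd / self.inlet_density_equiv

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["time", "x"])
            for t, x in zip(self.events_t, self.events_x):
                writer.writerow([repr(float(t)), repr(float(x))])


@dataclass
class DensityField:
    """Time-averaged occupancy histogram with passive-expectation normalisation."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    counts: np.ndarray
    n_snapshots: int
    expected_per_bin: np.ndarray  # passive expectation per bin per snapshot
    meta: dict = field(default_factory=dict)

    @property
    def normalized(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.counts / (self.n_snapshots * self.expected_per_bin)

    def to_csv(self, path, sidecar_path=None) -> None:
        np.savetxt(
            path,
            self.normalized,
            header=(
                "normalized bacterial density (rows: x bins, cols: y bins)\n"
                f"n_snapshots = {self.n_snapshots}"
            ),
        )
        if sidecar_path is not None:
            with open(sidecar_path, "w") as fh:
                json.dump(
                    {
                        "x_edges": list(map(float, self.x_edges)),
                        "y_edges": list(map(float, self.y_edges)),
                        "n_snapshots": self.n_snapshots,
                        "expected_per_bin": float(self.expected_per_bin.flat[0]),
                        "meta": self.meta,
                    },
                    fh,
                    indent=1,
                )


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def sample_inlet_positions(n: int, domain_height: float, rng) -> np.ndarray:
    """Heights of newly injected agents, i.i.d. with density 2y/H² on [0, H].

    This is the flux-weighted distribution of a uniform suspension advected
    through the inlet by shear flow; sampled by inverse CDF y = H √u.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    if domain_height <= 0:
        raise ParameterError("domain_height must be > 0")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    return domain_height * np.sqrt(rng.random(n))


def step_agents(state: AgentState, config: SimConfig, rng, t: float = 0.0) -> StepResult:
    """Advance all live agents by one Euler–Maruyama step.

    Agents crossing y = 0 adhere: their event time and surface position are
    interpolated linearly to the crossing.  Agents leaving through x = l (or
    swimming out upstream of x = 0) are removed as outflow.  The top boundary
    applies the configured policy (specular reflection mirrors both y and
    theta; absorb removes the agent as outflow).
    """
    dt, vs, beta = config.dt, config.rel_swim_speed, config.beta
    x0, y0, th0 = state.x, state.y, state.theta
    n = len(x0)
    if n == 0:
        return StepResult(state, np.empty(0), np.empty(0), 0)

    cos_t, sin_t = np.cos(th0), np.sin(th0)
    x1 = x0 + (y0 + vs * cos_t) * dt
    y1 = y0 + vs * sin_t * dt
    drift = 0.5 * (beta * np.cos(2.0 * th0) - 1.0)
    th1 = th0 + drift * dt
    if not config.disable_noise:
        th1 = th1 + np.sqrt(2.0 * dt / config.rot_peclet) * rng.standard_normal(n)
    th1 = np.mod(th1, 2.0 * np.pi)

    crossed = y1 <= 0.0
    if np.any(crossed):
        frac = y0[crossed] / (y0[crossed] - y1[crossed])
        x_cross = x0[crossed] + frac * (x1[crossed] - x0[crossed])
        t_cross = t + frac * dt
        on_surface = (x_cross >= 0.0) & (x_cross <= config.domain_length)
        adhered_t = t_cross[on_surface]
        adhered_x = x_cross[on_surface]
        n_corner_exits = int(np.sum(~on_surface))
    else:
        adhered_t = np.empty(0)
        adhered_x = np.empty(0)
        n_corner_exits = 0

    keep = ~crossed
    x1, y1, th1 = x1[keep], y1[keep], th1[keep]

    over_top = y1 > config.domain_height
    if np.any(over_top):
        if config.top_boundary == "reflect":
            y1[over_top] = 2.0 * config.domain_height - y1[over_top]
            th1[over_top] = np.mod(-th1[over_top], 2.0 * np.pi)
        else:  # absorb
            inside = ~over_top
            x1, y1, th1 = x1[inside], y1[inside], th1[inside]

    outflow = (x1 > config.domain_length) | (x1 < 0.0)
    n_exited = int(np.sum(outflow)) + n_corner_exits
    if config.top_boundary == "absorb":
        n_exited += int(np.sum(over_top))
    inside = ~outflow
    new_state = AgentState(x=x1[inside], y=y1[inside], theta=th1[inside])
    return StepResult(new_state, adhered_t, adhered_x, n_exited)


def net_adhesion_rate(
    events_t: np.ndarray, config: SimConfig, summary: AdhesionSummary | None = None
) -> AdhesionSummary:
    """Windowed net adhesion rate: events per unit time, mean ± SD over windows.

    Events outside [t_burnin, t_end] are ignored.  A single window yields an
    SD of 0 with ``single_window=True`` flagged.
    """
    n_win = config.n_windows
    if n_win < 1:
        raise ConfigError("no whole measurement window fits the protocol")
    events_t = np.asarray(events_t, dtype=float)
    t0 = config.t_burnin
    edges = t0 + config.window_length * np.arange(n_win + 1)
    counts, _ = np.histogram(events_t, bins=edges)
    rates = counts / config.window_length
    mean = float(np.mean(rates))
    sd = float(np.std(rates, ddof=1)) if n_win > 1 else 0.0
    if summary is None:
        summary = AdhesionSummary(
            events_t=events_t,
            events_x=np.empty(0),
            rate_mean=mean,
            rate_sd=sd,
            n_windows=n_win,
            single_window=(n_win == 1),
            window_rates=rates,
            inlet_density_equiv=config.inlet_density_equiv,
        )
    else:
        summary.rate_mean = mean
        summary.rate_sd = sd
        summary.n_windows = n_win
        summary.single_window = n_win == 1
        summary.window_rates = rates
    return summary


def density_histogram(
    x: np.ndarray,
    y: np.ndarray,
    config: SimConfig,
    bins: tuple[int, int] | None = None,
    n_snapshots: int = 1,
) -> DensityField:
    """Occupancy histogram of agent positions, passive-expectation normalised.

    The expected count per bin (absence of motility) is the uniform steady
    number density 2·(n_inject/dt)/H² times the bin area.
    """
    bins = bins or config.density_bins
    if min(bins) < 2:
        raise ConfigError("bins must be >= 2 per axis")
    x_edges = np.linspace(0.0, config.domain_length, bins[0] + 1)
    y_edges = np.linspace(0.0, config.domain_height, bins[1] + 1)
    counts, _, _ = np.histogram2d(x, y, bins=[x_edges, y_edges])
    area = (x_edges[1] - x_edges[0]) * (y_edges[1] - y_edges[0])
    n0 = 2.0 * (config.n_inject / config.dt) / config.domain_height**2
    expected = np.full_like(counts, n0 * area)
    return DensityField(
        x_edges=x_edges,
        y_edges=y_edges,
        counts=counts,
        n_snapshots=n_snapshots,
        expected_per_bin=expected,
    )


# ---------------------------------------------------------------------------
# Full protocol
# ---------------------------------------------------------------------------


def _inlet_orientation_sampler(config: SimConfig):
    """Closure drawing inlet angles (uniform, or steady diffusive Jeffery)."""
    if config.inlet_orientation == "uniform" or (
        config.beta == 0.0 and config.inlet_orientation == "jeffery"
    ):
        # beta = 0 steady distribution is exactly uniform
        return lambda n, rng: rng.random(n) * 2.0 * np.pi
    pdf = _orient.steady_orientation_pdf(config.beta, config.rot_peclet)
    ang, cum = pdf.cdf()
    return lambda n, rng: np.interp(rng.random(n), cum, ang)


def run_simulation(config: SimConfig) -> tuple[AdhesionSummary, DensityField | None]:
    """Run the full injection/transport/adhesion protocol.

    Injects agents at the configured rate with flux-weighted inlet heights
    and steady-state inlet orientations, steps the population to ``t_end``,
    and returns the windowed adhesion summary together with the time-averaged
    density field (if recorded).  Bookkeeping satisfies
    injected = adhered + exited + live exactly.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    draw_theta = _inlet_orientation_sampler(config)
    _validate_height(config)

    state = AgentState.empty()
    events_t: list[np.ndarray] = []
    events_x: list[np.ndarray] = []
    n_injected = n_adhered = n_exited = 0
    inject_acc = 0.0

    n_steps = int(round(config.t_end / config.dt))
    hist: DensityField | None = None
    n_snapshots = 0

    for istep in range(n_steps):
        t = istep * config.dt
        # injection at x = 0
        inject_acc += config.n_inject
        k = int(inject_acc)
        if k > 0:
            inject_acc -= k
            y_new = sample_inlet_positions(k, config.domain_height, rng)
            th_new = draw_theta(k, rng)
            state = AgentState(
                x=np.concatenate([state.x, np.zeros(k)]),
                y=np.concatenate([state.y, y_new]),
                theta=np.concatenate([state.theta, th_new]),
            )
            n_injected += k

        res = step_agents(state, config, rng, t=t)
        state = res.state
        n_adhered += len(res.adhered_t)
        n_exited += res.n_exited
        if len(res.adhered_t):
            events_t.append(res.adhered_t)
            events_x.append(res.adhered_x)

        if (
            config.record_density
            and t >= config.t_burnin
            and istep % config.sample_every == 0
        ):
            snap = density_histogram(state.x, state.y, config)
            if hist is None:
                hist = snap
            else:
                hist.counts += snap.counts
            n_snapshots += 1

    ev_t = np.concatenate(events_t) if events_t else np.empty(0)
    ev_x = np.concatenate(events_x) if events_x else np.empty(0)
    order = np.argsort(ev_t, kind="stable")
    ev_t, ev_x = ev_t[order], ev_x[order]

    # exact conservation of agents
    assert n_injected == n_adhered + n_exited + len(state), (
        n_injected,
        n_adhered,
        n_exited,
        len(state),
    )

    summary = AdhesionSummary(
        events_t=ev_t,
        events_x=ev_x,
        rate_mean=0.0,
        rate_sd=0.0,
        n_windows=0,
        single_window=False,
        window_rates=np.empty(0),
        inlet_density_equiv=config.inlet_density_equiv,
        n_injected=n_injected,
        n_adhered=n_adhered,
        n_exited=n_exited,
        n_live=len(state),
    )
    net_adhesion_rate(ev_t, config, summary)
    summary.events_x = ev_x
    if hist is not None:
        hist.n_snapshots = n_snapshots
        hist.meta = {"config": asdict(config)}
    return summary, hist


def _validate_height(config: SimConfig) -> None:
    """Warn when the domain is not comfortably taller than the depletion layer."""
    from . import theory as _theory

    if config.rel_swim_speed <= 0:
        return
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pe_eff = _theory.effective_peclet(config.groups, config.beta)
    except ParameterError:
        return
    bl = (config.domain_length / pe_eff) ** (1.0 / 3.0)
    if config.domain_height < 3.0 * bl:
        warnings.warn(
            f"domain_height {config.domain_height:g} is below 3 boundary-layer "
            f"thicknesses ({3 * bl:g}); near-wall depletion may be distorted",
            UserWarning,
            stacklevel=3,
        )


def simulate_orientation_samples(
    beta: float,
    rot_peclet: float,
    n_agents: int,
    t_end: float,
    dt: float = 5e-3,
    t_burnin: float = 20.0,
    sample_interval: float = 2.0,
    seed: int = 0,
) -> np.ndarray:
    """Angle samples from free (wall-less) Langevin orientation dynamics.

    The orientation SDE is independent of position, so this is the
    infinite-domain limit of the full simulator; used to check that the
    long-run angle histogram converges to the steady Fokker-Planck
    distribution.  Returns a flat array of (approximately decorrelated)
    angle samples collected every ``sample_interval`` after burn-in.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    theta = rng.random(n_agents) * 2.0 * np.pi
    n_steps = int(round(t_end / dt))
    every = max(1, int(round(sample_interval / dt)))
    out = []
    sigma = np.sqrt(2.0 * dt / rot_peclet)
    for istep in range(n_steps):
        theta = theta + 0.5 * (beta * np.cos(2.0 * theta) - 1.0) * dt
        theta = theta + sigma * rng.standard_normal(n_agents)
        if istep * dt >= t_burnin and istep % every == 0:
            out.append(np.mod(theta, 2.0 * np.pi).copy())
    return np.concatenate(out)
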