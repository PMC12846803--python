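# Methods

## Model

We model a dilute suspension of spheroidal microswimmers in two dimensions
under simple shear `u = γ̇ y x̂` over the half-plane `y > 0`, with the wall
at `y = 0` perfectly absorbing: every first contact is an irreversible
adhesion event. Each swimmer carries a position and a heading angle θ
(measured counterclockwise from the flow axis) and moves at fixed speed
`Vs` along its heading while being advected by the flow. The heading obeys
Jeffery rotation plus rotational diffusion: in shear-rate units the angular
drift is `ω(θ) = ½(β cos 2θ − 1)`, always clockwise, slowest when the body
is aligned with the flow (for elongated bodies, β → 1) and uniform for
spheres (β = 0). Rotational diffusion with coefficient `Dr` enters as
additive noise on θ, which preserves the unit heading exactly — the reason
we evolve the angle rather than the heading vector. Run-and-tumble species
are approximated by substituting the tumble rate for `Dr`. Swimmer–swimmer
and swimmer–wall hydrodynamic interactions, translational Brownian motion
(beyond an optional constant `DT`), imperfect adhesion, and feedback of the
swimmers on the flow are all outside the model.

Two dimensionless groups control everything: the relative swim speed
`𝒱s = Vs/(γ̇L)` (with `L` the flow lengthscale) and the rotational Péclet
number `Pe_r = γ̇/Dr`. All internal units are µm and s; public constructors
document units and perform no implicit conversion.

## Steady orientation distribution

The inlet heading distribution — and the far-field orientation statistics —
solve the periodic Fokker–Planck balance `∂θ(ω p) = Pe_r⁻¹ ∂²θ p`. We solve
it by Fourier spectral collocation: only even harmonics couple (the
distribution is π-periodic), each mode `k` obeys a three-term recurrence
coupling `k ± 2`, and the linear system is closed with unit normalisation.
The retained-mode count doubles (16 → 4096) until the truncation residual —
computable exactly as the coupling of the outermost mode — falls below
1e-8; a `SolverError` naming the residual is raised otherwise. Spectral
accuracy makes the solve exact to machine precision at modest mode counts
for Pe_r ≲ 100. Sampling uses inverse-transform interpolation of the
cumulative integral on a 512-point grid (refinement changes densities by
< 1e-6).

The closed moment model tracks density ρ, polar order n and nematic order Q
with standard 2D closures for the third and fourth orientation moments. In
the printed fourth-moment closure the final term breaks full index symmetry
as typeset; we use the symmetric completion `δ_kl Q_ij`, which the symmetry
of ⟨ssss⟩ requires. The far-field steady state is n = 0 with
`Q = [β Pe_r/(4(16+Pe_r²))]·[[Pe_r, 4],[4, −Pe_r]]`. A point worth
recording: this Q is an *exact* steady state of the closed moment system,
not merely a small-β approximation — in 2D the anticommutator identity
`{E, Q} = tr(EQ) I` for symmetric traceless tensors cancels the quadratic
source terms identically. The closure itself is accurate against the
agent-based model only within an envelope (Pe_r ≲ 1 for β > 0.5, ≲ 10 for
0 < β ≤ 0.5, ≲ 100 for spheres); leaving it triggers a
`ClosureAccuracyWarning`, never an error, since the downstream formulas
remain well-defined bounds.

## Boundary-layer theory

Adhesion depletes the suspension in a layer of thickness
`ε ỹ ~ (x/Pe_eff)^{1/3}`. There, a small heading anisotropy proportional to
the vertical density gradient drives a wall-ward swimming flux; eliminating
the orientation variables gives a Lévêque-type equation with the effective
Péclet number `Pe_eff(𝒱s, Pe_r, β)` quoted in the README. Its similarity
solution is a regularised lower incomplete gamma function (evaluated via
`scipy.special.gammainc` for numerical stability), the local adhesion rate
is `0.538 Pe_eff^{-2/3} x^{-1/3}`, and the net rate over a surface of
length l integrates in closed form. In the streamwise orientation
coefficient the printed constant `64 + 46β` cannot be cross-checked against
any identity we test; only its sign (upstream swimming for a wall-ward
depletion gradient) and the vertical component's exact link to `Pe_eff`
carry weight downstream.

The dimensional adhesion rate `Ĵ ∝ (Deff + DT)^{2/3} γ̇^{1/3}` is
nonmonotone in γ̇ because `Deff` decays as `γ̇⁻²` at high shear. The
critical shear rate is found by Brent bounded minimisation of `−ln Ĵ` over
log γ̇ on `[10⁻³ Dr, 10³ Dr]` (relative tolerance 1e-10 by default; an
endpoint hit raises). For spheres without thermal diffusion the stationary
point is `2Dr/√3 ≈ 1.155 Dr`. Note an asymmetry deliberately kept: the
high-shear `γ̇⁻¹` decay of the rate is a property of the motility-generated
diffusivity alone; any nonzero `DT` floor eventually restores the passive
`γ̇^{1/3}` growth (for the built-in E. coli parameters, beyond
γ̇ ≈ 35 s⁻¹). Asymptotic-exponent evaluations therefore set `DT = 0`,
matching the agent-based model, which carries no translational noise.

The validity-regime classifier labels a point A when `𝒱s ≥ 1` (swimming
alters the outer flow), B when the computed layer thickness
`ε = Pe_eff^{-1/3}` (at downstream position x = 1, configurable) is below a
threshold `ε₀ = 5×10⁻⁴` (layer thinner than a cell body of 5 µm over
L = 1 cm), C when `Pe_r ≥ 1/ε₀` (alignment starves the wall of incoming
headings) and D when `𝒱s ≤ ε₀` (active-stress corrections), in that fixed
precedence, else VALID. B compares the *computed* ε against the threshold;
C and D use the fixed threshold itself — the reading under which the
built-in pathogen/scenario table lands where expected (catheter flows
VALID; rivers and arteries in B/D).

## Agent-based protocol

Euler–Maruyama stepping with fixed δt = 10⁻² (in shear-rate time units).
Per step: agents are injected at x = 0 with heights `y = H√u` (the
flux-weighted inlet law `p(y) = 2y/H²` of a uniform suspension carried
through the inlet by shear) and headings sampled from the steady
orientation distribution at the run's own (β, Pe_r) (a uniform-inlet
option exists for sensitivity checks); positions and angles are advanced;
agents crossing y ≤ 0 adhere, with event time and surface position
interpolated linearly to the crossing (sub-step accuracy removes a grid
artifact from the event histogram); agents leaving through x = l — or the
rare upstream swimmers crossing x < 0 — are removed as outflow. The top
boundary, about which the physical problem (a half-plane) says nothing, is
specular by default: y and θ are mirrored, preserving the far-field
statistics; an absorbing policy is available. Bookkeeping is exact:
injected = adhered + exited + live on every run, asserted at runtime.

Fractional injection rates use a deterministic accumulator, so arbitrary
average rates are achievable with whole agents. One seeded PCG64 generator
drives each run; runs are bit-reproducible for a fixed seed.

Measurement follows a windowed protocol: events before a burn-in of 300
time units are discarded, the remainder splits into equal windows (four by
default), and the net rate is reported as mean ± SD over windows — since
agents are independent, windows are statistically independent replicates.
The event rate divided by the inlet-density equivalent
`ρ∞ = (n_inject/δt)/(H²/2)` — obtained by equating the agent number flux to
the continuum inlet flux — gives the dimensionless net adhesion `∫J dx`
comparable with theory. Occupancy histograms are normalised by the expected
motility-free count per bin (uniform density `2·(n_inject/δt)/H²` times bin
area), so the far field reads one.

## Problem sizes and what the tests show

Two preset families exist. The `paper_*` presets reconstruct the full
published protocol (100 agents per step, t = 10³–10⁴, of order 10⁷–10⁸
agents; hours of compute); the exponents of the published agent counts were
garbled in our source text and are reconstructed as 10⁷/10⁸. The `desk`
presets are ~100× reduced: injection 1–10 agents per unit time, t = 1500,
four windows of 300, and a per-run domain height of
`clip(5 × layer thickness at x = l, 0.15, 1.5)` so agents are not wasted
far above the layer. At this scale a six-point shear sweep takes ~45 s and
a density run ~20 s on one CPU.

The reduced runs reproduce, with wide stochastic tolerances: the
nonmonotone adhesion-vs-shear curve (interior maximum ≫ 3 pooled SDs above
both endpoints of a 0.1–50 s⁻¹ E. coli sweep), the low-shear `γ̇^{1/3}`
growth (measured at L = 7500 µm, where the relative swim speed is small
enough for the scaling regime), the high-shear decay tracking the theory's
local slope, the 50%-density contour of the similarity solution within two
bins outside the inlet corner, and the scaling collapse within three
window-SDs at (Pe_r = 1, 𝒱s = 0.01, β = 0). Two caveats the tests make
visible rather than hide: the simulator sits a real ~10% *below* the
closed-form rate at finite 𝒱s (the theory is an upper bound; an extra
boundary layer at the inlet corner, excluded from density comparisons below
x = 0.5, accounts for the difference), and the closed theory's intermediate
high-shear slope is steeper than the asymptotic −1 (the −1 law is reached
only near γ̇ ≳ 100 Dr, below desk-scale event counts), so the asymptote is
verified analytically while the simulation is compared against the local
theory slope.

What the synthetic runs cannot show: real bacteria tumble rather than
diffuse rotationally (the substitution is exact only for dilute, force-free
cells), swim in 3D, interact with walls hydrodynamically, and detach;
agreement here validates the transport/adhesion mathematics, not those
biological simplifications.

## Numerical and design choices

- Incomplete-gamma convention: the density uses the *lower* incomplete
  gamma, regularised internally.
- Parameter point estimates only: the built-in Table values carry published
  uncertainties (e.g. Vs = 22 ± 5 µm/s) that we do not propagate.
- The critical-shear reporting convention for species comparisons is two
  significant figures (1.1 s⁻¹ for E. coli, 0.039 s⁻¹ for P. aeruginosa).
- Degenerate inputs fail loudly: `Pe_r = 0` or `𝒱s = 0` name the divergent
  quiescent limit; x ≤ 0 is a domain error; a domain shallower than three
  layer thicknesses warns.
- Window/burn-in consistency (at least one whole window) is validated at
  configuration time; a single window reports SD = 0 with an explicit flag.
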