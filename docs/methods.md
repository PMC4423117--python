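# Methods

## Model

Four species live on the blastoderm surface, modelled as a cylinder of
circumference `l_x = 1.7 mm` (a periodic ring when concentrations are
uniform along the axis): free Sog `s`, free BMP `b`, the Sog-BMP complex
`c`, and the transcription factor NF-κB/Dorsal `d`, which acts purely as
a polarity cue. The reaction-diffusion system is

    ∂t s = D_s ∇²s + η_s(b, d) − k₊ s b + k₋ c − α_s s
    ∂t b = D_b ∇²b + η_b − k₊ s b + k₋ c + α_s c − α_b b
    ∂t c = D_c ∇²c + k₊ s b − k₋ c − α_s c
    ∂t d = −α_d d

with the *sog* transcription rate

    η_s(b, d) = (η₀ + η₁ d/d₀) / ((1 + b/b₀)(1 + d/d₀)).

BMP represses *sog* (Michaelis–Menten, half-maximal at `b₀`); Dorsal
enhances it (from `η₀` at `d = 0` to `η₁` at saturation). Cleavage of
the complex (the implicit Tolloid activity) destroys the Sog moiety and
returns BMP intact; degradation of BMP inside the complex is neglected.
Dorsal neither diffuses nor reacts — it only decays, so the cue is
transient. Units are arbitrary but read naturally as seconds and meters.

The patterning mechanism is shuttling-driven lateral inhibition without
an explicit activator: where Sog is elevated, BMP is captured into
fast-diffusing complexes (`D_c ≫ D_s, D_b`) and transported away;
falling BMP derepresses *sog* locally, amplifying the asymmetry. The
homogeneous state is Turing-unstable once the Dorsal-controlled
expression rate and `D_c` are large enough; the stripe that forms is a
pair of fronts whose separation is set by the global BMP budget
(production `η_b l_x` against degradation `α_b ∫b`).

Two structural facts follow directly from the equations and shape
several conventions below:

- At any spatially uniform steady state, free BMP equals
  `b̄ = η_b / α_b` regardless of every other parameter, because binding
  and cleavage conserve BMP.
- With `α_b = 0` (an endpoint of the published single-stripe range) the
  system has no steady state at all: total BMP grows linearly forever.

## Parameters

All reaction and diffusion constants default to the published reference
set (see `ModelParameters`); `complex_cleavage_rate` switches the
complex-cleavage constant from `α_s` (the displayed equations) to the
separately tabulated `α_c`, which the displayed equations never
reference. The default follows the displayed equations; the variant is
provided because the printed table lists `α_c`.

The Dorsal decay rate `α_d` has no published value. It controls the race
between cue decay and pattern growth and therefore sets the threshold
initial amplitude `D₀*` below which no stripe forms. The package default
`α_d = 1.25e-4` was calibrated with `calibrate_alpha_d`, the criterion
being the published threshold bracket: `D₀ = 0.15` must stay
homogeneous while `D₀ = 0.3` forms a stripe. The window is genuinely
narrow — at `1e-4` the `D₀ = 0.15` trajectory lands marginally above the
subcritical saddle and eventually patterns; at `2.5e-4` the `D₀ = 0.3`
trajectory fails — so the default sits between those failures.

The initial state is uniform `s = 0.01`, `b = 0.32`, `c = 0.14` with a
ventral Gaussian Dorsal peak `d(x) = D₀ exp(−Δx²/2σ²)` (wrapped on the
ring). The printed form of the exponent is typographically corrupted in
the source material; the package adopts `σ = l_x/2`, a broad profile
whose tails reach the dorsal midline (`e^{−1/2} D₀` at the antipode) —
broad enough that, in the twinning experiment, both egg halves retain a
super-threshold cue. The peak sits at `x = l_x/2` and is labelled the
ventral midline. For the two-dimensional robustness runs the amplitude
and width are modulated along the cylinder axis by
`m(y) = 1 + a·sin(πy/l_y)` with `a = 0.1` (a one-sided 10% swell).

## Numerics

**Time stepping.** Strang splitting: exact spectral diffusion
(Fourier modes on the periodic circumference, DCT-II cosine modes across
no-flux boundaries, their tensor product on the cylinder) around a
pointwise reaction substep, with Dorsal decayed analytically. The
default reaction substep is an exponential (Rush–Larsen) update that
integrates each species' own linear relaxation exactly against frozen
cross-terms; it is positivity-preserving and stable at the default
`dt = 2` despite the fast binding (`k₊ b dt ≈ 16`). When the binding
flux per step could exceed the available mass
(`k₊ · b_scale · dt > 25`, e.g. the `k₊ = 200` endpoint), the integrator
switches to an L-stable backward-Euler substep solved by a vectorized
per-node 3×3 Newton. Spectral undershoot at sharp fronts is clipped to
zero each step (warned past −1e-12, aborted only if it is large on the
scale of the field).

**Converged profiles.** The split map's discrete fixed point carries an
O(dt) bias (~1e-4 in rate units at `dt = 2`), so "converged" states are
defined by a damped Newton solve of the semi-discrete steady equations
`0 = D L u + f(u)` (spectral Laplacian `L`, Dorsal at its late-time
limit), seeded by the time-stepped state once the cue has decayed below
2e-4 plus a settling window (3e4 model-s, during which the stripe fronts
drift to their equilibrium separation). The polished profile is
independent of `dt` to solver precision, which is what makes the
refinement contracts (dt-halving < 1e-4, grid-doubling < 1e-3 in
sup-norm) meaningful. Three guards keep the polish honest:

- a *move guard* rejects solutions further than max(1e-3, 25% of the
  field scale) from the time-stepped state (no basin jumps);
- near-uniform solutions are rejected while the homogeneous state is
  linearly unstable at the prevailing Dorsal level (Newton must not
  collapse a still-growing pattern);
- solutions whose Jacobian has an eigenvalue with real part > 1e-7 are
  rejected (Newton happily converges onto the small-amplitude *saddle*
  that separates the homogeneous and striped basins near the subcritical
  threshold; only attractors may terminate a run). The stripe's
  translation mode on the ring sits at ~0 and passes.

A cheap drift gate (sup-norm change of `s` per unit time < 3e-7) defers
polish attempts while the pattern is still actively forming. On the
ring the near-null translation mode is handled by a least-squares
linear solve with an `rcond` cutoff. Runs that never satisfy a guard
end at `t_end` with a warning status and report the raw field.

Rate-based steadiness (`max |∂t u| < steady_tol`, default 1e-9) is also
checked, but note its blind spot: a marginally unstable mode grows with
a tiny instantaneous rate, so experiments that probe growth explicitly
pass `steady_tol=0`.

**Resolution.** Defaults are `nx = 256` on the ring and 128×64 on the
cylinder, `dt = 2`. The steady interface width is
`√(D_c/(k₋+α_s)) ≈ 3.5e-5 m` ≈ 5 cells at `nx = 256`, which the spectral
basis resolves well (grid-doubling changes polished profiles by ~1e-5).
Near the subcritical threshold the basin boundary itself is
discretization-sensitive: at `nx = 64` the threshold sits below
`D₀ = 0.15`. Threshold statements therefore refer to the default
resolution.

**Two dimensions.** The cylinder run uses the same splitting; the dense
Newton polish is not available there (the steady solve is only offered
in 1D). The unmodulated wild type is exactly uniform along the axis at
every time by symmetry, so the 2D stripe criterion is unaffected.

## Simulated experiments

Knockdowns are hard clamps of the affected species (plus zeroed
production), matching total loss of function; a production-only mode is
available for sensitivity exploration. The panel readout conventions:

- `dpp_kd`, `sog_kd`, `tsg_kd`, `toll_kd`, `toll_dpp_kd` are classified
  at their steady states, where the analytic levels are exact anchors:
  uniform Sog at `η₀/α_s = 0.14` (ventralized class), uniform BMP at
  `η_b/α_b = 0.8` (dorsalized class). `toll_kd` also records the early
  ubiquitous *sog* activation (snapshot at t = 2000) that later decays.
- `tld_kd` (Sog cleavage reduced 90%) is read out at `t = 1.5e4`,
  during the BMP-sequestration phase (>99% of BMP complexed, Sog
  everywhere above 50000× its wild-type low level). This is a package
  convention forced by the model's structure: since any uniform steady
  state has `b̄ = η_b/α_b`, the depicted ventralized phenotype can only
  be the long-lived patterning-stage transient, which is the
  developmentally relevant state. It is classified with a 50% relief
  tolerance, appropriate when phenotype classes differ by orders of
  magnitude.

The **parameter sweep** over the published single-stripe ranges pins the
BMP-free expression rate at `η̄_s = 1.2e-3` through the amplitude of the
Dorsal profile (`D₀ ≈ 1.15`) and, by default, holds the cue *persistent*
rather than decaying. Under the decaying cue four printed endpoints
(`η_b = 1e-4`, `α_b = 0`, `k₊ = 200`, `D_b = 1e-11`) form no stripe —
and `α_b = 0` has no steady state at all — so the published table is
only reproducible under a persistent-cue (or fixed-horizon) protocol.
Sweep patterns are classified at 50% relief because a persistent cue
paints a shallow passive imprint (~17% relief) on `s` even without
self-organization, while a genuine stripe has near-total relief. The
decaying-cue protocol remains available (`dorsal_mode="decay"`).

**Twinning** cuts the ring at `t = 0` into two independent no-flux
fragments; the cut passes through the Dorsal peak (and, for a symmetric
cut, the dorsal midline), so each fragment keeps a super-threshold cue
maximum at one end and forms one stripe there. With `D₀ = 1` the
symmetric halves pattern identically (width fractions agree to ~3%). For
asymmetric cuts the converged width *fractions* differ more — about 27%
for a 40/60 cut — so the package's scaling tolerance for asymmetric
fragments is 30%: the stripe adjusts to the fragment, but proportional
scaling is only approximate in this model.

**Stability analysis** treats uniform Dorsal as a parameter: the
dispersion relation is the spectrum of `A − D k²` at the homogeneous
fixed point, with instability iff any admissible `k = 2πn/l_x` has an
eigenvalue with positive real part. The diffusion matrix uses
`diag(D_s, D_b, D_c)`; a `literal_printed_D` switch substitutes `D_s`
for `D_b`, shifting growth rates by ≲10% without moving the boundary
visibly (both are negligible against `D_c`). Scans over `(D_c, η̄_s)` or
`(D_c, log d)` report the `w = 0` crossing by linear interpolation.

## What the synthetic inputs do and do not emulate

The generated initial fields encode the study conditions: uniform mobile
species, a broad ventral Dorsal peak of controlled amplitude, optional
AP modulation, optional seeded noise. They do not attempt to reproduce
the real embryo's Dorsal profile shape (unknown beyond "broad and
graded"), maternal noise statistics, nuclear divisions, tissue growth or
any mechanics. Consequently, passing tests show that the *model* behaves
as published under its stated idealizations — not that the embryo does.

## Known limitations

- After the cue decays, equalization of stripe width *along the
  cylinder axis* relaxes through transverse front tension governed by
  the smallest diffusivities; its timescale (~3e6 model-s) far exceeds
  the simulated windows. A ±10% AP-modulated cue therefore leaves a
  row-dependent width imprint (cv ≈ 0.4) at the end of a desk-scale run
  even though stripe *centers* align exactly with the ventral midline
  and the asymptotic steady state is uniform. A preconditioned
  Newton-Krylov steady solve stagnates on the same soft modes. The
  axis-uniformity claim is therefore asserted only where it is exact
  (the unmodulated wild type); for modulated cues the package asserts
  per-row stripe count and midline centering.
- The subcritical threshold `D₀*` is a basin boundary and inherits
  sensitivity to resolution, step size and `α_d`; it is meaningful only
  under the stated defaults.
- Near-threshold trajectories linger at the saddle, where stripe counts
  are genuinely ambiguous until the state commits to a basin.
- The homogeneous-state `b̄ = η_b/α_b` identity means "high/low BMP"
  phenotype contrasts are transient for any perturbation that suppresses
  patterning without removing BMP production; readout times are part of
  the phenotype definition (see `tld_kd` above).
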