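"""Named in-silico experiments: wild type, knockdowns, threshold, twinning, sweeps.

Each scenario bundles parameter overrides, hard species clamps and an
initial-profile override.  Loss-of-function phenotypes follow the
modelling conventions of the knockdown simulations:

==============  ====================================================
scenario        implementation
==============  ====================================================
wt              reference parameters, Dorsal amplitude ``D0 = 0.3``
dpp_kd          BMP clamped to zero (and no BMP production)
sog_kd          Sog clamped to zero (hence no complex either)
tsg_kd          no complex formation, ``k_plus = 0``
tld_kd          Sog degradation reduced by 90 %
toll_kd         Dorsal clamped to zero
toll_dpp_kd     Dorsal and BMP both clamped
twinning        ``D0 = 1`` and the ring cut into two fragments
subthreshold    ``D0 = 0.15`` (below the patterning threshold)
sweep:<p>=<v>   one parameter moved to ``v``, all else reference
==============  ====================================================

An alternative "production" knockdown mode removes only the source term
of the targeted gene instead of clamping the protein, for sensitivity
exploration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dynamics import Grid, ScenarioConstraints, SimulationResult, run
from .metrics import PatternSummary, count_stripes
from .model import ModelParameters, dorsal_for_eta_bar, eta_bar
from .profiles import ProfileSpec, initial_state

__all__ = [
    "ScenarioConfig",
    "SCENARIO_NAMES",
    "TABLE2_RANGES",
    "SWEEP_ETA_BAR",
    "make_scenario",
    "build_grid",
    "run_scenario",
    "threshold_experiment",
    "bisect_threshold",
    "parameter_sweep",
    "twinning_experiment",
    "calibrate_alpha_d",
]

#: single-stripe parameter ranges (each varied alone, expression rate
#: pinned at SWEEP_ETA_BAR unless the rate itself is swept)
TABLE2_RANGES: dict[str, tuple[float, float]] = {
    "eta_bar": (6e-4, 1.4e-3),
    "b0": (0.1, 0.5),
    "eta_b": (8e-6, 1e-4),
    "alpha_s": (1.6e-3, 1.2e-2),
    "alpha_b": (0.0, 1e-4),
    "k_plus": (0.05, 200.0),
    "k_minus": (0.0, 0.5),
    "D_s": (0.0, 1e-9),
    "D_b": (0.0, 1e-11),
    "D_c": (7e-10, 1e-6),
}

SWEEP_ETA_BAR = 1.2e-3

SCENARIO_NAMES = ("wt", "dpp_kd", "sog_kd", "tsg_kd", "tld_kd", "toll_kd",
                  "toll_dpp_kd", "twinning", "subthreshold")


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulated experiment: overrides + clamps + profile + topology.

    ``run_defaults`` are integrator arguments the scenario needs unless
    the caller overrides them (e.g. the Tolloid knockdown is read out
    during the BMP-sequestration phase rather than at t → ∞, because
    continued BMP production eventually overwhelms sequestration at any
    true steady state).  ``flatness`` is the relief tolerance used to
    classify this scenario's final pattern as uniform.
    """

    name: str
    overrides: dict = field(default_factory=dict)
    clamps: frozenset = frozenset()
    profile: ProfileSpec = ProfileSpec()
    cut_fraction: float | None = None   # twinning: arc fraction of fragment A
    dorsal_mode: str = "decay"
    run_defaults: dict = field(default_factory=dict)
    flatness: float = 0.05

    def apply(self, p: ModelParameters) -> ModelParameters:
        unknown = set(self.overrides) - set(p.to_dict())
        if unknown:
            raise ValueError(f"overrides reference unknown parameters: {sorted(unknown)}")
        return p.with_overrides(**self.overrides) if self.overrides else p

    @property
    def constraints(self) -> ScenarioConstraints:
        return ScenarioConstraints(clamps=self.clamps, dorsal_mode=self.dorsal_mode)

    def to_dict(self) -> dict:
        return {
            "name": self.name, "overrides": dict(self.overrides),
            "clamps": sorted(self.clamps), "profile": self.profile.to_dict(),
            "cut_fraction": self.cut_fraction, "dorsal_mode": self.dorsal_mode,
        }


def make_scenario(name: str, p: ModelParameters | None = None,
                  knockdown_mode: str = "clamp") -> ScenarioConfig:
    """Construct the named scenario.

    ``knockdown_mode="production"`` removes gene expression instead of
    clamping protein levels (the clamp is the reference behaviour,
    matching total loss of the protein)."""
    p = p or ModelParameters()
    if knockdown_mode not in ("clamp", "production"):
        raise ValueError("knockdown_mode must be 'clamp' or 'production'")
    prod = knockdown_mode == "production"
    wt_profile = ProfileSpec(D0=0.3)

    if name == "wt":
        return ScenarioConfig("wt", profile=wt_profile)
    if name == "dpp_kd":
        return ScenarioConfig("dpp_kd", overrides={"eta_b": 0.0},
                              clamps=frozenset() if prod else frozenset({"b"}),
                              profile=wt_profile)
    if name == "sog_kd":
        if prod:
            return ScenarioConfig("sog_kd", overrides={"eta0": 0.0, "eta1": 1e-12},
                                  profile=wt_profile)
        return ScenarioConfig("sog_kd", clamps=frozenset({"s", "c"}), profile=wt_profile)
    if name == "tsg_kd":
        return ScenarioConfig("tsg_kd", overrides={"k_plus": 0.0}, profile=wt_profile)
    if name == "tld_kd":
        # read out during BMP sequestration: >99% of BMP is complexed and
        # sog is derepressed everywhere; at t -> infinity constitutive BMP
        # production restores free BMP to eta_b/alpha_b in any scenario
        # whose Sog supply cannot pattern, so the phenotype is the
        # long-lived patterning-stage state, not the asymptotic one
        return ScenarioConfig("tld_kd", overrides={"alpha_s": 0.1 * p.alpha_s},
                              profile=wt_profile,
                              run_defaults={"t_end": 1.5e4, "polish": "never",
                                            "warn_nonconverged": False},
                              flatness=0.5)
    if name == "toll_kd":
        return ScenarioConfig("toll_kd", clamps=frozenset({"d"}),
                              profile=replace(wt_profile, D0=0.0),
                              run_defaults={"snapshot_times": (2000.0,)})
    if name == "toll_dpp_kd":
        return ScenarioConfig("toll_dpp_kd", overrides={"eta_b": 0.0},
                              clamps=frozenset({"d"}) if prod else frozenset({"d", "b"}),
                              profile=replace(wt_profile, D0=0.0))
    if name == "twinning":
        return ScenarioConfig("twinning", profile=ProfileSpec(D0=1.0), cut_fraction=0.5)
    if name == "subthreshold":
        return ScenarioConfig("subthreshold", profile=ProfileSpec(D0=0.15))
    if name.startswith("sweep:"):
        try:
            key, val = name[len("sweep:"):].split("=")
            value = float(val)
        except ValueError:
            raise ValueError(f"malformed sweep scenario {name!r}; use sweep:<param>=<value>")
        return _sweep_scenario(key.strip(), value, p)
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES} "
                     f"or sweep:<param>=<value>")


def _sweep_scenario(param: str, value: float, p: ModelParameters,
                    dorsal_mode: str = "fixed") -> ScenarioConfig:
    if param not in TABLE2_RANGES:
        raise ValueError(f"unknown sweep parameter {param!r}; "
                         f"choose from {sorted(TABLE2_RANGES)}")
    if param == "eta_bar":
        overrides = {}
        D0 = dorsal_for_eta_bar(value, p)
    else:
        overrides = {param: value}
        D0 = dorsal_for_eta_bar(SWEEP_ETA_BAR, p)
    # a persistent cue paints a shallow passive imprint on s even without
    # self-organization; a genuine stripe has near-total relief, so sweep
    # patterns are classified at the phenotype scale
    return ScenarioConfig(f"sweep:{param}={value:g}", overrides=overrides,
                          profile=ProfileSpec(D0=D0), dorsal_mode=dorsal_mode,
                          flatness=0.5)


def build_grid(scenario: ScenarioConfig, dim: int = 1, nx: int = 256,
               ny: int = 64, p: ModelParameters | None = None) -> Grid:
    """Grid matching the scenario's topology (cut-ring for twinning)."""
    p = p or ModelParameters()
    if scenario.cut_fraction is not None:
        if dim != 1:
            raise ValueError("the twinning cut is defined on the 1D ring")
        n1 = int(round(nx * scenario.cut_fraction))
        i = nx // 2  # cell boundary at the Dorsal peak (ventral midline)
        return Grid(nx=nx, l_x=p.l_x, topology="cut-ring", cuts=(i, (i + n1) % nx))
    if dim == 2:
        return Grid(nx=nx, ny=ny, l_x=p.l_x, l_y=p.l_y, dim=2, topology="cylinder")
    return Grid(nx=nx, l_x=p.l_x, topology="ring")


def _summarize(result: SimulationResult, grid: Grid,
               flatness: float = 0.05) -> PatternSummary:
    s = result.final.s
    if grid.dim == 2:
        s = s[:, grid.ny // 2]
    topo = "interval" if grid.topology in ("interval",) else "ring"
    if grid.topology == "cut-ring":
        # census the two fragments and merge
        parts = [count_stripes(s[idx], "interval", flatness,
                               converged=result.converged)
                 for idx in grid.fragments()]
        merged = PatternSummary(
            stripe_count=sum(pt.stripe_count for pt in parts),
            stripes=[cw for pt in parts for cw in pt.stripes],
            uniformity_cv=float(np.std([pt.uniformity_cv for pt in parts])),
            level_high=max(pt.level_high for pt in parts),
            level_low=min(pt.level_low for pt in parts),
            converged=result.converged,
        )
        return merged
    return count_stripes(s, topo, flatness, converged=result.converged)


def run_scenario(name_or_config, grid: Grid | None = None,
                 p: ModelParameters | None = None, dim: int = 1,
                 nx: int = 256, ny: int = 64,
                 **run_kwargs) -> tuple[SimulationResult, PatternSummary]:
    """Run one scenario end to end and census the final Sog pattern."""
    p = p or ModelParameters()
    sc = make_scenario(name_or_config, p) if isinstance(name_or_config, str) else name_or_config
    pp = sc.apply(p)
    grid = grid or build_grid(sc, dim=dim, nx=nx, ny=ny, p=pp)
    state0 = initial_state(grid, sc.profile, pp)
    kwargs = {**sc.run_defaults, **run_kwargs}
    result = run(grid, state0, pp, sc.constraints, **kwargs)
    return result, _summarize(result, grid, sc.flatness)


def threshold_experiment(D0_values, grid: Grid | None = None,
                         p: ModelParameters | None = None,
                         **run_kwargs) -> dict[float, PatternSummary]:
    """Wild-type runs over initial Dorsal amplitudes; stripe census per D0."""
    p = p or ModelParameters()
    out = {}
    for D0 in D0_values:
        if D0 < 0:
            raise ValueError("D0 must be >= 0")
        sc = ScenarioConfig(f"threshold:D0={D0:g}", profile=ProfileSpec(D0=D0))
        _, summary = run_scenario(sc, grid=grid, p=p, **run_kwargs)
        out[float(D0)] = summary
    return out


def bisect_threshold(lo: float = 0.15, hi: float = 0.3, iters: int = 5,
                     p: ModelParameters | None = None, grid: Grid | None = None,
                     **run_kwargs) -> tuple[float, float]:
    """Bracket the critical initial Dorsal amplitude for stripe formation.

    Assumes no stripe at ``lo`` and a stripe at ``hi`` (raises
    otherwise); returns the final ``(lo, hi)`` bracket."""
    ends = threshold_experiment([lo, hi], grid=grid, p=p, **run_kwargs)
    if ends[lo].stripe_count != 0 or ends[hi].stripe_count == 0:
        raise ValueError(
            f"bracket invalid: stripe counts {ends[lo].stripe_count} at {lo}, "
            f"{ends[hi].stripe_count} at {hi}")
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        res = threshold_experiment([mid], grid=grid, p=p, **run_kwargs)
        if res[mid].stripe_count:
            hi = mid
        else:
            lo = mid
    return lo, hi


def parameter_sweep(param: str, values=None, grid: Grid | None = None,
                    p: ModelParameters | None = None, n_interior: int = 3,
                    dorsal_mode: str = "fixed", **run_kwargs) -> list[dict]:
    """Stripe counts along one row of the single-stripe parameter table.

    Every other parameter stays at its reference value and the BMP-free
    *sog* expression rate is pinned at ``SWEEP_ETA_BAR`` through the
    amplitude of the Dorsal profile.  By default the polarity cue
    persists (``dorsal_mode="fixed"``) so the census reflects where a
    stripe exists at all rather than where the decaying cue wins its
    race against relaxation; pass ``dorsal_mode="decay"`` for the
    transient protocol.  ``values=None`` runs both printed endpoints
    plus ``n_interior`` log-spaced interior points.
    """
    if param not in TABLE2_RANGES:
        raise ValueError(f"unknown sweep parameter {param!r}")
    p = p or ModelParameters()
    if values is None:
        lo, hi = TABLE2_RANGES[param]
        interior = np.geomspace(max(lo, hi * 1e-4), hi, n_interior + 2)[1:-1] \
            if n_interior else []
        values = [lo, *interior, hi]
    rows = []
    for v in values:
        sc = _sweep_scenario(param, float(v), p, dorsal_mode=dorsal_mode)
        _, summary = run_scenario(sc, grid=grid, p=p, **run_kwargs)
        rows.append({"param": param, "value": float(v),
                     "stripe_count": summary.stripe_count,
                     "width": sum(summary.widths), "converged": summary.converged})
    return rows


def twinning_experiment(cut_fractions=(0.5,), grid: Grid | None = None,
                        p: ModelParameters | None = None, nx: int = 256,
                        **run_kwargs) -> dict[float, list[PatternSummary]]:
    """Egg-fragmentation runs: cut the ring at t = 0, pattern each half.

    The cut passes through the Dorsal peak (ventral midline), so each
    fragment retains the cue maximum at one end; with ``D0 = 1`` the cue
    exceeds the patterning threshold in both fragments and each forms
    its own stripe.  Returns per-fragment pattern summaries keyed by cut
    fraction."""
    p = p or ModelParameters()
    out = {}
    for frac in cut_fractions:
        if not 0 < frac < 1:
            raise ValueError("cut fraction must lie in (0, 1)")
        sc = ScenarioConfig(f"twinning:{frac:g}", profile=ProfileSpec(D0=1.0),
                            cut_fraction=frac)
        g = grid or build_grid(sc, nx=nx, p=p)
        result, _ = run_scenario(sc, grid=g, p=p, **run_kwargs)
        out[float(frac)] = [
            count_stripes(result.final.s[idx], "interval", converged=result.converged)
            for idx in g.fragments()
        ]
    return out


def calibrate_alpha_d(p: ModelParameters | None = None,
                      D0_below: float = 0.15, D0_above: float = 0.3,
                      candidates=None, **run_kwargs) -> float:
    """Largest Dorsal decay rate placing the stripe threshold in
    ``(D0_below, D0_above]``.

    Scans candidate rates from fast to slow and returns the first for
    which ``D0_above`` patterns while ``D0_below`` does not.  The
    package default was chosen with this procedure."""
    p = p or ModelParameters()
    if candidates is None:
        candidates = np.geomspace(4e-4, 2.5e-5, 9)
    for a in sorted(candidates, reverse=True):
        pa = p.with_overrides(alpha_d=float(a))
        res = threshold_experiment([D0_below, D0_above], p=pa, **run_kwargs)
        if res[D0_below].stripe_count == 0 and res[D0_above].stripe_count == 1:
            return float(a)
    raise RuntimeError("no candidate decay rate places the threshold in the window")
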