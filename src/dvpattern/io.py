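"""Configuration files, run manifests, snapshot output and figures.

Everything is text: parameters and profiles live in flat key-value JSON
(unknown keys are rejected so typos cannot silently revert a value to
its default), snapshots are tab-separated tables with one row per grid
cell, and each completed run directory carries exactly one manifest
recording the fully resolved configuration so that the run can be
reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import time
from importlib import resources
from pathlib import Path

import numpy as np

from .dynamics import Grid, SimulationResult
from .metrics import PatternSummary
from .model import FieldState, ModelParameters
from .profiles import ProfileSpec

__all__ = [
    "RunManifest",
    "load_config",
    "save_config",
    "default_parameters",
    "write_outputs",
    "read_snapshot",
    "plot_profiles",
]

_PARAM_KEYS = {f.name for f in dataclasses.fields(ModelParameters)}
_PROFILE_KEYS = {f.name for f in dataclasses.fields(ProfileSpec)}
_RUN_KEYS = {"dt", "t_end", "steady_tol", "nx", "ny", "dim", "scenario", "seed"}


def default_parameters() -> ModelParameters:
    """Reference parameter set, read from the packaged defaults file."""
    with resources.files("dvpattern").joinpath("defaults.json").open() as fh:
        data = json.load(fh)
    return ModelParameters(**data)


def load_config(path) -> tuple[ModelParameters, ProfileSpec, dict]:
    """Read a flat key-value config file.

    Keys are the field names of :class:`ModelParameters` and
    :class:`ProfileSpec` plus a small set of run options; anything else
    is an error naming the offending key.  Missing keys fall back to
    the packaged defaults.
    """
    data = json.loads(Path(path).read_text())
    if not isinstance(data, dict):
        raise ValueError("config must be a flat JSON object")
    unknown = set(data) - _PARAM_KEYS - _PROFILE_KEYS - _RUN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    base = default_parameters().to_dict()
    base.update({k: v for k, v in data.items() if k in _PARAM_KEYS})
    params = ModelParameters(**base)
    profile = ProfileSpec(**{k: v for k, v in data.items() if k in _PROFILE_KEYS})
    options = {k: v for k, v in data.items() if k in _RUN_KEYS}
    return params, profile, options


def save_config(path, p: ModelParameters, profile: ProfileSpec | None = None,
                options: dict | None = None) -> None:
    data = dict(p.to_dict())
    if profile is not None:
        data.update(profile.to_dict())
    if options:
        bad = set(options) - _RUN_KEYS
        if bad:
            raise ValueError(f"unknown run options: {sorted(bad)}")
        data.update(options)
    Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")


@dataclasses.dataclass
class RunManifest:
    """Resolved record of one run: enough to reproduce it exactly."""

    parameters: dict
    profile: dict
    grid: dict
    scenario: str
    seed: int | None
    converged: bool
    convergence_metric: float
    version: str
    timestamp: str
    outputs: list

    @classmethod
    def create(cls, p: ModelParameters, profile: ProfileSpec, grid: Grid,
               scenario: str, result: SimulationResult, seed: int | None,
               outputs: list) -> "RunManifest":
        from . import __version__
        return cls(
            parameters=p.to_dict(), profile=profile.to_dict(), grid=grid.to_dict(),
            scenario=scenario, seed=seed, converged=result.converged,
            convergence_metric=float(result.convergence_metric),
            version=__version__,
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
            outputs=outputs,
        )

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))


def _snapshot_table(state: FieldState, grid: Grid) -> str:
    cols = ["x"] + (["y"] if grid.dim == 2 else []) + ["s", "b", "c", "d"]
    lines = ["\t".join(cols)]
    if grid.dim == 2:
        X, Y = np.meshgrid(grid.x, grid.y, indexing="ij")
        data = np.column_stack([X.ravel(), Y.ravel(), state.s.ravel(),
                                state.b.ravel(), state.c.ravel(), state.d.ravel()])
    else:
        data = np.column_stack([grid.x, state.s, state.b, state.c, state.d])
    for row in data:
        lines.append("\t".join(repr(float(v)) for v in row))
    return "\n".join(lines) + "\n"


def read_snapshot(path) -> dict[str, np.ndarray]:
    """Read back a snapshot table into column arrays (full precision)."""
    lines = Path(path).read_text().strip().split("\n")
    header = lines[0].split("\t")
    data = np.array([[float(v) for v in ln.split("\t")] for ln in lines[1:]])
    return {name: data[:, i] for i, name in enumerate(header)}


def write_outputs(result: SimulationResult, summary: PatternSummary | None,
                  out_dir, p: ModelParameters, profile: ProfileSpec, grid: Grid,
                  scenario: str = "wt", seed: int | None = None,
                  plot: bool = False) -> list:
    """Write snapshots, summary, manifest and (optionally) figures.

    Returns the list of files written.  Plotting failures never fail
    the run; figures are a convenience, the text outputs are the record.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = []
    for snap in [*result.snapshots, result.final]:
        name = f"snapshot_t{snap.t:.0f}.tsv"
        (out / name).write_text(_snapshot_table(snap, grid))
        files.append(name)
    if summary is not None:
        (out / "summary.json").write_text(json.dumps(summary.to_dict(), indent=2) + "\n")
        files.append("summary.json")
    if plot:
        try:
            name = plot_profiles(result, grid, out / "profiles.png")
            files.append(name)
        except Exception:  # pragma: no cover - plotting is best effort
            pass
    manifest = RunManifest.create(p, profile, grid, scenario, result, seed, files)
    manifest.write(out / "manifest.json")
    files.append("manifest.json")
    return files


def plot_profiles(result: SimulationResult, grid: Grid, path) -> str:
    """Concentration profile panels over time (1D) or final maps (2D)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    states = [*result.snapshots, result.final]
    if grid.dim == 1:
        fig, axes = plt.subplots(1, len(states), figsize=(3 * len(states), 2.8),
                                 sharey=True, squeeze=False)
        for ax, st in zip(axes[0], states):
            x = grid.x * 1e3
            ax.plot(x, st.d, color="0.4", label="Dorsal")
            ax.plot(x, st.s / max(st.s.max(), 1e-30), "b", label="Sog (scaled)")
            ax.plot(x, st.b, "r", label="BMP")
            ax.set_title(f"t = {st.t:.0f}")
            ax.set_xlabel("x (mm)")
        axes[0, 0].legend(fontsize=7)
    else:
        fig, axes = plt.subplots(1, 2, figsize=(8, 3))
        for ax, (field, label) in zip(axes, ((result.final.s, "Sog"),
                                             (result.final.b, "BMP"))):
            im = ax.imshow(field.T, origin="lower", aspect="auto",
                           extent=[0, grid.l_x * 1e3, 0, grid.l_y * 1e3])
            ax.set_title(label)
            ax.set_xlabel("x (mm)")
            ax.set_ylabel("y (mm)")
            fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return Path(path).name
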