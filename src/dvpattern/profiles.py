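"""Initial concentration fields for every simulated experiment.

The mobile species always start uniform (``s = 0.01``, ``b = 0.32``,
``c = 0.14``); what varies between experiments is the initial
NF-kB/Dorsal field: a broad ventral Gaussian of amplitude ``D0`` (0.3 in
the reference runs, 1 for twinning, 0.15 below threshold), an
AP-modulated variant for the two-dimensional robustness test, or a
uniform field with small seeded noise for stability checks.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .model import FieldState, ModelParameters

__all__ = [
    "ProfileSpec",
    "DEFAULT_S0",
    "DEFAULT_B0",
    "DEFAULT_C0",
    "gaussian_dorsal_profile",
    "modulated_profile_2d",
    "perturbed_uniform_profile",
    "initial_state",
]

# uniform starting concentrations of the mobile species
DEFAULT_S0 = 0.01
DEFAULT_B0 = 0.32
DEFAULT_C0 = 0.14


@dataclass(frozen=True)
class ProfileSpec:
    """Shape of the initial Dorsal field.

    ``sigma`` and ``center`` default to ``l_x / 2`` at construction of
    the field (a broad Gaussian whose tails reach the dorsal side — the
    value at the antipode is ``D0 * exp(-1/2)``).  The peak sits at
    ``x = l_x / 2``; that position is labelled the ventral midline in
    all outputs, with ``x = 0`` the dorsal midline.

    ``modulation_amp`` adds the fractional anterior-posterior modulation
    of amplitude and width used on the cylinder; ``noise_amp`` is only
    used by uniform perturbed profiles.
    """

    D0: float = 0.3
    sigma: float | None = None
    center: float | None = None
    modulation_amp: float = 0.0
    noise_amp: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.D0 < 0:
            raise ValueError("D0 must be >= 0")
        if not (0 <= self.modulation_amp < 1):
            raise ValueError("modulation_amp must lie in [0, 1)")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.noise_amp < 0:
            raise ValueError("noise_amp must be >= 0")

    def resolved_sigma(self, l_x: float) -> float:
        return self.sigma if self.sigma is not None else l_x / 2.0

    def resolved_center(self, l_x: float) -> float:
        return self.center if self.center is not None else l_x / 2.0

    def to_dict(self) -> dict:
        return asdict(self)


def _ring_distance(x: np.ndarray, center: float, l_x: float) -> np.ndarray:
    """Shortest signed distance to ``center`` on a ring of circumference ``l_x``."""
    return (x - center + l_x / 2.0) % l_x - l_x / 2.0


def gaussian_dorsal_profile(grid, D0: float, sigma: float, center: float) -> np.ndarray:
    """Periodically wrapped Gaussian Dorsal profile on a 1D ring.

    ``d(x) = D0 * exp(-delta(x, center)^2 / (2 sigma^2))`` with ``delta``
    the shortest distance on the ring, so the profile closes smoothly
    over the periodic seam and peaks at exactly ``D0``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    delta = _ring_distance(grid.x, center, grid.l_x)
    return D0 * np.exp(-(delta**2) / (2.0 * sigma**2))


def modulated_profile_2d(grid, D0: float, sigma: float, modulation_amp: float,
                         center: float | None = None) -> np.ndarray:
    """Dorsal field on the cylinder with amplitude and width varying along y.

    ``d(x, y) = D0 m(y) exp(-delta(x)^2 / (2 (sigma m(y))^2))`` with
    ``m(y) = 1 + modulation_amp * sin(pi y / l_y)``: both the amplitude
    and the standard deviation of the ventral peak swell by the given
    fraction mid-axis and shrink by it at the ends.
    """
    if grid.dim != 2:
        raise ValueError("modulated_profile_2d requires a 2D cylinder grid")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    center = grid.l_x / 2.0 if center is None else center
    delta = _ring_distance(grid.x, center, grid.l_x)[:, None]
    m = 1.0 + modulation_amp * np.sin(np.pi * grid.y / grid.l_y)[None, :]
    return D0 * m * np.exp(-(delta**2) / (2.0 * (sigma * m) ** 2))


def perturbed_uniform_profile(grid, level: float, noise_amp: float, seed: int) -> np.ndarray:
    """Uniform field plus seeded uniform noise in ``[-noise_amp, +noise_amp]``.

    Used to probe stability of the homogeneous state: below the Dorsal
    threshold such small fluctuations must not nucleate a stripe.
    """
    if noise_amp < 0 or level < noise_amp:
        raise ValueError("need level >= noise_amp >= 0 so the field stays nonnegative")
    rng = np.random.default_rng(seed)
    return level + rng.uniform(-noise_amp, noise_amp, size=grid.shape)


def initial_state(grid, spec: ProfileSpec, p: ModelParameters) -> FieldState:
    """Assemble the full starting state: uniform mobile species, Gaussian Dorsal."""
    sigma = spec.resolved_sigma(grid.l_x)
    center = spec.resolved_center(grid.l_x)
    if grid.dim == 2:
        d = modulated_profile_2d(grid, spec.D0, sigma, spec.modulation_amp, center)
    else:
        if spec.modulation_amp:
            raise ValueError("AP modulation requires a 2D cylinder grid")
        d = gaussian_dorsal_profile(grid, spec.D0, sigma, center)
    shape = grid.shape
    return FieldState(
        s=np.full(shape, DEFAULT_S0),
        b=np.full(shape, DEFAULT_B0),
        c=np.full(shape, DEFAULT_C0),
        d=d,
        t=0.0,
    )
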