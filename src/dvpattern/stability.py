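"""Linear stability of the homogeneous state and the Turing instability map.

With Dorsal treated as a spatially uniform, tunable parameter, small
sinusoidal perturbations of the mobile species around the homogeneous
fixed point obey ``w (δs, δb, δc) = (A - D k²)(δs, δb, δc)`` where ``A``
is the reaction Jacobian at the fixed point and ``D`` the diagonal
diffusion matrix.  The homogeneous state is stable iff every eigenvalue
has a negative real part for every wavenumber ``k = 2πn / l_x``
admissible on the ring.  Pattern formation switches on when either the
complex diffusion constant or the Dorsal level is raised past the
boundary ``max Re w = 0`` at the lowest nonzero wavenumber.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ModelParameters, dorsal_for_eta_bar, eta_bar, homogeneous_fixed_point

__all__ = [
    "DispersionResult",
    "jacobian",
    "dispersion_max_eigenvalue",
    "stability_scan",
    "smallest_ring_wavenumber",
]


def smallest_ring_wavenumber(p: ModelParameters) -> float:
    """``k = 2π / l_x``, the lowest nonzero mode the circumference admits."""
    return 2.0 * np.pi / p.l_x


@dataclass(frozen=True)
class DispersionResult:
    k: float
    eigenvalues: np.ndarray  # three complex eigenvalues of A - D k^2
    w_max: float             # largest real part


def _diffusion_matrix(p: ModelParameters, literal_printed: bool = False) -> np.ndarray:
    """Diagonal diffusion matrix for the (s, b, c) perturbation system.

    ``literal_printed=True`` reproduces a variant with ``D_s`` in the
    BMP slot instead of ``D_b``; since both are negligible against
    ``D_c`` the instability boundary is insensitive to the choice.
    """
    Db = p.D_s if literal_printed else p.D_b
    return np.diag([p.D_s, Db, p.D_c])


def jacobian(d: float, p: ModelParameters,
             eta_bar_value: float | None = None) -> np.ndarray:
    """Reaction Jacobian ``A = ∂(f_s, f_b, f_c)/∂(s, b, c)`` at the fixed point.

    ``d`` is the uniform Dorsal level; alternatively the lumped
    BMP-free expression rate can be pinned directly via
    ``eta_bar_value`` (as in the parameter scans).
    """
    if eta_bar_value is None:
        eta_bar_value = eta_bar(d, p)
        sbar, bbar, cbar = homogeneous_fixed_point(d, p)
    else:
        sbar, bbar, cbar = fixed_point_at_eta_bar(eta_bar_value, p)
    cl = p.cleavage
    kp, km = p.k_plus, p.k_minus
    d_eta_db = -eta_bar_value / (p.b0 * (1.0 + bbar / p.b0) ** 2)
    return np.array([
        [-kp * bbar - p.alpha_s, d_eta_db - kp * sbar, km],
        [-kp * bbar, -kp * sbar - p.alpha_b, km + cl],
        [kp * bbar, kp * sbar, -(km + cl)],
    ])


def fixed_point_at_eta_bar(value: float, p: ModelParameters) -> tuple[float, float, float]:
    """Homogeneous fixed point with the expression rate pinned at ``value``.

    Identical to :func:`dvpattern.model.homogeneous_fixed_point` except
    the Dorsal dependence enters only through the lumped rate, which may
    exceed the range reachable by any ``d`` (useful for scans)."""
    if p.alpha_b == 0.0:
        raise ValueError("alpha_b = 0: no finite fixed point")
    bbar = p.eta_b / p.alpha_b
    cl = p.cleavage
    denom_c = p.k_minus + cl
    loss_s = p.alpha_s + p.k_plus * bbar * cl / denom_c
    sbar = value / (1.0 + bbar / p.b0) / loss_s
    cbar = p.k_plus * sbar * bbar / denom_c
    return sbar, bbar, cbar


def dispersion_max_eigenvalue(k: float, d: float, p: ModelParameters,
                              eta_bar_value: float | None = None,
                              literal_printed_D: bool = False) -> DispersionResult:
    """Eigenvalues of ``A - D k²`` and their largest real part.

    At ``k = 0`` this reduces to the spectrum of the reaction Jacobian
    alone; instability of a band of nonzero ``k`` at stable ``k = 0`` is
    the Turing signature."""
    A = jacobian(d, p, eta_bar_value)
    M = A - _diffusion_matrix(p, literal_printed_D) * k**2
    ev = np.linalg.eigvals(M)
    return DispersionResult(k=float(k), eigenvalues=ev, w_max=float(ev.real.max()))


_AXIS_NAMES = ("D_c", "d", "eta_bar")


def stability_scan(axis1: tuple[str, np.ndarray], axis2: tuple[str, np.ndarray],
                   p: ModelParameters, k: float | None = None,
                   literal_printed_D: bool = False):
    """Map ``max Re w`` over a 2-parameter grid and extract the boundary.

    Axes may be ``"D_c"``, ``"d"`` (uniform Dorsal level) or
    ``"eta_bar"`` (the lumped BMP-free expression rate; ``d`` values are
    converted through it, so the two parameterizations give the same
    map).  ``k`` defaults to the smallest nonzero ring wavenumber.

    Returns
    -------
    dict with ``axis1``, ``axis2`` (names and value arrays), ``w_max``
    (2D array, axis1 varying along rows) and ``boundary`` — for each
    axis1 value, the axis2 location where ``w_max`` crosses zero
    (linear interpolation; NaN when no crossing).
    """
    (n1, v1), (n2, v2) = axis1, axis2
    for n in (n1, n2):
        if n not in _AXIS_NAMES:
            raise ValueError(f"unsupported scan axis {n!r}; choose from {_AXIS_NAMES}")
    if n1 == n2:
        raise ValueError("scan axes must differ")
    k = smallest_ring_wavenumber(p) if k is None else k
    v1 = np.asarray(v1, dtype=float)
    v2 = np.asarray(v2, dtype=float)

    def point(a1, a2):
        pp, d_level, ebv = p, 0.0, None
        for name, val in ((n1, a1), (n2, a2)):
            if name == "D_c":
                pp = pp.with_overrides(D_c=val)
            elif name == "d":
                d_level = val
            else:
                ebv = val
        return dispersion_max_eigenvalue(k, d_level, pp, eta_bar_value=ebv,
                                         literal_printed_D=literal_printed_D).w_max

    w = np.array([[point(a1, a2) for a2 in v2] for a1 in v1])
    boundary = np.full(v1.size, np.nan)
    for i in range(v1.size):
        row = w[i]
        sign_change = np.nonzero(np.diff(np.sign(row)))[0]
        if sign_change.size:
            j = sign_change[0]
            f = row[j] / (row[j] - row[j + 1])
            boundary[i] = v2[j] + f * (v2[j + 1] - v2[j])
    return {
        "axis1": (n1, v1), "axis2": (n2, v2), "k": k,
        "w_max": w, "boundary": boundary,
    }
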