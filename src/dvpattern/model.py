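"""Core reaction network of the BMP/Sog dorsoventral patterning model.

Four species live on the embryonic circumference: free Sog (``s``), free
BMP (``b``), the fast-diffusing Sog-BMP complex (``c``) and the polarity
cue NF-kB/Dorsal (``d``).  BMP represses *sog* transcription, Dorsal
enhances it, Sog sequesters BMP into complexes whose rapid transport
depletes BMP near regions of high *sog* expression.  This module holds
the rate constants, the *sog* regulation function, the pointwise
reaction terms and the closed-form spatially homogeneous fixed point;
space and time live in :mod:`dvpattern.dynamics`.

Units are arbitrary but read naturally as seconds for time and meters
for length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields, replace
from typing import Literal

import numpy as np

__all__ = [
    "ModelParameters",
    "FieldState",
    "sog_expression_rate",
    "eta_bar",
    "dorsal_for_eta_bar",
    "reaction_terms",
    "homogeneous_fixed_point",
]


@dataclass(frozen=True)
class ModelParameters:
    """Rate, binding and diffusion constants of the patterning network.

    Defaults are the published reference set.  ``alpha_d`` (Dorsal decay)
    has no published value; the default here is calibrated so that the
    initial Dorsal amplitude threshold for stripe formation falls between
    0.15 and 0.3 (see :func:`dvpattern.scenarios.calibrate_alpha_d`).

    Attributes
    ----------
    eta0:
        Basal *sog* expression rate with neither Dorsal nor BMP present.
    eta1:
        Asymptotic *sog* expression rate at saturating Dorsal, ``eta1 > eta0``.
    b0:
        BMP concentration that halves *sog* expression.
    d0:
        Dorsal concentration at which the Dorsal-dependent activation
        reaches its midpoint ``(eta0 + eta1) / 2``.
    eta_b:
        Constitutive BMP production rate.
    alpha_s:
        Free-Sog degradation rate (Tolloid-mediated cleavage).
    alpha_b:
        Free-BMP degradation rate.
    alpha_c:
        Alternative complex-cleavage rate, used only when
        ``complex_cleavage_rate == "alpha_c"``.
    alpha_d:
        Dorsal decay rate; the polarity cue fades with this rate.
    k_plus, k_minus:
        Sog + BMP binding and complex dissociation rates.
    D_s, D_b, D_c:
        Diffusion constants.  Pattern formation requires ``D_c`` to
        exceed both ``D_s`` and ``D_b``: the complex is the long-range
        carrier that shuttles BMP away from the Sog stripe.
    l_x, l_y:
        Embryo circumference and cylinder-axis extent.
    complex_cleavage_rate:
        Which constant multiplies the complex-cleavage flux (``alpha_s c``
        released into BMP, removed from the complex).  The reference
        equations use ``alpha_s`` for both free Sog and the complex;
        ``"alpha_c"`` switches the complex term to ``alpha_c``.
    """

    eta0: float = 2.8e-4
    eta1: float = 2e-3
    b0: float = 0.2
    d0: float = 1.0
    eta_b: float = 4e-5
    alpha_s: float = 2e-3
    alpha_b: float = 5e-5
    alpha_c: float = 2e-4
    alpha_d: float = 1.25e-4
    k_plus: float = 5.0
    k_minus: float = 5e-5
    D_s: float = 1.5e-13
    D_b: float = 7.8e-13
    D_c: float = 2.5e-9
    l_x: float = 0.0017
    l_y: float = 0.002
    complex_cleavage_rate: Literal["alpha_s", "alpha_c"] = "alpha_s"

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            if f.name == "complex_cleavage_rate":
                continue
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"parameter {f.name} must be finite and >= 0, got {v}")
        if self.eta1 <= self.eta0:
            raise ValueError("eta1 must exceed eta0 (Dorsal enhances sog expression)")
        if self.complex_cleavage_rate not in ("alpha_s", "alpha_c"):
            raise ValueError("complex_cleavage_rate must be 'alpha_s' or 'alpha_c'")

    @property
    def cleavage(self) -> float:
        """Effective complex-cleavage constant selected by the config switch."""
        return self.alpha_s if self.complex_cleavage_rate == "alpha_s" else self.alpha_c

    def with_overrides(self, **kwargs: float) -> "ModelParameters":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass
class FieldState:
    """Concentration fields of all four species at one instant.

    Arrays share a common shape, ``(nx,)`` on a ring or ``(nx, ny)`` on a
    cylinder; the owning grid defines the coordinates.
    """

    s: np.ndarray
    b: np.ndarray
    c: np.ndarray
    d: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.s, self.b, self.c, self.d)}
        if len(shapes) != 1:
            raise ValueError(f"species arrays must share one shape, got {shapes}")

    @property
    def shape(self) -> tuple:
        return self.s.shape

    def copy(self) -> "FieldState":
        return FieldState(self.s.copy(), self.b.copy(), self.c.copy(), self.d.copy(), self.t)

    def min_concentration(self) -> float:
        return min(float(a.min()) for a in (self.s, self.b, self.c, self.d))


def _check_nonneg(name: str, value) -> None:
    if np.any(np.asarray(value) < 0):
        raise ValueError(f"{name} must be nonnegative")


def sog_expression_rate(b, d, p: ModelParameters):
    """Transcription rate of *sog* given local BMP ``b`` and Dorsal ``d``.

    Michaelis-Menten repression by BMP combined with saturating activation
    by Dorsal::

        eta_s(b, d) = (eta0 + eta1 * d/d0) / ((1 + b/b0) * (1 + d/d0))

    Strictly decreasing in ``b``, strictly increasing in ``d`` (because
    ``eta1 > eta0``), and bounded by ``eta1``.
    """
    _check_nonneg("b", b)
    _check_nonneg("d", d)
    b = np.asarray(b, dtype=float)
    d = np.asarray(d, dtype=float)
    out = (p.eta0 + p.eta1 * d / p.d0) / ((1.0 + b / p.b0) * (1.0 + d / p.d0))
    return out if out.ndim else float(out)


def eta_bar(d, p: ModelParameters):
    """BMP-free *sog* expression rate ``eta_s(0, d)``.

    The Dorsal level enters the dynamics only through this lumped rate,
    which interpolates from ``eta0`` at ``d = 0`` to ``eta1`` at
    saturating Dorsal.
    """
    _check_nonneg("d", d)
    d = np.asarray(d, dtype=float)
    out = (p.eta0 + p.eta1 * d / p.d0) / (1.0 + d / p.d0)
    return out if out.ndim else float(out)


def dorsal_for_eta_bar(value: float, p: ModelParameters) -> float:
    """Invert :func:`eta_bar`: the Dorsal level giving the requested rate.

    Defined for ``eta0 <= value < eta1``.
    """
    if not (p.eta0 <= value < p.eta1):
        raise ValueError(
            f"eta_bar value {value} outside attainable range [{p.eta0}, {p.eta1})"
        )
    return p.d0 * (value - p.eta0) / (p.eta1 - value)


def reaction_terms(s, b, c, d, p: ModelParameters):
    """Pointwise reaction rates ``(f_s, f_b, f_c)`` of the three mobile species.

    ::

        f_s = eta_s(b, d) - k+ s b + k- c - alpha_s s
        f_b = eta_b       - k+ s b + k- c + alpha_cl c - alpha_b b
        f_c =               k+ s b - k- c - alpha_cl c

    where ``alpha_cl`` is the complex-cleavage constant (``alpha_s`` by
    default).  Cleavage of the complex destroys the Sog moiety and
    releases the BMP moiety intact; degradation of BMP inside the
    complex is neglected.  Dorsal has no reaction term here — it decays
    autonomously in the dynamics.
    """
    for name, v in (("s", s), ("b", b), ("c", c)):
        _check_nonneg(name, v)
    s = np.asarray(s, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    cl = p.cleavage
    bind = p.k_plus * s * b
    f_s = sog_expression_rate(b, d, p) - bind + p.k_minus * c - p.alpha_s * s
    f_b = p.eta_b - bind + p.k_minus * c + cl * c - p.alpha_b * b
    f_c = bind - p.k_minus * c - cl * c
    if np.ndim(f_c) == 0:
        return float(f_s), float(f_b), float(f_c)
    return f_s, f_b, f_c


def homogeneous_fixed_point(d: float, p: ModelParameters) -> tuple[float, float, float]:
    """Spatially uniform steady state ``(s̄, b̄, c̄)`` at fixed Dorsal level ``d``.

    Solving ``f_c = 0`` gives ``c̄ = k+ s̄ b̄ / (k- + alpha_cl)``;
    substituting into ``f_b = 0`` makes every binding/cleavage flux
    cancel, leaving ``b̄ = eta_b / alpha_b``; ``f_s = 0`` then yields::

        s̄ = eta_s(b̄, d) / (alpha_s + k+ b̄ alpha_cl / (k- + alpha_cl))

    The root is unique among nonnegative states.

    Raises
    ------
    ValueError
        If ``alpha_b == 0`` while BMP is produced (``eta_b > 0``): total
        BMP then grows without bound and no finite fixed point exists.
    """
    _check_nonneg("d", d)
    if p.alpha_b == 0.0:
        if p.eta_b > 0.0:
            raise ValueError(
                "alpha_b = 0 with eta_b > 0: BMP has no sink, no finite fixed point"
            )
        bbar = 0.0
    else:
        bbar = p.eta_b / p.alpha_b
    cl = p.cleavage
    denom_c = p.k_minus + cl
    if denom_c == 0.0:
        # complex neither dissociates nor cleaves: with binding it would
        # absorb everything; only sensible when no binding occurs
        if p.k_plus * bbar != 0.0:
            raise ValueError("k_minus + cleavage = 0 with active binding: no fixed point")
        sbar = eta_bar(d, p) / ((1.0 + bbar / p.b0) * p.alpha_s) if p.alpha_s else 0.0
        return sbar, bbar, 0.0
    loss_s = p.alpha_s + p.k_plus * bbar * cl / denom_c
    sbar = sog_expression_rate(bbar, d, p) / loss_s
    cbar = p.k_plus * sbar * bbar / denom_c
    return float(sbar), float(bbar), float(cbar)
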