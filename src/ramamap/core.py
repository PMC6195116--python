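"""Closed-form Ramachandran-number mathematics.

The Ramachandran number ℛ collapses the two backbone dihedral angles
(φ, ψ) of one residue into a single scalar in [0, 1] by sweeping the
Ramachandran plot along lines parallel to the negatively sloping
diagonal: ℛ depends only on φ + ψ and increases from the bottom-left
corner of the plot to the top-right.  With the default angle range
[−180°, 180°) the closed form is

    ℛ(φ, ψ) = (φ + ψ + 360°) / 720°

which places right-handed α-helices near ℛ ≈ 0.34, β-strands near
ℛ ≈ 0.52 and polyproline-II helices near ℛ ≈ 0.6.

This module also provides:

* a *signed* variant ℛₛ that multiplies ℛ by −1 when ψ < φ, resolving
  the ambiguity between mirror-image conformations of achiral backbones
  (e.g. polyglycines and peptoids, where ppII and the α_D helix fall on
  the same diagonal sweep);
* the original σ-discretized formulation, which tiles the plot with
  (360σ)² cells and indexes them along diagonal sweeps with integer
  labels — its σ → ∞ limit is the simplified closed form above, and it
  serves here as an independent numerical oracle;
* the per-residue trajectory deviation metrics D₁ = |ℛ_t − ℛ₁| and
  D₋₁ = |ℛ_t − ℛ_{t−1}|.

All functions accept scalars or array-likes and propagate NaN, the
in-band representation of an undefined dihedral (chain termini, chain
breaks, missing atoms).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AngleBounds",
    "DEFAULT_BOUNDS",
    "ramachandran_number",
    "signed_ramachandran_number",
    "discretized_ramachandran_number",
    "deviation_from_first",
    "deviation_from_previous",
]

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class AngleBounds:
    """Half-open angle ranges [phi_min, phi_max) × [psi_min, psi_max).

    Each range must span exactly 360°.  The default, [−180°, 180°) for
    both angles, is the convention used throughout; an alternative such
    as [0°, 360°) shifts the meaning of ℛ but keeps the formula valid.
    Use :meth:`from_radians` when the limits are given in radians.
    """

    phi_min: float = -180.0
    phi_max: float = 180.0
    psi_min: float = -180.0
    psi_max: float = 180.0

    def __post_init__(self) -> None:
        if not (
            math.isclose(self.phi_max - self.phi_min, 360.0, abs_tol=1e-9)
            and math.isclose(self.psi_max - self.psi_min, 360.0, abs_tol=1e-9)
        ):
            raise ValueError(
                "each angle range must span exactly 360 degrees, got "
                f"phi span {self.phi_max - self.phi_min}, "
                f"psi span {self.psi_max - self.psi_min}"
            )

    @property
    def lam(self) -> float:
        """Range width λ (360° by construction)."""
        return self.phi_max - self.phi_min

    @classmethod
    def from_radians(
        cls,
        phi_min: float = -math.pi,
        psi_min: float = -math.pi,
    ) -> "AngleBounds":
        """Build bounds from lower limits given in radians."""
        pmin = math.degrees(phi_min)
        smin = math.degrees(psi_min)
        return cls(pmin, pmin + 360.0, smin, smin + 360.0)


DEFAULT_BOUNDS = AngleBounds()


def _as_float(x):
    arr = np.asarray(x, dtype=float)
    if np.isinf(arr).any():
        raise ValueError("dihedral angles must be finite or NaN (undefined)")
    return arr


def _wrap(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Wrap angles into [lo, lo + 360), leaving values already inside
    the *closed* interval [lo, hi] untouched.

    The closed upper edge is deliberate: an input sitting exactly on the
    upper boundary (e.g. φ = ψ = 180° with default bounds) keeps its
    face value so that ℛ = 1.0 is reachable; 1.0 and 0.0 label the same
    conformation, one full diagonal sweep apart.
    """
    inside = (x >= lo) & (x <= hi)
    wrapped = lo + np.mod(x - lo, 360.0)
    return np.where(inside, x, wrapped)


def ramachandran_number(phi, psi, bounds: AngleBounds = DEFAULT_BOUNDS):
    """Simplified Ramachandran number ℛ(φ, ψ) ∈ [0, 1].

    Parameters
    ----------
    phi, psi:
        Backbone dihedrals in degrees (scalar or array-like).  Values
        outside the bounds are wrapped by multiples of 360°; NaN marks
        an undefined dihedral and yields NaN.
    bounds:
        Angle-range convention; default [−180°, 180°)².

    Returns
    -------
    float or ndarray
        (φ + ψ − (φ_min + ψ_min)) / ((φ_max + ψ_max) − (φ_min + ψ_min)),
        i.e. (φ + ψ + 360)/720 with the default bounds.
    """
    phi = _wrap(_as_float(phi), bounds.phi_min, bounds.phi_max)
    psi = _wrap(_as_float(psi), bounds.psi_min, bounds.psi_max)
    lo = bounds.phi_min + bounds.psi_min
    hi = bounds.phi_max + bounds.psi_max
    r = (phi + psi - lo) / (hi - lo)
    return r if r.ndim else float(r)


def signed_ramachandran_number(phi, psi, bounds: AngleBounds = DEFAULT_BOUNDS):
    """Signed Ramachandran number ℛₛ ∈ [−1, 1].

    |ℛₛ| equals :func:`ramachandran_number`; the sign is positive when
    ψ ≥ φ (upper-left half of the plot, where chiral backbones live)
    and negative when ψ < φ.  The comparison uses the wrapped angles,
    and the boundary ψ = φ belongs to the positive branch.
    """
    phi = _wrap(_as_float(phi), bounds.phi_min, bounds.phi_max)
    psi = _wrap(_as_float(psi), bounds.psi_min, bounds.psi_max)
    r = ramachandran_number(phi, psi, bounds)
    sign = np.where(psi >= phi, 1.0, -1.0)
    sign = np.where(np.isnan(np.asarray(phi, float) + np.asarray(psi, float)), np.nan, sign)
    out = np.asarray(r) * sign
    return out if out.ndim else float(out)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # [x] = nearest integer; half-ties resolved away from zero.
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def _integer_rnumber(phi, psi, sigma: float, lam: float):
    """Unnormalized integer-spaced Ramachandran number R_ℤ.

    Tiles the plot with squares of side 1/σ and labels them with
    increasing integers along −1/2-sloped diagonal sweeps from the
    bottom-left corner.
    """
    t1 = _round_half_away((phi - psi + lam) * sigma / _SQRT2)
    width = _round_half_away(_SQRT2 * lam * sigma)
    t2 = _round_half_away((phi + psi + lam) * sigma / _SQRT2)
    return t1 + width * t2


def discretized_ramachandran_number(
    phi, psi, sigma: float, bounds: AngleBounds = DEFAULT_BOUNDS
):
    """σ-discretized Ramachandran number (the original formulation).

    Normalizes R_ℤ between its values at the lower and upper corners of
    the bounds.  As σ → ∞ this converges to
    :func:`ramachandran_number`; at finite σ it differs by O(1/(λσ)),
    which makes it a useful independent oracle for the closed form.

    Parameters
    ----------
    sigma:
        Scaling factor in reciprocal degrees, > 0.  Cell side is 1/σ.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    phi = _wrap(_as_float(phi), bounds.phi_min, bounds.phi_max)
    psi = _wrap(_as_float(psi), bounds.psi_min, bounds.psi_max)
    lam = bounds.lam
    r_lo = _integer_rnumber(bounds.phi_min, bounds.psi_min, sigma, lam)
    r_hi = _integer_rnumber(bounds.phi_max, bounds.psi_max, sigma, lam)
    r = (_integer_rnumber(phi, psi, sigma, lam) - r_lo) / (r_hi - r_lo)
    return r if np.ndim(r) else float(r)


def _deviation(series, reference: str) -> np.ndarray:
    s = np.asarray(series, dtype=float)
    if s.ndim != 1 or s.size == 0:
        raise ValueError("series must be a non-empty 1-D sequence")
    out = np.empty_like(s)
    out[0] = 0.0 if np.isfinite(s[0]) else np.nan
    if reference == "first":
        out[1:] = np.abs(s[1:] - s[0])
    else:
        out[1:] = np.abs(np.diff(s))
    return out


def deviation_from_first(series) -> np.ndarray:
    """Per-frame deviation D₁ = |ℛ_t − ℛ₁| for one residue's series.

    The first element is 0 by definition; NaN entries (undefined ℛ)
    propagate to NaN deviations.
    """
    return _deviation(series, "first")


def deviation_from_previous(series) -> np.ndarray:
    """Per-frame deviation D₋₁ = |ℛ_t − ℛ_{t−1}|; first element is 0."""
    return _deviation(series, "previous")
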