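"""Worm-like-chain mechanics for dsDNA and ssDNA.

Two elasticity models underpin every length conversion in the pipeline:

* an extensible worm-like chain for double-stranded DNA,

  .. math:: x/L_c = 1 - \\tfrac12 \\sqrt{k_BT/(F L_p)} + F/S,

  with persistence length ``Lp = 51.1`` nm and stretch modulus
  ``S = 1006`` pN appropriate for ~100 mM NaCl, and

* the Marko–Siggia interpolation for single-stranded DNA,

  .. math:: F = \\frac{k_BT}{L_p}\\left(\\tfrac14 (1-x/L_c)^{-2}
            + x/L_c - \\tfrac14\\right),

  with ``Lp = 0.87`` nm and contour length ``0.69`` nm/nt.

At the reference force of 17 pN the dsDNA model gives an extension of
0.33 nm per base pair (helical rise 0.34 nm/bp), the factor used to turn
tether extensions into telomere lengths in base pairs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "KBT_PN_NM",
    "DsWlcParams",
    "SsWlcParams",
    "ds_relative_extension",
    "extension_to_bp",
    "bp_to_extension",
    "nm_per_bp",
    "ss_force",
    "ss_relative_extension",
    "ss_nm_per_nt",
]

#: Thermal energy k_B * 296.15 K (23 degrees C), pN nm.
KBT_PN_NM = 4.089


@dataclass(frozen=True)
class DsWlcParams:
    """Extensible WLC parameters for double-stranded DNA.

    Attributes
    ----------
    persistence_length : float
        Bending persistence length, nm.
    stretch_modulus : float
        Enthalpic stretch modulus S, pN.
    rise_per_bp : float
        Helical rise (contour length per base pair), nm/bp.
    thermal_energy : float
        k_B T, pN nm.
    """

    persistence_length: float = 51.1
    stretch_modulus: float = 1006.0
    rise_per_bp: float = 0.34
    thermal_energy: float = KBT_PN_NM

    def __post_init__(self) -> None:
        for name in ("persistence_length", "stretch_modulus", "rise_per_bp",
                     "thermal_energy"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 3.8 <= self.thermal_energy <= 4.3:
            raise ValueError(
                "thermal_energy outside [3.8, 4.3] pN nm (0-40 degrees C)")


@dataclass(frozen=True)
class SsWlcParams:
    """Marko–Siggia WLC parameters for single-stranded DNA."""

    persistence_length: float = 0.87
    contour_per_nt: float = 0.69
    thermal_energy: float = KBT_PN_NM

    def __post_init__(self) -> None:
        for name in ("persistence_length", "contour_per_nt", "thermal_energy"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


def ds_relative_extension(force, params: DsWlcParams | None = None):
    """Relative extension x/Lc of dsDNA at a stretching force.

    Parameters
    ----------
    force : float or array_like
        Stretching force, pN.  Must be strictly positive — the
        inverse-square-root entropic term diverges at zero force.
    params : DsWlcParams, optional

    Returns
    -------
    float or ndarray
        x/Lc (dimensionless).  May exceed 1 at very high force because of
        the enthalpic F/S term.
    """
    p = params or DsWlcParams()
    f = np.asarray(force, dtype=float)
    if np.any(f <= 0):
        raise ValueError("force must be strictly positive (model diverges at F = 0)")
    rel = (1.0
           - 0.5 * np.sqrt(p.thermal_energy / (f * p.persistence_length))
           + f / p.stretch_modulus)
    return rel if rel.ndim else float(rel)


def nm_per_bp(force: float, params: DsWlcParams | None = None) -> float:
    """Extension per base pair at a given force, nm/bp."""
    p = params or DsWlcParams()
    return p.rise_per_bp * ds_relative_extension(force, p)


def extension_to_bp(extension, force: float,
                    params: DsWlcParams | None = None):
    """Convert a dsDNA tether extension (nm) at ``force`` (pN) to base pairs."""
    ext = np.asarray(extension, dtype=float)
    if np.any(ext < 0):
        raise ValueError("extension must be non-negative")
    bp = ext / nm_per_bp(force, params)
    return bp if bp.ndim else float(bp)


def bp_to_extension(n_bp, force: float,
                    params: DsWlcParams | None = None):
    """Predicted dsDNA extension (nm) of ``n_bp`` base pairs at ``force`` (pN)."""
    n = np.asarray(n_bp, dtype=float)
    ext = n * nm_per_bp(force, params)
    return ext if ext.ndim else float(ext)


def ss_force(relative_extension, params: SsWlcParams | None = None):
    """Marko–Siggia force (pN) of ssDNA at relative extension r = x/Lc.

    Monotone increasing on [0, 1); diverges as r -> 1.
    """
    p = params or SsWlcParams()
    r = np.asarray(relative_extension, dtype=float)
    if np.any(r < 0) or np.any(r >= 1):
        raise ValueError("relative extension must lie in [0, 1)")
    f = (p.thermal_energy / p.persistence_length
         * (0.25 * (1.0 - r) ** -2 + r - 0.25))
    return f if f.ndim else float(f)


def ss_relative_extension(force: float,
                          params: SsWlcParams | None = None,
                          xtol: float = 1e-9) -> float:
    """Numeric inverse of :func:`ss_force`: the unique r in [0, 1) at ``force``.

    Solved by bracketed root finding to absolute tolerance ``xtol``.
    """
    if force < 0:
        raise ValueError("force must be non-negative")
    if force == 0:
        return 0.0
    p = params or SsWlcParams()

    def resid(r: float) -> float:
        return ss_force(r, p) - force

    hi = 1.0 - 1e-12
    if resid(hi) < 0:  # pragma: no cover - unreachable for finite force
        raise ValueError("force beyond model range")
    return float(brentq(resid, 0.0, hi, xtol=xtol))


def ss_nm_per_nt(force: float, params: SsWlcParams | None = None) -> float:
    """ssDNA extension per nucleotide at ``force``, nm/nt."""
    p = params or SsWlcParams()
    return p.contour_per_nt * ss_relative_extension(force, p)
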