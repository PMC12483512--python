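"""Unit conventions and ideal Gaussian-chain statistics.

All lengths are in base pairs (1 bp = 0.34 nm), energies in units of
``k_B T``, and times in the simulation unit ``t0 = bp^2 / D_site``, where
``D_site`` is the diffusion coefficient of a single coarse-grained chain
site.  Conversion to SI happens only at the biochemical-rate boundary
(:mod:`idrsearch.theory`).

The transcription factor (TF) is modelled as an ideal (Rouse) bead-spring
chain: ``n_b`` binding sites on the intrinsically disordered region (IDR)
plus one DNA-binding-domain (DBD) site at a chain end, connected by
segments of statistical length ``l0``.  For an ideal chain the separation
of any two sites ``n_seg`` segments apart is Gaussian with variance
``n_seg * l0**2``, which is all the equilibrium theory needs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BP_IN_NM",
    "BP_IN_M",
    "UnitSystem",
    "TFArchitecture",
    "gaussian_propagator",
]

#: One base pair in nanometres.
BP_IN_NM = 0.34
#: One base pair in metres.
BP_IN_M = 0.34e-9


@dataclass(frozen=True)
class UnitSystem:
    """Internal unit conventions (bp, k_BT, t0 = bp^2/D_site)."""

    bp_in_nm: float = BP_IN_NM

    def bp_to_nm(self, x: float) -> float:
        return x * self.bp_in_nm

    def nm_to_bp(self, x: float) -> float:
        return x / self.bp_in_nm

    def bp3_to_nm3(self, v: float) -> float:
        return v * self.bp_in_nm**3

    def nm3_to_bp3(self, v: float) -> float:
        return v / self.bp_in_nm**3

    def time_t0_to_seconds(self, t_t0: float, d_si: float) -> float:
        """Convert a time in t0 units to seconds given D_site in m^2/s."""
        if d_si <= 0:
            raise ValueError("D_site must be positive")
        return t_t0 * BP_IN_M**2 / d_si


@dataclass(frozen=True)
class TFArchitecture:
    """Coarse-grained TF chain: ``n_b`` IDR sites plus one terminal DBD site.

    Parameters
    ----------
    n_b:
        Number of IDR binding sites (>= 0).
    l0:
        Segment length between adjacent sites, in bp (> 0).
    dbd_index:
        Chain index of the DBD site. The DBD sits at a chain end; by
        convention index 0 (IDR sites are 1..n_b).
    """

    n_b: int
    l0: float
    dbd_index: int = 0
    n_tilde: int = field(init=False)
    gyration_radius: float = field(init=False)

    def __post_init__(self) -> None:
        if self.n_b < 0:
            raise ValueError("n_b must be >= 0")
        if self.l0 <= 0:
            raise ValueError("l0 must be positive")
        if self.dbd_index not in (0, self.n_b):
            raise ValueError("DBD site must be terminal (index 0 or n_b)")
        object.__setattr__(self, "n_tilde", self.n_b + 1)
        object.__setattr__(
            self, "gyration_radius", math.sqrt(self.n_tilde / 6.0) * self.l0
        )

    @property
    def r_p(self) -> float:
        """Gyration radius r_p = sqrt(n_tilde/6) * l0 (bp)."""
        return self.gyration_radius


def gaussian_propagator(r, n_seg, l0):
    """Probability density of the end-to-end vector of an ideal subchain.

    For two sites separated by ``n_seg`` Gaussian segments of length
    ``l0`` the 3D density of their separation ``r`` is

        f(r, l) = (3 / (2 pi l^2))^{3/2} exp(-3 r^2 / (2 l^2)),

    with ``l = sqrt(n_seg) * l0``.  Units: bp^-3.

    Parameters may be scalars or arrays (broadcast).
    """
    r = np.asarray(r, dtype=float)
    n_seg_arr = np.asarray(n_seg, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation r must be >= 0")
    if np.any(n_seg_arr < 1):
        raise ValueError("n_seg must be >= 1")
    if l0 <= 0:
        raise ValueError("l0 must be positive")
    l2 = n_seg_arr * float(l0) ** 2
    out = (3.0 / (2.0 * np.pi * l2)) ** 1.5 * np.exp(-3.0 * r**2 / (2.0 * l2))
    if out.ndim == 0:
        return float(out)
    return out


def log_gaussian_propagator(r2, n_seg, l0):
    """``log f`` evaluated from the squared separation (vectorised)."""
    l2 = np.asarray(n_seg, dtype=float) * float(l0) ** 2
    return 1.5 * np.log(3.0 / (2.0 * np.pi * l2)) - 3.0 * np.asarray(r2) / (2.0 * l2)
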