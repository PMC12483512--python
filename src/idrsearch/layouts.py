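"""Target layouts: DBD target plus IDR targets on a linear DNA "antenna".

A layout is a set of 3D points (bp) on a straight line through the DBD
target, which sits at the origin.  Two arrangements are used:

* ``one_sided`` — the ``n_t`` IDR targets sit consecutively on one side of
  the DBD target (the convention for the equilibrium configuration sums,
  matching a DBD at the chain end).
* ``symmetric`` — IDR targets alternate on both sides of the central DBD
  target (the antenna geometry of the dynamical search simulations).

Spacings are either exactly ``d`` (``equal`` mode) or exponentially
distributed with mean ``d`` (``poisson`` mode, for robustness checks).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["TargetLayout", "make_layout"]

_MODES = ("equal", "poisson")
_SIDES = ("one_sided", "symmetric")


@dataclass(frozen=True)
class TargetLayout:
    """Positions of the DBD target (origin) and ``n_t`` IDR targets."""

    positions: np.ndarray  # (n_t + 1, 3), row 0 is the DBD target
    d: float  # nominal (mean) spacing, bp
    n_t: int
    mode: str = "equal"
    side: str = "one_sided"
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    L: Optional[float] = None  # antenna length, bp

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        ax = np.asarray(self.axis, dtype=float)
        norm = np.linalg.norm(ax)
        if norm == 0:
            raise ValueError("axis must be a nonzero vector")
        object.__setattr__(self, "axis", ax / norm)
        if pos.shape != (self.n_t + 1, 3):
            raise ValueError("positions must have shape (n_t + 1, 3)")
        if not np.allclose(pos[0], 0.0):
            raise ValueError("DBD target must sit at the origin")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.side not in _SIDES:
            raise ValueError(f"side must be one of {_SIDES}")
        # collinearity along axis
        proj = pos @ self.axis
        offaxis = pos - proj[:, None] * self.axis[None, :]
        if self.n_t > 0 and np.max(np.abs(offaxis)) > 1e-9:
            raise ValueError("targets must be collinear along axis")
        if self.L is None:
            span = 2.0 * np.max(np.abs(proj)) if self.n_t > 0 else 0.0
            object.__setattr__(self, "L", float(span))

    @property
    def coords(self) -> np.ndarray:
        """Signed 1D coordinates of all targets along the antenna axis."""
        return self.positions @ self.axis

    @property
    def idr_coords(self) -> np.ndarray:
        return self.coords[1:]

    def to_dict(self) -> dict:
        return {
            "positions": self.positions.tolist(),
            "d": self.d,
            "n_t": self.n_t,
            "mode": self.mode,
            "side": self.side,
            "axis": self.axis.tolist(),
            "L": self.L,
        }

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, payload: dict) -> "TargetLayout":
        return cls(
            positions=np.asarray(payload["positions"], dtype=float),
            d=float(payload["d"]),
            n_t=int(payload["n_t"]),
            mode=payload.get("mode", "equal"),
            side=payload.get("side", "one_sided"),
            axis=np.asarray(payload.get("axis", [0.0, 0.0, 1.0]), dtype=float),
            L=payload.get("L"),
        )

    @classmethod
    def from_file(cls, path) -> "TargetLayout":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def from_coords(
        cls,
        coords: Sequence[float],
        d: float,
        mode: str = "equal",
        side: str = "one_sided",
        axis=(0.0, 0.0, 1.0),
        L: Optional[float] = None,
    ) -> "TargetLayout":
        """Build from signed 1D coordinates of the IDR targets."""
        ax = np.asarray(axis, dtype=float)
        ax = ax / np.linalg.norm(ax)
        coords = np.asarray(coords, dtype=float)
        pos = np.concatenate([[0.0], coords])[:, None] * ax[None, :]
        return cls(pos, d=d, n_t=len(coords), mode=mode, side=side, axis=ax, L=L)


def _alternating_signs(n: int) -> np.ndarray:
    # +1, -1, +1, -1, ... so odd counts put the extra target on the + side
    s = np.ones(n)
    s[1::2] = -1.0
    return s


def make_layout(
    mode: str,
    n_t: Optional[int] = None,
    d: float = 10.0,
    L: Optional[float] = None,
    seed: Optional[int] = None,
    side: str = "symmetric",
    axis=(0.0, 0.0, 1.0),
) -> TargetLayout:
    """Construct a target layout.

    ``equal`` mode places targets at exact multiples of ``d``; ``poisson``
    mode draws exponential spacings with mean ``d`` (seeded).  In
    ``symmetric`` arrangement targets alternate between the two sides of
    the DBD target; in ``one_sided`` they run outward on one side.  Either
    ``n_t`` or ``L`` must determine the target count; giving both
    inconsistently in ``equal`` mode is an error.
    """
    if mode not in _MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if side not in _SIDES:
        raise ValueError(f"unknown side {side!r}")
    if d <= 0:
        raise ValueError("d must be positive")
    if n_t is None and L is None:
        raise ValueError("either n_t or L must be given")
    if mode == "equal" and L is not None:
        if side == "symmetric":
            n_pairs = int(np.floor((L / 2.0) / d + 1e-12))
            n_from_l = 2 * n_pairs
        else:
            n_from_l = int(np.floor(L / d + 1e-12))
        if n_t is None:
            n_t = n_from_l
        elif side == "symmetric" and abs(n_t - n_from_l) > 1:
            raise ValueError(
                f"antenna of length L={L} with spacing d={d} holds {n_from_l} "
                f"targets, inconsistent with n_t={n_t}"
            )
        elif side == "one_sided" and n_t * d > L + 1e-12:
            raise ValueError("n_t * d exceeds antenna length L")
    if n_t is None:  # poisson mode with L given
        n_t = max(int(np.floor((L / (2.0 if side == 'symmetric' else 1.0)) / d)), 1) * (
            2 if side == "symmetric" else 1
        )

    if mode == "equal":
        if side == "one_sided":
            coords = d * np.arange(1, n_t + 1)
        else:
            ranks = d * (np.arange(n_t) // 2 + 1)
            coords = ranks * _alternating_signs(n_t)
    else:
        rng = np.random.default_rng(seed)
        if side == "one_sided":
            coords = np.cumsum(rng.exponential(d, size=n_t))
        else:
            n_plus = (n_t + 1) // 2
            n_minus = n_t - n_plus
            plus = np.cumsum(rng.exponential(d, size=n_plus))
            minus = -np.cumsum(rng.exponential(d, size=n_minus))
            coords = np.empty(n_t)
            coords[0::2] = plus
            coords[1::2] = minus
    return TargetLayout.from_coords(coords, d=d, mode=mode, side=side, axis=axis, L=L)
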