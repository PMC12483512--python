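"""Metropolis oracle for the equilibrium binding probability.

This samples the *continuous* bead-spring TF (harmonic bonds, square-well
targets of volume ``V1`` and depths ``E_B``/``E_DBD``) in a periodic box of
volume ``V`` and measures the DBD-bound occupancy directly.  It shares no
code with the configuration-sum engine in :mod:`idrsearch.equilibrium`, so
agreement between the two is a genuine cross-check of the partition-function
convention.

Each target well saturates at one contribution (a target containing two
sites still counts once), matching the injective configuration counting;
the residual phase-space difference is O(V1 * f(0, l0)) and negligible for
the well sizes used here.  Intended for small systems (n_b, n_t <= ~3);
mixing relies on whole-chain teleport moves, so ``V`` should be small
enough that bound states are visited often.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .equilibrium import EnergyModel
from .layouts import TargetLayout
from .units import TFArchitecture

__all__ = ["MetropolisEstimate", "metropolis_oracle"]


@dataclass
class MetropolisEstimate:
    """Occupancy estimate of the DBD-bound sector with a batch-means SE."""

    p_tf: float
    se: float
    p_free: float
    p_idr_only: float
    acceptance: float
    n_sweeps: int
    converged: bool
    batch_means: np.ndarray

    def summary(self) -> str:
        flag = "" if self.converged else "  [NON-CONVERGENCE DIAGNOSTIC]"
        return (
            f"Metropolis oracle: P_TF = {self.p_tf:.5g} +- {self.se:.2g} "
            f"({self.n_sweeps} sweeps, acc {self.acceptance:.2f}){flag}"
        )


def metropolis_oracle(
    arch: TFArchitecture,
    layout: TargetLayout,
    energy: EnergyModel,
    n_sweeps: int = 400_000,
    seed: int = 0,
    n_burn: int | None = None,
    n_batches: int = 25,
) -> MetropolisEstimate:
    """Estimate P_TF by direct Metropolis sampling (independent of the
    configuration-sum engine).

    The box side is ``V**(1/3)`` and the well radius ``(3 V1 / 4 pi)**(1/3)``.
    Batch means over ``n_batches`` batches give the standard error; the
    estimate is flagged non-converged when any batch deviates from the
    grand mean by more than five batch standard deviations.
    """
    from ._kernels import metropolis_kernel

    box = energy.V ** (1.0 / 3.0)
    r1 = (3.0 * energy.V1 / (4.0 * math.pi)) ** (1.0 / 3.0)
    span = abs(layout.coords).max() if layout.n_t else 0.0
    if span > 0.45 * box:
        raise ValueError(
            "target span approaches the periodic box size; enlarge V or "
            "shrink the layout"
        )
    if n_burn is None:
        n_burn = max(n_sweeps // 10, 1000)
    kseed = int(np.random.SeedSequence(seed).generate_state(1)[0] % (2**31 - 1))
    targets = np.ascontiguousarray(layout.positions)
    fracs, batch_tf, acc = metropolis_kernel(
        int(arch.n_b),
        float(arch.l0),
        float(energy.E_B),
        float(energy.E_DBD),
        float(r1),
        float(box),
        targets,
        int(n_sweeps),
        int(n_burn),
        kseed,
        int(n_batches),
    )
    p_tf = float(fracs[2])
    bstd = float(batch_tf.std(ddof=1))
    se = bstd / math.sqrt(n_batches)
    converged = bool(np.max(np.abs(batch_tf - batch_tf.mean())) <= 5.0 * bstd) if bstd > 0 else True
    return MetropolisEstimate(
        p_tf=p_tf,
        se=se,
        p_free=float(fracs[0]),
        p_idr_only=float(fracs[1]),
        acceptance=float(acc),
        n_sweeps=n_sweeps,
        converged=converged,
        batch_means=np.asarray(batch_tf),
    )
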