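"""Design-principle scans of the equilibrium binding model.

These sweep the configuration-sum engine over the experimentally relevant
knobs -- segment-to-spacing ratio ``l0/d``, site and target counts
``n_b``/``n_t``, well depth ``E_B`` and IDR truncation -- and return
long-format tables.  Default parameters are the typical nuclear values
used throughout: nucleus volume 1 um^3, ``E_DBD`` = 15, ``E_B`` = 10,
``V1`` = 1 bp^3 and ``d = sqrt(50)`` bp.

The qualitative findings these tables expose: binding is maximally
enhanced when ``l0 ~ d``; the affinity gain is governed by
``min(n_b, n_t)`` (L-shaped contours); the minimal site count needed for
strong binding decreases with ``E_B``; and the gain switches on once
``E_B`` exceeds the threshold energy and saturates at ``1/P_simple``.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .equilibrium import (
    EnergyModel,
    binding_probability,
    threshold_energy,
)
from .layouts import make_layout
from .units import TFArchitecture

__all__ = [
    "DEFAULT_ENERGY",
    "DEFAULT_D",
    "scan_l0_over_d",
    "scan_nb_nt",
    "scan_contour",
    "scan_eb",
    "truncation_curve",
    "randomized_layout_scan",
    "scan_design_principles",
]

#: nucleus volume 1 um^3 expressed in bp^3
V_NUCLEUS_BP3 = (1e3 / 0.34) ** 3
DEFAULT_D = math.sqrt(50.0)
DEFAULT_ENERGY = EnergyModel(E_B=10.0, E_DBD=15.0, V1=1.0, V=V_NUCLEUS_BP3)

_GRID_CAP = 2000  # maximum number of grid points per scan


def _check_grid(n_points: int) -> None:
    if n_points > _GRID_CAP:
        raise ValueError(f"scan grid of {n_points} points exceeds cap {_GRID_CAP}")


def _solve(n_b, n_t, l0, d, energy, layout=None):
    arch = TFArchitecture(n_b=n_b, l0=l0)
    if layout is None:
        layout = make_layout("equal", n_t=n_t, d=d, side="one_sided")
    return binding_probability(arch, layout, energy)


def scan_l0_over_d(
    nb_nt: Sequence[tuple] = ((1, 1), (2, 2), (4, 4), (8, 8)),
    ratios: Sequence[float] = tuple(np.round(np.arange(0.3, 2.51, 0.2), 3)),
    d: float = DEFAULT_D,
    energy: EnergyModel = DEFAULT_ENERGY,
) -> pd.DataFrame:
    """Q versus l0/d for several (n_b, n_t) pairs."""
    _check_grid(len(nb_nt) * len(ratios))
    rows = []
    for n_b, n_t in nb_nt:
        layout = make_layout("equal", n_t=n_t, d=d, side="one_sided")
        for ratio in ratios:
            res = _solve(n_b, n_t, ratio * d, d, energy, layout)
            rows.append(
                {
                    "n_b": n_b,
                    "n_t": n_t,
                    "l0_over_d": ratio,
                    "Q": res.Q,
                    "P_TF": res.P_TF,
                }
            )
    return pd.DataFrame(rows)


def argmax_l0_over_d(table: pd.DataFrame) -> pd.DataFrame:
    """Per (n_b, n_t), the grid ratio maximising Q (ties -> smaller ratio)."""
    out = []
    for (n_b, n_t), g in table.groupby(["n_b", "n_t"]):
        g = g.sort_values("l0_over_d")
        best = g.loc[g["Q"].idxmax()]
        out.append({"n_b": n_b, "n_t": n_t, "argmax_ratio": best["l0_over_d"]})
    return pd.DataFrame(out)


def scan_nb_nt(
    n_b_values: Sequence[int] = tuple(range(1, 9)),
    n_t_values: Sequence[int] = tuple(range(1, 9)),
    d: float = DEFAULT_D,
    energy: EnergyModel = DEFAULT_ENERGY,
) -> pd.DataFrame:
    """Q heatmap over n_b x n_t at l0 = d."""
    _check_grid(len(n_b_values) * len(n_t_values))
    rows = []
    for n_t in n_t_values:
        layout = make_layout("equal", n_t=n_t, d=d, side="one_sided")
        for n_b in n_b_values:
            res = _solve(n_b, n_t, d, d, energy, layout)
            rows.append({"n_b": n_b, "n_t": n_t, "Q": res.Q, "P_TF": res.P_TF})
    return pd.DataFrame(rows)


def scan_contour(
    e_b_values: Sequence[float] = (10.0, 11.0, 12.0, 13.0),
    threshold: float = 0.9,
    max_n: int = 8,
    d: float = DEFAULT_D,
    energy: EnergyModel = DEFAULT_ENERGY,
) -> pd.DataFrame:
    """Minimal diagonal site/target count reaching P_TF >= threshold.

    For each E_B, reports n_star = min{n : P_TF(n_b=n_t=n) >= threshold}
    (NaN when not reached by ``max_n``).
    """
    _check_grid(len(e_b_values) * max_n)
    rows = []
    for e_b in e_b_values:
        en = EnergyModel(E_B=e_b, E_DBD=energy.E_DBD, V1=energy.V1, V=energy.V)
        n_star = np.nan
        for n in range(1, max_n + 1):
            res = _solve(n, n, d, d, en)
            if res.P_TF >= threshold:
                n_star = n
                break
        rows.append({"E_B": e_b, "threshold": threshold, "n_star": n_star})
    return pd.DataFrame(rows)


def scan_eb(
    n_values: Sequence[int] = (1, 2, 4, 8),
    e_b_values: Sequence[float] = tuple(np.round(np.arange(2.0, 16.1, 1.0), 3)),
    d: float = DEFAULT_D,
    energy: EnergyModel = DEFAULT_ENERGY,
) -> pd.DataFrame:
    """Q versus E_B at l0 = d for n_b = n_t = n, with the threshold-energy
    marker and the saturation level 1/P_simple in the table metadata."""
    _check_grid(len(n_values) * len(e_b_values))
    phi = energy.V1 ** (1.0 / 3.0) / d
    e_th = threshold_energy(phi)
    rows = []
    for n in n_values:
        layout = make_layout("equal", n_t=n, d=d, side="one_sided")
        for e_b in e_b_values:
            en = EnergyModel(E_B=e_b, E_DBD=energy.E_DBD, V1=energy.V1, V=energy.V)
            res = _solve(n, n, d, d, en, layout)
            rows.append(
                {
                    "n": n,
                    "E_B": e_b,
                    "Q": res.Q,
                    "P_TF": res.P_TF,
                    "E_th": e_th,
                    "Q_saturation": 1.0 / res.P_simple,
                }
            )
    return pd.DataFrame(rows)


def truncation_curve(
    n_b_full: int = 8,
    n_t: int = 8,
    d: float = DEFAULT_D,
    energy: Optional[EnergyModel] = None,
    aa_per_segment: int = 20,
) -> pd.DataFrame:
    """Relative binding probability versus IDR truncation.

    Truncation removes IDR sites from the distal chain end; the x axis is
    expressed in amino acids via ``aa_per_segment``.  The curve is
    normalised to 1 at zero truncation.
    """
    if energy is None:
        # E_DBD is the one free parameter of the comparison with truncation
        # experiments; E_B just above threshold
        energy = EnergyModel(E_B=11.0, E_DBD=22.0, V1=1.0, V=V_NUCLEUS_BP3)
    layout = make_layout("equal", n_t=n_t, d=d, side="one_sided")
    rows = []
    p_full = None
    for removed in range(0, n_b_full + 1):
        n_b = n_b_full - removed
        res = _solve(n_b, n_t, d, d, energy, layout)
        if p_full is None:
            p_full = res.P_TF
        rows.append(
            {
                "removed_sites": removed,
                "truncation_aa": removed * aa_per_segment,
                "n_b": n_b,
                "P_TF": res.P_TF,
                "relative_P_TF": res.P_TF / p_full,
            }
        )
    return pd.DataFrame(rows)


def randomized_layout_scan(
    n_b: int = 4,
    n_t: int = 4,
    mean_spacing: float = DEFAULT_D,
    ratios: Sequence[float] = tuple(np.round(np.arange(0.4, 2.01, 0.2), 3)),
    e_b_values: Sequence[float] = (),
    n_replicates: int = 100,
    seed: int = 0,
    energy: EnergyModel = DEFAULT_ENERGY,
) -> pd.DataFrame:
    """Robustness of the design principles under Poisson target spacing.

    Draws ``n_replicates`` layouts with exponential inter-target spacings
    (mean ``mean_spacing``) and reports the median and interquartile range
    of Q over replicates, either versus ``l0/<d>`` (default) or versus
    ``E_B`` when ``e_b_values`` is given.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    layouts = [
        make_layout("poisson", n_t=n_t, d=mean_spacing, seed=int(s), side="one_sided")
        for s in seeds
    ]
    rows = []
    if e_b_values:
        for e_b in e_b_values:
            en = EnergyModel(
                E_B=e_b, E_DBD=energy.E_DBD, V1=energy.V1, V=energy.V
            )
            qs = [
                binding_probability(
                    TFArchitecture(n_b, mean_spacing), lay, en
                ).Q
                for lay in layouts
            ]
            qs = np.asarray(qs)
            rows.append(
                {
                    "E_B": e_b,
                    "q_median": float(np.median(qs)),
                    "q_q1": float(np.quantile(qs, 0.25)),
                    "q_q3": float(np.quantile(qs, 0.75)),
                }
            )
        return pd.DataFrame(rows)
    for ratio in ratios:
        arch = TFArchitecture(n_b, ratio * mean_spacing)
        qs = np.asarray(
            [binding_probability(arch, lay, energy).Q for lay in layouts]
        )
        rows.append(
            {
                "l0_over_d": ratio,
                "q_median": float(np.median(qs)),
                "q_q1": float(np.quantile(qs, 0.25)),
                "q_q3": float(np.quantile(qs, 0.75)),
            }
        )
    return pd.DataFrame(rows)


_SCANS = {
    "l0_over_d": scan_l0_over_d,
    "nb_nt": scan_nb_nt,
    "contour": scan_contour,
    "eb": scan_eb,
    "truncation": truncation_curve,
    "poisson": randomized_layout_scan,
}


def scan_design_principles(kind: str, **params) -> pd.DataFrame:
    """Dispatch a named design-principle scan; returns a long-format table."""
    if kind not in _SCANS:
        raise ValueError(f"unknown scan {kind!r}; choose from {sorted(_SCANS)}")
    return _SCANS[kind](**params)
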