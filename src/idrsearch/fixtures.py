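"""Reproducible experiment drivers.

Each figure-level study (equilibrium design-principle scans, the
search-time-vs-antenna-length simulation study, and the comparison-scale
estimates) is wrapped in a driver that executes at either ``reduced`` or
``full`` scale, writes long-format CSV tables with a parameter header, a
JSON summary, and an :class:`ExperimentManifest` from which any entry can
be re-run bit-exactly (all randomness is seeded; per-run seeds are spawned
from the master seed with ``numpy.random.SeedSequence``).

``full`` scale runs the original-scale study conditions and is costly for
the dynamical scans; ``reduced`` scale (the default) shrinks the nucleus,
the antenna grid and the run counts, which preserves every qualitative
conclusion while fitting on one CPU.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from . import __version__
from .dynamics import SimulationConfig, estimate_mfpt
from .layouts import make_layout
from .scans import (
    DEFAULT_D,
    V_NUCLEUS_BP3,
    argmax_l0_over_d,
    scan_contour,
    scan_eb,
    scan_l0_over_d,
    scan_nb_nt,
    truncation_curve,
)
from .theory import (
    RateConversionParams,
    SearchTimeModel,
    optimal_antenna,
    rates,
    t_total_theory,
)
from .equilibrium import EnergyModel, binding_probability
from .units import TFArchitecture

__all__ = ["ExperimentManifest", "write_table", "run_figure_scan", "make_layout"]

FIGURE_IDS = ("fig2a", "fig2b", "fig2c", "fig2d", "fig3", "fig4a", "fig4b", "fig4c")

#: frozen reduced-scale conditions of the search-time-vs-L study
REDUCED_FIG3 = dict(
    R=60.0, a=1.0, d=5.0, l0=5.0, n_tilde=3, E_B=10.0,
    L_grid=(10.0, 24.0, 44.0, 80.0), n_runs=40, max_time=1.0e6,
)
#: full-scale conditions (very costly; hours to days on one CPU)
FULL_FIG3 = dict(
    R=500.0, a=0.5, d=10.0, l0=5.0, n_tilde=4, E_B=11.0,
    L_grid=(100.0, 200.0, 300.0, 450.0, 700.0), n_runs=500, max_time=1.0e9,
)


@dataclass
class ExperimentManifest:
    """Everything needed to reproduce one experiment."""

    experiment_id: str
    scale: str
    seed: int
    parameters: Dict
    outputs: List[str] = field(default_factory=list)
    package_version: str = __version__
    created: str = ""

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True, default=str)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "ExperimentManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


def write_table(df: pd.DataFrame, path, params: Dict) -> None:
    """CSV with a commented metadata header (parameters + version)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# idrsearch {__version__}\n")
        for key in sorted(params):
            fh.write(f"# {key} = {params[key]}\n")
        df.to_csv(fh, index=False)


def _json_dump(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")


def _fig3_study(scale: str, seed: int, outdir: Path, params_override=None):
    p = dict(REDUCED_FIG3 if scale == "reduced" else FULL_FIG3)
    if params_override:
        p.update(params_override)
    rows = []
    per_run = []
    seeds = np.random.SeedSequence(seed).generate_state(len(p["L_grid"]))
    for L, s in zip(p["L_grid"], seeds):
        cfg = SimulationConfig(
            R=p["R"], a=p["a"], d=p["d"], L=L, l0=p["l0"],
            n_tilde=p["n_tilde"], E_B=p["E_B"], max_time=p["max_time"],
        )
        est = estimate_mfpt(cfg, p["n_runs"], seed=int(s), keep_records=True)
        t3d = np.array([r.t_total - r.time_attached for r in est.records])
        t1d = np.array([r.time_attached for r in est.records])
        nr = np.array([r.n_rounds for r in est.records])
        rows.append(
            {
                "L": L,
                "t_total": est.mean,
                "t_total_se": est.se,
                "t3d": t3d.mean(),
                "t3d_se": t3d.std(ddof=1) / np.sqrt(len(t3d)),
                "t1d": t1d.mean(),
                "t1d_se": t1d.std(ddof=1) / np.sqrt(len(t1d)),
                "single_round_fraction": float(np.mean(nr == 1)),
                "n_runs": len(t3d),
                "n_censored": est.n_censored,
            }
        )
        for r in est.records:
            per_run.append(
                {
                    "L": L,
                    "seed": r.seed,
                    "t_total": r.t_total,
                    "t_3d_first_attach": r.t_3d,
                    "t_1d": r.time_attached,
                    "n_rounds": r.n_rounds,
                    "terminated": r.terminated,
                }
            )
    table = pd.DataFrame(rows)
    runs = pd.DataFrame(per_run)
    fit = SearchTimeModel(
        table.rename(columns={"t3d": "t3d", "t1d": "t1d"}),
        n_tilde=p["n_tilde"], R=p["R"], D=1.0, l0=p["l0"],
    ).fit()
    summary = {
        "parameters": p,
        "seed": seed,
        "alpha": fit.alpha,
        "alpha_se": fit.alpha_se,
        "beta": fit.beta,
        "beta_se": fit.beta_se,
        "argmin_L": float(table.loc[table["t_total"].idxmin(), "L"]),
        "t_min": float(table["t_total"].min()),
    }
    write_table(table, outdir / "search_time_vs_L.csv", p)
    write_table(runs, outdir / "first_passage_runs.csv", p)
    _json_dump(summary, outdir / "summary.json")
    return [str(outdir / n) for n in
            ("search_time_vs_L.csv", "first_passage_runs.csv", "summary.json")], p


def _fig4b_table(scale: str) -> pd.DataFrame:
    # search time vs antenna length at cellular scale (R = 1 um), in seconds
    # per cell for a TF copy number of 100
    r_bp = 1e-6 / 0.34e-9
    params = RateConversionParams()
    ls = np.geomspace(300, 8000, 12 if scale == "reduced" else 40)
    t3, t1, tt = t_total_theory(ls, 4, r_bp, 1.0, 5.0, 0.5, 14.5, split=True)
    t0_s = (0.34e-9) ** 2 / params.D_SI
    return pd.DataFrame(
        {
            "L_bp": ls,
            "t_total_t0": tt,
            "t_per_cell_s": tt * t0_s / params.copy_number,
        }
    )


def _fig4c_table(scale: str) -> pd.DataFrame:
    r_bp = 1e-6 / 0.34e-9
    params = RateConversionParams()
    en = EnergyModel(E_B=11.0, E_DBD=22.0, V1=1.0, V=V_NUCLEUS_BP3)
    lay = make_layout("equal", n_t=8, d=DEFAULT_D, side="one_sided")
    rows = []
    for n_b in range(1, 9):
        res = binding_probability(TFArchitecture(n_b, DEFAULT_D), lay, en)
        _, t_min = optimal_antenna(n_b + 1, r_bp, 1.0, 5.0, 0.5, 14.5)
        rr = rates(t_min, res.P_TF, params)
        rows.append(
            {
                "n_b": n_b,
                "idr_length_aa": n_b * 20,
                "P_TF": res.P_TF,
                "k_on_per_M_s": rr.k_on,
                "k_off_per_s": rr.k_off,
                "k_D_M": rr.k_D,
            }
        )
    return pd.DataFrame(rows)


def run_figure_scan(
    experiment_id: str,
    scale: str = "reduced",
    seed: int = 0,
    outdir="figures",
    params_override: Optional[Dict] = None,
) -> Path:
    """Execute one figure-level study; returns the artifact directory."""
    if experiment_id not in FIGURE_IDS:
        raise ValueError(f"unknown experiment {experiment_id!r}; ids: {FIGURE_IDS}")
    if scale not in ("reduced", "full"):
        raise ValueError("scale must be 'reduced' or 'full'")
    outdir = Path(outdir) / f"{experiment_id}_{scale}_seed{seed}"
    outdir.mkdir(parents=True, exist_ok=True)
    params: Dict = {"scale": scale, "seed": seed}
    outputs: List[str] = []

    if experiment_id == "fig2a":
        pairs = ((1, 1), (2, 2), (4, 4)) if scale == "reduced" else (
            (1, 1), (1, 4), (2, 2), (4, 4), (4, 8), (8, 8))
        tab = scan_l0_over_d(nb_nt=pairs)
        write_table(tab, outdir / "q_vs_l0_over_d.csv", params)
        write_table(argmax_l0_over_d(tab), outdir / "argmax.csv", params)
        outputs = ["q_vs_l0_over_d.csv", "argmax.csv"]
    elif experiment_id == "fig2b":
        n = 6 if scale == "reduced" else 8
        tab = scan_nb_nt(tuple(range(1, n + 1)), tuple(range(1, n + 1)))
        write_table(tab, outdir / "q_heatmap.csv", params)
        outputs = ["q_heatmap.csv"]
    elif experiment_id == "fig2c":
        tabs = [scan_contour(threshold=thr) for thr in (0.9, 0.5)]
        tab = pd.concat(tabs, ignore_index=True)
        write_table(tab, outdir / "n_star_vs_eb.csv", params)
        outputs = ["n_star_vs_eb.csv"]
    elif experiment_id == "fig2d":
        from .equilibrium import threshold_energy

        tab = scan_eb()
        params["E_th"] = threshold_energy(1.0 / DEFAULT_D)
        write_table(tab, outdir / "q_vs_eb.csv", params)
        outputs = ["q_vs_eb.csv"]
    elif experiment_id == "fig3":
        outputs, p = _fig3_study(scale, seed, outdir, params_override)
        outputs = [Path(o).name for o in outputs]
        params.update(p)
    elif experiment_id == "fig4a":
        tab = truncation_curve()
        write_table(tab, outdir / "truncation.csv", params)
        outputs = ["truncation.csv"]
    elif experiment_id == "fig4b":
        tab = _fig4b_table(scale)
        write_table(tab, outdir / "search_time_cellular.csv", params)
        outputs = ["search_time_cellular.csv"]
    elif experiment_id == "fig4c":
        tab = _fig4c_table(scale)
        write_table(tab, outdir / "rates_vs_idr_length.csv", params)
        outputs = ["rates_vs_idr_length.csv"]

    manifest = ExperimentManifest(
        experiment_id=experiment_id,
        scale=scale,
        seed=seed,
        parameters=params,
        outputs=outputs,
        created=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.to_json(outdir / "manifest.json")
    return outdir
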