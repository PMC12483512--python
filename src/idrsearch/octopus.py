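"""Statistics of the octopusing walk: the effective 1D diffusion of a TF
attached to the antenna through the asynchronous binding and unbinding of
its IDR sites.

Works on :class:`~idrsearch.dynamics.FirstPassageRecord` objects recorded
with a finite ``sample_dt``.  A site is *bound* when it sits within the
capture radius (default ``2 w_d``) of a target; the TF is *attached* while
at least one site is bound.  The on/off feedback that bypasses the
speed-stability trade-off is quantified by the conditional rates of
gaining or losing one bound site as a function of the current bound count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import FirstPassageRecord, SimulationConfig

__all__ = [
    "OctopusSummary",
    "bound_count_series",
    "attached_segments",
    "effective_d1",
    "feedback_statistics",
    "summarize_octopusing",
]


def bound_count_series(
    record: FirstPassageRecord, capture_radius: Optional[float] = None
) -> np.ndarray:
    """Number of bound sites per sample (sites within the capture radius of
    any target)."""
    if record.site_target_dist is None:
        raise ValueError("record carries no series; rerun with sample_dt > 0")
    cfg = record.config
    if capture_radius is None:
        capture_radius = 2.0 * cfg.w_d
    if record.sample_times is not None and len(record.sample_times) > 1:
        stride = record.sample_times[1] - record.sample_times[0]
        if stride > cfg.w_d**2:  # slower than the well-crossing time w_d^2/D
            import warnings

            warnings.warn(
                f"sample stride {stride:g} t0 is coarser than w_d^2/D = "
                f"{cfg.w_d**2:g} t0; binding events may be missed",
                stacklevel=2,
            )
    return (record.site_target_dist < capture_radius).sum(axis=1).astype(np.int64)


def attached_segments(counts: np.ndarray, min_len: int = 2) -> List[slice]:
    """Maximal runs of samples with at least one bound site."""
    att = counts > 0
    segs: List[slice] = []
    start = None
    for i, flag in enumerate(att):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if i - start >= min_len:
                segs.append(slice(start, i))
            start = None
    if start is not None and len(att) - start >= min_len:
        segs.append(slice(start, len(att)))
    return segs


def _msd_1d(series: np.ndarray, lags: Sequence[int]) -> np.ndarray:
    out = np.empty(len(lags))
    for k, lag in enumerate(lags):
        if lag >= len(series):
            out[k] = np.nan
        else:
            diff = series[lag:] - series[:-lag]
            out[k] = np.mean(diff**2)
    return out


def effective_d1(
    records: Sequence[FirstPassageRecord],
    config: Optional[SimulationConfig] = None,
    lag_window: tuple = (10, 100),
    capture_radius: Optional[float] = None,
    min_segment: int = 200,
):
    """Effective 1D diffusion coefficient of the attached walk.

    Pools the axial (antenna-axis) centre-of-mass MSD over all attached
    segments of at least ``min_segment`` samples and fits MSD = 2 D1 t over
    integer lags in ``lag_window``.  Returns (D1, se, n_segments); (nan,
    nan, 0) with a diagnostic when nothing is attached long enough.
    """
    if not records:
        return math.nan, math.nan, 0
    cfg = config or records[0].config
    stride = cfg.sample_dt
    lags = np.arange(lag_window[0], lag_window[1] + 1)
    slopes = []
    n_seg = 0
    for rec in records:
        if rec.axial_position_series is None:
            continue
        counts = bound_count_series(rec, capture_radius)
        for seg in attached_segments(counts, min_len=min_segment):
            z = np.asarray(rec.axial_position_series[seg], dtype=float)
            msd = _msd_1d(z, lags)
            ok = np.isfinite(msd)
            if ok.sum() < 3:
                continue
            slope = np.polyfit(lags[ok] * stride, msd[ok], 1)[0]
            slopes.append(slope / 2.0)
            n_seg += 1
    if not slopes:
        return math.nan, math.nan, 0
    slopes = np.asarray(slopes)
    d1 = float(np.mean(slopes))
    se = float(slopes.std(ddof=1) / math.sqrt(len(slopes))) if len(slopes) > 1 else math.nan
    return d1, se, n_seg


def feedback_statistics(
    records: Sequence[FirstPassageRecord],
    config: Optional[SimulationConfig] = None,
    capture_radius: Optional[float] = None,
    min_dwell_samples: int = 1,
) -> pd.DataFrame:
    """Conditional on/off rates versus the current bound-site count.

    For every bound count ``m`` occupied during attached episodes, counts
    transitions ``m -> m+1`` (binding one more site) and ``m -> m-1``
    (losing one) between consecutive samples, and divides by the total time
    spent at ``m``.  Rates are in 1/t0.  Sparse bins (< 10 visits) are
    flagged in the ``sparse`` column.
    """
    if not records:
        raise ValueError("no records given")
    cfg = config or records[0].config
    stride = cfg.sample_dt
    n_max = cfg.n_tilde
    time_at = np.zeros(n_max + 1)
    up = np.zeros(n_max + 1)
    down = np.zeros(n_max + 1)
    visits = np.zeros(n_max + 1)
    for rec in records:
        counts = bound_count_series(rec, capture_radius)
        for seg in attached_segments(counts, min_len=2):
            c = counts[seg]
            for m0, m1 in zip(c[:-1], c[1:]):
                time_at[m0] += stride
                visits[m0] += 1
                if m1 > m0:
                    up[m0] += 1
                elif m1 < m0:
                    down[m0] += 1
    rows = []
    for m in range(n_max + 1):
        if visits[m] == 0:
            continue
        rows.append(
            {
                "bound_count": m,
                "time_at": time_at[m],
                "n_up": int(up[m]),
                "n_down": int(down[m]),
                "on_rate": up[m] / time_at[m] if time_at[m] > 0 else np.nan,
                "off_rate": down[m] / time_at[m] if time_at[m] > 0 else np.nan,
                "sparse": visits[m] < 10,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class OctopusSummary:
    """Headline octopusing statistics pooled over runs."""

    mean_bound_count: float
    bound_count_histogram: np.ndarray  # normalised over 0..n_tilde
    d1: float
    d1_se: float
    detachment_rate: float  # full detachments per unit attached time
    fraction_attached: float
    feedback: pd.DataFrame

    def summary(self) -> str:
        hist = ", ".join(
            f"{m}:{p:.3f}" for m, p in enumerate(self.bound_count_histogram)
        )
        return "\n".join(
            [
                "Octopusing walk summary",
                "=" * 40,
                f"mean bound sites (attached): {self.mean_bound_count:.3f}",
                f"bound-count histogram: {hist}",
                f"effective D1 = {self.d1:.4g} +- {self.d1_se:.2g} bp^2/t0",
                f"full-detachment rate = {self.detachment_rate:.3g} /t0",
                f"fraction of time attached = {self.fraction_attached:.3f}",
            ]
        )


def summarize_octopusing(
    records: Sequence[FirstPassageRecord],
    config: Optional[SimulationConfig] = None,
    capture_radius: Optional[float] = None,
) -> OctopusSummary:
    cfg = config or records[0].config
    all_counts = []
    att_time = 0.0
    tot_time = 0.0
    detach = 0
    for rec in records:
        counts = bound_count_series(rec, capture_radius)
        segs = attached_segments(counts, min_len=2)
        for seg in segs:
            all_counts.append(counts[seg])
        att = counts > 0
        # a full detachment = an attached episode that ends within the record
        for seg in segs:
            if seg.stop < len(counts):
                detach += 1
        att_time += att.sum() * cfg.sample_dt
        tot_time += len(counts) * cfg.sample_dt
    if all_counts:
        pooled = np.concatenate(all_counts)
        hist = np.bincount(pooled, minlength=cfg.n_tilde + 1)[: cfg.n_tilde + 1]
        hist = hist / hist.sum()
        mean_bound = float(pooled.mean())
    else:
        hist = np.zeros(cfg.n_tilde + 1)
        mean_bound = math.nan
    d1, d1_se, _ = effective_d1(records, cfg, capture_radius=capture_radius)
    return OctopusSummary(
        mean_bound_count=mean_bound,
        bound_count_histogram=hist,
        d1=d1,
        d1_se=d1_se,
        detachment_rate=detach / att_time if att_time > 0 else math.nan,
        fraction_attached=att_time / tot_time if tot_time > 0 else math.nan,
        feedback=feedback_statistics(records, cfg, capture_radius)
        if all_counts
        else pd.DataFrame(),
    )
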