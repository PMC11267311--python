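"""Calcium-trace analytics: ΔF/F0, response detection, group activation.

Traces are stimulus-locked fluorescence time series (e.g. Rhod-4 imaging of
astrocytes with a neurotransmitter administered mid-recording). The baseline
F0 is the mean fluorescence over all pre-stimulus samples; a cell responds
when ΔF/F0 = F/F0 - 1 exceeds a threshold (10% by default) at any
post-stimulus sample. Group activation is reported as fold change of mean
maximum amplitude versus the control group, and cells are clustered by the
Pearson correlation of their ΔF/F0 series.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

GROUPS = ("CONT", "DA", "ACh", "DA+ACh")


@dataclass
class TraceSet:
    """Uniformly sampled fluorescence traces sharing one time base.

    ``F`` has shape ``(n_cells, n_timepoints)``; ``groups`` holds treatment
    labels such as CONT / DA / ACh / DA+ACh.
    """

    times: np.ndarray
    F: np.ndarray
    stimulus_time: float
    cells: np.ndarray
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.F = np.atleast_2d(np.asarray(self.F, dtype=float))
        dts = np.diff(self.times)
        if len(dts) and (dts.min() <= 0 or not np.allclose(dts, dts[0])):
            raise ValueError("times must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.F)):
            raise ValueError("fluorescence values must be finite")
        if not self.times[0] <= self.stimulus_time <= self.times[-1]:
            raise ValueError("stimulus_time must lie within the record")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def n_cells(self) -> int:
        return self.F.shape[0]


@dataclass
class TraceStats:
    cell: str
    group: str
    f0: float
    dff: np.ndarray
    responded: bool
    response_time: float | None
    max_amplitude: float


def dff(trace_set: TraceSet) -> list[TraceStats]:
    """Compute F0 and the ΔF/F0 series per cell.

    F0 is the mean of F over samples strictly before the stimulus; response
    fields are left unset (filled by :func:`detect_response`).
    """
    pre = trace_set.times < trace_set.stimulus_time
    if pre.sum() < 2:
        raise ValueError("need at least two pre-stimulus samples for F0")
    out = []
    for i in range(trace_set.n_cells):
        f0 = float(trace_set.F[i, pre].mean())
        if f0 <= 0:
            raise ValueError(f"non-positive baseline F0 for cell {trace_set.cells[i]}")
        series = trace_set.F[i] / f0 - 1.0
        out.append(
            TraceStats(
                cell=str(trace_set.cells[i]),
                group=str(trace_set.groups[i]),
                f0=f0,
                dff=series,
                responded=False,
                response_time=None,
                max_amplitude=float("nan"),
            )
        )
    return out


def detect_response(
    stats: TraceStats,
    times: np.ndarray,
    stimulus_time: float,
    theta: float = 0.10,
    min_consecutive: int = 1,
) -> TraceStats:
    """Apply the response criterion ΔF/F0 > theta to one cell's series.

    ``response_time`` is the time from stimulus to the first post-stimulus
    sample exceeding theta (the first of ``min_consecutive`` consecutive
    suprathreshold samples when debouncing is requested); ``max_amplitude``
    is the post-stimulus maximum of ΔF/F0.
    """
    post = np.asarray(times) > stimulus_time
    idx = np.flatnonzero(post)
    above = stats.dff[idx] > theta
    responded, rtime = False, None
    if min_consecutive <= 1:
        hits = np.flatnonzero(above)
        if len(hits):
            responded = True
            rtime = float(times[idx[hits[0]]] - stimulus_time)
    else:
        run = 0
        for j, a in enumerate(above):
            run = run + 1 if a else 0
            if run >= min_consecutive:
                responded = True
                rtime = float(times[idx[j - min_consecutive + 1]] - stimulus_time)
                break
    stats.responded = responded
    stats.response_time = rtime
    stats.max_amplitude = float(stats.dff[idx].max()) if len(idx) else float("nan")
    return stats


def analyze_traces(
    trace_set: TraceSet, theta: float = 0.10, min_consecutive: int = 1
) -> pd.DataFrame:
    """Full per-cell analysis: F0, response flag/time, max amplitude."""
    rows = []
    for st in dff(trace_set):
        st = detect_response(
            st, trace_set.times, trace_set.stimulus_time, theta, min_consecutive
        )
        rows.append(
            {
                "cell": st.cell,
                "group": st.group,
                "f0": st.f0,
                "responded": st.responded,
                "response_time": st.response_time,
                "max_amplitude": st.max_amplitude,
            }
        )
    return pd.DataFrame(rows)


def group_activation(
    stats: pd.DataFrame, control: str = "CONT"
) -> pd.DataFrame:
    """Per-group mean maximum amplitude and fold activation vs control.

    Fold activation for group g is ΔF_g / ΔF_control where ΔF is the group
    mean of per-cell maximum ΔF/F0 amplitudes.
    """
    if control not in set(stats["group"]):
        raise ValueError(f"control group {control!r} absent")
    means = stats.groupby("group")["max_amplitude"].mean()
    ctrl = means[control]
    if ctrl <= 0:
        raise ValueError("control mean amplitude is non-positive; fold undefined")
    out = means.rename("mean_max_amplitude").to_frame()
    out["fold_vs_control"] = means / ctrl
    return out.reset_index()


def trace_correlation_cluster(
    trace_set: TraceSet, n_clusters: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """Cluster cells by the Pearson correlation of their ΔF/F0 series.

    Returns (correlation matrix as DataFrame, cluster labels from an
    average-linkage cut on distance 1 - r).
    """
    if trace_set.n_cells < 2:
        raise ValueError("need at least two traces")
    series = np.vstack([st.dff for st in dff(trace_set)])
    if np.any(series.std(axis=1) == 0):
        raise ValueError("constant trace has undefined correlation")
    corr = np.corrcoef(series)
    dist = np.clip(1.0 - corr, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    Z = sch.linkage(squareform(dist, checks=False), method="average")
    labels = sch.fcluster(Z, t=n_clusters, criterion="maxclust")
    cells = [str(c) for c in trace_set.cells]
    return pd.DataFrame(corr, index=cells, columns=cells), labels
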