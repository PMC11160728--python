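"""Downstream analysis of 3D chromatin traces.

Operates on long-format trace tables (one row per traced genomic bin:
trace id, 0-based bin index, x/y/z in nm, per-point quality metrics) as
produced by sequential-hybridization DNA tracing after spot fitting.
Provides per-point and per-trace quality filtering, median pairwise
distance matrices, contact maps at a 3D distance threshold (120 nm by
default), difference matrices and distance-vs-genomic-separation scaling
curves, plus detection of the most contact-enriched block (a planted or
biological loop domain).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

TRACE_COLUMNS = ["trace_id", "bin_index", "x", "y", "z", "snr", "fit_sd", "barcode_dist"]


@dataclass
class QcParams:
    """Per-point thresholds and the minimum surviving points per trace."""

    min_snr: float = 2.0
    max_fit_sd: float = 100.0      # nm
    max_barcode_dist: float = 1000.0  # nm
    min_points: int = 20

    def __post_init__(self) -> None:
        if min(self.min_snr, self.max_fit_sd, self.max_barcode_dist) <= 0 \
                or self.min_points <= 0:
            raise ValueError("QC parameters must be positive")


class QcReport(NamedTuple):
    n_points_in: int
    n_points_pass: int
    n_traces_in: int
    n_traces_out: int


@dataclass
class DistanceMatrix:
    """Median pairwise 3D distances (nm) with per-cell sample counts."""

    values: np.ndarray
    counts: np.ndarray
    bin_kb: float = 12.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.counts = np.asarray(self.counts)

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


@dataclass
class ContactMap:
    """Contact frequencies in [0, 1] at a 3D distance threshold (nm)."""

    values: np.ndarray
    counts: np.ndarray
    threshold: float = 120.0
    bin_kb: float = 12.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def n_bins(self) -> int:
        return self.values.shape[0]


def qc_filter(traces: pd.DataFrame, params: QcParams | None = None
              ) -> tuple[pd.DataFrame, QcReport]:
    """Drop low-quality points, then traces with too few surviving points.

    Idempotent: running the filter on its own output changes nothing.
    """
    if params is None:
        params = QcParams()
    n_in = len(traces)
    n_traces_in = traces["trace_id"].nunique() if n_in else 0
    ok = (
        (traces["snr"] >= params.min_snr)
        & (traces["fit_sd"] <= params.max_fit_sd)
        & (traces["barcode_dist"] <= params.max_barcode_dist)
    )
    passed = traces[ok]
    sizes = passed.groupby("trace_id")["bin_index"].size()
    keep_ids = sizes[sizes >= params.min_points].index
    out = passed[passed["trace_id"].isin(keep_ids)].reset_index(drop=True)
    out.attrs.update(traces.attrs)
    return out, QcReport(n_in, len(passed), n_traces_in, len(keep_ids))


def _position_tensor(traces: pd.DataFrame, n_bins: int | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """(n_traces, n_bins, 3) coordinate array with NaN for missing bins."""
    if len(traces) == 0:
        raise ValueError("need at least one trace")
    if n_bins is None:
        n_bins = int(traces["bin_index"].max()) + 1
    ids = traces["trace_id"].unique()
    pos = np.full((len(ids), n_bins, 3), np.nan)
    id_map = {tid: k for k, tid in enumerate(ids)}
    rows = traces["trace_id"].map(id_map).to_numpy()
    cols = traces["bin_index"].to_numpy(dtype=int)
    pos[rows, cols, 0] = traces["x"].to_numpy(dtype=float)
    pos[rows, cols, 1] = traces["y"].to_numpy(dtype=float)
    pos[rows, cols, 2] = traces["z"].to_numpy(dtype=float)
    return pos, ids


def _distance_tensor(pos: np.ndarray, chunk: int = 64) -> np.ndarray:
    """(n_traces, n_bins, n_bins) pairwise 3D distances, NaN where missing."""
    n_t, n_b, _ = pos.shape
    out = np.empty((n_t, n_b, n_b), dtype=np.float32)
    for start in range(0, n_t, chunk):
        block = pos[start:start + chunk]
        diff = block[:, :, None, :] - block[:, None, :, :]
        out[start:start + chunk] = np.sqrt(np.sum(diff * diff, axis=-1))
    return out


def median_distance_matrix(traces: pd.DataFrame, n_bins: int | None = None
                           ) -> DistanceMatrix:
    """Entry (i, j): median over traces (having both bins) of the 3D distance."""
    pos, _ = _position_tensor(traces, n_bins)
    dist = _distance_tensor(pos)
    counts = np.sum(~np.isnan(dist), axis=0)
    with np.errstate(all="ignore"):
        med = np.nanmedian(dist, axis=0)
    med[counts == 0] = np.nan
    np.fill_diagonal(med, 0.0)
    return DistanceMatrix(values=med, counts=counts,
                          bin_kb=traces.attrs.get("bin_kb", 12.0))


def contact_map(traces: pd.DataFrame, threshold: float = 120.0,
                n_bins: int | None = None) -> ContactMap:
    """Entry (i, j): fraction of traces with both bins closer than ``threshold`` nm."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    pos, _ = _position_tensor(traces, n_bins)
    dist = _distance_tensor(pos)
    valid = ~np.isnan(dist)
    counts = valid.sum(axis=0)
    hits = np.sum((dist < threshold) & valid, axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.where(counts > 0, hits / np.maximum(counts, 1), np.nan)
    np.fill_diagonal(freq, 1.0)
    return ContactMap(values=freq, counts=counts, threshold=threshold,
                      bin_kb=traces.attrs.get("bin_kb", 12.0))


def difference_matrix(a: DistanceMatrix, b: DistanceMatrix) -> np.ndarray:
    """Elementwise a - b; missing cells propagate as NaN."""
    if a.values.shape != b.values.shape:
        raise ValueError("distance matrices must have the same shape")
    if a.bin_kb != b.bin_kb:
        raise ValueError("distance matrices must share bin_kb")
    return a.values - b.values


@dataclass
class ScalingCurve:
    """All pairwise distances keyed by genomic separation, plus the medians."""

    points: pd.DataFrame            # separation_kb, distance_nm
    medians: pd.DataFrame           # separation_kb, median_nm, n

    def exponent(self) -> float:
        """Power-law exponent of median distance vs genomic separation."""
        m = self.medians.dropna()
        m = m[(m["separation_kb"] > 0) & (m["median_nm"] > 0)]
        slope, _ = np.polyfit(np.log(m["separation_kb"]), np.log(m["median_nm"]), 1)
        return float(slope)


def scaling_curve(traces: pd.DataFrame, n_bins: int | None = None) -> ScalingCurve:
    """Long-format distance-vs-separation table from all trace pairs."""
    bin_kb = traces.attrs.get("bin_kb", 12.0)
    pos, _ = _position_tensor(traces, n_bins)
    dist = _distance_tensor(pos)
    n_b = dist.shape[1]
    iu, ju = np.triu_indices(n_b, k=1)
    sep = (ju - iu) * bin_kb
    vals = dist[:, iu, ju]                      # (n_traces, n_pairs)
    keep = ~np.isnan(vals)
    points = pd.DataFrame({
        "separation_kb": np.broadcast_to(sep, vals.shape)[keep],
        "distance_nm": vals[keep].astype(float),
    })
    med = (points.groupby("separation_kb")["distance_nm"]
           .agg(median_nm="median", n="size").reset_index())
    return ScalingCurve(points=points, medians=med)


def detect_contact_block(contacts: ContactMap, min_width: int = 5
                         ) -> tuple[int, int]:
    """Most contact-enriched contiguous bin interval (inclusive bounds).

    Enrichment is measured against the mean contact frequency at each
    genomic separation (the distance-decay expectation); the interval
    maximising the summed off-diagonal enrichment of its sub-block is
    returned.  Intended to recover loop/domain boundaries.
    """
    c = contacts.values.astype(float).copy()
    n = c.shape[0]
    if n < min_width:
        raise ValueError("matrix smaller than min_width")
    # distance-decay expectation per separation
    expected = np.zeros_like(c)
    for d in range(1, n):
        diag = np.diagonal(c, offset=d)
        m = np.nanmean(diag) if np.any(np.isfinite(diag)) else 0.0
        expected[np.arange(n - d), np.arange(d, n)] = m
        expected[np.arange(d, n), np.arange(n - d)] = m
    enr = np.nan_to_num(c - expected, nan=0.0)
    np.fill_diagonal(enr, 0.0)
    # 2D prefix sums for O(1) block scores
    ps = np.zeros((n + 1, n + 1))
    ps[1:, 1:] = np.cumsum(np.cumsum(enr, axis=0), axis=1)
    best, best_iv = -np.inf, (0, n - 1)
    for s in range(n):
        for e in range(s + min_width - 1, n):
            total = ps[e + 1, e + 1] - ps[s, e + 1] - ps[e + 1, s] + ps[s, s]
            score = total / 2.0   # symmetric matrix, zero diagonal
            if score > best:
                best, best_iv = score, (s, e)
    return best_iv


def interval_jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    """Jaccard overlap of two inclusive bin intervals."""
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)
    union = (a[1] - a[0] + 1) + (b[1] - b[0] + 1) - inter
    return inter / union if union else 0.0
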