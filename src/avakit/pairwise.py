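"""Pairwise synchrony: zero-lag correlation, event synchronization, shuffle correction.

Two complementary pair metrics are computed on the spike-rate raster:

* zero-lag Pearson correlation r of the per-frame rate series;
* event synchronization Q, a rate-normalized count of near-coincident
  events with an adaptive coincidence window (half the minimum of the
  four neighboring inter-event intervals, capped), in [0, 1].

Both are shuffle-corrected by subtracting the mean metric over
ISI-preserving surrogate rasters, which removes the component of the
raw metric explained by firing rates and slow timescales alone.
Undefined pairs (zero-variance or event-free neurons) are excluded from
distributions rather than zero-filled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import shuffle_raster
from .raster import ROIMap, SpikeRaster

__all__ = [
    "PairMatrix",
    "MetricDistribution",
    "zero_lag_correlation",
    "event_synchronization",
    "shuffle_correct",
    "distance_binned_means",
    "metric_distribution",
]


@dataclass
class PairMatrix:
    """Symmetric neuron x neuron pair metric; diagonal and undefined pairs NaN."""

    values: np.ndarray
    metric: str

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    def pair_values(self) -> np.ndarray:
        """Defined off-diagonal values, each unordered pair once."""
        iu = np.triu_indices(self.n_neurons, k=1)
        v = self.values[iu]
        return v[np.isfinite(v)]

    def pair_table(self, rois: ROIMap | None = None) -> pd.DataFrame:
        iu = np.triu_indices(self.n_neurons, k=1)
        df = pd.DataFrame(
            {"neuron_i": iu[0], "neuron_j": iu[1], self.metric: self.values[iu]}
        )
        if rois is not None:
            df.insert(2, "distance_um", rois.distances()[iu])
        return df


def zero_lag_correlation(raster: SpikeRaster) -> PairMatrix:
    """Pearson correlation of the lambda time series at lag zero.

    Pairs involving a zero-variance series are NaN (undefined), as is
    the diagonal.
    """
    if raster.n_neurons < 2:
        raise ValueError("need at least 2 neurons")
    if raster.n_frames < 2:
        raise ValueError("need at least 2 frames")
    lam = raster.lam
    sd = lam.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(lam)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, np.nan)
    return PairMatrix(values=r, metric="correlation")


def _neighbor_isi_min(times: np.ndarray) -> np.ndarray:
    """Per event, the smaller of its two adjacent ISIs (inf where absent)."""
    if times.size < 2:
        return np.full(times.size, np.inf)
    isi = np.diff(times).astype(float)
    prev = np.concatenate(([np.inf], isi))
    nxt = np.concatenate((isi, [np.inf]))
    return np.minimum(prev, nxt)


def _event_sync_pair(tx, ty, nx, ny, tau_max: float) -> float:
    dt = tx[:, None] - ty[None, :]
    tau = 0.5 * np.minimum(nx[:, None], ny[None, :])
    tau = np.minimum(tau, tau_max)
    equal = 0.5 * (dt == 0).sum()
    c_xy = ((dt > 0) & (dt <= tau)).sum() + equal  # events of x following y
    c_yx = ((dt < 0) & (-dt <= tau)).sum() + equal
    return float((c_xy + c_yx) / np.sqrt(tx.size * ty.size))


def event_synchronization(raster: SpikeRaster, tau_max: float = 2.0) -> PairMatrix:
    """Event synchronization Q with an adaptive coincidence window.

    The window for an event pair is half the minimum of the four
    neighboring ISIs, capped at ``tau_max`` frames (default 2: at 15 Hz
    sampling, wider windows would conflate separate transients).
    Same-frame coincidences count half to each direction, so identical
    trains give exactly Q = 1. Pairs with an event-free neuron are NaN.
    """
    n = raster.n_neurons
    times = [np.flatnonzero(raster.mask[i]) for i in range(n)]
    nmins = [_neighbor_isi_min(t) for t in times]
    q = np.full((n, n), np.nan)
    for i in range(n):
        if times[i].size == 0:
            continue
        for j in range(i + 1, n):
            if times[j].size == 0:
                continue
            q[i, j] = q[j, i] = _event_sync_pair(
                times[i], times[j], nmins[i], nmins[j], tau_max
            )
    return PairMatrix(values=q, metric="event_sync")


def shuffle_correct(
    raster: SpikeRaster,
    metric: str = "correlation",
    n_shuffles: int = 20,
    seed=None,
    method: str = "subtract",
    tau_max: float = 2.0,
) -> PairMatrix:
    """Shuffle-corrected pair metric.

    The observed matrix minus the per-pair mean over ``n_shuffles``
    independently ISI-shuffled rasters (``method='zscore'`` divides the
    difference by the shuffle SD instead).
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    if metric == "correlation":
        fn = zero_lag_correlation
    elif metric == "event_sync":
        def fn(r):
            return event_synchronization(r, tau_max=tau_max)
    else:
        raise ValueError("metric must be 'correlation' or 'event_sync'")
    observed = fn(raster).values
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    shuffled = np.empty((n_shuffles,) + observed.shape)
    for k, child in enumerate(ss.spawn(n_shuffles)):
        shuffled[k] = fn(shuffle_raster(raster, seed=child)).values
    mean = shuffled.mean(axis=0)
    if method == "subtract":
        corrected = observed - mean
    elif method == "zscore":
        sd = shuffled.std(axis=0, ddof=1) if n_shuffles > 1 else np.full_like(mean, np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            corrected = (observed - mean) / sd
    else:
        raise ValueError("method must be 'subtract' or 'zscore'")
    return PairMatrix(values=corrected, metric=f"{metric}_corrected")


def distance_binned_means(
    matrix: PairMatrix, rois: ROIMap, bin_edges: np.ndarray
) -> pd.DataFrame:
    """Mean and SEM of a pair metric within centroid-distance bins (um)."""
    if matrix.n_neurons != rois.n_rois:
        raise ValueError("matrix and ROI map must cover the same neurons")
    bin_edges = np.asarray(bin_edges, dtype=float)
    iu = np.triu_indices(matrix.n_neurons, k=1)
    d = rois.distances()[iu]
    v = matrix.values[iu]
    ok = np.isfinite(v)
    d, v = d[ok], v[ok]
    rows = []
    for lo, hi in zip(bin_edges[:-1], bin_edges[1:]):
        sel = (d >= lo) & (d < hi)
        n = int(sel.sum())
        if n == 0:
            rows.append((lo, hi, np.nan, np.nan, 0))
        else:
            vals = v[sel]
            sem = vals.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
            rows.append((lo, hi, vals.mean(), sem, n))
    return pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "mean", "sem", "n_pairs"])


@dataclass
class MetricDistribution:
    """Normalized histogram (probability mass) of pair-metric values plus CDF."""

    edges: np.ndarray
    hist: np.ndarray
    cdf: np.ndarray
    n_pairs: int


def metric_distribution(matrix: PairMatrix, bin_edges: np.ndarray) -> MetricDistribution:
    """Per-movie normalized histogram of defined pair values and its CDF.

    Values outside the bin range are clipped into the end bins so the
    histogram always sums to one (and the CDF ends at one).
    """
    v = matrix.pair_values()
    if v.size == 0:
        raise ValueError("all pairs undefined")
    edges = np.asarray(bin_edges, dtype=float)
    clipped = np.clip(v, edges[0], np.nextafter(edges[-1], -np.inf))
    counts, _ = np.histogram(clipped, bins=edges)
    hist = counts / v.size
    return MetricDistribution(edges=edges, hist=hist, cdf=np.cumsum(hist), n_pairs=int(v.size))
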