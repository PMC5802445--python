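"""Spatiotemporal avalanche (cluster) extraction and size statistics.

An avalanche is a maximal run of consecutive frames in which at least
one ROI is active, delimited by silent frames. Each cluster records the
active ROI identities and their rate amplitudes frame by frame; its size
is either the total rate (``size_lambda``, sum of lambda over all
activations) or the activation count (``size_count``), and its duration
is the number of frames.

Size distributions are log-binned (geometric bin edges); the power-law
exponent is estimated by least squares on log bin-center vs log density
up to a predicted system-size cutoff, and the deviation from power-law
form is summarized by the Kolmogorov-Smirnov distance between the
empirical size CDF and the fitted power-law CDF on the fit range. Mean
size as a function of duration gives the size-duration scaling exponent
chi; at mean-field criticality the expected values are an exponent of
3/2 and chi = 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .raster import SpikeRaster

__all__ = [
    "Cluster",
    "ClusterSet",
    "SizeDistribution",
    "PowerLawFit",
    "ScalingFit",
    "extract_clusters",
    "size_distribution",
    "fit_power_law",
    "size_duration_scaling",
    "predicted_cutoff",
]


@dataclass
class Cluster:
    """One spatiotemporal cluster of consecutive active frames."""

    start_frame: int
    duration: int
    roi_ids: list  # per-frame arrays of active ROI indices
    lams: list  # per-frame arrays of matching rate amplitudes
    edge: bool = False  # touches the start or end of the recording

    @property
    def size_count(self) -> int:
        return int(sum(ids.size for ids in self.roi_ids))

    @property
    def size_lambda(self) -> float:
        return float(sum(v.sum() for v in self.lams))

    @property
    def frame_lambda_sums(self) -> np.ndarray:
        return np.array([v.sum() for v in self.lams])

    @property
    def frame_counts(self) -> np.ndarray:
        return np.array([ids.size for ids in self.roi_ids])


@dataclass
class ClusterSet:
    """All clusters of one movie plus the context needed for cutoffs."""

    clusters: list
    n_neurons: int
    n_frames: int
    frame_rate: float = 15.0

    def __len__(self) -> int:
        return len(self.clusters)

    def __iter__(self):
        return iter(self.clusters)

    def sizes(self, size_mode: str = "count") -> np.ndarray:
        if size_mode == "count":
            return np.array([c.size_count for c in self.clusters], dtype=float)
        if size_mode == "lambda":
            return np.array([c.size_lambda for c in self.clusters])
        raise ValueError("size_mode must be 'count' or 'lambda'")

    def durations(self) -> np.ndarray:
        return np.array([c.duration for c in self.clusters], dtype=float)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cluster_id": np.arange(len(self.clusters)),
                "start_frame": [c.start_frame for c in self.clusters],
                "duration_frames": [c.duration for c in self.clusters],
                "size_count": [c.size_count for c in self.clusters],
                "size_lambda": [c.size_lambda for c in self.clusters],
                "edge_flag": [c.edge for c in self.clusters],
            }
        )


def extract_clusters(raster: SpikeRaster, lambda_min: float = 0.0) -> ClusterSet:
    """Combine successive frames with >= 1 active ROI into clusters.

    A frame is active when some ROI has ``lam > lambda_min`` (the raster
    is normally already thresholded upstream, so the default keeps every
    event). Clusters touching either end of the recording are flagged.
    """
    lam = raster.lam
    active = raster.mask if lambda_min == 0 else lam > lambda_min
    frame_active = active.any(axis=0)
    T = raster.n_frames
    edges = np.diff(np.concatenate(([0], frame_active.astype(np.int8), [0])))
    starts = np.flatnonzero(edges == 1)
    ends = np.flatnonzero(edges == -1)
    clusters = []
    for s, e in zip(starts, ends):
        roi_ids, lams = [], []
        for t in range(s, e):
            ids = np.flatnonzero(active[:, t])
            roi_ids.append(ids)
            lams.append(lam[ids, t])
        clusters.append(
            Cluster(
                start_frame=int(s),
                duration=int(e - s),
                roi_ids=roi_ids,
                lams=lams,
                edge=bool(s == 0 or e == T),
            )
        )
    return ClusterSet(
        clusters=clusters,
        n_neurons=raster.n_neurons,
        n_frames=T,
        frame_rate=raster.frame_rate,
    )


@dataclass
class SizeDistribution:
    """Log-binned probability density of cluster sizes."""

    edges: np.ndarray
    centers: np.ndarray  # geometric bin centers
    density: np.ndarray  # probability mass / bin width
    n_clusters: int
    size_mode: str
    sizes: np.ndarray = field(repr=False, default=None)  # raw sizes (for KS)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.edges[:-1],
                "bin_hi": self.edges[1:],
                "bin_center": self.centers,
                "density": self.density,
            }
        )


def size_distribution(
    clusters: ClusterSet | np.ndarray,
    size_mode: str = "count",
    bin_factor: float = 2.0,
    s_min: float = 1.0,
) -> SizeDistribution:
    """Log-binned density of cluster sizes (geometric bins).

    Bin edges are ``s_min * bin_factor**k``; density is probability mass
    per bin divided by bin width, so the density integrates to one over
    the binned range.
    """
    if bin_factor <= 1:
        raise ValueError("bin_factor must be > 1")
    if isinstance(clusters, ClusterSet):
        sizes = clusters.sizes(size_mode)
    else:
        sizes = np.asarray(clusters, dtype=float)
    sizes = sizes[sizes >= s_min]
    if sizes.size == 0:
        raise ValueError("no clusters with size >= s_min")
    edges = [s_min]
    while edges[-1] <= sizes.max():
        edges.append(edges[-1] * bin_factor)
    edges = np.array(edges)
    mass, _ = np.histogram(sizes, bins=edges)
    mass = mass / sizes.size
    widths = np.diff(edges)
    if np.allclose(sizes, np.round(sizes)):
        # integer sizes: place each bin at the geometric mean of its
        # integer support (plotting the singleton bin {1} at sqrt(lo*hi)
        # would put it far off the continuum line and bias the slope)
        centers = np.empty(edges.size - 1)
        for k, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
            support = np.arange(np.ceil(lo), np.ceil(hi))
            centers[k] = np.exp(np.mean(np.log(support))) if support.size else np.sqrt(lo * hi)
    else:
        centers = np.sqrt(edges[:-1] * edges[1:])
    return SizeDistribution(
        edges=edges,
        centers=centers,
        density=mass / widths,
        n_clusters=int(sizes.size),
        size_mode=size_mode,
        sizes=sizes,
    )


@dataclass
class PowerLawFit:
    """Power-law fit P(s) ~ s**(-exponent) over [s_min, cutoff]."""

    exponent: float  # reported positive
    s_min: float
    cutoff: float
    ks_distance: float  # vs the fitted exponent (default diagnostic)
    ks_distance_ref15: float  # vs the mean-field reference exponent 1.5
    n_in_range: int
    n_bins_used: int
    intercept: float
    method: str = "ls"


def predicted_cutoff(n_neurons: int, size_mode: str = "count", mean_amplitude: float = 1.0) -> float:
    """System-size cutoff: N activations (count) or N * mean amplitude (rate)."""
    if size_mode == "count":
        return float(n_neurons)
    return float(n_neurons) * mean_amplitude


def _power_law_cdf(values: np.ndarray, tau: float, s_min: float, cutoff: float) -> np.ndarray:
    """CDF of a power law truncated to [s_min, cutoff].

    Integer-valued samples get the discrete (zeta-normalized) CDF,
    continuous samples the continuous one; comparing an integer-valued
    empirical CDF against a continuous model would inflate the KS
    distance at the smallest sizes.
    """
    if np.allclose(values, np.round(values)):
        support = np.arange(int(np.ceil(s_min)), int(np.floor(cutoff)) + 1, dtype=float)
        pmf = support**-tau
        pmf /= pmf.sum()
        cdf_vals = np.cumsum(pmf)
        idx = np.searchsorted(support, np.round(values), side="right") - 1
        return cdf_vals[np.clip(idx, 0, support.size - 1)]
    if abs(tau - 1.0) < 1e-9:
        return np.log(values / s_min) / np.log(cutoff / s_min)
    a, b = s_min ** (1.0 - tau), cutoff ** (1.0 - tau)
    return (values ** (1.0 - tau) - a) / (b - a)


def _ks_distance(sizes: np.ndarray, tau: float, s_min: float, cutoff: float) -> float:
    xs = np.sort(sizes[(sizes >= s_min) & (sizes <= cutoff)])
    if xs.size == 0:
        return float("nan")
    n = xs.size
    model = _power_law_cdf(xs, tau, s_min, cutoff)
    ecdf_hi = np.arange(1, n + 1) / n
    if np.allclose(xs, np.round(xs)):
        # discrete reference: both CDFs are step functions with the same
        # atoms, so the sup is attained at the atoms (right limits)
        last = np.r_[np.diff(xs) > 0, True]
        return float(np.abs(ecdf_hi[last] - model[last]).max())
    ecdf_lo = np.arange(0, n) / n
    return float(max(np.abs(ecdf_hi - model).max(), np.abs(model - ecdf_lo).max()))


def _mle_exponent(sizes: np.ndarray, s_min: float, cutoff: float) -> float:
    """Discrete truncated power-law MLE (cross-check for the LS fit)."""
    xs = np.round(sizes[(sizes >= s_min) & (sizes <= cutoff)]).astype(int)
    support = np.arange(int(np.ceil(s_min)), int(np.floor(cutoff)) + 1, dtype=float)
    logs = np.log(xs).sum()

    def nll(tau):
        z = (support**-tau).sum()
        return tau * logs + xs.size * np.log(z)

    res = minimize_scalar(nll, bounds=(1.01, 6.0), method="bounded")
    return float(res.x)


def fit_power_law(
    dist: SizeDistribution,
    cutoff: float,
    s_min: float | None = None,
    method: str = "ls",
) -> PowerLawFit:
    """Fit P(s) ~ s**-tau over [s_min, cutoff] and compute KS distances.

    The default estimator is least squares on log bin-center vs log
    density over occupied bins in range (the conventional fit to a
    log-binned avalanche distribution); ``method='mle'`` uses a discrete
    truncated maximum-likelihood estimate as a cross-check. The KS
    distance is reported against both the fitted exponent and the
    mean-field reference exponent 3/2.
    """
    s_min = dist.edges[0] if s_min is None else s_min
    # only bins lying fully inside [s_min, cutoff]: a bin straddling the
    # cutoff has its density diluted by the truncated part of its width
    sel = (dist.density > 0) & (dist.edges[:-1] >= s_min) & (dist.edges[1:] <= cutoff)
    if sel.sum() < 3:
        raise ValueError("need >= 3 occupied bins within [s_min, cutoff] to fit")
    x = np.log10(dist.centers[sel])
    y = np.log10(dist.density[sel])
    slope, intercept = np.polyfit(x, y, 1)
    if method == "ls":
        exponent = -slope
    elif method == "mle":
        exponent = _mle_exponent(dist.sizes, s_min, cutoff)
    else:
        raise ValueError("method must be 'ls' or 'mle'")
    in_range = dist.sizes[(dist.sizes >= s_min) & (dist.sizes <= cutoff)]
    return PowerLawFit(
        exponent=float(exponent),
        s_min=float(s_min),
        cutoff=float(cutoff),
        ks_distance=_ks_distance(dist.sizes, exponent, s_min, cutoff),
        ks_distance_ref15=_ks_distance(dist.sizes, 1.5, s_min, cutoff),
        n_in_range=int(in_range.size),
        n_bins_used=int(sel.sum()),
        intercept=float(intercept),
        method=method,
    )


@dataclass
class ScalingFit:
    """Size-duration scaling <s>(T) ~ T**chi."""

    exponent: float
    durations: np.ndarray
    mean_sizes: np.ndarray
    min_per_duration: int


def size_duration_scaling(
    clusters: ClusterSet,
    size_mode: str = "count",
    min_per_duration: int = 10,
) -> ScalingFit:
    """Least-squares fit of log mean size vs log duration.

    Only durations represented by at least ``min_per_duration`` clusters
    enter the fit; at least three distinct durations are required.
    """
    if len(clusters) == 0:
        raise ValueError("no clusters")
    durs = clusters.durations()
    sizes = clusters.sizes(size_mode)
    uniq, counts = np.unique(durs, return_counts=True)
    keep = uniq[counts >= min_per_duration]
    if keep.size < 3:
        raise ValueError("need >= 3 distinct durations with enough clusters")
    means = np.array([sizes[durs == d].mean() for d in keep])
    slope, _ = np.polyfit(np.log10(keep), np.log10(means), 1)
    return ScalingFit(
        exponent=float(slope),
        durations=keep,
        mean_sizes=means,
        min_per_duration=min_per_duration,
    )
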