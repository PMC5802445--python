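"""Branching parameters, single-neuron bursts, and the burst-removal intervention.

The temporal branching parameter sigma compares descendant activity to
ancestor activity within a cluster: the total rate in all frames after
the first, divided by the total rate in the first frame. For a
subcritical branching process with offspring mean m and no persistence,
the pooled ratio converges to m / (1 - m) (expected total progeny of a
Galton-Watson tree beyond its root generation), and sigma = 1 marks the
critical point.

The spatial branching parameter uses activation counts instead of rates
and splits downstream activations into "new" (ROI not yet active in the
cluster) and "repeat" (ROI previously active in the same cluster); the
two components sum exactly to the total. First-frame activations form
the ancestor context but are themselves neither new nor repeat.

Bursts are maximal runs of consecutive active frames of a single
neuron. Elevated burst persistence shows up as a shallower burst-length
distribution, a larger multi-frame-burst fraction and inflated repeat
branching; `remove_persistent_bursts` implements the causal
intervention of truncating a random subset of multi-frame bursts after
their first frame.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .avalanche import ClusterSet
from .raster import SpikeRaster

__all__ = [
    "BranchingEstimate",
    "BurstSet",
    "BurstSlopeFit",
    "temporal_branching",
    "spatial_branching",
    "branching_estimates",
    "extract_bursts",
    "burst_length_stats",
    "remove_persistent_bursts",
]


@dataclass
class BranchingEstimate:
    """Temporal (rate-based) and spatial (count-based) branching parameters.

    ``sigma_spatial_new + sigma_spatial_repeat == sigma_spatial_total``
    holds exactly in both estimator modes. Fields not computed by the
    producing call are None.
    """

    sigma_temporal: float | None
    sigma_spatial_total: float | None
    sigma_spatial_new: float | None
    sigma_spatial_repeat: float | None
    mode: str
    n_clusters: int


def _check_mode(mode: str) -> None:
    if mode not in ("pooled", "per_cluster_mean"):
        raise ValueError("mode must be 'pooled' or 'per_cluster_mean'")


def temporal_branching(clusters: ClusterSet, mode: str = "pooled") -> BranchingEstimate:
    """Rate-based branching: descendant lambda over first-frame lambda.

    ``pooled`` divides the summed descendant rate of all clusters by the
    summed first-frame rate; ``per_cluster_mean`` averages the
    per-cluster ratios (duration-1 clusters contribute 0).
    """
    _check_mode(mode)
    if len(clusters) == 0:
        raise ValueError("no clusters")
    firsts = np.array([c.frame_lambda_sums[0] for c in clusters])
    totals = np.array([c.size_lambda for c in clusters])
    if (firsts <= 0).any():
        raise ValueError("cluster with zero first-frame rate")
    if mode == "pooled":
        sigma = (totals - firsts).sum() / firsts.sum()
    else:
        sigma = ((totals - firsts) / firsts).mean()
    return BranchingEstimate(float(sigma), None, None, None, mode, len(clusters))


def spatial_branching(clusters: ClusterSet, mode: str = "pooled") -> BranchingEstimate:
    """Count-based branching with new/repeat decomposition.

    Downstream activations (frames after the first) are labeled repeat
    when the ROI was active in any earlier frame of the same cluster,
    new otherwise; the denominator is the first-frame activation count.
    """
    _check_mode(mode)
    if len(clusters) == 0:
        raise ValueError("no clusters")
    firsts = np.empty(len(clusters))
    news = np.empty(len(clusters))
    repeats = np.empty(len(clusters))
    for k, c in enumerate(clusters):
        seen = set(c.roi_ids[0].tolist())
        n_new = n_rep = 0
        for ids in c.roi_ids[1:]:
            for roi in ids.tolist():
                if roi in seen:
                    n_rep += 1
                else:
                    n_new += 1
            seen.update(ids.tolist())
        firsts[k] = c.roi_ids[0].size
        news[k] = n_new
        repeats[k] = n_rep
    if (firsts <= 0).any():
        raise ValueError("cluster with empty first frame")
    if mode == "pooled":
        den = firsts.sum()
        new, rep = news.sum() / den, repeats.sum() / den
    else:
        new, rep = (news / firsts).mean(), (repeats / firsts).mean()
    return BranchingEstimate(None, float(new + rep), float(new), float(rep), mode, len(clusters))


def branching_estimates(clusters: ClusterSet, mode: str = "pooled") -> BranchingEstimate:
    """Temporal and spatial branching in one combined estimate."""
    t = temporal_branching(clusters, mode)
    s = spatial_branching(clusters, mode)
    return BranchingEstimate(
        t.sigma_temporal,
        s.sigma_spatial_total,
        s.sigma_spatial_new,
        s.sigma_spatial_repeat,
        mode,
        len(clusters),
    )


@dataclass
class BurstSet:
    """Per-neuron maximal runs of consecutive active frames."""

    neuron_ids: np.ndarray
    starts: np.ndarray
    lengths: np.ndarray
    n_neurons: int
    n_frames: int

    @property
    def n_bursts(self) -> int:
        return self.lengths.size

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"neuron_id": self.neuron_ids, "start_frame": self.starts, "length": self.lengths}
        )


def extract_bursts(raster: SpikeRaster) -> BurstSet:
    """Run-length encode each neuron's activity mask."""
    nids, starts, lengths = [], [], []
    for i in range(raster.n_neurons):
        row = raster.mask[i].astype(np.int8)
        edges = np.diff(np.concatenate(([0], row, [0])))
        s = np.flatnonzero(edges == 1)
        e = np.flatnonzero(edges == -1)
        nids.append(np.full(s.size, i))
        starts.append(s)
        lengths.append(e - s)
    return BurstSet(
        neuron_ids=np.concatenate(nids) if nids else np.empty(0, int),
        starts=np.concatenate(starts),
        lengths=np.concatenate(lengths),
        n_neurons=raster.n_neurons,
        n_frames=raster.n_frames,
    )


@dataclass
class BurstSlopeFit:
    """Burst-length distribution summary."""

    slope: float  # positive beta for P(L) ~ L**-beta; nan when undefined
    fraction_multiframe: float
    lengths: np.ndarray
    probs: np.ndarray


def burst_length_stats(bursts: BurstSet, fit_range: tuple | None = None) -> BurstSlopeFit:
    """Slope of the pooled burst-length distribution and multi-frame fraction.

    The slope beta is a least-squares line on log length vs log
    probability over occupied lengths within ``fit_range`` (default: all
    occupied lengths); it is left nan when fewer than three occupied
    lengths are available. ``fraction_multiframe`` is the fraction of
    bursts longer than one frame.
    """
    if bursts.n_bursts == 0:
        raise ValueError("no bursts")
    lengths, counts = np.unique(bursts.lengths, return_counts=True)
    probs = counts / counts.sum()
    frac = float((bursts.lengths > 1).mean())
    lo, hi = (1, np.inf) if fit_range is None else fit_range
    sel = (lengths >= lo) & (lengths <= hi)
    if sel.sum() < 3:
        slope = float("nan")
    else:
        coef = np.polyfit(np.log10(lengths[sel]), np.log10(probs[sel]), 1)
        slope = float(-coef[0])
    return BurstSlopeFit(
        slope=slope,
        fraction_multiframe=frac,
        lengths=lengths.astype(float),
        probs=probs,
    )


def remove_persistent_bursts(raster: SpikeRaster, fraction: float, seed=None) -> SpikeRaster:
    """Truncate a random subset of multi-frame bursts after their first frame.

    Among bursts longer than one frame, ``round(fraction * count)``
    (nearest integer, ties up) are chosen uniformly without replacement
    and all their activity after the first frame is deleted. Everything
    else is untouched; no activity is ever created.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    bursts = extract_bursts(raster)
    multi = np.flatnonzero(bursts.lengths > 1)
    n_sel = int(np.floor(fraction * multi.size + 0.5))
    lam = raster.lam.copy()
    if n_sel > 0:
        rng = np.random.default_rng(seed)
        chosen = rng.choice(multi, size=n_sel, replace=False)
        for k in chosen:
            i = bursts.neuron_ids[k]
            s = bursts.starts[k]
            lam[i, s + 1 : s + bursts.lengths[k]] = 0.0
    return SpikeRaster.from_lambda(lam, frame_rate=raster.frame_rate)
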