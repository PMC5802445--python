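"""Per-movie orchestration, group aggregation and normality-gated statistics.

`run_movie_analysis` composes the whole chain for one movie — optional
deconvolution, pairwise metrics, avalanche statistics, branching and
burst measures — into a :class:`MovieSummary` whose provenance (config
hash and seeds) fully determines every number in it.

Group comparisons follow the normality-gated convention: each group is
tested with Shapiro-Wilk at alpha = 0.05; if every group passes, the
parametric test is used (Welch t, paired t, or one-way ANOVA with Tukey
post hoc), otherwise the rank-based one (Wilcoxon rank-sum, signed-rank,
or Kruskal-Wallis). Per-bin distribution comparisons use uncorrected
rank tests per bin, as in the convention this pipeline follows, and the
metadata records that no multiplicity correction was applied.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import avalanche as av
from . import branching as br
from . import pairwise as pw
from .preprocess import DeconvParams, deconvolve
from .raster import FluorescenceTraces, SpikeRaster

__all__ = [
    "AnalysisConfig",
    "MovieSummary",
    "GroupComparison",
    "run_movie_analysis",
    "cv_isi",
    "compare_two",
    "compare_multi",
    "per_bin_distribution_test",
    "report",
]

log = logging.getLogger("avakit")


@dataclass(frozen=True)
class AnalysisConfig:
    """All knobs of the per-movie analysis, hashable for provenance.

    ``corr_bins`` are (lo, hi, width) for the pair-correlation
    histogram; ``cutoff`` of None means the system-size prediction
    (n_neurons for count sizes).
    """

    decay_tau: float = 0.5
    threshold_k: float = 5.0
    n_shuffles: int = 20
    corr_bins: tuple = (-0.2, 0.6, 0.01)
    compute_event_sync: bool = True
    tau_max: float = 2.0
    lambda_min: float = 0.0
    size_mode: str = "count"
    bin_factor: float = 2.0
    s_min: float = 1.0
    cutoff: float | None = None
    min_per_duration: int = 10
    branching_mode: str = "pooled"
    seed: int = 0

    def corr_bin_edges(self) -> np.ndarray:
        lo, hi, w = self.corr_bins
        return np.arange(lo, hi + w / 2, w)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class MovieSummary:
    """All per-movie quantities plus provenance."""

    n_neurons: int
    n_frames: int
    frame_rate: float
    rate_events_per_frame: float
    rate_hz: float
    cv_isi_median: float
    n_clusters: int
    exponent: float
    ks_distance: float
    ks_distance_ref15: float
    scaling_exponent: float
    sigma_temporal: float
    sigma_spatial_total: float
    sigma_spatial_new: float
    sigma_spatial_repeat: float
    sigma_temporal_per_cluster: float
    n_bursts: int
    burst_slope: float
    fraction_multiframe: float
    corr_hist: np.ndarray = field(repr=False, default=None)
    corr_cdf: np.ndarray = field(repr=False, default=None)
    corr_mean: float = float("nan")
    q_hist: np.ndarray = field(repr=False, default=None)
    q_mean: float = float("nan")
    provenance: dict = field(default_factory=dict)

    SCALARS = (
        "n_neurons",
        "n_frames",
        "rate_events_per_frame",
        "rate_hz",
        "cv_isi_median",
        "n_clusters",
        "exponent",
        "ks_distance",
        "ks_distance_ref15",
        "scaling_exponent",
        "sigma_temporal",
        "sigma_spatial_total",
        "sigma_spatial_new",
        "sigma_spatial_repeat",
        "sigma_temporal_per_cluster",
        "n_bursts",
        "burst_slope",
        "fraction_multiframe",
        "corr_mean",
        "q_mean",
    )

    def to_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, np.ndarray):
                d[k] = v.tolist()
        return d

    def scalar_row(self) -> dict:
        return {k: getattr(self, k) for k in self.SCALARS}


def cv_isi(raster: SpikeRaster, min_events: int = 3) -> np.ndarray:
    """Per-neuron coefficient of variation of inter-event intervals.

    Neurons with fewer than ``min_events`` events yield NaN. CV > 1
    indicates burstier-than-Poisson firing.
    """
    out = np.full(raster.n_neurons, np.nan)
    for i in range(raster.n_neurons):
        t = np.flatnonzero(raster.mask[i])
        if t.size >= min_events:
            isi = np.diff(t)
            mu = isi.mean()
            if mu > 0:
                out[i] = isi.std(ddof=1) / mu
    return out


def run_movie_analysis(
    movie: SpikeRaster | FluorescenceTraces,
    config: AnalysisConfig | None = None,
    compute_pairwise: bool = True,
    provenance: dict | None = None,
) -> MovieSummary:
    """Run the full analysis chain on one movie.

    ``movie`` may be a raster (analysis starts at clustering) or
    fluorescence traces (deconvolved first). Fits that cannot be
    computed (no clusters, too few occupied bins or durations) are
    recorded as NaN rather than raised, so degenerate movies still
    produce a summary.
    """
    config = AnalysisConfig() if config is None else config
    if isinstance(movie, FluorescenceTraces):
        log.info("deconvolving traces (tau=%.3g s, k=%.3g)", config.decay_tau, config.threshold_k)
        raster = deconvolve(movie, DeconvParams(config.decay_tau, config.threshold_k))
    elif isinstance(movie, SpikeRaster):
        raster = movie
    else:
        raise TypeError("movie must be a SpikeRaster or FluorescenceTraces")

    rate = float(raster.mask.mean())
    cv = cv_isi(raster)
    cv_med = float(np.nanmedian(cv)) if np.isfinite(cv).any() else float("nan")

    corr_hist = corr_cdf = q_hist = None
    corr_mean = q_mean = float("nan")
    if compute_pairwise:
        log.info("pairwise metrics (%d shuffles)", config.n_shuffles)
        edges = config.corr_bin_edges()
        corr = pw.shuffle_correct(raster, "correlation", config.n_shuffles, seed=config.seed)
        vals = corr.pair_values()
        if vals.size:
            d = pw.metric_distribution(corr, edges)
            corr_hist, corr_cdf = d.hist, d.cdf
            corr_mean = float(vals.mean())
        if config.compute_event_sync:
            q = pw.shuffle_correct(
                raster,
                "event_sync",
                config.n_shuffles,
                seed=config.seed + 1,
                tau_max=config.tau_max,
            )
            qv = q.pair_values()
            if qv.size:
                q_hist = pw.metric_distribution(q, edges).hist
                q_mean = float(qv.mean())

    log.info("cluster extraction")
    clusters = av.extract_clusters(raster, lambda_min=config.lambda_min)
    exponent = ks = ks15 = chi = float("nan")
    sig_t = sig_tot = sig_new = sig_rep = sig_t_pcm = float("nan")
    if len(clusters) > 0:
        cutoff = config.cutoff
        if cutoff is None:
            cutoff = av.predicted_cutoff(raster.n_neurons, config.size_mode)
        try:
            dist = av.size_distribution(
                clusters, config.size_mode, config.bin_factor, config.s_min
            )
            fit = av.fit_power_law(dist, cutoff=cutoff, s_min=config.s_min)
            exponent, ks, ks15 = fit.exponent, fit.ks_distance, fit.ks_distance_ref15
        except ValueError:
            pass
        try:
            chi = av.size_duration_scaling(
                clusters, config.size_mode, config.min_per_duration
            ).exponent
        except ValueError:
            pass
        est = br.branching_estimates(clusters, config.branching_mode)
        sig_t, sig_tot = est.sigma_temporal, est.sigma_spatial_total
        sig_new, sig_rep = est.sigma_spatial_new, est.sigma_spatial_repeat
        sig_t_pcm = br.temporal_branching(clusters, "per_cluster_mean").sigma_temporal

    bursts = br.extract_bursts(raster)
    slope = frac = float("nan")
    if bursts.n_bursts > 0:
        bfit = br.burst_length_stats(bursts)
        slope, frac = bfit.slope, bfit.fraction_multiframe

    prov = {"config_hash": config.hash(), "seed": config.seed}
    if provenance:
        prov.update(provenance)
    return MovieSummary(
        n_neurons=raster.n_neurons,
        n_frames=raster.n_frames,
        frame_rate=raster.frame_rate,
        rate_events_per_frame=rate,
        rate_hz=rate * raster.frame_rate,
        cv_isi_median=cv_med,
        n_clusters=len(clusters),
        exponent=exponent,
        ks_distance=ks,
        ks_distance_ref15=ks15,
        scaling_exponent=chi,
        sigma_temporal=sig_t,
        sigma_spatial_total=sig_tot,
        sigma_spatial_new=sig_new,
        sigma_spatial_repeat=sig_rep,
        sigma_temporal_per_cluster=sig_t_pcm,
        n_bursts=bursts.n_bursts,
        burst_slope=slope,
        fraction_multiframe=frac,
        corr_hist=corr_hist,
        corr_cdf=corr_cdf,
        corr_mean=corr_mean,
        q_hist=q_hist,
        q_mean=q_mean,
        provenance=prov,
    )


@dataclass
class GroupComparison:
    """Outcome of one normality-gated two-group (or omnibus) comparison."""

    field: str
    groups: tuple
    n: tuple
    test: str
    statistic: float
    pvalue: float
    normal: tuple  # per-group Shapiro-Wilk pass at alpha
    paired: bool
    alpha: float = 0.05
    posthoc: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "field": self.field,
            "groups": list(self.groups),
            "n": list(self.n),
            "test": self.test,
            "statistic": self.statistic,
            "pvalue": self.pvalue,
            "normal": list(self.normal),
            "paired": self.paired,
            "alpha": self.alpha,
        }
        if self.posthoc is not None:
            d["posthoc"] = self.posthoc.to_dict(orient="records")
        return d


def _shapiro_normal(x: np.ndarray, alpha: float) -> bool:
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return False  # degenerate sample: route to the rank-based branch
    return bool(stats.shapiro(x).pvalue > alpha)


def compare_two(
    a,
    b,
    paired: bool = False,
    alpha: float = 0.05,
    field: str = "",
    group_names: tuple = ("a", "b"),
) -> GroupComparison:
    """Shapiro-Wilk-gated two-group comparison, two-tailed.

    Both groups normal at ``alpha``: Welch t (or paired t); otherwise
    Wilcoxon rank-sum (or signed-rank when paired).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need n >= 3 per group")
    if paired and a.size != b.size:
        raise ValueError("paired comparison requires equal group sizes")
    norm = (_shapiro_normal(a, alpha), _shapiro_normal(b, alpha))
    if all(norm):
        if paired:
            res = stats.ttest_rel(a, b)
            test = "paired t"
        else:
            res = stats.ttest_ind(a, b, equal_var=False)
            test = "Welch t"
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        if paired:
            d = a - b
            if np.all(d == 0):
                stat, p = 0.0, 1.0
            else:
                res = stats.wilcoxon(a, b)
                stat, p = float(res.statistic), float(res.pvalue)
            test = "Wilcoxon signed-rank"
        else:
            res = stats.ranksums(a, b)
            stat, p = float(res.statistic), float(res.pvalue)
            test = "Wilcoxon rank-sum"
    return GroupComparison(
        field=field,
        groups=group_names,
        n=(a.size, b.size),
        test=test,
        statistic=stat,
        pvalue=p,
        normal=norm,
        paired=paired,
        alpha=alpha,
    )


def compare_multi(
    groups: list,
    alpha: float = 0.05,
    field: str = "",
    group_names: tuple | None = None,
) -> GroupComparison:
    """Normality-gated omnibus comparison of >= 3 groups.

    All groups normal: one-way ANOVA followed by Tukey HSD (post hoc
    table attached); otherwise Kruskal-Wallis.
    """
    if len(groups) < 3:
        raise ValueError("need >= 3 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size < 3 for g in arrays):
        raise ValueError("need n >= 3 per group")
    names = tuple(group_names) if group_names else tuple(f"g{i}" for i in range(len(arrays)))
    norm = tuple(_shapiro_normal(g, alpha) for g in arrays)
    posthoc = None
    if all(norm):
        res = stats.f_oneway(*arrays)
        test = "one-way ANOVA"
        tk = stats.tukey_hsd(*arrays)
        rows = []
        for i in range(len(arrays)):
            for j in range(i + 1, len(arrays)):
                rows.append(
                    {
                        "group_a": names[i],
                        "group_b": names[j],
                        "statistic": float(tk.statistic[i, j]),
                        "pvalue": float(tk.pvalue[i, j]),
                    }
                )
        posthoc = pd.DataFrame(rows)
    else:
        res = stats.kruskal(*arrays)
        test = "Kruskal-Wallis"
    return GroupComparison(
        field=field,
        groups=names,
        n=tuple(g.size for g in arrays),
        test=test,
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        normal=norm,
        paired=False,
        alpha=alpha,
        posthoc=posthoc,
    )


def per_bin_distribution_test(
    hists_a: np.ndarray,
    hists_b: np.ndarray,
    paired: bool = False,
    alpha: float = 0.05,
    values_a=None,
    values_b=None,
) -> dict:
    """Per-bin rank tests of per-movie histograms plus a distribution test.

    ``hists_a``/``hists_b`` are movies x bins arrays of normalized
    histograms sharing bin edges. Each bin is compared with a rank-sum
    (or signed-rank when paired) test at ``alpha``, uncorrected. The
    maximum difference of the group-averaged CDFs is always reported;
    when pooled raw pair values are supplied, a two-sample KS test on
    them is included as well.
    """
    A = np.atleast_2d(np.asarray(hists_a, dtype=float))
    B = np.atleast_2d(np.asarray(hists_b, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValueError("histograms must share bin edges")
    if paired and A.shape[0] != B.shape[0]:
        raise ValueError("paired comparison requires equal movie counts")
    n_bins = A.shape[1]
    pvals = np.ones(n_bins)
    for k in range(n_bins):
        x, y = A[:, k], B[:, k]
        if np.ptp(np.concatenate([x, y])) == 0:
            continue
        if paired:
            d = x - y
            pvals[k] = 1.0 if np.all(d == 0) else float(stats.wilcoxon(x, y).pvalue)
        else:
            pvals[k] = float(stats.ranksums(x, y).pvalue)
    cdf_a = np.cumsum(A.mean(axis=0))
    cdf_b = np.cumsum(B.mean(axis=0))
    out = {
        "pvalues": pvals,
        "significant": pvals < alpha,
        "alpha": alpha,
        "multiplicity_correction": "none",
        "ks_avg_cdf_distance": float(np.abs(cdf_a - cdf_b).max()),
    }
    if values_a is not None and values_b is not None:
        ks = stats.ks_2samp(np.asarray(values_a, float), np.asarray(values_b, float))
        out["ks_pooled_statistic"] = float(ks.statistic)
        out["ks_pooled_pvalue"] = float(ks.pvalue)
    return out


def report(summaries: dict, comparisons: list, outdir) -> list:
    """Write summaries and comparisons as JSON + CSV; returns written paths.

    ``summaries`` maps group label -> list of MovieSummary.
    """
    if not summaries or all(len(v) == 0 for v in summaries.values()):
        raise ValueError("no summaries to report")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    blob = {
        g: [s.to_dict() for s in lst] for g, lst in summaries.items()
    }
    p = outdir / "summaries.json"
    p.write_text(json.dumps(blob, indent=1))
    paths.append(p)

    rows = []
    for g, lst in summaries.items():
        for i, s in enumerate(lst):
            rows.append({"group": g, "movie": i, **s.scalar_row()})
    p = outdir / "summaries.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    paths.append(p)

    p = outdir / "comparisons.json"
    p.write_text(json.dumps([c.to_dict() for c in comparisons], indent=1))
    paths.append(p)
    log.info("report written to %s", outdir)
    return paths
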