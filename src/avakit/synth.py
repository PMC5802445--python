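"""Synthetic branching-process rasters with controlled cascade and burst statistics.

The generator emulates spontaneous population activity recorded by
two-photon calcium imaging: a small field of neurons (default 80) sampled
at 15 Hz for 5000 frames. Activity is a driven branching process on the
frame grid:

* Poisson(``drive_rate``) spontaneous seed activations per frame, placed
  on uniformly chosen neurons;
* every cascade-activated neuron (seeded or hit by offspring) at frame
  ``t`` spawns Poisson(``offspring_mean``) descendant activations at
  ``t + 1``, targets chosen uniformly with replacement over all neurons
  (self-excitation allowed);
* every neuron active at ``t`` independently stays active at ``t + 1``
  with probability ``persist_prob`` (the single-neuron persistent-burst
  mechanism). Persistence-only continuations do not themselves spawn
  offspring: they model passive burst prolongation superimposed on the
  cascade, so raising ``persist_prob`` inflates repeat activations and
  burst lengths without recruiting additional new neurons.

``offspring_mean`` is the branching ratio of the cascade component:
values near 1 give near-critical avalanche statistics (power-law sizes,
exponent about 3/2), values below 1 give subcritical cascades with
closed-form expected total progeny. ``persist_prob`` controls how often
single neurons emit multi-frame bursts independently of cascade spread.

Each activation carries a rate amplitude drawn from ``lambda_amplitude``
(constant 1.0 by default so count-based and rate-based avalanche sizes
coincide); a neuron activated several times in one frame is active once,
with the amplitudes summed.

A forward fluorescence model (AR(1) indicator kernel plus white noise)
and a uniform ROI-centroid generator complete the synthetic study so the
full analysis chain can be exercised without real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .raster import FluorescenceTraces, ROIMap, SpikeRaster

__all__ = [
    "SimParams",
    "PRESETS",
    "CohortMovie",
    "simulate_branching_raster",
    "generate_roi_map",
    "spikes_to_fluorescence",
    "make_cohort",
]


@dataclass(frozen=True)
class SimParams:
    """Parameters of the driven branching-process raster generator.

    Attributes
    ----------
    n_neurons, n_frames : int
        Population size and recording length (frames).
    frame_rate : float
        Sampling rate in Hz (default 15, the imaging frame rate).
    offspring_mean : float
        Expected descendants per active neuron per frame (branching
        ratio of the cascade component); >= 0, critical at 1.
    drive_rate : float
        Expected spontaneous seed activations per frame over the whole
        population.
    persist_prob : float
        Probability that an active neuron stays active in the next
        frame, independent of cascade propagation; in [0, 1).
    lambda_amplitude : float or ("exponential", scale)
        Per-activation rate amplitude: a float gives a constant
        amplitude, the tuple draws i.i.d. exponential amplitudes.
    seed : int or None
        RNG seed; identical seeds give bit-identical rasters.
    """

    n_neurons: int = 80
    n_frames: int = 5000
    frame_rate: float = 15.0
    offspring_mean: float = 0.42
    drive_rate: float = 0.15
    persist_prob: float = 0.05
    lambda_amplitude: float | tuple = 1.0
    seed: int | None = None

    def validate(self) -> None:
        if self.n_neurons < 2:
            raise ValueError("n_neurons must be >= 2")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.offspring_mean < 0:
            raise ValueError("offspring_mean must be >= 0")
        if self.drive_rate < 0:
            raise ValueError("drive_rate must be >= 0")
        if not 0.0 <= self.persist_prob < 1.0:
            raise ValueError("persist_prob must be in [0, 1)")
        if isinstance(self.lambda_amplitude, tuple):
            kind, scale = self.lambda_amplitude
            if kind != "exponential" or scale <= 0:
                raise ValueError("lambda_amplitude tuple must be ('exponential', scale>0)")
        elif self.lambda_amplitude <= 0:
            raise ValueError("constant lambda_amplitude must be positive")


#: Study conditions. ``sal`` and ``pcp`` share the standard recording
#: geometry (80 neurons, 5000 frames, 15 Hz) and an identical subcritical
#: cascade; they differ only in per-neuron burst persistence, the minimal
#: hypothesis for the elevated repeat-activation phenotype. ``critical``
#: is the theory anchor: branching ratio 1, low drive, large population.
PRESETS: dict[str, SimParams] = {
    "sal": SimParams(offspring_mean=0.42, persist_prob=0.05),
    "pcp": SimParams(offspring_mean=0.42, persist_prob=0.25),
    "critical": SimParams(
        n_neurons=500,
        n_frames=150_000,
        offspring_mean=1.0,
        drive_rate=0.05,
        persist_prob=0.0,
    ),
}


def _draw_amplitudes(rng: np.random.Generator, n: int, spec) -> np.ndarray:
    if isinstance(spec, tuple):
        return rng.exponential(spec[1], size=n)
    return np.full(n, float(spec))


def _next_seed_gap(rng: np.random.Generator, drive: float) -> int:
    """Silent frames until the next frame with >= 1 Poisson seed."""
    p_seed = -np.expm1(-drive)
    return int(rng.geometric(p_seed)) - 1


def _truncated_poisson(rng: np.random.Generator, mu: float) -> int:
    """Poisson(mu) conditioned on being >= 1 (inverse-CDF walk)."""
    u = rng.random() * -np.expm1(-mu)
    k, term, cdf = 1, mu * np.exp(-mu), 0.0
    while True:
        cdf += term
        if u <= cdf or k > 10_000:
            return k
        k += 1
        term *= mu / k


def simulate_branching_raster(params: SimParams, dtype=np.float64) -> SpikeRaster:
    """Simulate a spike-rate raster from the driven branching process.

    Returns a :class:`SpikeRaster`; reproducible given ``params.seed``.
    Silent stretches are sampled in one step (geometric gap to the next
    seeding frame), so runtime scales with the number of active frames
    rather than the recording length. ``dtype`` controls the rate-array
    precision (float32 keeps very large simulations in memory).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n, T = params.n_neurons, params.n_frames
    m, p, drive = params.offspring_mean, params.persist_prob, params.drive_rate

    # column-major: each frame's column is contiguous, which keeps the
    # per-frame accumulate/scan cheap on long recordings
    lam = np.zeros((n, T), dtype=dtype, order="F")
    constant_amp = not isinstance(params.lambda_amplitude, tuple)
    prev_active = np.empty(0, dtype=np.intp)  # all active (may persist)
    prev_spawners = np.empty(0, dtype=np.intp)  # cascade-activated (spawn)
    t = 0
    while t < T:
        parts = []
        if prev_active.size == 0:
            if drive == 0:
                break  # nothing can ever activate again
            # jump straight to the next seeding frame
            t += _next_seed_gap(rng, drive)
            if t >= T:
                break
            parts.append(rng.integers(0, n, _truncated_poisson(rng, drive)))
        else:
            n_seed = rng.poisson(drive)
            if n_seed:
                parts.append(rng.integers(0, n, n_seed))
            if m > 0 and prev_spawners.size:
                n_off = rng.poisson(m * prev_spawners.size)
                if n_off:
                    parts.append(rng.integers(0, n, n_off))
        persisters = np.empty(0, dtype=np.intp)
        if p > 0 and prev_active.size:
            persisters = prev_active[rng.random(prev_active.size) < p]
        if parts or persisters.size:
            targets = np.concatenate(parts) if parts else np.empty(0, dtype=np.intp)
            all_targets = np.concatenate([targets, persisters])
            # sparse accumulate: touch only the k hit neurons, not all n
            ids, inverse = np.unique(all_targets, return_inverse=True)
            if constant_amp:
                vals = np.bincount(inverse) * float(params.lambda_amplitude)
            else:
                amps = _draw_amplitudes(rng, all_targets.size, params.lambda_amplitude)
                vals = np.bincount(inverse, weights=amps)
            lam[ids, t] = vals
            prev_active = ids
            prev_spawners = np.unique(targets) if targets.size else targets
        else:
            prev_active = np.empty(0, dtype=np.intp)
            prev_spawners = np.empty(0, dtype=np.intp)
        t += 1
    return SpikeRaster.from_lambda(lam, frame_rate=params.frame_rate, check=False)


def generate_roi_map(n: int, field_size: float = 557.0, seed=None) -> ROIMap:
    """Uniform ROI centroids in a square field of ``field_size`` um."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    xy = rng.uniform(0.0, field_size, size=(2, n))
    return ROIMap(x=xy[0], y=xy[1], field_size=field_size)


def spikes_to_fluorescence(
    raster: SpikeRaster,
    decay_tau: float = 0.5,
    noise_sd: float = 0.05,
    seed=None,
) -> FluorescenceTraces:
    """Forward model: AR(1) indicator convolution of the spike rates.

    ``F(t) = gamma * F(t-1) + lam(t) + noise(t)`` with
    ``gamma = exp(-1 / (frame_rate * decay_tau))`` and ``F(0) = lam(0)``;
    the white noise enters the recursion, so exact AR(1) inversion
    recovers ``lam(t) + noise(t)``.
    """
    if decay_tau <= 0:
        raise ValueError("decay_tau must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    gamma = np.exp(-1.0 / (raster.frame_rate * decay_tau))
    drive = raster.lam
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        eps = rng.normal(0.0, noise_sd, size=drive.shape)
        eps[:, 0] = 0.0  # F(0) = lam(0) by construction
        drive = drive + eps
    values = lfilter([1.0], [1.0, -gamma], drive, axis=1)
    return FluorescenceTraces(values=values, frame_rate=raster.frame_rate)


@dataclass
class CohortMovie:
    """One synthetic movie: raster, forward-modeled traces and ROI map."""

    group: str
    movie_id: int
    params: SimParams
    raster: SpikeRaster
    traces: FluorescenceTraces
    rois: ROIMap


def make_cohort(
    sal_params: SimParams | None = None,
    pcp_params: SimParams | None = None,
    movies_per_group: int = 15,
    seed=None,
    decay_tau: float = 0.5,
    noise_sd: float = 0.05,
    field_size: float = 557.0,
) -> list[CohortMovie]:
    """Generate a two-group cohort of labeled movies.

    Defaults mirror the study design of 15 movies per treatment group.
    Each movie gets a distinct child seed spawned from ``seed``, so the
    whole cohort is reproducible while movies stay independent.
    """
    if movies_per_group < 1:
        raise ValueError("movies_per_group must be >= 1")
    sal_params = PRESETS["sal"] if sal_params is None else sal_params
    pcp_params = PRESETS["pcp"] if pcp_params is None else pcp_params
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * movies_per_group * 3)
    it = iter(children)
    movies: list[CohortMovie] = []
    for group, base in (("sal", sal_params), ("pcp", pcp_params)):
        for i in range(movies_per_group):
            sim_seed, fluor_seed, roi_seed = next(it), next(it), next(it)
            params = replace(base, seed=sim_seed)
            raster = simulate_branching_raster(params)
            traces = spikes_to_fluorescence(
                raster, decay_tau=decay_tau, noise_sd=noise_sd, seed=fluor_seed
            )
            rois = generate_roi_map(params.n_neurons, field_size=field_size, seed=roi_seed)
            movies.append(CohortMovie(group, i, params, raster, traces, rois))
    return movies
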