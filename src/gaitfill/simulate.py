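"""Synthetic gait trajectories and occlusion-gap simulation.

The generator is a sinusoidal latent-factor model — the minimal construction
that jointly exhibits the three structural properties the completion models
rely on: (1) strong cross-channel correlation (all channels are mixtures of a
few shared latent factors, so the matrix is low rank); (2) periodic,
low-frequency motion (the factors are sines/cosines at a gait fundamental and
its first few harmonics); (3) joint spectral support (every channel draws on
the same harmonic basis).  It is a structural stand-in for captured gait, not
a biomechanical model; amplitudes, offsets and noise are in millimetres.

Gaps emulate marker occlusion: a gap removes all three coordinates of one
marker over a contiguous frame interval, with counts and lengths drawn from
the benchmarking protocol (5-20 gaps of 10-50 % of a gait cycle per trial).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .trajectory import ObservationMask, TrajectoryMatrix

__all__ = ["GaitSimConfig", "GapSpec", "Gap", "generate_trajectories", "simulate_gaps"]


@dataclass
class GaitSimConfig:
    """Parameters of the synthetic gait generator.

    Defaults emulate a typical optical-capture session: 37 markers at 240 Hz
    over ten one-second gait cycles, four harmonics of the stride frequency,
    five shared latent factors, oscillation amplitudes of 10-100 mm around
    static marker positions within +/-500 mm.
    """

    n_markers: int = 37
    n_frames: int = 2400
    frame_rate: float = 240.0
    cycle_frames: int = 240
    n_harmonics: int = 4
    latent_rank: int = 5
    amplitude_range: tuple[float, float] = (10.0, 100.0)
    offset_range: tuple[float, float] = (-500.0, 500.0)
    noise_sd: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_markers < 1 or self.n_frames < 2:
            raise ValueError("need at least 1 marker and 2 frames")
        if self.latent_rank > 2 * self.n_harmonics:
            raise ValueError(
                "latent_rank must be <= 2 * n_harmonics "
                "(each harmonic contributes one sine and one cosine)"
            )
        if self.cycle_frames < 4 * self.n_harmonics:
            raise ValueError("cycle_frames must be >= 4 * n_harmonics (Nyquist)")
        if self.latent_rank < 1:
            raise ValueError("latent_rank must be >= 1")
        if not (self.amplitude_range[0] <= self.amplitude_range[1]):
            raise ValueError("amplitude_range must be (low, high) with low <= high")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @property
    def marker_names(self) -> list[str]:
        return [f"M{k:02d}" for k in range(self.n_markers)]


@dataclass
class Gap:
    """One simulated occlusion: marker index, half-open frame interval."""

    marker: int
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GapSpec:
    """Gap-simulation protocol: per trial, draw ``n_gaps`` uniformly from
    ``n_gaps_range``, each gap's length uniformly from
    ``gap_fraction_range`` x cycle length, placed uniformly in time on a
    uniformly chosen marker."""

    n_gaps_range: tuple[int, int] = (5, 20)
    gap_fraction_range: tuple[float, float] = (0.10, 0.50)
    repetitions: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.n_gaps_range
        if not (1 <= lo <= hi):
            raise ValueError("n_gaps_range must satisfy 1 <= low <= high")
        flo, fhi = self.gap_fraction_range
        if not (0 < flo <= fhi <= 1):
            raise ValueError("gap_fraction_range must satisfy 0 < low <= high <= 1")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


def generate_trajectories(cfg: GaitSimConfig) -> tuple[TrajectoryMatrix, TrajectoryMatrix]:
    """Generate one synthetic capture.

    Returns ``(observable, ground_truth)``: the ground truth is the noiseless
    low-rank periodic matrix; the observable copy adds i.i.d. Gaussian
    measurement noise of sd ``noise_sd`` (they coincide when ``noise_sd=0``).

    Construction: a shared harmonic basis S (sines/cosines at the stride
    fundamental ``1/cycle_frames`` and its first ``n_harmonics`` multiples),
    a ``latent_rank x 2 n_harmonics`` loading mixing the basis into unit-RMS
    latent factors, and a per-channel mixing of those factors scaled to a
    channel amplitude drawn from ``amplitude_range``, plus a static offset per
    channel.  Noiseless rank is at most ``latent_rank`` (+1 when offsets are
    non-zero, for the DC direction).
    """
    rng = np.random.default_rng(cfg.rng_seed)
    n, m = cfg.n_frames, cfg.n_markers
    n_ch = 3 * m

    t = np.arange(n)
    cols = []
    for h in range(1, cfg.n_harmonics + 1):
        phase = 2 * np.pi * h * t / cfg.cycle_frames
        cols.append(np.sin(phase))
        cols.append(np.cos(phase))
    S = np.column_stack(cols)  # n x 2H

    loading = rng.standard_normal((cfg.latent_rank, 2 * cfg.n_harmonics))
    Z = S @ loading.T  # n x k latent factors
    rms = np.sqrt(np.mean(Z**2, axis=0))
    Z = Z / rms  # unit-RMS factors so channel amplitudes are interpretable

    directions = rng.standard_normal((n_ch, cfg.latent_rank))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    amplitudes = rng.uniform(*cfg.amplitude_range, size=n_ch)
    mixing = directions * amplitudes[:, None]

    offsets = rng.uniform(*cfg.offset_range, size=n_ch) if cfg.offset_range != (0.0, 0.0) else np.zeros(n_ch)

    truth_values = Z @ mixing.T + offsets
    names = cfg.marker_names
    truth = TrajectoryMatrix(truth_values, cfg.frame_rate, names)

    observable_values = truth_values
    if cfg.noise_sd > 0:
        observable_values = truth_values + rng.normal(0.0, cfg.noise_sd, size=truth_values.shape)
    observable = TrajectoryMatrix(observable_values.copy(), cfg.frame_rate, names)
    return observable, truth


def simulate_gaps(
    truth: TrajectoryMatrix, spec: GapSpec, cycle_frames: int
) -> tuple[TrajectoryMatrix, ObservationMask, list[Gap]]:
    """Punch occlusion gaps into a trajectory matrix.

    Each gap hides all three coordinates of one marker over one contiguous
    interval; overlapping gaps on a marker merge in the mask (occlusions
    union).  Returns the gapped copy (NaN at missing), the observed mask and
    the list of gaps as drawn (before merging).
    """
    if cycle_frames > truth.n_frames:
        raise ValueError("cycle_frames must not exceed n_frames")
    max_len = int(round(spec.gap_fraction_range[1] * cycle_frames))
    if max_len > truth.n_frames:
        raise ValueError("longest possible gap exceeds the sequence length")

    rng = np.random.default_rng(spec.rng_seed)
    n_gaps = int(rng.integers(spec.n_gaps_range[0], spec.n_gaps_range[1] + 1))

    observed = np.ones_like(truth.values, dtype=bool)
    gaps: list[Gap] = []
    for _ in range(n_gaps):
        marker = int(rng.integers(truth.n_markers))
        frac = rng.uniform(*spec.gap_fraction_range)
        length = max(1, int(round(frac * cycle_frames)))
        start = int(rng.integers(0, truth.n_frames - length + 1))
        gap = Gap(marker=marker, start=start, end=start + length)
        gaps.append(gap)
        observed[gap.start : gap.end, 3 * marker : 3 * marker + 3] = False

    gapped_values = truth.values.copy()
    gapped_values[~observed] = np.nan
    gapped = TrajectoryMatrix(gapped_values, truth.frame_rate, list(truth.marker_names))
    return gapped, ObservationMask(observed), gaps
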