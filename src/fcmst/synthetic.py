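"""Synthetic two-group cohorts of phase-coupled multichannel oscillations.

The generator emulates the structure of a resting-state EEG study without
claiming physiological realism: every channel carries a band-limited
oscillation locked to a common carrier with a per-channel constant phase
offset (the "true" lagged coupling), corrupted by i.i.d. wrapped-Gaussian
phase jitter (weaker jitter = stronger coupling), a shared *zero-lag*
oscillator mixed into all channels (the volume-conduction confound that the
phase lag index is designed to reject), and additive Gaussian noise:

    x_i(t) = cos(theta(t) + delta_i + eps_i(t)) + g_i * s(t) + eta_i(t)

theta(t) integrates an instantaneous frequency drawn uniformly inside the
band, constant within an epoch and redrawn per epoch; s(t) is an independent
oscillator in the same band entering every channel with zero lag and gain
g_i.  For a channel pair with offsets delta_i, delta_j and jitter SD sigma
the phase difference is delta_i - delta_j + N(0, 2 sigma^2), so the expected
phase-locking value of the raw phases is exp(-sigma^2) — an analytic check
used in the tests.

All randomness flows through :class:`numpy.random.SeedSequence`; per-subject
seeds are split from the master seed by counter, so cohorts are bit-identical
across runs and independent of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import BandDefinition
from .errors import InvalidSpecError
from .recording import SCALP_19, Recording, write_csv

__all__ = [
    "CouplingSpec",
    "CohortSpec",
    "SubjectRecording",
    "lag_matrix_from_offsets",
    "default_coupling_spec",
    "default_cohort_spec",
    "generate_coupled_recording",
    "generate_cohort",
    "write_cohort",
]


def lag_matrix_from_offsets(offsets) -> np.ndarray:
    """Build the antisymmetric pairwise lag matrix lag(i,j) = d_i - d_j."""
    d = np.asarray(offsets, dtype=float)
    return d[:, None] - d[None, :]


@dataclass(frozen=True)
class CouplingSpec:
    """Ground-truth coupling structure of one simulated subject.

    Parameters
    ----------
    n_channels : int
        Number of channels (>= 2).
    band : BandDefinition
        Frequency interval of the carrier and of the shared source.
    lag_matrix : ndarray (n_channels x n_channels)
        Constant pairwise phase offsets in radians; antisymmetric with zero
        diagonal.  Offsets are realised per channel as d_i = lag(i, 0).
    jitter_sd : float
        SD of the i.i.d. wrapped-Gaussian phase jitter (radians).  0 means
        perfect locking; values >> pi destroy coupling.
    common_source_gain : float
        Overall gain of the shared zero-lag oscillator.
    source_topography : ndarray (n_channels,)
        Per-channel mixing profile of the shared source; the effective gain
        of channel i is ``common_source_gain * source_topography[i]``.  A
        non-uniform default keeps the confound visible after average
        referencing (a spatially uniform projection would be removed
        exactly by the average reference, and is also unphysical).
    noise_sd : float
        SD of the additive broadband Gaussian noise (signal units).
    """

    n_channels: int
    band: BandDefinition
    lag_matrix: np.ndarray
    jitter_sd: float = 0.0
    common_source_gain: float = 0.0
    source_topography: np.ndarray = None
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.n_channels < 2:
            raise InvalidSpecError("need at least 2 channels")
        lag = np.asarray(self.lag_matrix, dtype=float)
        if lag.shape != (self.n_channels, self.n_channels):
            raise InvalidSpecError(
                f"lag_matrix shape {lag.shape} != "
                f"({self.n_channels}, {self.n_channels})"
            )
        if not np.allclose(lag, -lag.T, atol=1e-12):
            raise InvalidSpecError("lag_matrix must be antisymmetric")
        if not np.allclose(np.diag(lag), 0.0):
            raise InvalidSpecError("lag_matrix diagonal must be zero")
        object.__setattr__(self, "lag_matrix", lag)
        topo = self.source_topography
        topo = np.ones(self.n_channels) if topo is None else np.asarray(
            topo, dtype=float
        )
        if topo.shape != (self.n_channels,):
            raise InvalidSpecError("source_topography must be (n_channels,)")
        object.__setattr__(self, "source_topography", topo)
        if self.jitter_sd < 0 or self.noise_sd < 0:
            raise InvalidSpecError("jitter_sd and noise_sd must be >= 0")
        if self.common_source_gain < 0 or (topo < 0).any():
            raise InvalidSpecError("source gains must be >= 0")

    def channel_offsets(self) -> np.ndarray:
        """Per-channel phase offsets d_i realising the lag matrix."""
        return self.lag_matrix[:, 0].copy()


def default_coupling_spec(
    n_channels: int = 19,
    band: BandDefinition = BandDefinition("alpha", 8.0, 12.0),
    jitter_sd: float = 0.8,
    common_source_gain: float = 0.0,
    noise_sd: float = 0.5,
    offsets=None,
) -> CouplingSpec:
    """The reference coupling structure used for cohort simulations.

    The default ensemble is *zero-lag*: every channel tracks the shared
    carrier through its own phase jitter, and inter-channel coupling after
    average referencing comes from the heterogeneous jitter residuals.
    This is the regime in which the phase lag index is, by construction,
    blind to the shared-source confound (all coupling mass sits at phase
    difference 0 mod pi), while the phase locking value is fully exposed
    to it.  Pass ``offsets`` (one per channel, radians) to install genuine
    lagged coupling instead.  The source topography is spread linearly
    over (0.25, 1.75).
    """
    if offsets is None:
        offsets = np.zeros(n_channels)
    topography = np.linspace(0.25, 1.75, n_channels)
    return CouplingSpec(
        n_channels=n_channels,
        band=band,
        lag_matrix=lag_matrix_from_offsets(offsets),
        jitter_sd=jitter_sd,
        common_source_gain=common_source_gain,
        source_topography=topography,
        noise_sd=noise_sd,
    )


def _phase_ramp(rng, band, fs, n_samples, samples_per_epoch):
    """Cumulative phase of an oscillator with per-epoch constant frequency."""
    n_epochs = -(-n_samples // samples_per_epoch)
    freqs = rng.uniform(band.low_hz, band.high_hz, size=n_epochs)
    inst_f = np.repeat(freqs, samples_per_epoch)[:n_samples]
    return 2 * np.pi * np.cumsum(inst_f) / fs


def generate_coupled_recording(
    spec: CouplingSpec,
    fs: float,
    duration: float,
    seed,
    epoch_len_s: float | None = None,
    channel_labels=None,
) -> Recording:
    """Simulate one subject's continuous recording.

    Parameters
    ----------
    spec : CouplingSpec
    fs : float
        Sampling rate (Hz); must satisfy fs > 2 * band.high_hz.
    duration : float
        Length in seconds; ``duration * fs`` must be an integer.
    seed : int or numpy.random.SeedSequence
        Source of all randomness; identical seeds give identical output.
    epoch_len_s : float, optional
        Epoch length used to redraw the instantaneous frequency; defaults
        to the whole duration (a single constant frequency).
    """
    if not (0 < spec.band.low_hz < spec.band.high_hz < fs / 2):
        raise InvalidSpecError(
            f"band ({spec.band.low_hz}, {spec.band.high_hz}) Hz outside "
            f"(0, {fs / 2}) at fs={fs}"
        )
    n_samples = duration * fs
    if abs(n_samples - round(n_samples)) > 1e-9:
        raise InvalidSpecError(
            f"duration*fs = {n_samples} is not an integer number of samples"
        )
    n_samples = int(round(n_samples))
    spe = n_samples if epoch_len_s is None else int(round(epoch_len_s * fs))
    rng = np.random.default_rng(seed)

    theta = _phase_ramp(rng, spec.band, fs, n_samples, spe)
    theta_src = _phase_ramp(rng, spec.band, fs, n_samples, spe)
    source = np.cos(theta_src)

    delta = spec.channel_offsets()
    gains = spec.common_source_gain * spec.source_topography
    data = np.empty((n_samples, spec.n_channels))
    for i in range(spec.n_channels):
        phase = theta + delta[i]
        if spec.jitter_sd > 0:
            phase = phase + rng.normal(0.0, spec.jitter_sd, n_samples)
        x = np.cos(phase) + gains[i] * source
        if spec.noise_sd > 0:
            x = x + rng.normal(0.0, spec.noise_sd, n_samples)
        data[:, i] = x

    if channel_labels is None and spec.n_channels == 19:
        channel_labels = SCALP_19
    return Recording(data, fs, channel_labels or ())


@dataclass(frozen=True)
class CohortSpec:
    """Design of a two-group simulated cohort.

    ``group_effect`` maps :class:`CouplingSpec` field names to the value the
    field takes in group B (group A keeps the base spec).  ``None`` or an
    empty mapping gives a null cohort (both groups identically distributed).
    """

    base: CouplingSpec
    n_per_group: int = 20
    group_effect: dict | None = None
    fs: float = 512.0
    epoch_len_s: float = 8.0
    n_epochs: int = 75
    seed: int = 0

    def __post_init__(self):
        if self.n_per_group < 2:
            raise InvalidSpecError("n_per_group must be >= 2")
        if self.n_epochs < 1:
            raise InvalidSpecError("n_epochs must be >= 1")
        if self.fs <= 2 * self.base.band.high_hz:
            raise InvalidSpecError(
                f"fs={self.fs} must exceed twice the upper band edge "
                f"({self.base.band.high_hz} Hz)"
            )
        if self.group_effect:
            valid = set(CouplingSpec.__dataclass_fields__)
            bad = set(self.group_effect) - valid
            if bad:
                raise InvalidSpecError(
                    f"unknown CouplingSpec fields in group_effect: {sorted(bad)}"
                )

    def group_spec(self, group: str) -> CouplingSpec:
        if group == "A" or not self.group_effect:
            return self.base
        return replace(self.base, **self.group_effect)


def default_cohort_spec(seed: int = 0, **overrides) -> CohortSpec:
    """The study-sized cohort design: 20+20 subjects, 75 x 8 s epochs at 512 Hz."""
    base = overrides.pop("base", default_coupling_spec())
    return CohortSpec(base=base, seed=seed, **overrides)


@dataclass(frozen=True)
class SubjectRecording:
    subject_id: str
    group: str
    seed: int
    recording: Recording


def _subject_seeds(master_seed: int, n: int) -> np.ndarray:
    """Counter-based split of the master seed into n per-subject seeds (< 2^31)."""
    state = np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint64)
    return (state % (2**31)).astype(np.int64)


def generate_cohort(spec: CohortSpec) -> list[SubjectRecording]:
    """Simulate all subjects of both groups; deterministic given ``spec.seed``."""
    n = spec.n_per_group
    seeds = _subject_seeds(spec.seed, 2 * n)
    duration = spec.n_epochs * spec.epoch_len_s
    cohort = []
    for k in range(2 * n):
        group = "A" if k < n else "B"
        sid = f"{group}{(k % n) + 1:02d}"
        rec = generate_coupled_recording(
            spec.group_spec(group),
            fs=spec.fs,
            duration=duration,
            seed=int(seeds[k]),
            epoch_len_s=spec.epoch_len_s,
        )
        cohort.append(SubjectRecording(sid, group, int(seeds[k]), rec))
    return cohort


def write_cohort(cohort: list[SubjectRecording], out_dir) -> Path:
    """Write one CSV per subject plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for subj in cohort:
        fname = f"{subj.subject_id}.csv"
        write_csv(subj.recording, out_dir / fname)
        rows.append(
            {
                "subject_id": subj.subject_id,
                "group": subj.group,
                "seed": subj.seed,
                "file": fname,
                "fs": subj.recording.fs,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
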