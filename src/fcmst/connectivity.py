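"""Phase-based functional connectivity: phase lag index and phase locking value.

Instantaneous phase is the argument of the analytic signal (Hilbert
transform) of each band-limited channel.  For a channel pair with phase
difference series dphi(t_k), wrapped to (-pi, pi]:

* PLI  = | < sign(dphi(t_k)) >_t |      — asymmetry of the phase-difference
  distribution around zero; blind to coupling with dphi centred at 0 mod pi,
  which makes it insensitive to a shared zero-lag (volume-conducted) source.
  sign(0) contributes 0.
* PLV  = | < exp(j dphi(t_k)) >_t |     — concentration of the phase
  difference anywhere on the circle; 1 = perfect locking, including the
  zero-lag locking PLI discards.

Both are computed per epoch over interior samples (a configurable edge
fraction, default 5% per side, is excluded to suppress Hilbert transients)
and then averaged across epochs into a symmetric channel x channel matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert

from .bands import BandDefinition
from .errors import DegeneratePhaseError, InvalidParameterError
from .preprocessing import BandEpochSet

__all__ = [
    "PhaseEpoch",
    "ConnectivityMatrix",
    "wrap_phase",
    "instantaneous_phase",
    "pli",
    "plv",
    "connectivity_matrix",
    "MEASURES",
]

MEASURES = ("PLI", "PLV")

#: Fraction of samples dropped at each epoch edge before the FC sums.
DEFAULT_EDGE_FRACTION = 0.05


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to the interval (-pi, pi]."""
    return np.pi - np.mod(np.pi - np.asarray(phi, dtype=float), 2 * np.pi)


@dataclass
class PhaseEpoch:
    """Instantaneous phases of one epoch: (n_channels, n_samples), radians.

    ``interior`` is the slice of samples retained for connectivity sums
    after edge trimming.
    """

    phases: np.ndarray
    fs: float
    band: BandDefinition | None = None
    interior: slice = field(default_factory=lambda: slice(None))

    @property
    def n_channels(self) -> int:
        return self.phases.shape[0]

    def interior_phases(self) -> np.ndarray:
        return self.phases[:, self.interior]


def instantaneous_phase(
    band_epoch: np.ndarray,
    fs: float,
    band: BandDefinition | None = None,
    edge_fraction: float = DEFAULT_EDGE_FRACTION,
) -> PhaseEpoch:
    """Extract instantaneous phase per channel via the analytic signal.

    ``band_epoch`` is (n_channels, n_samples) with n_samples >= 64.  The
    returned phases are wrapped to (-pi, pi]; ``edge_fraction`` of the
    samples at each end is marked for exclusion from connectivity sums.
    """
    x = np.asarray(band_epoch, dtype=float)
    if x.ndim != 2:
        raise InvalidParameterError("band_epoch must be (channels, samples)")
    n = x.shape[1]
    if n < 64:
        raise InvalidParameterError(f"need >= 64 samples per epoch, got {n}")
    if not np.isfinite(x).all():
        raise InvalidParameterError("band_epoch contains non-finite values")
    power = (x**2).sum(axis=1)
    dead = np.flatnonzero(power == 0.0)
    if dead.size:
        raise DegeneratePhaseError(
            f"all-zero channel(s) {dead.tolist()}: instantaneous phase undefined"
        )
    analytic = hilbert(x, axis=1)
    phases = np.angle(analytic)
    margin = int(round(edge_fraction * n))
    interior = slice(margin, n - margin) if margin else slice(None)
    return PhaseEpoch(phases=phases, fs=fs, band=band, interior=interior)


def pli(delta_phi) -> float:
    """Phase lag index of a phase-difference sample series.

    |mean of sign(dphi)| with dphi wrapped to (-pi, pi]; sign(0) counts 0.
    """
    d = np.asarray(delta_phi, dtype=float).ravel()
    if d.size == 0:
        raise InvalidParameterError("empty phase-difference series")
    if not np.isfinite(d).all():
        raise InvalidParameterError("non-finite phase differences")
    return float(np.abs(np.mean(np.sign(wrap_phase(d)))))


def plv(delta_phi) -> float:
    """Phase locking value: modulus of the mean unit phasor of dphi."""
    d = np.asarray(delta_phi, dtype=float).ravel()
    if d.size == 0:
        raise InvalidParameterError("empty phase-difference series")
    if not np.isfinite(d).all():
        raise InvalidParameterError("non-finite phase differences")
    return float(np.abs(np.mean(np.exp(1j * d))))


@dataclass
class ConnectivityMatrix:
    """Symmetric channel x channel functional connectivity weights.

    Diagonal is 0 for PLI (sign(0) = 0) and 1 for PLV (perfect
    self-locking); off-diagonal entries lie in [0, 1].
    """

    weights: np.ndarray
    measure: str
    band: BandDefinition | None = None
    subject_id: str = ""
    n_epochs_averaged: int = 1
    channel_labels: tuple = ()

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InvalidParameterError("weights must be square")
        if self.measure not in MEASURES:
            raise InvalidParameterError(
                f"measure must be one of {MEASURES}, got {self.measure!r}"
            )

    @property
    def n_channels(self) -> int:
        return self.weights.shape[0]


def _epoch_measure_matrix(phases: np.ndarray, measure: str) -> np.ndarray:
    """Pairwise PLI or PLV over the sample axis of (channels, samples) phases."""
    if measure == "PLV":
        # PLV_ij = |<z_i conj(z_j)>_t| via a single Gram product.
        z = np.exp(1j * phases)
        gram = z @ z.conj().T / phases.shape[1]
        return np.abs(gram)
    # PLI: wrapped per-sample differences by direct subtraction, which is
    # exact for identical phases (sign(0) = 0 must not be destroyed by
    # round-off, unlike a phasor-product + angle route).
    dphi = wrap_phase(phases[:, None, :] - phases[None, :, :])
    return np.abs(np.sign(dphi).mean(axis=2))


def connectivity_matrix(
    phase_epochs: list[PhaseEpoch] | PhaseEpoch,
    measure: str,
    subject_id: str = "",
    channel_labels: tuple = (),
) -> ConnectivityMatrix:
    """Average per-epoch pairwise PLI/PLV matrices over epochs.

    Each epoch contributes a full pairwise matrix computed over its interior
    samples; epoch matrices are averaged arithmetically.  Symmetry holds by
    construction; the diagonal is forced to the measure's self-value.
    """
    if measure not in MEASURES:
        raise InvalidParameterError(
            f"measure must be one of {MEASURES}, got {measure!r}"
        )
    if isinstance(phase_epochs, PhaseEpoch):
        phase_epochs = [phase_epochs]
    if not phase_epochs:
        raise InvalidParameterError("need at least one phase epoch")
    n_channels = phase_epochs[0].n_channels
    band = phase_epochs[0].band
    acc = np.zeros((n_channels, n_channels))
    for ep in phase_epochs:
        if ep.n_channels != n_channels:
            raise InvalidParameterError(
                f"channel count mismatch across epochs: "
                f"{ep.n_channels} != {n_channels}"
            )
        acc += _epoch_measure_matrix(ep.interior_phases(), measure)
    w = acc / len(phase_epochs)
    np.fill_diagonal(w, 0.0 if measure == "PLI" else 1.0)
    return ConnectivityMatrix(
        weights=w,
        measure=measure,
        band=band,
        subject_id=subject_id,
        n_epochs_averaged=len(phase_epochs),
        channel_labels=tuple(channel_labels),
    )


def epoch_connectivity(
    band_epochs: BandEpochSet,
    measure: str,
    edge_fraction: float = DEFAULT_EDGE_FRACTION,
) -> list[ConnectivityMatrix]:
    """One connectivity matrix per epoch of a :class:`BandEpochSet`."""
    out = []
    for e in range(band_epochs.n_epochs):
        ph = instantaneous_phase(
            band_epochs.tensor[e],
            fs=band_epochs.fs,
            band=band_epochs.band,
            edge_fraction=edge_fraction,
        )
        out.append(
            connectivity_matrix(
                ph,
                measure,
                subject_id=band_epochs.subject_id,
                channel_labels=band_epochs.channel_labels,
            )
        )
    return out
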