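"""The in-memory container for a continuous multichannel recording, plus I/O.

A :class:`Recording` is a plain (samples x channels) float array with a
sampling rate and ordered channel labels.  Text CSV (header row = channel
labels) is the primary interchange format; EDF/EDF+ files are read through
:mod:`mne` when that optional dependency is installed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidParameterError

#: The 19 scalp electrodes of the 10-20 montage analysed here.  The full
#: electro-cap montage also carries the ear references A1/A2, which are
#: excluded so that the network node count is N = 19.
SCALP_19 = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Pz", "Cz",
)


@dataclass
class Recording:
    """Continuous multichannel signal.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
        Signal values (microvolts for real EEG; arbitrary units for
        synthetic data).
    fs : float
        Sampling rate in Hz.
    channel_labels : tuple of str
        Ordered channel names, one per column of ``data``.
    """

    data: np.ndarray
    fs: float
    channel_labels: tuple = field(default=())

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise InvalidParameterError("data must be 2-D (samples x channels)")
        if self.fs <= 0:
            raise InvalidParameterError(f"fs must be positive, got {self.fs}")
        if self.n_channels < 2:
            raise InvalidParameterError("a Recording needs at least 2 channels")
        if not np.isfinite(self.data).all():
            raise InvalidParameterError("data contains non-finite samples")
        if not self.channel_labels:
            self.channel_labels = tuple(
                f"ch{i:02d}" for i in range(self.n_channels)
            )
        self.channel_labels = tuple(self.channel_labels)
        if len(self.channel_labels) != self.n_channels:
            raise InvalidParameterError(
                f"{len(self.channel_labels)} labels for "
                f"{self.n_channels} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def select_channels(self, labels) -> "Recording":
        """Return a copy restricted to ``labels``, in the given order."""
        idx = []
        for lab in labels:
            try:
                idx.append(self.channel_labels.index(lab))
            except ValueError:
                raise InvalidParameterError(f"channel {lab!r} not in recording")
        return replace(
            self, data=self.data[:, idx], channel_labels=tuple(labels)
        )

    def copy(self) -> "Recording":
        return replace(self, data=self.data.copy())


def read_csv(path, fs: float) -> Recording:
    """Read a headered CSV matrix (columns = channel labels) as a Recording."""
    df = pd.read_csv(path)
    return Recording(df.to_numpy(dtype=float), fs, tuple(df.columns))


def write_csv(rec: Recording, path) -> None:
    """Write a Recording to a headered CSV (samples x channels)."""
    pd.DataFrame(rec.data, columns=list(rec.channel_labels)).to_csv(
        path, index=False, float_format="%.6g"
    )


def read_edf(path, channels=None) -> Recording:
    """Read an EDF/EDF+ file; requires the optional ``mne`` dependency."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover - optional dependency
        raise ImportError(
            "reading EDF requires mne (pip install fcmst[edf])"
        ) from err
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    rec = Recording(
        raw.get_data().T * 1e6,  # volts -> microvolts
        float(raw.info["sfreq"]),
        tuple(raw.ch_names),
    )
    if channels is not None:
        rec = rec.select_channels(channels)
    return rec


def read_recording(path, fs: float | None = None, channels=None) -> Recording:
    """Dispatch on file extension: ``.edf`` -> EDF, anything else -> CSV."""
    path = Path(path)
    if path.suffix.lower() == ".edf":
        return read_edf(path, channels=channels)
    if fs is None:
        raise InvalidParameterError("fs is required for CSV input")
    rec = read_csv(path, fs)
    if channels is not None:
        rec = rec.select_channels(channels)
    return rec
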