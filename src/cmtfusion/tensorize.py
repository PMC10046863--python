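"""EEG spectrogram tensorization.

Multichannel EEG recorded simultaneously with fMRI is converted into a
third-order nonnegative power tensor X (time segments x frequency bins x
channels).  The recording is cut into contiguous segments of one repetition
time (TR) each — one segment per fMRI volume, so the tensor's first mode is
synchronized with the BOLD time axis.  Each segment/channel is transformed
with Thomson's multitaper method (DPSS tapers), and the squared Fourier
amplitudes are averaged into half-open frequency bins (default 0.5 Hz wide,
covering [1, 30) Hz).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.signal.windows import dpss

logger = logging.getLogger(__name__)


def default_bin_edges(fmin: float = 1.0, fmax: float = 30.0, width: float = 0.5) -> np.ndarray:
    """Half-open frequency bin edges [fmin, fmin+width), ..., up to fmax."""
    n = int(round((fmax - fmin) / width))
    return fmin + width * np.arange(n + 1)


@dataclass
class EEGTensor:
    """Third-order spectral-power tensor (segments x frequency bins x channels)."""

    data: np.ndarray
    freq_bin_edges: np.ndarray
    channel_labels: list[str] = field(default_factory=list)
    TR: float = 2.0
    fs: float = 250.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.freq_bin_edges = np.asarray(self.freq_bin_edges, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EEGTensor data must be 3-dimensional")
        if self.data.shape[1] != self.freq_bin_edges.size - 1:
            raise ValueError("frequency dimension does not match bin edges")
        if not self.channel_labels:
            self.channel_labels = [f"E{c + 1:02d}" for c in range(self.data.shape[2])]
        if len(self.channel_labels) != self.data.shape[2]:
            raise ValueError("channel label count does not match data")

    @property
    def shape(self):
        return self.data.shape

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data)
            f.create_dataset("freq_bin_edges", data=self.freq_bin_edges)
            f.create_dataset(
                "channel_labels",
                data=np.array(self.channel_labels, dtype=h5py.string_dtype()),
            )
            f.attrs["fs"] = self.fs
            f.attrs["TR"] = self.TR

    @classmethod
    def from_hdf5(cls, path) -> "EEGTensor":
        with h5py.File(path, "r") as f:
            return cls(
                data=f["data"][()],
                freq_bin_edges=f["freq_bin_edges"][()],
                channel_labels=[s.decode() if isinstance(s, bytes) else str(s)
                                for s in f["channel_labels"][()]],
                fs=float(f.attrs["fs"]),
                TR=float(f.attrs["TR"]),
            )


def _segment_length(fs: float, TR: float) -> int:
    n = fs * TR
    if abs(n - round(n)) > 1e-9:
        raise ValueError(f"fs*TR = {n} is not an integer number of samples")
    return int(round(n))


def segment_eeg(raw: np.ndarray, fs: float, TR: float, n_volumes: int) -> np.ndarray:
    """Cut raw EEG (samples x channels) into per-volume segments.

    Returns an array (n_volumes, fs*TR, n_channels) of contiguous,
    non-overlapping segments anchored at sample 0.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if raw.ndim != 2:
        raise ValueError("raw EEG must be 1- or 2-dimensional")
    if raw.shape[0] == 1 and raw.shape[1] > 1:
        raw = raw.T  # accept a single channel given as a row
    seg_len = _segment_length(fs, TR)
    needed = n_volumes * seg_len
    if raw.shape[0] < needed:
        raise ValueError(
            f"raw EEG has {raw.shape[0]} samples; {needed} required for "
            f"{n_volumes} volumes of {seg_len} samples"
        )
    return raw[:needed].reshape(n_volumes, seg_len, raw.shape[1])


def multitaper_band_power(
    segment: np.ndarray,
    fs: float,
    time_bandwidth: float = 2.0,
    n_tapers: int = 3,
) -> tuple[np.ndarray, np.ndarray]:
    """Thomson multitaper power estimate for one channel segment.

    Averages squared Fourier amplitudes over unit-energy DPSS tapers.
    Returns ``(freqs, power)`` on the grid ``fs / len(segment)``.
    """
    segment = np.asarray(segment, dtype=float).ravel()
    n = segment.size
    if n < 8:
        raise ValueError("segment too short for spectral estimation")
    if n_tapers > 2 * time_bandwidth - 1:
        raise ValueError(
            f"n_tapers={n_tapers} exceeds 2*NW-1={2 * time_bandwidth - 1:g}"
        )
    tapers = dpss(n, time_bandwidth, Kmax=n_tapers)
    tapers = np.atleast_2d(tapers)
    spectra = np.fft.rfft(tapers * segment[None, :], axis=1)
    power = np.mean(np.abs(spectra) ** 2, axis=0)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, power


def bin_spectrum(estimate: np.ndarray, grid: np.ndarray, edges: np.ndarray) -> np.ndarray:
    """Average a fine-grid spectral estimate into half-open frequency bins.

    Bin j collects grid points with frequency in ``[edges[j], edges[j+1])``;
    an empty bin yields 0 and a logged warning.
    """
    estimate = np.asarray(estimate, dtype=float)
    grid = np.asarray(grid, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("bin edges must be strictly increasing")
    idx = np.digitize(grid, edges) - 1  # j such that edges[j] <= f < edges[j+1]
    n_bins = edges.size - 1
    valid = (idx >= 0) & (idx < n_bins)
    sums = np.bincount(idx[valid], weights=estimate[valid], minlength=n_bins)
    counts = np.bincount(idx[valid], minlength=n_bins)
    out = np.zeros(n_bins)
    nonempty = counts > 0
    out[nonempty] = sums[nonempty] / counts[nonempty]
    if not np.all(nonempty):
        logger.warning("%d empty frequency bins set to 0", int((~nonempty).sum()))
    return out


def build_eeg_tensor(
    raw: np.ndarray,
    fs: float,
    TR: float,
    n_volumes: int,
    edges: np.ndarray | None = None,
    time_bandwidth: float = 2.0,
    n_tapers: int = 3,
    demean: bool = True,
    channel_labels: list[str] | None = None,
) -> EEGTensor:
    """Full tensorization: segment -> multitaper -> bin, per channel.

    ``demean`` removes each segment's mean before the transform to keep DC
    from leaking into the lowest bin (the study's data were band-passed).
    """
    segments = segment_eeg(raw, fs, TR, n_volumes)  # (Is, L, Ic)
    n_seg, seg_len, n_chan = segments.shape
    if edges is None:
        edges = default_bin_edges()
    if n_tapers > 2 * time_bandwidth - 1:
        raise ValueError(
            f"n_tapers={n_tapers} exceeds 2*NW-1={2 * time_bandwidth - 1:g}"
        )
    if demean:
        segments = segments - segments.mean(axis=1, keepdims=True)
    tapers = np.atleast_2d(dpss(seg_len, time_bandwidth, Kmax=n_tapers))
    freqs = np.fft.rfftfreq(seg_len, d=1.0 / fs)
    n_bins = edges.size - 1
    # precompute the bin-averaging matrix once (equivalent to bin_spectrum)
    idx = np.digitize(freqs, edges) - 1
    valid = (idx >= 0) & (idx < n_bins)
    counts = np.bincount(idx[valid], minlength=n_bins)
    if np.any(counts == 0):
        logger.warning("%d empty frequency bins set to 0", int((counts == 0).sum()))
    A = np.zeros((n_bins, freqs.size))
    A[idx[valid], np.flatnonzero(valid)] = 1.0 / np.maximum(counts, 1)[idx[valid]]
    X = np.empty((n_seg, n_bins, n_chan))
    for c in range(n_chan):  # chunk by channel to bound memory
        tapered = tapers[:, None, :] * segments[None, :, :, c]
        power = np.mean(np.abs(np.fft.rfft(tapered, axis=2)) ** 2, axis=0)
        X[:, :, c] = power @ A.T
    return EEGTensor(
        data=X, freq_bin_edges=edges, channel_labels=channel_labels or [],
        TR=TR, fs=fs,
    )
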