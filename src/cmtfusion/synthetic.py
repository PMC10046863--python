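"""Synthetic coupled EEG-fMRI data with known ground truth.

The study paradigm this generator emulates is an event-related gambling
task inside the scanner: 80 trials of door choice followed by win/lose
feedback, TR = 2 s, 560 fMRI volumes (18 min 40 s), 64-channel EEG sampled
at 250 Hz, and 90 AAL ROI-averaged BOLD series.  Each latent source r has

* a temporal signature ``s_r`` defined on the volume grid (shared between
  modalities — this is the coupling),
* a nonnegative spectral signature ``f_r`` (a band-limited bump in
  [1, 30) Hz) and a smooth channel topography ``c_r`` on the EEG side,
* a sparse ROI map ``v_r`` on the fMRI side, where ``s_r`` enters after
  convolution with an ROI-specific HRF ``sum_k B[v, k] h_k``.

One designated source follows the stimulus timecourse (lightly smoothed,
with low-amplitude noise), so downstream model selection has a planted
"stimulus-related component" to find.  fMRI structure unrelated to the EEG
is represented by a rank-Q term ``N P^T``.

All generators draw from a single ``numpy`` Generator seeded per call, so
identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .hrf import HRFBasis, convolve

#: per-trial phase durations in seconds (sums to 14 s so that the 80-trial
#: task lasts 1120 s = 18 min 40 s)
DEFAULT_TRIAL_SCHEDULE = {
    "choice": 4.0,
    "gaze": 2.0,
    "feedback": 2.0,
    "score": 2.0,
    "rest": 4.0,
}

#: short smoothing kernel applied to the stimulus before planting it as a
#: temporal signature (keeps correlation with the raw stimulus high)
_STIM_KERNEL = np.array([0.15, 0.7, 0.15])


@dataclass
class StimulusTimecourse:
    """Binary per-volume indicator of feedback presentation."""

    values: np.ndarray
    condition: str = "both"  # win | lose | both
    TR: float = 2.0

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("stimulus timecourse must be binary")
        self.values = self.values.astype(float)
        if self.condition not in ("win", "lose", "both"):
            raise ValueError(f"unknown condition {self.condition!r}")

    def __len__(self) -> int:
        return self.values.size


def generate_stimulus_timecourse(
    n_trials: int = 80,
    trial_schedule: dict | None = None,
    TR: float = 2.0,
    condition: str = "both",
    p_win: float = 0.5,
    seed: int | None = None,
) -> StimulusTimecourse:
    """Mark every volume whose acquisition window overlaps a feedback arrow.

    A volume t covers the half-open interval ``[t*TR, (t+1)*TR)``; it is
    marked 1 when that interval overlaps the feedback phase of a trial whose
    outcome matches ``condition`` (wins drawn Bernoulli(p_win) per trial).
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if TR <= 0:
        raise ValueError("TR must be positive")
    sched = dict(trial_schedule or DEFAULT_TRIAL_SCHEDULE)
    trial_len = sum(sched.values())
    total = n_trials * trial_len
    n_vol = total / TR
    if abs(n_vol - round(n_vol)) > 1e-9:
        raise ValueError("task length is not an integer number of volumes")
    n_vol = int(round(n_vol))
    rng = np.random.default_rng(seed)
    wins = rng.random(n_trials) < p_win
    fb_offset = sched.get("choice", 0.0) + sched.get("gaze", 0.0)
    fb_dur = sched.get("feedback", 0.0)
    values = np.zeros(n_vol, dtype=int)
    for i in range(n_trials):
        if condition == "win" and not wins[i]:
            continue
        if condition == "lose" and wins[i]:
            continue
        a = i * trial_len + fb_offset
        b = a + fb_dur
        t0 = int(np.floor(a / TR))
        t1 = int(np.ceil(b / TR))
        for t in range(max(t0, 0), min(t1, n_vol)):
            # overlap of [t*TR, (t+1)*TR) with [a, b)
            if max(t * TR, a) < min((t + 1) * TR, b):
                values[t] = 1
    return StimulusTimecourse(values=values, condition=condition, TR=TR)


@dataclass
class GroundTruth:
    """Latent factors from which both modalities are synthesized."""

    S: np.ndarray  # (Is, R) temporal signatures
    F: np.ndarray  # (If, R) nonnegative spectral signatures
    C: np.ndarray  # (Ic, R) channel topographies
    V: np.ndarray  # (Iv, R) sparse ROI maps
    B: np.ndarray  # (Iv, K) HRF basis coefficients, rows near (1, 0, ...)
    N: np.ndarray  # (Is, Q) uncoupled temporal factors
    P: np.ndarray  # (Iv, Q) uncoupled spatial factors
    seed: int = 0
    stim_component_index: int = 0
    freq_bin_edges: np.ndarray | None = None
    stimulus: StimulusTimecourse | None = None

    def __post_init__(self):
        for name in ("S", "F", "C", "V", "B", "N", "P"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        R = self.S.shape[1]
        if not (self.F.shape[1] == self.C.shape[1] == self.V.shape[1] == R):
            raise ValueError("inconsistent R across S, F, C, V")
        if R < 1 or self.B.shape[1] < 1:
            raise ValueError("R and K must be >= 1")
        if self.N.shape[1] != self.P.shape[1]:
            raise ValueError("inconsistent Q across N, P")
        if np.any(self.F < 0):
            raise ValueError("spectral signatures must be nonnegative")
        if not 0 <= self.stim_component_index < R:
            raise ValueError("stim_component_index out of range")

    @property
    def R(self) -> int:
        return self.S.shape[1]

    @property
    def K(self) -> int:
        return self.B.shape[1]

    @property
    def Q(self) -> int:
        return self.N.shape[1]

    @property
    def dims(self) -> tuple[int, int, int, int]:
        return (self.S.shape[0], self.F.shape[0], self.C.shape[0], self.V.shape[0])

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            for name in ("S", "F", "C", "V", "B", "N", "P"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["seed"] = self.seed
            f.attrs["stim_component_index"] = self.stim_component_index
            if self.freq_bin_edges is not None:
                f.create_dataset("freq_bin_edges", data=self.freq_bin_edges)
            if self.stimulus is not None:
                f.create_dataset("stimulus", data=self.stimulus.values)
                f.attrs["stimulus_condition"] = self.stimulus.condition
                f.attrs["TR"] = self.stimulus.TR


def _smooth_standardized(rng, n: int, sigma: float) -> np.ndarray:
    x = gaussian_filter1d(rng.standard_normal(n), sigma, mode="wrap")
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_ground_truth(
    R: int,
    K: int,
    Q: int,
    dims: tuple[int, int, int, int],
    stimulus: StimulusTimecourse,
    seed: int = 0,
    freq_range: tuple[float, float] = (1.0, 30.0),
    roi_density: float = 0.15,
    b_perturb: float = 0.1,
    stim_noise: float = 0.1,
) -> GroundTruth:
    """Draw a full set of latent factors with the model's assumed structure.

    The stimulus-driven temporal signature is the binary stimulus smoothed
    with a short 3-tap kernel plus low-amplitude AR(1) noise (std
    ``stim_noise`` relative to the signal); other temporal signatures are
    smooth Gaussian processes.  Spectral signatures are unimodal bumps at
    distinct centers inside ``freq_range``; ROI maps have at most
    ``roi_density`` (<= 20%) of entries nonzero; HRF coefficient rows are
    ``(1, 0, ...)`` plus N(0, b_perturb) perturbations.
    """
    Is, If, Ic, Iv = dims
    if min(Is, If, Ic, Iv) < 1 or R < 1 or K < 1 or Q < 0:
        raise ValueError("dimensions must be positive; R, K >= 1; Q >= 0")
    if Q > 0 and Iv < Q:
        raise ValueError(f"Iv={Iv} too small for Q={Q} uncoupled factors")
    if len(stimulus) != Is:
        raise ValueError(
            f"stimulus length {len(stimulus)} does not match Is={Is}"
        )
    if not 0 < roi_density <= 0.2:
        raise ValueError("roi_density must lie in (0, 0.2]")
    rng = np.random.default_rng(seed)
    stim_idx = 0

    # temporal signatures
    S = np.empty((Is, R))
    stim_vec = stimulus.values.astype(float)
    smoothed = np.convolve(stim_vec, _STIM_KERNEL, mode="same")
    ar = np.empty(Is)
    ar[0] = rng.standard_normal()
    eps = rng.standard_normal(Is)
    for t in range(1, Is):
        ar[t] = 0.5 * ar[t - 1] + eps[t]
    ar = ar / max(ar.std(), 1e-12)
    stim_sig = smoothed + stim_noise * max(smoothed.std(), 1e-12) * ar
    # unit-variance columns: sources enter both modalities with
    # comparable amplitude
    S[:, stim_idx] = stim_sig / max(stim_sig.std(), 1e-12)
    for r in range(R):
        if r == stim_idx:
            continue
        S[:, r] = _smooth_standardized(rng, Is, sigma=max(Is / 40, 2.0))

    # spectral signatures: unimodal bumps at distinct band centers
    lo, hi = freq_range
    grid = lo + (hi - lo) * (np.arange(If) + 0.5) / If
    centers = lo + (hi - lo) * (np.arange(R) + 0.75 * rng.random(R) + 0.125) / R
    F = np.empty((If, R))
    for r in range(R):
        width = (hi - lo) / (3.0 * R) * (0.8 + 0.4 * rng.random())
        F[:, r] = np.exp(-0.5 * ((grid - centers[r]) / width) ** 2)

    # smooth channel topographies (channels treated as a 1-D neighborhood)
    C = np.column_stack(
        [_smooth_standardized(rng, Ic, sigma=max(Ic / 8, 1.0)) for _ in range(R)]
    )

    # sparse ROI maps
    m = max(1, int(np.floor(roi_density * Iv)))
    V = np.zeros((Iv, R))
    for r in range(R):
        rois = rng.choice(Iv, size=m, replace=False)
        V[rois, r] = rng.choice((-1.0, 1.0), size=m) * rng.uniform(0.5, 1.5, size=m)

    # near-canonical HRF coefficients
    B = np.zeros((Iv, K))
    B[:, 0] = 1.0
    B += b_perturb * rng.standard_normal((Iv, K))

    N = np.column_stack(
        [_smooth_standardized(rng, Is, sigma=max(Is / 40, 2.0)) for _ in range(Q)]
    ) if Q > 0 else np.zeros((Is, 0))
    P = rng.standard_normal((Iv, Q)) if Q > 0 else np.zeros((Iv, 0))

    return GroundTruth(
        S=S, F=F, C=C, V=V, B=B, N=N, P=P, seed=seed,
        stim_component_index=stim_idx,
        freq_bin_edges=np.linspace(lo, hi, If + 1),
        stimulus=stimulus,
    )


def _add_noise(signal: np.ndarray, snr_db: float, rng) -> np.ndarray:
    """Additive white Gaussian noise at SNR = 10 log10(||sig||^2/||noise||^2)."""
    if np.isinf(snr_db):
        return signal
    noise = rng.standard_normal(signal.shape)
    sig_norm = np.linalg.norm(signal)
    noise_norm = np.linalg.norm(noise)
    if noise_norm == 0 or sig_norm == 0:
        return signal
    scale = sig_norm / (noise_norm * 10.0 ** (snr_db / 20.0))
    return signal + scale * noise


def assemble_eeg_tensor(
    gt: GroundTruth,
    snr_db: float = np.inf,
    seed: int | None = None,
    nonneg: bool = False,
) -> np.ndarray:
    """Noisy CP tensor ``[[S, F, C]]`` + white noise at ``snr_db``.

    ``nonneg=True`` clips negative entries to zero after adding noise
    (spectral power is physically nonnegative).
    """
    X = np.einsum("tr,fr,cr->tfc", gt.S, gt.F, gt.C, optimize=True)
    X = _add_noise(X, snr_db, np.random.default_rng(seed))
    if nonneg:
        X = np.clip(X, 0.0, None)
    return X


def assemble_fmri_matrix(
    gt: GroundTruth,
    basis: HRFBasis,
    snr_db: float = np.inf,
    seed: int | None = None,
) -> np.ndarray:
    """Coupled BOLD matrix: HRF-convolved sources + uncoupled term + noise.

    ``Y[t, v] = sum_r sum_k (H_k s_r)[t] B[v, k] V[v, r] + (N P^T)[t, v]``
    """
    if basis.K != gt.K:
        raise ValueError(f"basis K={basis.K} does not match ground truth K={gt.K}")
    Y = np.zeros((gt.S.shape[0], gt.V.shape[0]))
    for k in range(gt.K):
        Zk = convolve(basis, k, gt.S)  # (Is, R)
        Wk = gt.B[:, k : k + 1] * gt.V  # (Iv, R)
        Y += Zk @ Wk.T
    Y += gt.N @ gt.P.T
    return _add_noise(Y, snr_db, np.random.default_rng(seed))


def synthesize_raw_eeg(
    gt: GroundTruth,
    fs: float = 250.0,
    TR: float = 2.0,
    freq_grid: np.ndarray | None = None,
    snr_db: float = np.inf,
    seed: int | None = None,
) -> np.ndarray:
    """Raw multichannel EEG whose per-segment band power follows the truth.

    Each source emits a sum of sinusoids on ``freq_grid`` with squared
    amplitudes proportional to its spectral signature, amplitude-modulated
    per TR segment by ``sqrt(max(S, 0))``, mixed to channels through C, plus
    white noise at ``snr_db``.  Output shape (Is * fs * TR, Ic).
    """
    n = fs * TR
    if abs(n - round(n)) > 1e-9:
        raise ValueError("fs*TR must be an integer number of samples")
    seg_len = int(round(n))
    Is, If, Ic, _ = gt.dims
    if freq_grid is None:
        edges = gt.freq_bin_edges
        if edges is None:
            edges = np.linspace(1.0, 30.0, If + 1)
        freq_grid = 0.5 * (edges[:-1] + edges[1:])
    freq_grid = np.asarray(freq_grid, dtype=float)
    if freq_grid.size != If:
        raise ValueError("freq_grid length must equal If")
    rng = np.random.default_rng(seed)
    n_samples = Is * seg_len
    t = np.arange(n_samples) / fs
    amp_seg = np.sqrt(np.clip(gt.S, 0.0, None))  # (Is, R)
    signal = np.zeros((n_samples, Ic))
    for r in range(gt.R):
        phases = rng.uniform(0.0, 2 * np.pi, If)
        weights = np.sqrt(gt.F[:, r])
        carrier = np.sum(
            weights[None, :] * np.sin(2 * np.pi * freq_grid[None, :] * t[:, None]
                                      + phases[None, :]),
            axis=1,
        )
        envelope = np.repeat(amp_seg[:, r], seg_len)
        signal += np.outer(carrier * envelope, gt.C[:, r])
    return _add_noise(signal, snr_db, rng)


# --------------------------------------------------------------------------
# plain-text / HDF5 exports

def write_roi_tsv(Y: np.ndarray, path, roi_labels: list[str] | None = None) -> None:
    """BOLD ROI series as TSV: first column time index, header = ROI labels."""
    Y = np.asarray(Y)
    labels = roi_labels or [f"ROI{v + 1:03d}" for v in range(Y.shape[1])]
    df = pd.DataFrame(Y, columns=labels)
    df.insert(0, "time", np.arange(Y.shape[0]))
    df.to_csv(path, sep="\t", index=False)


def read_roi_tsv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t")
    labels = [c for c in df.columns if c != "time"]
    return df[labels].to_numpy(dtype=float), labels


def write_events_tsv(stim: StimulusTimecourse, path) -> None:
    """Stimulus events as TSV with columns onset, duration, condition."""
    onsets = np.flatnonzero(stim.values) * stim.TR
    df = pd.DataFrame(
        {
            "onset": onsets,
            "duration": np.full(onsets.size, stim.TR),
            "condition": [stim.condition] * onsets.size,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path, n_volumes: int, TR: float = 2.0,
                    condition: str = "both") -> StimulusTimecourse:
    df = pd.read_csv(path, sep="\t")
    values = np.zeros(n_volumes, dtype=int)
    for _, row in df.iterrows():
        t0 = int(np.floor(row["onset"] / TR))
        t1 = int(np.ceil((row["onset"] + row["duration"]) / TR))
        values[max(t0, 0): min(t1, n_volumes)] = 1
    return StimulusTimecourse(values=values, condition=condition, TR=TR)


def write_eeg_hdf5(raw: np.ndarray, path, fs: float, TR: float,
                   channel_labels: list[str] | None = None) -> None:
    raw = np.asarray(raw)
    labels = channel_labels or [f"E{c + 1:02d}" for c in range(raw.shape[1])]
    with h5py.File(path, "w") as f:
        f.create_dataset("eeg", data=raw)
        f.create_dataset(
            "channel_labels", data=np.array(labels, dtype=h5py.string_dtype())
        )
        f.attrs["fs"] = fs
        f.attrs["TR"] = TR


def read_eeg_hdf5(path) -> tuple[np.ndarray, float, float, list[str]]:
    with h5py.File(path, "r") as f:
        raw = f["eeg"][()]
        labels = [s.decode() if isinstance(s, bytes) else str(s)
                  for s in f["channel_labels"][()]]
        return raw, float(f.attrs["fs"]), float(f.attrs["TR"]), labels
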