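"""Hemodynamic response basis and causal convolution operators.

The neurovascular coupling between electrophysiological activity and the
BOLD signal is modeled as a linear, time-invariant convolution with a
hemodynamic response function (HRF).  Rather than fixing a single HRF for
the whole brain, each region of interest (ROI) carries its own response
curve, expressed as a linear combination of K basis functions::

    hrf_v(t) = sum_k B[v, k] * h_k(t)

with the widely used canonical basis: a double-gamma response (peak near
6 s, undershoot near 16 s), its temporal derivative and its dispersion
derivative.  The coefficients ``B`` (one row per ROI) are estimated by the
coupled decomposition; the basis itself is fixed.

All convolution here happens at the fMRI sampling grid (one sample per TR),
with zero initial conditions and output truncated to the signal length, so
that ``H_k s`` is a causal, length-preserving linear map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gamma as _gamma_dist


DEFAULT_THETA = {
    "peak_delay": 6.0,       # s, delay of response peak
    "undershoot_delay": 16.0,  # s, delay of post-stimulus undershoot
    "peak_dispersion": 1.0,    # s, width of the response gamma
    "undershoot_dispersion": 1.0,
    "undershoot_ratio": 1.0 / 6.0,
}


@dataclass
class HRFBasis:
    """K hemodynamic basis functions sampled on a causal lag grid.

    Attributes
    ----------
    lags : (L,) array, seconds, ``0, TR, 2*TR, ...``
    basis : (K, L) array, ``basis[k]`` is h_k evaluated on ``lags``;
        h_1 is normalized to unit peak.
    theta : dict of shape parameters used to construct the curves.
    TR : sampling interval in seconds.
    kind : identifier of the basis family.
    """

    lags: np.ndarray
    basis: np.ndarray
    theta: dict = field(default_factory=dict)
    TR: float = 2.0
    kind: str = "canonical+derivatives"

    @property
    def K(self) -> int:
        return self.basis.shape[0]

    @property
    def n_lags(self) -> int:
        return self.lags.size

    def to_tsv(self, path) -> None:
        """Export lag grid and basis curves for inspection."""
        cols = {"lag": self.lags}
        for k in range(self.K):
            cols[f"h_{k + 1}"] = self.basis[k]
        pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


def _double_gamma(t: np.ndarray, theta: dict) -> np.ndarray:
    """Canonical double-gamma HRF, unnormalized, zero at negative lags."""
    pd_, ud = theta["peak_delay"], theta["undershoot_delay"]
    pw, uw = theta["peak_dispersion"], theta["undershoot_dispersion"]
    ratio = theta["undershoot_ratio"]
    peak = _gamma_dist.pdf(t, a=pd_ / pw, scale=pw)
    under = _gamma_dist.pdf(t, a=ud / uw, scale=uw)
    h = peak - ratio * under
    h[t < 0] = 0.0
    return h


def build_hrf_basis(
    kind: str = "canonical+derivatives",
    K: int = 3,
    TR: float = 2.0,
    duration: float = 32.0,
    theta: dict | None = None,
) -> HRFBasis:
    """Construct the canonical HRF basis sampled at the fMRI grid.

    Parameters
    ----------
    kind : only ``"canonical+derivatives"`` is provided.
    K : number of basis functions, 1 (canonical), 2 (+temporal derivative)
        or 3 (+dispersion derivative).
    TR : sampling interval, seconds.
    duration : extent of the lag grid, seconds (>= 16 s recommended so the
        undershoot is represented).
    theta : optional overrides of :data:`DEFAULT_THETA` entries.
    """
    if kind != "canonical+derivatives":
        raise ValueError(f"unsupported basis kind: {kind!r}")
    if not 1 <= K <= 3:
        raise ValueError(f"K must be in {{1, 2, 3}} for {kind}, got {K}")
    if TR <= 0:
        raise ValueError("TR must be positive")
    th = dict(DEFAULT_THETA)
    if theta:
        unknown = set(theta) - set(th)
        if unknown:
            raise ValueError(f"unknown theta parameters: {sorted(unknown)}")
        th.update(theta)

    lags = np.arange(0.0, duration + TR / 2, TR)
    # Evaluate on a fine grid for stable derivatives, then subsample at TR.
    dt = 0.01
    tf = np.arange(0.0, duration + dt / 2, dt)
    h1f = _double_gamma(tf, th)

    curves_fine = [h1f]
    if K >= 2:
        # temporal derivative: sensitivity to small shifts of onset
        shifted = dict(th)
        shifted["peak_delay"] = th["peak_delay"] + dt
        shifted["undershoot_delay"] = th["undershoot_delay"] + dt
        curves_fine.append((h1f - _double_gamma(tf, shifted)) / dt)
    if K >= 3:
        # dispersion derivative: sensitivity to response width
        dd = 0.01
        wider = dict(th)
        wider["peak_dispersion"] = th["peak_dispersion"] + dd
        curves_fine.append((h1f - _double_gamma(tf, wider)) / dd)

    idx = np.rint(lags / dt).astype(int)
    basis = np.stack([c[idx] for c in curves_fine])
    # unit-peak normalization (h_1 contract; derivatives scaled likewise
    # so B coefficients are comparable across k)
    for k in range(basis.shape[0]):
        m = np.max(np.abs(basis[k]))
        if m > 0:
            basis[k] = basis[k] / m
    return HRFBasis(lags=lags, basis=basis, theta=th, TR=TR, kind=kind)


def make_convolution_operator(basis: HRFBasis, k: int, Is: int) -> np.ndarray:
    """Materialize the causal Toeplitz convolution matrix H_k (Is x Is).

    ``(H_k s)[t] = sum_{tau >= 0} h_k[tau] * s[t - tau]`` with zero initial
    conditions; the output is truncated to length ``Is``.
    """
    if not 0 <= k < basis.K:
        raise IndexError(f"basis index {k} out of range for K={basis.K}")
    h = basis.basis[k]
    col = np.zeros(Is)
    L = min(h.size, Is)
    col[:L] = h[:L]
    row = np.zeros(Is)
    row[0] = col[0]
    from scipy.linalg import toeplitz

    return toeplitz(col, row)


def convolve(basis: HRFBasis, k: int, s: np.ndarray) -> np.ndarray:
    """Apply H_k to a signal (or each column of a matrix) without
    materializing the Toeplitz matrix."""
    if not 0 <= k < basis.K:
        raise IndexError(f"basis index {k} out of range for K={basis.K}")
    s = np.asarray(s, dtype=float)
    h = basis.basis[k]
    if s.ndim == 1:
        return np.convolve(s, h)[: s.shape[0]]
    from scipy.signal import fftconvolve

    out = fftconvolve(s, h[:, None], axes=0)
    return out[: s.shape[0]]


def roi_hrf(B: np.ndarray, basis: HRFBasis, v: int) -> np.ndarray:
    """ROI-specific HRF curve ``sum_k B[v, k] h_k`` on the basis lag grid."""
    B = np.asarray(B, dtype=float)
    if not 0 <= v < B.shape[0]:
        raise IndexError(f"ROI index {v} out of range for {B.shape[0]} ROIs")
    if B.shape[1] != basis.K:
        raise ValueError(
            f"coefficient matrix has K={B.shape[1]} but basis has K={basis.K}"
        )
    return B[v] @ basis.basis
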