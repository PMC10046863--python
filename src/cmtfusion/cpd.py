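"""Canonical polyadic decomposition (CPD) of the EEG tensor.

The EEG power tensor X (segments x frequencies x channels) is approximated
by a sum of R rank-1 terms ``X ~ sum_r s_r o f_r o c_r``, written
``[[S, F, C]]``.  Each component couples a temporal signature (band-power
over volumes), a spectral signature and a channel topography.  The CPD fit
serves two roles downstream: it initializes the coupled EEG-fMRI
decomposition, and its factors feed the core-consistency diagnostic used
for rank selection.

The solver is alternating least squares (ALS) on the exact Frobenius
objective, with ridge-regularized Gram inverses for degenerate modes.  Any
minimizer of the same objective reaching the stated tolerance is
equivalent for the pipeline's purposes; ALS has a guaranteed monotone cost
trace, which the diagnostics expose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.optimize import linear_sum_assignment

_RIDGE = 1e-12


@dataclass
class CPDFactors:
    """Factor matrices of a three-way CP model (scale carried in S)."""

    S: np.ndarray  # (Is, R) temporal signatures
    F: np.ndarray  # (If, R) spectral signatures
    C: np.ndarray  # (Ic, R) channel signatures

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        ranks = {self.S.shape[1], self.F.shape[1], self.C.shape[1]}
        if len(ranks) != 1:
            raise ValueError(f"inconsistent ranks across factors: {ranks}")

    @property
    def rank(self) -> int:
        return self.S.shape[1]

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.S.shape[0], self.F.shape[0], self.C.shape[0]

    def copy(self) -> "CPDFactors":
        return CPDFactors(self.S.copy(), self.F.copy(), self.C.copy())

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            for name in ("S", "F", "C"):
                f.create_dataset(name, data=getattr(self, name))

    @classmethod
    def from_hdf5(cls, path) -> "CPDFactors":
        with h5py.File(path, "r") as f:
            return cls(f["S"][()], f["F"][()], f["C"][()])


def random_init(dims: tuple[int, int, int], R: int, seed: int | None = None) -> CPDFactors:
    """Standard-normal random starting point, reproducible for fixed seed."""
    if R < 1:
        raise ValueError("R must be >= 1")
    rng = np.random.default_rng(seed)
    Is, If, Ic = dims
    return CPDFactors(
        rng.standard_normal((Is, R)),
        rng.standard_normal((If, R)),
        rng.standard_normal((Ic, R)),
    )


def cpd_reconstruct(factors: CPDFactors) -> np.ndarray:
    """Dense tensor ``sum_r s_r o f_r o c_r``."""
    return np.einsum("tr,fr,cr->tfc", factors.S, factors.F, factors.C, optimize=True)


def factor_match_score(a: CPDFactors, b: CPDFactors) -> float:
    """Permutation-, sign- and scale-invariant similarity of two factor sets.

    Max over component pairings of the mean over components of the product
    across modes of the absolute cosine similarity.  1.0 means identical up
    to the CP indeterminacies; independent random factors score near 0.
    """
    if a.rank != b.rank:
        raise ValueError(f"rank mismatch: {a.rank} vs {b.rank}")
    if a.dims != b.dims:
        raise ValueError(f"dimension mismatch: {a.dims} vs {b.dims}")
    score = np.ones((a.rank, b.rank))
    for Ma, Mb in ((a.S, b.S), (a.F, b.F), (a.C, b.C)):
        na = np.linalg.norm(Ma, axis=0)
        nb = np.linalg.norm(Mb, axis=0)
        denom = np.outer(na, nb)
        cos = np.zeros_like(denom)
        ok = denom > 0
        cos[ok] = np.abs(Ma.T @ Mb)[ok] / denom[ok]
        score *= cos
    rows, cols = linear_sum_assignment(-score)
    return float(score[rows, cols].mean())


@dataclass
class CPDDiagnostics:
    cost_trace: list = field(default_factory=list)  # squared residual per sweep
    n_iter: int = 0
    converged: bool = False
    rel_error: float = np.nan  # ||X - Xhat||_F / ||X||_F


class CPDecomposition:
    """CP model of a third-order tensor; ``fit`` returns :class:`CPDResults`.

    Parameters
    ----------
    tensor : ndarray or object with a ``data`` attribute (e.g. EEGTensor).
    rank : number of components R.
    """

    def __init__(self, tensor, rank: int):
        data = getattr(tensor, "data", tensor)
        self.X = np.asarray(data, dtype=float)
        if self.X.ndim != 3:
            raise ValueError("CPD requires a third-order tensor")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("tensor contains non-finite entries")
        if rank < 1:
            raise ValueError("rank must be >= 1")
        self.rank = rank
        dmax = min(
            self.X.shape[0] * self.X.shape[1],
            self.X.shape[0] * self.X.shape[2],
            self.X.shape[1] * self.X.shape[2],
        )
        if rank > dmax:
            import warnings

            warnings.warn("rank exceeds identifiability guideline", stacklevel=2)

    def fit(
        self,
        init: CPDFactors | None = None,
        max_iter: int = 2000,
        tol: float = 1e-8,
        seed: int | None = None,
    ) -> "CPDResults":
        """Alternating least squares from ``init`` (random if omitted)."""
        X = self.X
        R = self.rank
        if init is None:
            init = random_init(X.shape, R, seed)
        if init.dims != X.shape or init.rank != R:
            raise ValueError("init does not match tensor dims / rank")
        S, F, C = init.S.copy(), init.F.copy(), init.C.copy()
        normX2 = float(np.sum(X * X))
        diag = CPDDiagnostics()
        cost_prev = None
        for it in range(max_iter):
            # mode-wise least squares via MTTKRP and ridge-regularized Grams
            G = (F.T @ F) * (C.T @ C)
            M = np.einsum("tfc,fr,cr->tr", X, F, C, optimize=True)
            S = np.linalg.solve(G + _RIDGE * np.eye(R), M.T).T

            G = (S.T @ S) * (C.T @ C)
            M = np.einsum("tfc,tr,cr->fr", X, S, C, optimize=True)
            F = np.linalg.solve(G + _RIDGE * np.eye(R), M.T).T

            G = (S.T @ S) * (F.T @ F)
            M = np.einsum("tfc,tr,fr->cr", X, S, F, optimize=True)
            C = np.linalg.solve(G + _RIDGE * np.eye(R), M.T).T

            # cost without forming the dense tensor:
            # ||X - Xhat||^2 = ||X||^2 - 2<M, C> + ||Xhat||^2
            GS = (S.T @ S) * (F.T @ F) * (C.T @ C)
            cost = normX2 - 2.0 * float(np.sum(M * C)) + float(np.sum(GS))
            cost = max(cost, 0.0)
            diag.cost_trace.append(cost)
            diag.n_iter = it + 1
            if cost_prev is not None:
                denom = max(cost_prev, 1e-300)
                if abs(cost_prev - cost) / denom < tol:
                    diag.converged = True
                    break
            cost_prev = cost
        factors = CPDFactors(S, F, C)
        resid = X - cpd_reconstruct(factors)
        diag.rel_error = float(
            np.linalg.norm(resid) / max(np.sqrt(normX2), 1e-300)
        )
        return CPDResults(self, factors, diag)


@dataclass
class CPDResults:
    model: CPDecomposition
    factors: CPDFactors
    diagnostics: CPDDiagnostics

    def reconstruct(self) -> np.ndarray:
        return cpd_reconstruct(self.factors)

    def summary(self) -> str:
        d = self.diagnostics
        lines = [
            "CP decomposition results",
            f"  rank:            {self.factors.rank}",
            f"  dims:            {self.factors.dims}",
            f"  sweeps:          {d.n_iter}",
            f"  converged:       {d.converged}",
            f"  rel. error:      {d.rel_error:.3e}",
        ]
        return "\n".join(lines)


def cpd_fit(
    X,
    R: int,
    init: CPDFactors | None = None,
    max_iter: int = 2000,
    tol: float = 1e-8,
    seed: int | None = None,
) -> tuple[CPDFactors, CPDDiagnostics]:
    """Functional wrapper around :class:`CPDecomposition`."""
    res = CPDecomposition(X, R).fit(init=init, max_iter=max_iter, tol=tol, seed=seed)
    return res.factors, res.diagnostics
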