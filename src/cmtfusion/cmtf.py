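"""Coupled matrix-tensor factorization (CMTF) of EEG and fMRI data.

The EEG power tensor X (segments x frequencies x channels) and the BOLD
ROI matrix Y (segments x ROIs) are decomposed jointly into R sources that
share their temporal signatures::

    X ~ [[S, F, C]]
    Y ~ sum_r sum_k (H_k s_r) (B[:, k] * v_r)^T  +  N P^T

where ``H_k`` is causal convolution with the k-th HRF basis function, B
holds ROI-specific HRF coefficients, and the rank-Q term ``N P^T`` absorbs
BOLD structure unrelated to the EEG.  The fit minimizes

    J = beta_x ||X - Xhat||_F^2 + beta_y ||Y - Yhat||_F^2
        + gamma_x ||lambda_x||_1 + gamma_y ||lambda_y||_1

with per-source amplitudes ``lambda_x,r = ||s_r|| ||f_r|| ||c_r||`` and
``lambda_y,r = sum_k ||B[:,k] * v_r||``; the L1 terms discourage spurious
large-amplitude sources.  The nonsmooth norms are smoothed as
``sqrt(. ^2 + eps)`` so a limited-memory quasi-Newton solver applies; the
analytic gradient of every block is supplied to ``scipy.optimize``.

Ensembles of fits from independent CP initializations (default 50) feed
the stability clustering used for model selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import h5py
import numpy as np
from scipy.optimize import minimize

from .cpd import CPDFactors, CPDecomposition, random_init
from .hrf import HRFBasis, make_convolution_operator

logger = logging.getLogger(__name__)

_RIDGE = 1e-8


class OptimizationError(RuntimeError):
    """Raised when the coupled fit diverges."""


@dataclass
class ROITimeSeriesMatrix:
    """BOLD time series per ROI (time points x ROIs)."""

    data: np.ndarray
    roi_labels: list[str] = field(default_factory=list)
    TR: float = 2.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("ROI matrix must be 2-dimensional")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("ROI matrix contains non-finite entries")
        if not self.roi_labels:
            self.roi_labels = [f"ROI{v + 1:03d}" for v in range(self.data.shape[1])]
        if len(self.roi_labels) != self.data.shape[1]:
            raise ValueError("roi label count does not match data")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class CMTFWeights:
    """Cost-function weights.

    By default the whole cost is made dimensionless: the data terms are
    weighted by ``1/||data||_F^2`` and the amplitude penalties are applied
    to amplitudes expressed relative to the data norm (i.e. the effective
    multiplier of ``||lambda_x||_1`` is ``gamma_x / ||X||_F``), so the
    defaults behave comparably across data scales.  Pass explicit
    ``beta_*`` to override; ``scale_free=False`` leaves the gammas raw.
    """

    beta_x: float | None = None
    beta_y: float | None = None
    gamma_x: float = 0.01
    gamma_y: float = 0.01
    scale_free: bool = True
    _is_resolved: bool = False

    def resolved(self, X: np.ndarray, Y: np.ndarray) -> "CMTFWeights":
        if self._is_resolved:
            return self
        nx2 = max(float(np.sum(X * X)), 1e-300)
        ny2 = max(float(np.sum(Y * Y)), 1e-300)
        bx = self.beta_x if self.beta_x is not None else 1.0 / nx2
        by = self.beta_y if self.beta_y is not None else 1.0 / ny2
        gx, gy = self.gamma_x, self.gamma_y
        if self.scale_free:
            gx = gx / np.sqrt(nx2)
            gy = gy / np.sqrt(ny2)
        if min(bx, by, gx, gy) < 0:
            raise ValueError("weights must be nonnegative")
        return CMTFWeights(bx, by, gx, gy, scale_free=self.scale_free,
                           _is_resolved=True)


@dataclass
class CMTFModel:
    """All factor sets of a fitted coupled decomposition."""

    S: np.ndarray  # (Is, R)
    F: np.ndarray  # (If, R)
    C: np.ndarray  # (Ic, R)
    V: np.ndarray  # (Iv, R)
    B: np.ndarray  # (Iv, K)
    N: np.ndarray  # (Is, Q)
    P: np.ndarray  # (Iv, Q)
    v_scale: np.ndarray | None = None  # (R,) coupling amplitudes, default 1
    weights: CMTFWeights = field(default_factory=CMTFWeights)
    basis_kind: str = "canonical+derivatives"

    def __post_init__(self):
        for name in ("S", "F", "C", "V", "B", "N", "P"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        R = self.S.shape[1]
        if not (self.F.shape[1] == self.C.shape[1] == self.V.shape[1] == R):
            raise ValueError("inconsistent R across S, F, C, V")
        if self.N.shape[1] != self.P.shape[1]:
            raise ValueError("inconsistent Q across N, P")
        if self.v_scale is None:
            self.v_scale = np.ones(R)
        self.v_scale = np.asarray(self.v_scale, dtype=float)

    @property
    def rank(self) -> int:
        return self.S.shape[1]

    @property
    def Q(self) -> int:
        return self.N.shape[1]

    @property
    def K(self) -> int:
        return self.B.shape[1]

    def eeg_factors(self) -> CPDFactors:
        return CPDFactors(self.S.copy(), self.F.copy(), self.C.copy())

    def copy(self) -> "CMTFModel":
        return CMTFModel(
            self.S.copy(), self.F.copy(), self.C.copy(), self.V.copy(),
            self.B.copy(), self.N.copy(), self.P.copy(),
            v_scale=self.v_scale.copy(), weights=self.weights,
            basis_kind=self.basis_kind,
        )

    def to_hdf5(self, path) -> None:
        with h5py.File(path, "w") as f:
            for name in ("S", "F", "C", "V", "B", "N", "P", "v_scale"):
                f.create_dataset(name, data=getattr(self, name))
            f.attrs["basis_kind"] = self.basis_kind

    @classmethod
    def from_hdf5(cls, path) -> "CMTFModel":
        with h5py.File(path, "r") as f:
            return cls(
                *(f[name][()] for name in ("S", "F", "C", "V", "B", "N", "P")),
                v_scale=f["v_scale"][()],
                basis_kind=str(f.attrs["basis_kind"]),
            )


def _hrf_matrices(basis: HRFBasis, Is: int) -> list[np.ndarray]:
    return [make_convolution_operator(basis, k, Is) for k in range(basis.K)]


def fmri_forward(model: CMTFModel, basis: HRFBasis,
                 H: list[np.ndarray] | None = None) -> np.ndarray:
    """Predicted BOLD matrix from the coupled and uncoupled terms."""
    Is = model.S.shape[0]
    if H is None:
        H = _hrf_matrices(basis, Is)
    if len(H) != model.K:
        raise ValueError(f"model K={model.K} does not match basis K={len(H)}")
    Vs = model.V * model.v_scale[None, :]
    Yhat = model.N @ model.P.T
    for k in range(model.K):
        Yhat = Yhat + (H[k] @ model.S) @ (model.B[:, k : k + 1] * Vs).T
    return Yhat


def amplitudes(model: CMTFModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-source amplitudes (lambda_x, lambda_y).

    ``lambda_x,r = ||s_r|| ||f_r|| ||c_r||``;
    ``lambda_y,r = sum_k ||B[:, k] * (v_scale_r v_r)||`` (elementwise over
    ROIs).
    """
    lam_x = (
        np.linalg.norm(model.S, axis=0)
        * np.linalg.norm(model.F, axis=0)
        * np.linalg.norm(model.C, axis=0)
    )
    Vs = model.V * model.v_scale[None, :]
    lam_y = np.zeros(model.rank)
    for k in range(model.K):
        lam_y += np.linalg.norm(model.B[:, k : k + 1] * Vs, axis=0)
    return lam_x, lam_y


def cmtf_objective(model: CMTFModel, X: np.ndarray, Y: np.ndarray,
                   basis: HRFBasis, weights: CMTFWeights | None = None) -> float:
    """Value of the coupled cost J at the given model (exact L1 terms)."""
    w = (weights or model.weights).resolved(X, Y)
    Xhat = np.einsum("tr,fr,cr->tfc", model.S, model.F, model.C, optimize=True)
    Yhat = fmri_forward(model, basis)
    lam_x, lam_y = amplitudes(model)
    return float(
        w.beta_x * np.sum((X - Xhat) ** 2)
        + w.beta_y * np.sum((Y - Yhat) ** 2)
        + w.gamma_x * np.sum(np.abs(lam_x))
        + w.gamma_y * np.sum(np.abs(lam_y))
    )


def normalize_model(model: CMTFModel) -> CMTFModel:
    """Canonical form for clustering: F, C, V columns unit-norm.

    The F/C scales are absorbed into S (X reconstruction unchanged); the
    resulting rescaling of the coupled BOLD term is compensated by the
    per-component amplitude ``v_scale``, which also absorbs the V norms, so
    the Y reconstruction is unchanged as well.  Sign convention: the
    largest-magnitude entry of each F column is positive, and likewise for
    each C and V column (compensated in S / v_scale).  Zero columns are
    left untouched and logged.
    """
    m = model.copy()
    R = m.rank
    for r in range(R):
        nf = np.linalg.norm(m.F[:, r])
        nc = np.linalg.norm(m.C[:, r])
        nv = np.linalg.norm(m.V[:, r])
        if nf == 0 or nc == 0 or nv == 0:
            logger.warning("component %d has a zero column; left unnormalized", r)
            continue
        m.F[:, r] /= nf
        m.C[:, r] /= nc
        m.S[:, r] *= nf * nc
        m.V[:, r] /= nv
        m.v_scale[r] *= nv / (nf * nc)
        # sign conventions
        if m.F[np.argmax(np.abs(m.F[:, r])), r] < 0:
            m.F[:, r] *= -1.0
            m.S[:, r] *= -1.0
            m.v_scale[r] *= -1.0
        if m.C[np.argmax(np.abs(m.C[:, r])), r] < 0:
            m.C[:, r] *= -1.0
            m.S[:, r] *= -1.0
            m.v_scale[r] *= -1.0
        if m.V[np.argmax(np.abs(m.V[:, r])), r] < 0:
            m.V[:, r] *= -1.0
            m.v_scale[r] *= -1.0
    return m


@dataclass
class CMTFDiagnostics:
    cost_trace: list = field(default_factory=list)
    n_iter: int = 0
    converged: bool = False
    grad_norm: float = np.nan
    rel_error_x: float = np.nan
    rel_error_y: float = np.nan
    seed: int | None = None
    message: str = ""


class CMTF:
    """Coupled EEG-fMRI decomposition model; ``fit`` returns CMTFResults.

    Parameters
    ----------
    X : EEG power tensor (or EEGTensor), shape (Is, If, Ic).
    Y : BOLD ROI matrix (or ROITimeSeriesMatrix), shape (Is, Iv).
    basis : HRF basis providing the K convolution operators.
    rank : number of shared sources R.
    q : rank of the uncoupled BOLD term.
    weights : cost weights (data terms default to 1/||data||_F^2,
        gamma_x = gamma_y = 0.01).
    smooth_eps : smoothing constant for the L1-of-norms terms.
    """

    def __init__(self, X, Y, basis: HRFBasis, rank: int, q: int = 1,
                 weights: CMTFWeights | None = None, smooth_eps: float = 1e-9):
        self.X = np.asarray(getattr(X, "data", X), dtype=float)
        self.Y = np.asarray(getattr(Y, "data", Y), dtype=float)
        if self.X.ndim != 3 or self.Y.ndim != 2:
            raise ValueError("X must be third-order, Y a matrix")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValueError(
                f"time dimensions differ: X has {self.X.shape[0]}, "
                f"Y has {self.Y.shape[0]}"
            )
        if not (np.all(np.isfinite(self.X)) and np.all(np.isfinite(self.Y))):
            raise ValueError("inputs contain non-finite entries")
        if rank < 1 or q < 0:
            raise ValueError("rank must be >= 1 and q >= 0")
        self.basis = basis
        self.rank = rank
        self.q = q
        self.weights = (weights or CMTFWeights()).resolved(self.X, self.Y)
        self.smooth_eps = smooth_eps
        self.H = _hrf_matrices(basis, self.X.shape[0])
        self._shapes = None

    # ---- parameter vector packing -------------------------------------
    def _pack(self, S, F, C, V, B, N, P) -> np.ndarray:
        mats = (S, F, C, V, B, N, P)
        self._shapes = [m.shape for m in mats]
        return np.concatenate([m.ravel() for m in mats])

    def _unpack(self, theta: np.ndarray):
        out = []
        pos = 0
        for shape in self._shapes:
            n = int(np.prod(shape))
            out.append(theta[pos : pos + n].reshape(shape))
            pos += n
        return out

    # ---- objective and analytic gradient ------------------------------
    def _objective_grad(self, theta: np.ndarray):
        S, F, C, V, B, N, P = self._unpack(theta)
        w, eps = self.weights, self.smooth_eps
        K, R = self.basis.K, self.rank

        Xhat = np.einsum("tr,fr,cr->tfc", S, F, C, optimize=True)
        Rx = Xhat - self.X
        Z = [self.H[k] @ S for k in range(K)]
        W = [B[:, k : k + 1] * V for k in range(K)]
        Yhat = N @ P.T
        for k in range(K):
            Yhat += Z[k] @ W[k].T
        Ry = Yhat - self.Y

        J = w.beta_x * float(np.sum(Rx * Rx)) + w.beta_y * float(np.sum(Ry * Ry))

        ns = np.sqrt(np.sum(S * S, axis=0) + eps)
        nf = np.sqrt(np.sum(F * F, axis=0) + eps)
        nc = np.sqrt(np.sum(C * C, axis=0) + eps)
        lam_x = ns * nf * nc
        J += w.gamma_x * float(np.sum(lam_x))
        nw = [np.sqrt(np.sum(W[k] ** 2, axis=0) + eps) for k in range(K)]
        J += w.gamma_y * float(sum(np.sum(n) for n in nw))

        gS = 2.0 * w.beta_x * np.einsum("tfc,fr,cr->tr", Rx, F, C, optimize=True)
        gF = 2.0 * w.beta_x * np.einsum("tfc,tr,cr->fr", Rx, S, C, optimize=True)
        gC = 2.0 * w.beta_x * np.einsum("tfc,tr,fr->cr", Rx, S, F, optimize=True)
        gV = np.zeros_like(V)
        gB = np.zeros_like(B)
        for k in range(K):
            gZ = 2.0 * w.beta_y * (Ry @ W[k])
            gS += self.H[k].T @ gZ
            gW = 2.0 * w.beta_y * (Ry.T @ Z[k])
            gW += w.gamma_y * W[k] / nw[k][None, :]
            gV += gW * B[:, k : k + 1]
            gB[:, k] = np.sum(gW * V, axis=1)
        gN = 2.0 * w.beta_y * (Ry @ P)
        gP = 2.0 * w.beta_y * (Ry.T @ N)

        gS += w.gamma_x * (nf * nc / ns)[None, :] * S
        gF += w.gamma_x * (ns * nc / nf)[None, :] * F
        gC += w.gamma_x * (ns * nf / nc)[None, :] * C

        grad = np.concatenate(
            [g.ravel() for g in (gS, gF, gC, gV, gB, gN, gP)]
        )
        return J, grad

    # ---- initialization of the fMRI-side factors ----------------------
    def _init_model(self, init: CPDFactors) -> CMTFModel:
        S = init.S.copy()
        R, K, Q = self.rank, self.basis.K, self.q
        Iv = self.Y.shape[1]
        Z1 = self.H[0] @ S
        G = Z1.T @ Z1 + _RIDGE * np.trace(Z1.T @ Z1) / max(R, 1) * np.eye(R)
        V = np.linalg.solve(G, Z1.T @ self.Y).T  # ridge LS of Y on H_1 S
        B = np.zeros((Iv, K))
        B[:, 0] = 1.0
        resid = self.Y - Z1 @ V.T
        if Q > 0:
            U, sv, Vt = np.linalg.svd(resid, full_matrices=False)
            N = U[:, :Q] * sv[:Q]
            P = Vt[:Q].T
        else:
            N = np.zeros((self.Y.shape[0], 0))
            P = np.zeros((Iv, 0))
        return CMTFModel(S, init.F.copy(), init.C.copy(), V, B, N, P,
                         weights=self.weights, basis_kind=self.basis.kind)

    def fit(self, init: CPDFactors | None = None, max_iter: int = 1000,
            tol: float = 1e-8, seed: int | None = None) -> "CMTFResults":
        """Quasi-Newton (L-BFGS) minimization of J from a CP initialization.

        If ``init`` is omitted a random CP init is drawn from ``seed``.
        Stops at ``max_iter`` iterations or when the relative cost update
        falls below ``tol``.
        """
        if init is None:
            init = random_init(self.X.shape, self.rank, seed)
        if init.rank != self.rank:
            raise ValueError("init rank does not match model rank")
        model0 = self._init_model(init)
        theta0 = self._pack(model0.S, model0.F, model0.C, model0.V,
                            model0.B, model0.N, model0.P)
        diag = CMTFDiagnostics(seed=seed)
        J0, g0 = self._objective_grad(theta0)
        diag.cost_trace.append(J0)
        if max_iter == 0:
            diag.grad_norm = float(np.linalg.norm(g0))
            return self._finish(model0, diag)

        def callback(xk):
            Jk, _ = self._objective_grad(xk)
            diag.cost_trace.append(Jk)

        res = minimize(
            self._objective_grad, theta0, jac=True, method="L-BFGS-B",
            callback=callback,
            options={"maxiter": max_iter, "ftol": tol, "gtol": 1e-12,
                     "maxcor": 20},
        )
        if res.fun > 10.0 * J0 + 1e-12:
            raise OptimizationError(
                f"cost diverged: {res.fun:.3e} > 10 x initial {J0:.3e}"
            )
        S, F, C, V, B, N, P = self._unpack(res.x)
        model = CMTFModel(S, F, C, V, B, N, P, weights=self.weights,
                          basis_kind=self.basis.kind)
        diag.n_iter = int(res.nit)
        diag.converged = bool(res.success) or res.status == 0
        diag.message = str(res.message)
        diag.grad_norm = float(np.linalg.norm(res.jac))
        return self._finish(model, diag)

    def _finish(self, model: CMTFModel, diag: CMTFDiagnostics) -> "CMTFResults":
        Xhat = np.einsum("tr,fr,cr->tfc", model.S, model.F, model.C, optimize=True)
        Yhat = fmri_forward(model, self.basis, self.H)
        diag.rel_error_x = float(
            np.linalg.norm(self.X - Xhat) / max(np.linalg.norm(self.X), 1e-300)
        )
        diag.rel_error_y = float(
            np.linalg.norm(self.Y - Yhat) / max(np.linalg.norm(self.Y), 1e-300)
        )
        return CMTFResults(self, model, diag)


@dataclass
class CMTFResults:
    """Fitted coupled decomposition with diagnostics."""

    problem: CMTF
    model: CMTFModel
    diagnostics: CMTFDiagnostics

    @property
    def objective(self) -> float:
        return self.diagnostics.cost_trace[-1] if self.diagnostics.cost_trace else np.nan

    def reconstruct_eeg(self) -> np.ndarray:
        m = self.model
        return np.einsum("tr,fr,cr->tfc", m.S, m.F, m.C, optimize=True)

    def predict_fmri(self) -> np.ndarray:
        return fmri_forward(self.model, self.problem.basis, self.problem.H)

    def amplitudes(self) -> tuple[np.ndarray, np.ndarray]:
        return amplitudes(self.model)

    def normalized(self) -> "CMTFResults":
        return CMTFResults(self.problem, normalize_model(self.model),
                           self.diagnostics)

    def summary(self) -> str:
        d = self.diagnostics
        lam_x, lam_y = self.amplitudes()
        lines = [
            "Coupled matrix-tensor factorization results",
            f"  sources (R):       {self.model.rank}",
            f"  uncoupled rank Q:  {self.model.Q}",
            f"  HRF basis K:       {self.model.K}",
            f"  iterations:        {d.n_iter} (converged={d.converged})",
            f"  final cost J:      {self.objective:.6e}",
            f"  rel. error EEG:    {d.rel_error_x:.4f}",
            f"  rel. error fMRI:   {d.rel_error_y:.4f}",
            "  amplitudes:",
        ]
        for r in range(self.model.rank):
            lines.append(
                f"    source {r + 1}: lambda_x = {lam_x[r]:.4g}, "
                f"lambda_y = {lam_y[r]:.4g}"
            )
        return "\n".join(lines)


def cmtf_fit(X, Y, basis: HRFBasis, R: int, Q: int = 1,
             init: CPDFactors | None = None,
             weights: CMTFWeights | None = None, max_iter: int = 1000,
             tol: float = 1e-8, seed: int | None = None):
    """Functional wrapper: returns (CMTFModel, CMTFDiagnostics)."""
    res = CMTF(X, Y, basis, R, q=Q, weights=weights).fit(
        init=init, max_iter=max_iter, tol=tol, seed=seed
    )
    return res.model, res.diagnostics


def run_ensemble(X, Y, basis: HRFBasis, R: int, Q: int = 1,
                 n_runs: int = 50, weights: CMTFWeights | None = None,
                 seed: int | None = None, cpd_max_iter: int = 500,
                 cpd_tol: float = 1e-8, max_iter: int = 1000,
                 tol: float = 1e-8) -> list[CMTFResults]:
    """Ensemble of coupled fits from independent random CP initializations.

    Each run draws a random init, fits the CP model on X, uses its factors
    to initialize the coupled fit, and normalizes the result.  Failed runs
    are logged and skipped.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    run_seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    problem = CMTF(X, Y, basis, R, q=Q, weights=weights)
    cpd_problem = CPDecomposition(problem.X, R)
    results: list[CMTFResults] = []
    n_failed = 0
    for i, rs in enumerate(run_seeds):
        rs = int(rs)
        try:
            cp = cpd_problem.fit(init=random_init(problem.X.shape, R, rs),
                                 max_iter=cpd_max_iter, tol=cpd_tol)
            res = problem.fit(init=cp.factors, max_iter=max_iter, tol=tol,
                              seed=rs)
            results.append(res.normalized())
        except (OptimizationError, np.linalg.LinAlgError) as exc:
            n_failed += 1
            logger.warning("ensemble run %d (seed %d) failed: %s", i, rs, exc)
    if n_failed:
        logger.warning("%d of %d ensemble runs failed", n_failed, n_runs)
    return results
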