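"""Model selection for the coupled decomposition.

Choosing the number of sources R is the hard part of any CP-type analysis.
Four quantitative indicators are computed per candidate R:

1. **CORCONDIA** (core consistency): how close the least-squares Tucker
   core of the EEG tensor, given the fitted CP factors, is to a
   superdiagonal identity.  100% is ideal CP structure; below 80% flags an
   inappropriate model.
2. **Reproducibility**: components from an ensemble of independently
   initialized fits are clustered on a similarity graph; only clusters
   represented in more than ``min_cardinality`` runs (default 10 of 50)
   count as stable.
3. **Stimulus similarity**: absolute Pearson correlation between a
   temporal signature and the binary stimulus timecourse of the paradigm.
4. **Significance**: a permutation-based statistical non-parametric map
   (SnPM) over ROIs for the spatial signature of the stimulus-related
   component, with familywise error controlled through the max-statistic
   null distribution (circular shifts of the HRF-convolved signature).

``select_best_model`` codifies the gate-then-maximize rule: candidates
must pass the CORCONDIA gate and have a stable best component; among those
the R whose best component correlates most with the stimulus wins (ties to
the smaller R).  The full scoring trace is retained so a human can
override the automatic choice.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .cmtf import CMTFModel, CMTFResults
from .cpd import CPDFactors
from .hrf import HRFBasis, make_convolution_operator
from .synthetic import StimulusTimecourse

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# indicator 1: core consistency

def corcondia(X, factors: CPDFactors, ridge: float = 1e-12) -> float:
    """Core consistency diagnostic, in percent (can be negative).

    Solves the least-squares Tucker core G of the tensor given the three
    factor matrices (via ridge-regularized pseudo-inverses) and returns
    ``100 * (1 - sum((G - I)^2) / R)`` where I is the superdiagonal
    identity core.  Invariant to component permutation and to compensated
    column rescaling, because the pseudo-inverses absorb both.
    """
    X = np.asarray(getattr(X, "data", X), dtype=float)
    if X.shape != factors.dims:
        raise ValueError(f"tensor shape {X.shape} != factor dims {factors.dims}")
    R = factors.rank

    def pinv_ridge(M):
        G = M.T @ M
        scale = np.trace(G) / max(M.shape[1], 1)
        cond = np.linalg.cond(G) if np.all(np.isfinite(G)) else np.inf
        if cond > 1e12:
            logger.warning("rank-deficient factor set; ridge-regularized pinv")
        return np.linalg.solve(G + ridge * max(scale, 1.0) * np.eye(M.shape[1]), M.T)

    As = pinv_ridge(factors.S)
    Af = pinv_ridge(factors.F)
    Ac = pinv_ridge(factors.C)
    G = np.einsum("it,jf,kc,tfc->ijk", As, Af, Ac, X, optimize=True)
    ident = np.zeros((R, R, R))
    for r in range(R):
        ident[r, r, r] = 1.0
    return float(100.0 * (1.0 - np.sum((G - ident) ** 2) / R))


# ---------------------------------------------------------------------------
# indicator 2: reproducibility via graph clustering

@dataclass
class ComponentSignatures:
    """One component's signatures across the available modes."""

    s: np.ndarray
    f: np.ndarray
    c: np.ndarray
    v: np.ndarray | None = None

    def modes(self):
        out = [self.s, self.f, self.c]
        if self.v is not None:
            out.append(self.v)
        return out


def component_similarity(a: ComponentSignatures, b: ComponentSignatures) -> float:
    """Product over modes of absolute cosine similarity (in [0, 1])."""
    am, bm = a.modes(), b.modes()
    if len(am) != len(bm):
        raise ValueError("components expose different mode sets")
    sim = 1.0
    for x, y in zip(am, bm):
        if x.shape != y.shape:
            raise ValueError("mode dimension mismatch")
        nx_, ny = np.linalg.norm(x), np.linalg.norm(y)
        if nx_ == 0 or ny == 0:
            return 0.0
        sim *= abs(float(np.dot(x, y))) / (nx_ * ny)
    return sim


@dataclass
class ComponentCluster:
    """A connected cluster of mutually similar ensemble components."""

    members: list  # of (run index, component index)
    centroid: tuple  # member maximizing summed within-cluster similarity
    cardinality: int  # number of distinct runs represented

    def __post_init__(self):
        if self.centroid not in self.members:
            raise ValueError("centroid must be a cluster member")


def _component_of(model: CMTFModel, j: int) -> ComponentSignatures:
    return ComponentSignatures(
        s=model.S[:, j], f=model.F[:, j], c=model.C[:, j], v=model.V[:, j]
    )


def graph_cluster(ensemble, threshold: float = 0.9) -> list[ComponentCluster]:
    """Cluster every component of every run by thresholded similarity.

    Nodes are (run, component) pairs; edges connect pairs with similarity
    >= threshold; clusters are the connected components of that graph.
    The centroid is the node with maximal summed similarity to the other
    members; cardinality counts distinct runs.  Clusters are returned
    sorted by cardinality (descending), then by size.
    """
    if not ensemble:
        raise ValueError("ensemble is empty")
    models = [getattr(r, "model", r) for r in ensemble]
    nodes = [(i, j) for i, m in enumerate(models) for j in range(m.rank)]
    sigs = {(i, j): _component_of(models[i], j) for i, j in nodes}
    g = nx.Graph()
    g.add_nodes_from(nodes)
    sim = {}
    for a in range(len(nodes)):
        for b in range(a + 1, len(nodes)):
            u, v = nodes[a], nodes[b]
            s = component_similarity(sigs[u], sigs[v])
            sim[(u, v)] = sim[(v, u)] = s
            if s >= threshold:
                g.add_edge(u, v)
    clusters = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        if len(members) == 1:
            centroid = members[0]
        else:
            totals = {
                u: sum(sim[(u, v)] for v in members if v != u) for u in members
            }
            centroid = max(members, key=lambda u: (totals[u], u))
        cardinality = len({i for i, _ in members})
        clusters.append(ComponentCluster(members, centroid, cardinality))
    clusters.sort(key=lambda c: (-c.cardinality, -len(c.members), c.members[0]))
    return clusters


def reproducibility_filter(clusters: list[ComponentCluster],
                           min_cardinality: int = 10) -> list[ComponentCluster]:
    """Retain clusters represented in strictly more runs than the cutoff."""
    if min_cardinality < 1:
        raise ValueError("min_cardinality must be >= 1")
    return [c for c in clusters if c.cardinality > min_cardinality]


# ---------------------------------------------------------------------------
# indicator 3: similarity to the stimulus timecourse

def stimulus_similarity(s: np.ndarray, stim) -> float:
    """Absolute Pearson correlation of a temporal signature with the
    stimulus vector (absolute because factor signs are indeterminate)."""
    s = np.asarray(s, dtype=float)
    x = np.asarray(getattr(stim, "values", stim), dtype=float)
    if s.shape != x.shape:
        raise ValueError(f"length mismatch: {s.shape} vs {x.shape}")
    if np.ptp(s) == 0 or np.ptp(x) == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(abs(np.corrcoef(s, x)[0, 1]))


# ---------------------------------------------------------------------------
# indicator 4: SnPM significance of the spatial signature

@dataclass
class SnPMResult:
    stat: np.ndarray          # per-ROI |t| statistic
    p_values: np.ndarray      # permutation FWE-corrected p per ROI
    threshold: float          # FWE statistic threshold at level alpha
    significant: np.ndarray   # boolean mask over ROIs
    max_stat: float
    alpha: float
    n_perm: int


def _abs_t_all_rois(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """|t| of the slope of each ROI's series regressed on x (with
    intercept), computed via the correlation identity."""
    n = x.size
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=0, keepdims=True)
    sx = np.linalg.norm(xc)
    sy = np.linalg.norm(Yc, axis=0)
    r = np.zeros(Y.shape[1])
    ok = sy > 0
    r[ok] = (xc @ Yc[:, ok]) / (sx * sy[ok])
    r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    return np.abs(r) * np.sqrt((n - 2) / (1.0 - r**2))


def snpm_significance(model: CMTFModel, Y, basis: HRFBasis, r: int,
                      alpha: float = 0.05, n_perm: int = 999,
                      seed: int | None = None) -> SnPMResult:
    """Permutation max-statistic test of which ROIs follow source r.

    The regressor is the canonical-HRF-convolved temporal signature of the
    component; the null distribution is generated by circular shifts of
    that regressor, taking the maximum |t| over ROIs per shift, which
    controls the familywise error rate at ``alpha`` across ROIs.
    """
    Y = np.asarray(getattr(Y, "data", Y), dtype=float)
    if not 0 <= r < model.rank:
        raise IndexError(f"component {r} out of range for R={model.rank}")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99 for a meaningful threshold")
    if not 0 < alpha <= 1:
        raise ValueError("alpha must lie in (0, 1]")
    Is = Y.shape[0]
    if np.ptp(model.S[:, r]) == 0:
        raise ValueError("degenerate (constant) temporal signature")
    H1 = make_convolution_operator(basis, 0, Is)
    x = H1 @ model.S[:, r]
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) regressor after convolution")
    obs = _abs_t_all_rois(x, Y)
    rng = np.random.default_rng(seed)
    shifts = rng.integers(1, Is, size=n_perm)
    null_max = np.empty(n_perm)
    for b, sh in enumerate(shifts):
        null_max[b] = _abs_t_all_rois(np.roll(x, int(sh)), Y).max()
    # p_v = (1 + #{null_max >= T_v}) / (n_perm + 1); FWE-exact under the
    # circular-shift null
    exceed = (null_max[None, :] >= obs[:, None]).sum(axis=1)
    p_values = (1.0 + exceed) / (n_perm + 1.0)
    m = int(np.floor(alpha * (n_perm + 1)))
    if m >= 1:
        threshold = float(np.sort(null_max)[::-1][min(m, n_perm) - 1])
        if m > n_perm:
            threshold = -np.inf
    else:
        threshold = np.inf
    significant = p_values <= alpha
    return SnPMResult(stat=obs, p_values=p_values, threshold=threshold,
                      significant=significant, max_stat=float(obs.max()),
                      alpha=alpha, n_perm=n_perm)


# ---------------------------------------------------------------------------
# candidate evaluation and the selection rule

@dataclass
class CandidateReport:
    """Per-R record of the four indicators."""

    rank: int
    corcondia: float
    cluster_cardinalities: list[int]
    retained_cardinalities: list[int]
    best_component: tuple | None      # (run, component) centroid
    best_similarity: float
    best_component_retained: bool
    snpm: SnPMResult | None = None
    n_runs: int = 0


def evaluate_candidate(R: int, ensemble: list[CMTFResults], X, Y,
                       basis: HRFBasis, stim: StimulusTimecourse,
                       threshold: float = 0.9, min_cardinality: int = 10,
                       alpha: float = 0.05, n_perm: int = 999,
                       seed: int | None = None,
                       compute_snpm: bool = True) -> CandidateReport:
    """Compute all four indicators for one candidate R from its ensemble.

    The representative (centroid) component with the highest stimulus
    similarity defines the candidate's score; CORCONDIA and the SnPM are
    computed on the run containing that component.
    """
    if not ensemble:
        raise ValueError("ensemble is empty")
    models = [getattr(res, "model", res) for res in ensemble]
    clusters = graph_cluster(ensemble, threshold=threshold)
    retained = reproducibility_filter(clusters, min_cardinality=min_cardinality)
    best = None
    best_sim = -np.inf
    best_retained = False
    for cluster in clusters:
        i, j = cluster.centroid
        try:
            sim = stimulus_similarity(models[i].S[:, j], stim)
        except ValueError:
            continue
        if sim > best_sim:
            best, best_sim = (i, j), sim
            best_retained = cluster in retained
    cc = np.nan
    snpm = None
    if best is not None:
        i, j = best
        cc = corcondia(X, models[i].eeg_factors())
        if compute_snpm:
            snpm = snpm_significance(models[i], Y, basis, j, alpha=alpha,
                                     n_perm=n_perm, seed=seed)
    return CandidateReport(
        rank=R, corcondia=cc,
        cluster_cardinalities=[c.cardinality for c in clusters],
        retained_cardinalities=[c.cardinality for c in retained],
        best_component=best,
        best_similarity=float(best_sim) if np.isfinite(best_sim) else np.nan,
        best_component_retained=best_retained,
        snpm=snpm, n_runs=len(ensemble),
    )


@dataclass
class ModelSelectionReport:
    """Outcome of the gate-then-maximize selection across candidate R."""

    candidates: list[CandidateReport]
    chosen_R: int
    chosen_component: tuple | None
    no_eligible_model: bool
    trace: list = field(default_factory=list)
    corcondia_gate: float = 80.0

    def to_dict(self) -> dict:
        return {
            "chosen_R": self.chosen_R,
            "chosen_component": list(self.chosen_component)
            if self.chosen_component else None,
            "no_eligible_model": self.no_eligible_model,
            "corcondia_gate": self.corcondia_gate,
            "candidates": [
                {
                    "R": c.rank,
                    "corcondia": None if np.isnan(c.corcondia) else c.corcondia,
                    "cluster_cardinalities": c.cluster_cardinalities,
                    "retained_cardinalities": c.retained_cardinalities,
                    "best_component": list(c.best_component)
                    if c.best_component else None,
                    "best_similarity": None
                    if np.isnan(c.best_similarity) else c.best_similarity,
                    "best_component_retained": c.best_component_retained,
                    "n_runs": c.n_runs,
                    "snpm_max_stat": c.snpm.max_stat if c.snpm else None,
                    "snpm_threshold": c.snpm.threshold if c.snpm else None,
                    "significant_rois": np.flatnonzero(c.snpm.significant).tolist()
                    if c.snpm else None,
                }
                for c in self.candidates
            ],
            "trace": self.trace,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as f:
            json.dump(self.to_dict(), f, indent=2)

    def summary(self) -> str:
        lines = ["Model selection report",
                 f"  chosen R: {self.chosen_R}"
                 + (" (no eligible model; least-bad candidate)"
                    if self.no_eligible_model else "")]
        header = (f"  {'R':>3} {'CORCONDIA':>10} {'stability':>10} "
                  f"{'stim-sim':>9} {'eligible':>9}")
        lines.append(header)
        for c, t in zip(self.candidates, self.trace):
            card = max(c.retained_cardinalities, default=0)
            cc = f"{c.corcondia:.1f}" if np.isfinite(c.corcondia) else "n/a"
            sim = (f"{c.best_similarity:.3f}"
                   if np.isfinite(c.best_similarity) else "n/a")
            lines.append(f"  {c.rank:>3} {cc:>10} {card:>10} {sim:>9} "
                         f"{str(t['eligible']):>9}")
        return "\n".join(lines)


def select_best_model(candidates: list[CandidateReport],
                      corcondia_gate: float = 80.0) -> ModelSelectionReport:
    """Deterministic gate-then-maximize choice of R.

    A candidate is eligible when CORCONDIA >= the gate (default 80%) and
    its best-similarity component belongs to a retained (stable) cluster.
    Among eligible candidates the highest stimulus similarity wins; ties
    go to the smaller R.  With no eligible candidate the least-bad one
    (highest similarity overall) is returned flagged ``no_eligible_model``.
    """
    if not candidates:
        raise ValueError("no candidate reports given")
    trace = []
    eligible = []
    for c in candidates:
        ok_cc = np.isfinite(c.corcondia) and c.corcondia >= corcondia_gate
        ok_rep = c.best_component_retained
        entry = {
            "R": c.rank,
            "corcondia": None if np.isnan(c.corcondia) else c.corcondia,
            "corcondia_pass": bool(ok_cc),
            "reproducibility_pass": bool(ok_rep),
            "best_similarity": None
            if np.isnan(c.best_similarity) else c.best_similarity,
            "eligible": bool(ok_cc and ok_rep),
        }
        trace.append(entry)
        if ok_cc and ok_rep:
            eligible.append(c)
    pool = eligible
    flagged = False
    if not pool:
        flagged = True
        pool = [c for c in candidates if np.isfinite(c.best_similarity)]
        if not pool:
            pool = candidates
    chosen = max(pool, key=lambda c: (
        c.best_similarity if np.isfinite(c.best_similarity) else -np.inf,
        -c.rank,
    ))
    return ModelSelectionReport(
        candidates=candidates, chosen_R=chosen.rank,
        chosen_component=chosen.best_component,
        no_eligible_model=flagged, trace=trace,
        corcondia_gate=corcondia_gate,
    )
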