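"""End-to-end pipeline: simulate -> tensorize -> fit -> select -> report.

Each stage reads/writes files in a run directory, records content hashes
in a manifest, and is skipped on re-run when its inputs are unchanged, so
a pipeline run is reproducible and resumable.  Configuration is a nested
dict (typically loaded from YAML); :func:`default_config` documents every
knob with a value small enough for a quick desk run — the study-scale
settings (560 volumes, 64 channels, 58 bins, 90 ROIs, 50-run ensembles)
are commented inline.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic as syn
from .cmtf import CMTFResults, CMTFWeights, run_ensemble
from .hrf import build_hrf_basis
from .selection import evaluate_candidate, select_best_model
from .tensorize import EEGTensor, build_eeg_tensor, default_bin_edges

logger = logging.getLogger(__name__)

STAGES = ("simulate", "tensorize", "fit", "select", "report")


def default_config() -> dict:
    """A complete, self-consistent configuration for a synthetic run.

    Scaled for a quick single-CPU run; the study-scale values appear in
    comments next to each entry.
    """
    return {
        "seed": 7,
        "simulate": {
            "n_trials": 20,          # study: 80 (-> 560 volumes)
            "TR": 2.0,
            "fs": 250.0,
            "condition": "both",
            "p_win": 0.5,
            "R": 2,
            "K": 2,                  # study basis: canonical + derivatives
            "Q": 1,
            "n_channels": 16,        # study: 64
            "n_rois": 30,            # study: 90 AAL ROIs
            "snr_db_eeg": 20.0,
            "snr_db_fmri": 20.0,
        },
        "tensorize": {
            "fmin": 1.0,
            "fmax": 30.0,
            "bin_width": 0.5,        # 58 bins over [1, 30) Hz
            "time_bandwidth": 2.0,
            "n_tapers": 3,
        },
        "hrf": {
            "kind": "canonical+derivatives",
            "K": 2,
            "duration": 32.0,
        },
        "fit": {
            "r_grid": [1, 2, 3],
            "q": 1,
            "n_runs": 12,            # study: 50
            "gamma_x": 0.01,
            "gamma_y": 0.01,
            "cpd_max_iter": 200,
            "max_iter": 400,         # study: 1000
            "tol": 1e-8,
        },
        "select": {
            "threshold": 0.9,
            "min_cardinality": 2,    # study: 10 (of 50 runs)
            "alpha": 0.05,
            "n_perm": 199,           # study-style: 999
        },
    }


def load_config(path) -> dict:
    with open(path) as f:
        user = yaml.safe_load(f) or {}
    cfg = default_config()
    for key, val in user.items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = {"stages": {}, "outputs": {}, "cache_hits": []}
        if path.exists():
            self.data = json.loads(path.read_text())
            self.data["cache_hits"] = []

    def stage_fresh(self, stage: str, input_hash: str) -> bool:
        rec = self.data["stages"].get(stage)
        if rec is None or rec["input_hash"] != input_hash:
            return False
        return all(Path(p).exists() for p in rec["outputs"])

    def record(self, stage: str, input_hash: str, outputs: list[Path]):
        self.data["stages"][stage] = {
            "input_hash": input_hash,
            "outputs": [str(p) for p in outputs],
        }
        for p in outputs:
            self.data["outputs"][str(p)] = _hash_file(Path(p))

    def save(self, config: dict, version: str):
        self.data["config"] = config
        self.data["version"] = version
        self.path.write_text(json.dumps(self.data, indent=2, default=str))


def run_pipeline(config: dict, out_dir, force: bool = False) -> Path:
    """Execute every stage into ``out_dir``; unchanged stages are skipped.

    Returns the run directory.  On stage failure an exception naming the
    stage propagates and earlier outputs are preserved.
    """
    from . import __version__

    cfg = copy.deepcopy(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")
    state: dict = {}
    for stage in STAGES:
        input_hash = _hash_obj({"config": cfg, "stage": stage})
        if not force and manifest.stage_fresh(stage, input_hash):
            manifest.data["cache_hits"].append(stage)
            logger.info("stage %s: cached, skipping", stage)
            _load_stage_outputs(stage, cfg, out, state)
            continue
        logger.info("stage %s: running", stage)
        try:
            outputs = _run_stage(stage, cfg, out, state)
        except Exception as exc:
            manifest.save(cfg, __version__)
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest.record(stage, input_hash, outputs)
    manifest.save(cfg, __version__)
    return out


def _sim_dims(cfg: dict) -> tuple[int, int, int, int]:
    sim = cfg["simulate"]
    tz = cfg["tensorize"]
    n_vol = int(round(sim["n_trials"] * 14.0 / sim["TR"]))
    n_bins = int(round((tz["fmax"] - tz["fmin"]) / tz["bin_width"]))
    return n_vol, n_bins, sim["n_channels"], sim["n_rois"]


def _run_stage(stage: str, cfg: dict, out: Path, state: dict) -> list[Path]:
    if stage == "simulate":
        return _stage_simulate(cfg, out, state)
    if stage == "tensorize":
        return _stage_tensorize(cfg, out, state)
    if stage == "fit":
        return _stage_fit(cfg, out, state)
    if stage == "select":
        return _stage_select(cfg, out, state)
    if stage == "report":
        return _stage_report(cfg, out, state)
    raise ValueError(f"unknown stage {stage!r}")


def _stage_simulate(cfg: dict, out: Path, state: dict) -> list[Path]:
    sim = cfg["simulate"]
    seed = cfg["seed"]
    Is, If, Ic, Iv = _sim_dims(cfg)
    stim = syn.generate_stimulus_timecourse(
        n_trials=sim["n_trials"], TR=sim["TR"], condition=sim["condition"],
        p_win=sim["p_win"], seed=seed,
    )
    gt = syn.generate_ground_truth(
        R=sim["R"], K=sim["K"], Q=sim["Q"], dims=(Is, If, Ic, Iv),
        stimulus=stim, seed=seed,
        freq_range=(cfg["tensorize"]["fmin"], cfg["tensorize"]["fmax"]),
    )
    raw = syn.synthesize_raw_eeg(gt, fs=sim["fs"], TR=sim["TR"],
                                 snr_db=sim["snr_db_eeg"], seed=seed + 1)
    basis = build_hrf_basis(kind=cfg["hrf"]["kind"], K=sim["K"], TR=sim["TR"],
                            duration=cfg["hrf"]["duration"])
    Y = syn.assemble_fmri_matrix(gt, basis, snr_db=sim["snr_db_fmri"],
                                 seed=seed + 2)
    paths = [out / "ground_truth.h5", out / "eeg.h5", out / "Y.tsv",
             out / "events.tsv"]
    gt.to_hdf5(paths[0])
    syn.write_eeg_hdf5(raw, paths[1], fs=sim["fs"], TR=sim["TR"])
    syn.write_roi_tsv(Y, paths[2])
    syn.write_events_tsv(stim, paths[3])
    state.update(stim=stim, gt=gt, raw=raw, Y=Y, basis=basis)
    return paths


def _stage_tensorize(cfg: dict, out: Path, state: dict) -> list[Path]:
    sim, tz = cfg["simulate"], cfg["tensorize"]
    if "raw" not in state:
        state["raw"], _, _, _ = syn.read_eeg_hdf5(out / "eeg.h5")
    Is = _sim_dims(cfg)[0]
    edges = default_bin_edges(tz["fmin"], tz["fmax"], tz["bin_width"])
    X = build_eeg_tensor(state["raw"], fs=sim["fs"], TR=sim["TR"],
                         n_volumes=Is, edges=edges,
                         time_bandwidth=tz["time_bandwidth"],
                         n_tapers=tz["n_tapers"])
    X.to_hdf5(out / "X.h5")
    state["X"] = X
    return [out / "X.h5"]


def _ensure_inputs(cfg: dict, out: Path, state: dict):
    if "X" not in state:
        state["X"] = EEGTensor.from_hdf5(out / "X.h5")
    if "Y" not in state:
        state["Y"], _ = syn.read_roi_tsv(out / "Y.tsv")
    if "basis" not in state:
        state["basis"] = build_hrf_basis(
            kind=cfg["hrf"]["kind"], K=cfg["hrf"]["K"], TR=cfg["simulate"]["TR"],
            duration=cfg["hrf"]["duration"])
    if "stim" not in state:
        state["stim"] = syn.read_events_tsv(
            out / "events.tsv", n_volumes=_sim_dims(cfg)[0],
            TR=cfg["simulate"]["TR"], condition=cfg["simulate"]["condition"])


def _stage_fit(cfg: dict, out: Path, state: dict) -> list[Path]:
    _ensure_inputs(cfg, out, state)
    fit = cfg["fit"]
    weights = CMTFWeights(gamma_x=fit["gamma_x"], gamma_y=fit["gamma_y"])
    models_dir = out / "models"
    models_dir.mkdir(exist_ok=True)
    outputs = []
    ensembles = {}
    for R in fit["r_grid"]:
        ensemble = run_ensemble(
            state["X"], state["Y"], state["basis"], R, Q=fit["q"],
            n_runs=fit["n_runs"], weights=weights,
            seed=cfg["seed"] * 1000 + R,
            cpd_max_iter=fit["cpd_max_iter"], max_iter=fit["max_iter"],
            tol=fit["tol"],
        )
        ensembles[R] = ensemble
        diag_rows = []
        for i, res in enumerate(ensemble):
            path = models_dir / f"R{R}_run{i:02d}.h5"
            res.model.to_hdf5(path)
            outputs.append(path)
            d = res.diagnostics
            diag_rows.append({
                "run": i, "seed": d.seed, "n_iter": d.n_iter,
                "converged": d.converged, "cost": res.objective,
                "rel_error_x": d.rel_error_x, "rel_error_y": d.rel_error_y,
            })
        dpath = models_dir / f"R{R}_diagnostics.json"
        dpath.write_text(json.dumps(diag_rows, indent=2, default=str))
        outputs.append(dpath)
    state["ensembles"] = ensembles
    return outputs


def _stage_select(cfg: dict, out: Path, state: dict) -> list[Path]:
    _ensure_inputs(cfg, out, state)
    if "ensembles" not in state:
        state["ensembles"] = _load_ensembles(cfg, out)
    sel = cfg["select"]
    candidates = []
    for R, ensemble in sorted(state["ensembles"].items()):
        if not ensemble:
            continue
        candidates.append(evaluate_candidate(
            R, ensemble, state["X"], state["Y"], state["basis"], state["stim"],
            threshold=sel["threshold"], min_cardinality=sel["min_cardinality"],
            alpha=sel["alpha"], n_perm=sel["n_perm"], seed=cfg["seed"],
        ))
    report = select_best_model(candidates)
    report.to_json(out / "report.json")
    state["selection"] = report
    # significant-ROI table for the chosen component
    chosen = next(c for c in candidates if c.rank == report.chosen_R)
    rows = []
    if chosen.snpm is not None:
        for v in np.flatnonzero(chosen.snpm.significant):
            rows.append({"roi": f"ROI{v + 1:03d}", "stat": chosen.snpm.stat[v],
                         "p_fwe": chosen.snpm.p_values[v]})
    pd.DataFrame(rows, columns=["roi", "stat", "p_fwe"]).to_csv(
        out / "significant_rois.tsv", sep="\t", index=False)
    return [out / "report.json", out / "significant_rois.tsv"]


def _stage_report(cfg: dict, out: Path, state: dict) -> list[Path]:
    _ensure_inputs(cfg, out, state)
    if "ensembles" not in state:
        state["ensembles"] = _load_ensembles(cfg, out)
    if "selection" not in state:
        from .selection import ModelSelectionReport  # noqa: F401

        raise RuntimeError("select stage must run before report")
    report = state["selection"]
    run_i, _ = report.chosen_component or (0, 0)
    model = state["ensembles"][report.chosen_R][run_i].model
    return write_report(report, model, out, X=state["X"])


def write_report(selection, model, out_dir, X=None, plots: bool = False) -> list[Path]:
    """Emit per-component signature TSVs, the indicator table, and
    optionally simple matplotlib figures."""
    out = Path(out_dir)
    comp_dir = out / "components"
    comp_dir.mkdir(exist_ok=True)
    outputs = []
    names = {"temporal": model.S, "spectral": model.F,
             "channel": model.C, "roi": model.V}
    for r in range(model.rank):
        for name, M in names.items():
            p = comp_dir / f"component{r + 1}_{name}.tsv"
            pd.DataFrame({"index": np.arange(M.shape[0]),
                          "value": M[:, r]}).to_csv(p, sep="\t", index=False)
            outputs.append(p)
    table = out / "indicators.tsv"
    rows = []
    for c in selection.candidates:
        rows.append({
            "R": c.rank,
            "corcondia": c.corcondia,
            "max_cardinality": max(c.retained_cardinalities, default=0),
            "stimulus_similarity": c.best_similarity,
            "snpm_max_stat": c.snpm.max_stat if c.snpm else np.nan,
        })
    pd.DataFrame(rows).to_csv(table, sep="\t", index=False)
    outputs.append(table)
    if plots:
        outputs.extend(_plot_components(model, out))
    return outputs


def _plot_components(model, out: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(model.rank, 4, figsize=(14, 2.5 * model.rank),
                             squeeze=False)
    titles = ("temporal", "spectral", "channel", "ROI")
    mats = (model.S, model.F, model.C, model.V)
    for r in range(model.rank):
        for ax, title, M in zip(axes[r], titles, mats):
            if title in ("channel", "ROI"):
                ax.bar(np.arange(M.shape[0]), M[:, r])
            else:
                ax.plot(M[:, r])
            if r == 0:
                ax.set_title(title)
    fig.tight_layout()
    p = out / "components.png"
    fig.savefig(p, dpi=100)
    plt.close(fig)
    return [p]


def _load_ensembles(cfg: dict, out: Path) -> dict:
    from .cmtf import CMTFModel

    models_dir = out / "models"
    ensembles: dict = {}
    for R in cfg["fit"]["r_grid"]:
        runs = sorted(models_dir.glob(f"R{R}_run*.h5"))
        ens = []
        for p in runs:
            ens.append(_LoadedResult(CMTFModel.from_hdf5(p)))
        ensembles[R] = ens
    return ensembles


class _LoadedResult:
    """Minimal stand-in for CMTFResults when models are reloaded from disk."""

    def __init__(self, model):
        self.model = model


def _load_stage_outputs(stage: str, cfg: dict, out: Path, state: dict):
    """Repopulate in-memory state for a cached stage."""
    if stage == "simulate":
        state["raw"], _, _, _ = syn.read_eeg_hdf5(out / "eeg.h5")
        state["Y"], _ = syn.read_roi_tsv(out / "Y.tsv")
    elif stage == "tensorize":
        state["X"] = EEGTensor.from_hdf5(out / "X.h5")
    elif stage == "fit":
        _ensure_inputs(cfg, out, state)
        state["ensembles"] = _load_ensembles(cfg, out)
    elif stage == "select":
        _ensure_inputs(cfg, out, state)
        if "ensembles" not in state:
            state["ensembles"] = _load_ensembles(cfg, out)
        sel = cfg["select"]
        candidates = []
        for R, ensemble in sorted(state["ensembles"].items()):
            if not ensemble:
                continue
            candidates.append(evaluate_candidate(
                R, ensemble, state["X"], state["Y"], state["basis"],
                state["stim"], threshold=sel["threshold"],
                min_cardinality=sel["min_cardinality"], alpha=sel["alpha"],
                n_perm=sel["n_perm"], seed=cfg["seed"],
            ))
        state["selection"] = select_best_model(candidates)
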