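# cmtfusion

Coupled matrix–tensor factorization (CMTF) for simultaneous EEG–fMRI
source fusion.

## The problem

EEG and fMRI see the same neural events through very different windows:
EEG has millisecond temporal resolution but poor spatial localization,
while BOLD fMRI localizes well but is slow and smeared by hemodynamics.
In event-related paradigms (the motivating case is a win/lose gambling
task: 80 trials, TR = 2 s, 560 volumes, 64-channel EEG at 250 Hz, 90 AAL
ROIs), a symmetric fusion of the two recordings can separate latent
sources that neither modality resolves alone.

`cmtfusion` implements that fusion as a coupled decomposition:

* the EEG is tensorized into a third-order power tensor
  **X** ∈ ℝ^(Is×If×Ic) (TR-length segments × 0.5 Hz frequency bins ×
  channels) via Thomson multitaper spectrograms;
* the fMRI is the ROI time-series matrix **Y** ∈ ℝ^(Is×Iv);
* both are decomposed jointly into R sources that share temporal
  signatures s_r:

```
X ≈ Σ_r  s_r ∘ f_r ∘ c_r                      (CP model)
Y ≈ Σ_r Σ_k (H_k s_r)(b_k ⊙ v_r)ᵀ + N Pᵀ      (HRF-coupled + uncoupled)
```

Here H_k is causal convolution with the k-th canonical HRF basis function
(double-gamma + temporal + dispersion derivatives), B = [b_1 … b_K] holds
ROI-specific HRF coefficients, v_r is a spatial ROI map, and the rank-Q
term N Pᵀ absorbs BOLD structure with no EEG counterpart.  The fit
minimizes

```
J = βx‖X − X̂‖²F + βy‖Y − Ŷ‖²F + γx‖λx‖₁ + γy‖λy‖₁
```

with per-source amplitudes λx,r = ‖s_r‖‖f_r‖‖c_r‖ and
λy,r = Σ_k ‖b_k ⊙ v_r‖, using an L-BFGS quasi-Newton solver with analytic
gradients, initialized from canonical polyadic decompositions (CPD) of X.

Model selection over candidate R uses four indicators computed on 50-run
ensembles: CORCONDIA core consistency (gate at 80%), reproducibility
(graph-structured clustering of components; clusters present in > 10 runs
retained), similarity of temporal signatures to the binary stimulus
timecourse, and permutation-based SnPM significance of the ROI maps with
familywise-error control via the max-statistic null.

Because real simultaneous recordings of this kind are not publicly
shareable, the package ships a first-class synthetic-data module that
generates ground-truth sources, raw EEG, coupled BOLD series and the
gambling-paradigm stimulus timecourse, so the whole pipeline is testable
end to end.

## Who it is for

Researchers in multimodal neuroimaging who want a reproducible,
scriptable CMTF pipeline (library + CLI) operating on preprocessed
inputs: segmented multichannel EEG, ROI-averaged BOLD series (TSV), and a
stimulus event table (TSV).

## Worked example

```python
import numpy as np
import cmtfusion as cf

# 20-trial paradigm -> 140 volumes at TR = 2 s
stim = cf.generate_stimulus_timecourse(n_trials=20, TR=2.0,
                                       condition="both", seed=7)
basis = cf.build_hrf_basis(K=2, TR=2.0)
truth = cf.generate_ground_truth(R=2, K=2, Q=1, dims=(140, 20, 16, 30),
                                 stimulus=stim, seed=7)
X = cf.assemble_eeg_tensor(truth, snr_db=20.0, seed=8)
Y = cf.assemble_fmri_matrix(truth, basis, snr_db=20.0, seed=9)

cp = cf.CPDecomposition(X, rank=2).fit(seed=0, max_iter=300)
res = cf.CMTF(X, Y, basis, rank=2, q=1).fit(init=cp.factors, max_iter=500)
print(res.summary())

sim = [cf.stimulus_similarity(res.model.S[:, r], stim) for r in range(2)]
print("stimulus similarity per component:", np.round(sim, 3))
print("CORCONDIA:", round(cf.corcondia(X, res.model.eeg_factors()), 2))
snpm = cf.snpm_significance(res.model, Y, basis, int(np.argmax(sim)),
                            alpha=0.05, n_perm=999, seed=10)
print("significant ROIs:", np.flatnonzero(snpm.significant))
```

Output:

```
Coupled matrix-tensor factorization results
  sources (R):       2
  uncoupled rank Q:  1
  HRF basis K:       2
  iterations:        500 (converged=False)
  final cost J:      3.304485e-02
  rel. error EEG:    0.0998
  rel. error fMRI:   0.0956
  amplitudes:
    source 1: lambda_x = 256.8, lambda_y = 2.414
    source 2: lambda_x = 158.3, lambda_y = 2.525
stimulus similarity per component: [0.957 0.002]
CORCONDIA: 99.9
significant ROIs: [4]
```

At SNR 20 dB both modalities are fitted to ≈ 10% relative error; the
first component tracks the stimulus (|r| = 0.957, versus 0.002 for the
second), the 2-component CP structure is nearly ideal (CORCONDIA 99.9%),
and the FWE-corrected SnPM flags ROI 4 — one of the four ROIs where the
generator actually planted the stimulus source (the max-statistic test is
deliberately conservative at this short recording length).

The same analysis is available from the shell:

```sh
cmtf-fusion run --out runs/demo --seed 7      # simulate -> ... -> report
cmtf-fusion select --run-dir runs/demo --force-r 2   # manual override
```

A run directory contains `X.h5`, `Y.tsv`, `events.tsv`, per-run model
bundles under `models/`, `report.json` with the full four-indicator
table and selection trace, `significant_rois.tsv`, per-component
signature TSVs, and a `manifest.json` with content hashes for caching
and provenance.

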