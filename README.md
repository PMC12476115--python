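# dynamap

Weakly supervised spatiotemporal dense prediction of **dynamic brain
network maps** from 4D fMRI.

Resting-state fMRI is usually summarized per network by one static spatial
map and one scalar time course, which discards how a network's spatial
expression itself evolves over a scan. `dynamap` treats the problem as a
computer-vision dense-prediction task: a spatiotemporal vision transformer
maps a scan `x ∈ R^{h×w×d×t}` to per-network weight maps
`ŷ ∈ R^{K×h×w×d×t}` that change smoothly in both space and time. Because
no voxel-level ground truth exists, training targets come from **windowed
spatially constrained ICA**: for overlapping temporal windows (size 30,
stride 1), each spatial source `C_i = w_iᵀX` maximizes the negentropy
surrogate `J(w_i) ∝ (E[G(C_i)] − E[G(v)])²` subject to
`φ(C_i, R_i) ≥ ε` against a supplied reference map `R_i` and
`E[C_i²] = 1`. The network is fit to these noisy priors with a composite
loss

```
L = E[ log cosh(y − ŷ) / max(ε, SSIM(y, ŷ)) ]
```

which is robust to outlier voxels (log-cosh) while rewarding global
structural agreement (SSIM). The package also ships the evaluation
machinery for such maps — mARE, mIOU, SSIM, within-ROI homogeneity,
temporal-gradient maps, Shannon-entropy trends, blob (connected
component) counts — and voxelwise two-group statistics with
Benjamini–Hochberg FDR and `−log10(p)·sign(t)` display maps.

It is written for neuroimaging researchers who want subject-level,
temporally resolved network maps and a fully checkable synthetic test bed:
a phantom generator produces 4D volumes with known drifting sources,
known mixing, AR(1) noise, and two-group populations with planted
effects, so every stage can be validated against ground truth.

The model is implemented on a compact numpy reverse-mode autodiff engine
(`dynamap.autodiff`) — small transformer + decoder configurations train
in minutes on one CPU.

## Worked example

```python
import numpy as np
from dynamap.synthetic import PhantomSpec, generate_subject, export_references
from dynamap.constrained_ica import IcaProblem, fit_constrained
from dynamap.model import ModelConfig
from dynamap.trainer import TrainConfig, train, predict
from dynamap.objective import ssim

# a phantom subject with 3 drifting Gaussian sources in AR(1) noise
spec = PhantomSpec(shape=(12, 12, 12), n_timepoints=60, n_networks=3,
                   drift_amplitude=0.0, noise_sigma=0.1, seed=1)
vol, truth = generate_subject(spec)

# constrained ICA with the true maps as references
refs = np.stack([r.ravel() for r in export_references(truth)])
prior = fit_constrained(IcaProblem(X=vol.data.reshape(-1, 60).T,
                                   references=refs), seed=0)
for k in range(3):
    r = np.corrcoef(prior.components[k], truth.time_avg_maps[k].ravel())[0, 1]
    print(f"network {k}: recovery r = {r:.3f}, "
          f"constraint phi = {prior.constraint_correlations[k]:.3f}")
```

prints

```
network 0: recovery r = 0.959, constraint phi = 0.959
network 1: recovery r = 0.961, constraint phi = 0.961
network 2: recovery r = 0.959, constraint phi = 0.959
```

i.e. each estimated component matches its ground-truth source at r ≈ 0.96
while satisfying the reference constraint. Training the small
dense-prediction model on one phantom then drives the composite loss to a
fraction of its initial value and reproduces the prior maps at
SSIM ≈ 0.99 (see `tests/test_acceptance.py` for the exact contracts).

The same workflow is available from the shell:

```bash
dynamap simulate --out work/phantom --shape 16,16,16 --timepoints 60
dynamap priors --scan work/phantom/subject.nii.gz \
    --references work/phantom/reference_00.nii.gz \
    --references work/phantom/reference_01.nii.gz \
    --references work/phantom/reference_02.nii.gz \
    --window 30 --stride 1 --out work/priors
dynamap train --scan work/phantom/subject.nii.gz --prior work/priors \
    --set model.patch_size=5 --checkpoint work/ckpt
dynamap predict --checkpoint work/ckpt --scan work/phantom/subject.nii.gz \
    --out work/pred
dynamap evaluate --prior-dir work/priors --pred-dir work/pred \
    --out work/metrics.csv
```

Parameter sweeps (patch size, retained time points) are shell loops over
`--set model.patch_size=...` / `--set preprocess.n_timepoints=...`.

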