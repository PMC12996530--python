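# nanokymo

Simulation, deep-learning analysis and statistics for nanofluidic scattering
microscopy (NSM) kymographs.

NSM images single biomolecules diffusing freely inside sub-wavelength
nanofluidic channels, label-free: the interference between light scattered by
the channel and by the molecule produces a travelling contrast dip in a
kymograph (time x channel position). Two numbers characterize each molecule —
its molecular weight (MW), encoded in the integrated optical contrast
iOC ∝ MW/A for channel cross-section A, and its hydrodynamic radius (Rs),
encoded in the diffusivity D through Stokes–Einstein,
D = H(Rs)·k_B·T/(6π·η·Rs) with a hindrance factor H for wall drag. For
sub-10-kDa analytes the per-frame signal sits below the noise floor, so the
package pairs a physics-based kymograph simulator with a hierarchical vision
transformer (h-ViT) that never reconstructs pixel-wise trajectories: it emits
a coarse-grid *probability map* P(x, t) of molecule presence and a *property
map* of per-bin (MW, Rs, N) predictions, and reads out
θ̂ = Σ P·θ / Σ P — a probability-weighted average in which confident regions
dominate. Populations are then cleaned by probability-sum thresholding
(P_thresh = ½⟨P_control⟩ from buffer-only controls) and single-pass 3σ
Gaussian pruning, and estimator precision is benchmarked against Cramér–Rao
lower bounds: σ_rel ≥ √(2/N) for diffusivity from N increments and
σ_rel ≥ 1/(snr_eff·√N) for contrast amplitude.

The package is for method developers and microscopists who want to simulate
NSM-like data with a controlled noise model, train and probe
probability-weighted property regressors, or quantify how far a given
trajectory length N is from the information-theoretic precision limit.

## Worked example

Simulate a ground-truthed kymograph, train a tiny model, and estimate:

```python
import numpy as np
from nanokymo import benchmarks, hvit
from nanokymo.simulate import Kymograph

# desk-scale study: 50 x 50 nm^2 channel, 64 x 128 kymographs, high SNR,
# molecular weights drawn from the grid {5, 15, 30} kDa
result = benchmarks.desk_training_benchmark(seed=1)
print("MW grid:        ", result["mw_grid"])
print("predicted means:", [round(m, 1) for m in result["mw_pred_means"]])
print("Spearman rank:  ", result["spearman_mw"])
print("P_total signal / noise:",
      round(result["signal_p_total_mean"], 1),
      round(result["noise_p_total_mean"], 1))
```

which prints (seed 1):

```
MW grid:         [5.0, 15.0, 30.0]
predicted means: [7.9, 15.1, 27.1]
Spearman rank:   1.0
P_total signal / noise: 29.4 9.2
```

After 200 training steps the probability-weighted readout already orders the
three molecular weights correctly (Spearman 1.0) and molecule-bearing
kymographs carry about three times the probability mass of buffer-only noise,
which is what the P_thresh = ½⟨P_control⟩ rule exploits. The same pipeline is
scriptable from the shell:

```sh
nanokymo simulate --config run.yaml --n 24 --seed 7 --out sims/
nanokymo preprocess raw.tif --out kymo.h5
nanokymo train --config run.yaml --out model.npz
nanokymo predict model.npz kymo.h5 --area 1890 --out estimate.json
nanokymo analyze estimates.csv --controls controls.csv --out summary.json
nanokymo crlb --n-grid 100,1000,10000 --snr 0.1 --out crlb.csv
```

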