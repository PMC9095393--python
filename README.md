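# aihtct

Limited-angle CT reconstruction by **adaptive iterative hard thresholding
(AIHT)** — SART data-fidelity sweeps interleaved with spline-framelet hard
thresholding whose threshold is selected automatically from an L-curve —
together with the RMSE/PSNR evaluation protocol used to compare it against
FBP, plain SART and a fixed-threshold wavelet-frame baseline, and a
spectral-CT module with the diagnostic statistics used to separate hepatic
from carcinomatous peritoneal effusion (energy-spectrum curve slope, curve
typing, ROC sensitivity/specificity) on synthetic cohorts.

It is aimed at researchers studying iterative reconstruction under
restricted angular coverage (e.g. [0°, 90°) or [0°, 120°) instead of the
full half turn), where filtered backprojection produces severe streak and
boundary-degradation artifacts and regularization must supply the missing
information.

## The model

The reconstruction solves the ℓ0-framelet-regularized limited-angle problem

```
argmin_{h ∈ Ω}  ‖Z h − l‖²_B  +  Σ_i β_i ‖(A h)_i‖₀
```

where `Z` is the limited-angle line-integral operator (parallel beam,
Joseph interpolation), `l` the measured sinogram, `B` the SART ray-weight
diagonal, `A` the undecimated piecewise-linear B-spline tight framelet
(filters `k0 = [1,2,1]/4`, `k1 = √2[1,0,−1]/4`, `k2 = [−1,2,−1]/4`, so
`AᵀA = I`), and `Ω` the non-negative orthant. Each AIHT iteration performs

1. a SART sweep `h ← h + g·V⁻¹ZᵀB(l − Zh)` (view-sequential, `g ∈ (0,2]`),
2. framelet analysis, hard thresholding of the 8 detail subbands
   (`y ← 0` if `|y| ≤ β*`, else `y`), framelet synthesis,
3. projection onto `Ω` (clip negatives).

The threshold `β*` is re-selected every few iterations at the corner
(maximum Menger curvature) of the discrete L-curve of
(log₁₀ data misfit, log₁₀ surviving-coefficient count) over a candidate
grid; fixing `β*` instead gives the wavelet-frame (WF) baseline.

Image quality is scored as `RMSE = √(Σ(Pᵢ−Qᵢ)²/M)` over all `M` pixels and
`PSNR = 10·log₁₀(max|Q|²/RMSE²)` dB against the known phantom `Q`.

## Worked example

```python
import aihtct as a

result = a.run_experiment(a.ExperimentSpec())   # the packaged comparison
print(result.table.to_string(index=False))
```

prints

```
  range algorithm     rmse      psnr  n_iters                 notes
 [0,90]      sart 0.042262 22.288254      200  n_angles=90, sigma=0
 [0,90]        wf 0.049704 20.879440      200  n_angles=90, sigma=0
 [0,90]      aiht 0.026607 26.307254      200  n_angles=90, sigma=0
[0,120]      sart 0.021022 28.353941      200 n_angles=120, sigma=0
[0,120]      wf   0.031920 24.725901      200 n_angles=120, sigma=0
[0,120]      aiht 0.007782 36.985183      200 n_angles=120, sigma=0
```

Each row is one reconstruction of the packaged 128×128 piecewise-constant
phantom from clean projections over the given angular range (one view per
degree). AIHT attains the lowest RMSE and highest PSNR in both ranges —
adaptive thresholding beats both unregularized SART and the fixed-threshold
wavelet-frame variant — and every algorithm improves when the range widens
from 90° to 120°, since more views shrink the null space of `Z`.

The same pipeline is scriptable from a shell:

```sh
aihtct phantom --name default --size 128 --out phantom.tif
aihtct project --image phantom.tif --range 0 90 --out sino.csv
aihtct reconstruct --sino sino.csv --algorithm aiht --size 128 --out recon.tif
aihtct evaluate --recon recon.tif --reference phantom.tif
aihtct cohort --n-s1 50 --n-d0 42 --seed 1 --out cohort.csv
aihtct roc --cohort cohort.csv --feature water_iodine
```

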