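# quasarfield

Forward modelling and inversion for quantitative susceptibility mapping
(QSM) in magnetically inhomogeneous tissue.

MRI phase data measure tiny local shifts of the proton Larmor frequency.
In the standard QSM model those shifts are the 3D convolution of the
tissue susceptibility χ with the unit magnetic dipole response, whose
k-space form is `D(k) = 1/3 − (k·b̂₀)²/‖k‖²` with `D(0) = 0` (Lorentz
sphere correction). Real tissue — myelinated white matter above all —
also produces *macroscopically nondipolar* frequency shifts f_ρ from
microstructure, susceptibility-tensor off-diagonals and chemical
exchange. The extended forward model

    f = d * χ + f_ρ

separates the two sources. A dipole-only inversion applied to such data
misattributes f_ρ to susceptibility, producing streaking and biased
regional values; an inversion aware of the extended model can learn to
ignore the nondipolar part.

The package provides, as library modules and a `quasarfield` CLI:

* **dipole physics** — k-space dipole kernel, standard and extended
  forward models, an analytic magnetized-sphere oracle;
* **pattern synthesis** — seeded generators of susceptibility /
  nondipolar / magnitude volumes with natural-image-like (power-law)
  spectra, organic shapes and magnitude-dependent noise, composed into
  training samples through the extended model;
* **phantoms** — a three-sphere scene and a paired brain-like digital
  model (identical χ truth with and without a white-matter-confined
  nondipolar field) with CSF, WM, cortex and six deep-gray nuclei;
* **classical inversions** — thresholded k-space division (TKD) and
  Tikhonov-regularized division, with optional point-spread amplitude
  correction;
* **deep inversion** — a 3D U-Net (pure numpy engine, CPU) that refines
  the TKD solution, trainable in `deepole` mode (extended-model training
  data) or `dlqsm` mode (standard-model data) on identical χ streams;
* **metrics** — demeaned NRMSE, the XSIM structural-similarity variant,
  eroded ROI statistics, DGM slope fits, orthogonal distance regression,
  whole-brain referencing.

See `docs/methods.md` for the model details, parameter choices and
limitations.

## Worked example

Simulate the paired brain phantom, invert with the direct filter, and
score against truth:

```python
import numpy as np
from quasarfield.phantoms import make_brain_phantom, simulate_measurement
from quasarfield.dipole import build_dipole_kernel
from quasarfield.classical import tkd_invert
from quasarfield.metrics import evaluate_estimate

for micro in (False, True):
    bundle = make_brain_phantom((96, 96, 96), with_microstructure=micro, seed=1)
    f = simulate_measurement(bundle, snr=100, seed=51)          # ppm
    kernel = build_dipole_kernel(f.shape, f.voxel_size, f.b0_dir)
    chi_hat = tkd_invert(f, kernel, threshold=0.15, correct_underestimation=True)
    rep = evaluate_estimate(chi_hat, bundle.chi_truth, bundle.labels,
                            bundle.brain_mask)
    print(f"microstructure={micro}: dNRMSE={rep.dnrmse_percent:.1f}%  "
          f"DGM slope={rep.slope:.3f}  XSIM={rep.xsim:.3f}")
```

Output:

```
microstructure=False: dNRMSE=26.0%  DGM slope=1.037  XSIM=0.564
microstructure=True: dNRMSE=120.1%  DGM slope=1.086  XSIM=0.083
```

Without microstructure the corrected filter reconstructs the deep-gray
ladder accurately (slope ≈ 1) with the usual noise-streak floor. Adding
the white-matter nondipolar field — with χ truth unchanged — almost
quintuples the error and degrades similarity: the filter reads the extra
frequency shifts as susceptibility. The same experiment with the two
learned modes (`quasarfield study`, or `run_simulation_study`) shows the
extended-model network is the least affected on the microstructure
phantom, while networks trained on the standard model inherit the
misattribution.

The equivalent shell pipeline:

```sh
quasarfield phantom --grid 96 --microstructure on --seed 1 --out ph/
quasarfield invert --method tkd --correct --f ph/f_total.nii.gz --out chi.nii.gz
quasarfield evaluate --est chi.nii.gz --truth ph/chi_truth.nii.gz \
    --labels ph/labels.nii.gz --mask ph/mask.nii.gz --out report.json
```

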