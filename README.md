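# cbct4d

Simulation and motion-compensated reconstruction of **rapid-acquisition
thoracic 4D cone-beam CT**.

Modern ring-gantry linacs acquire a full CBCT in ~17 s — too fast for
respiratory-correlated (4D) reconstruction, which needs several breathing
cycles per gantry angle. For lung-cancer image guidance the question is
whether the projections of such a rapid 3D scan can still yield a usable 4D
image when reconstructed with **motion compensation** driven by the patient's
planning 4DCT. `cbct4d` is a self-contained simulation study of that
question: it generates a breathing digital thorax, simulates conventional
(1320 projections / 240 s) and rapid (491 projections / 16.6 s) full-fan
scans over a 200° arc, reconstructs them four ways, and quantifies image
quality against the ground-truth 4DCT.

## Methods at a glance

* **Phantom** — parametric thorax (body, lungs, liver with moving diaphragm
  dome, lung tumor) whose motion is a single smooth deformation
  `x ↦ x − s(t)·m(x)` with `s(t) = (1 − cos 2πt)/2`; the phase-to-reference
  deformation fields (DVFs) are therefore known analytically. A "planning"
  variant with scaled amplitudes and rigid drift emulates a different-day
  4DCT.
* **FDK** (Feldkamp–Davis–Kress) filtered backprojection with cosine
  pre-weighting, Parker short-scan weights, and a Ram-Lak ramp:
  **3DFDK** (all projections → one volume) and **4DFDK** (each respiratory
  phase from only its phase-binned projections).
* **MCFDK** — motion-compensated FDK: rigid registration of the 3DFDK
  volume to the planning 3DCT, transport of the planning DVFs, warp of every
  4DFDK phase to peak inhale, averaging, and inverse-warping back — using
  *all* data for *every* phase.
* **Metrics** — CNR `(μ_FG−μ_BG)/σ_BG`; tissue interface sharpness (TIS,
  mean fitted sigmoid rate across the diaphragm) and width
  `TIW = 2w·ln 9 / TIS`; RMSE and global SSIM
  (`c1=(0.01L)², c2=(0.03L)²`) after affine windowing; phase averages,
  cohort medians, paired t-tests.

See `docs/methods.md` for the full model description, numerical choices and
limitations.

## Worked example

```python
import cbct4d as c

cfg = c.StudyConfig(n_patients=10, seed=0, out_dir="results/study")
cohort = c.run_cohort(cfg)
print(cohort.summary.query("metric in ('tiw', 'rmse')").to_string(index=False))
```

prints (desk preset: 4 mm voxels, full protocol projection counts):

```
       arm metric       median          q25          q75  n
        gt    tiw 1.757780e+00 1.757780e+00 1.757780e+00 10
        gt   rmse 4.264321e-18 3.382823e-18 4.783085e-18 10
 conv4dfdk    tiw 4.471568e+00 4.406087e+00 4.531824e+00 10
 conv4dfdk   rmse 1.164420e-03 1.162461e-03 1.167999e-03 10
rapid3dfdk    tiw 1.602257e+01 1.566960e+01 1.749244e+01 10
rapid3dfdk   rmse 1.594742e-03 1.576468e-03 1.614995e-03 10
rapid4dfdk    tiw 8.288988e+00 7.313672e+00 9.080168e+00 10
rapid4dfdk   rmse 4.943178e-03 4.933427e-03 4.962688e-03 10
     mcfdk    tiw 5.377590e+00 5.191871e+00 6.176052e+00 10
     mcfdk   rmse 1.313399e-03 1.308739e-03 1.317181e-03 10
```

Reading it: TIW is the 10–90% width of the diaphragm edge in mm (smaller =
sharper; the ground truth's 1.76 mm is the voxel-edge floor), RMSE is in
attenuation units (mm⁻¹) against the ground-truth phase. The conventional
4D scan is sharpest and most accurate (TIW 4.5 mm), the rapid scan
reconstructed in 3D is heavily motion-blurred (16.0 mm), and motion
compensation recovers most of the difference from the same rapid data
(5.4 mm) — while the naive 4DFDK of the rapid scan (flagged "insufficient"
by the pipeline) is dominated by sparse-view streaks (RMSE 3–4× worse).
Per-patient tables, cohort quartiles and the paired t-test matrix are
written as CSV under `out_dir`.

The same pipeline is scriptable from the shell:

```bash
cbct4d phantom   --out pt1/ --seed 1
cbct4d simulate  --phantom pt1/ --protocol rapid --out pt1/proj
cbct4d reconstruct --algo mcfdk --proj pt1/proj --planning pt1/ --out pt1/rec
cbct4d evaluate  --rec pt1/rec --gt pt1/ --out pt1/metrics.csv
cbct4d run-study --out results/ --seed 0
```

Volumes and DVFs are MHA/NIfTI (SimpleITK) with JSON sidecars, so real
10-phase volumes or externally computed DVFs can be substituted for the
synthetic ones.

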