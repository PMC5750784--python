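# gaitid

Gait is a usable biometric: the way a person walks, recorded by body-worn
inertial sensors (IMUs), is stable enough to identify them within a known
group. `gaitid` implements a complete identification pipeline for
multi-sensor IMU recordings — five sensor nodes (ankle, wrist, knee, chest,
lower back), each with a triaxial accelerometer and gyroscope at 50 Hz —
aimed at researchers in wearable sensing and gait biometrics who want a
tested, reproducible reference implementation they can run end to end
without any data download.

The pipeline:

1. **Preprocessing** — per-sample vector magnitudes
   `Mag(t) = sqrt(Rx² + Ry² + Rz²)` (invariant to how the sensor was
   mounted), rest-interval bias calibration, and a 10th-order Butterworth
   band-pass over the 0.5–3.5 Hz walking band.
2. **Gait-cycle extraction** — the cycle frequency `f_cycle` is the
   DFT-magnitude peak of the ankle-accelerometer resultant inside
   0.5–1.5 Hz; activity windows above an amplitude threshold are walked one
   nominal cycle (`round(fs / f_cycle)` samples) at a time, snapping each
   boundary to the nearest rising zero crossing; the same markers slice all
   ten synchronized streams.
3. **Time-frequency expansion** — each cycle becomes a smoothed pseudo
   Wigner-Ville distribution

   `SPWV(t, ω) = ∫ W_ω(τ) [∫ W_t(u−t) x(u+τ/2) x*(u−τ/2) du] e^{−jωτ} dτ`

   rendered as a fixed-size 120×120×3 colormapped image.
4. **Per-source CNN** — one compact convolutional network per
   sensor/modality source (three conv/ReLU/max-pool stages with 32/32/64
   feature maps, a 64-unit fully-connected layer, softmax; SGD with
   momentum, fixed 19-epoch budget) produces per-subject log-likelihood
   scores `S_ij(x)`.
5. **Fusion** — *early*: the ten images stack into one 120×120×30 input for
   a single wider CNN; *late*: fused scores
   `Score_j(x) = Σ_i w_ij S_ij(x)` are LLR-normalized and thresholded, and
   **minimum error score fusion (MESF)** learns the subject-dependent
   weights `w_ij ∈ [0, ∞)` one at a time by exact threshold scans that
   never increase the training error. SUM and one-vs-rest linear-SVM
   combiners are included for comparison, along with ten-fold
   cross-validation utilities, accuracy/relative-error-reduction metrics
   and a two-sample t-test.

Because no public dataset accompanies the task, the package ships a
synthetic multi-sensor gait simulator (subject-specific harmonic signatures
near 1 Hz, rest intervals, session-constant mounting rotations, sensor
noise) with known ground truth; every stage is tested against it.
See `docs/methods.md` for the model details and design decisions.

## Worked example

```python
from gaitid import PipelineConfig, run_pipeline

cfg = PipelineConfig(n_subjects=5, duration=50.0, seed=1,
                     image_size=48, epochs=5,
                     fusion_methods=("mesf", "sum", "svm"))
report = run_pipeline(cfg)
print("cycles:", report["n_segments"])
print("best single source:", report["best_single"])
print("SUM :", round(report["sum"]["accuracy"], 2))
print("SVM :", round(report["svm"]["accuracy"], 2))
print("MESF:", round(report["mesf"]["accuracy"], 2))
```

prints (seed 1):

```
cycles: 208
best single source: {'source': '3_gyro', 'accuracy': 92.85714285714286}
SUM : 100.0
SVM : 100.0
MESF: 100.0
```

That is: 208 gait cycles were extracted from five simulated subjects, the
single best sensor/modality (here the knee gyroscope) identifies 92.9% of
held-out cycles on its own, and every fusion of the ten sources identifies
all test cycles correctly — the expected ordering: fusing complementary
sensors beats the best individual sensor.

The same pipeline is scriptable from the shell:

```bash
gaitid simulate --subjects 5 --duration 60 --seed 1 --out runs/raw
gaitid extract-cycles --in runs/raw --out runs/cycles
gaitid run-all --seed 1 --out runs/full
```

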