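# septatrack

Single-molecule analysis of divisome protein dynamics at the bacterial
division septum, built for the kind of experiment in which a sparsely
labeled septal protein (e.g. FtsN, FtsW/FtsI or FtsZ in *E. coli*) is
imaged at 1 frame/s with astigmatism-based 3D localization, and the
question is whether individual molecules at the septum are **stationary**
(engaged/immobile, exponential dwells) or move **processively** around
the division plane — and at what speed. Slow directional motion
(~9 nm/s) reports on active septal peptidoglycan synthesis, while fast
motion (~30 nm/s) tracks FtsZ treadmilling, so separating and
quantifying the populations is the core of the analysis.

The package covers the full chain:

1. **simcell** — synthetic-data generator: molecules on a cylindrical
   cell surface (radius ~400 nm) with stationary / slow / fast
   populations, blinking, detection losses, astigmatic width assignment
   and bottom-half visibility; plus bead calibration stacks, ring
   profiles, FRAP traces and cluster movies. Every downstream stage is
   testable against generator ground truth.
2. **loc3d** — 2D Gaussian spot fitting, bead-stack astigmatism
   calibration, z lookup (√σ metric, ×0.75 refractive-index rescale) and
   the 60–300 nm σ band-pass filter. Reads/writes ThunderSTORM-style CSV.
3. **tracking** — greedy nearest-neighbor linking (300 nm per frame
   transition, up to 8 dark frames) and septal track selection.
4. **geometry** — cylinder fit (PCA axis + nonlinear refinement) and
   unwrapping of 3D trajectories into 1D circumferential arc length
   `s = r·unwrap(θ)` and axial position `l`.
5. **segments** — BIC-penalized changepoint splitting of `s(t)`;
   per-segment statistics `R = σ_resid/|Δ|` and a permutation-test
   probability of processive motion `P`; a segment is processive iff
   `R ≤ 0.4` and `P ≥ 0.5` (segments of ≤5 frames are not classified).
6. **popfit** — single/double log-normal mixture fit of the speed CDF,

   CDF(v) = P₁·Φ((ln v − u₁)/σ₁) + (1 − P₁)·Φ((ln v − u₂)/σ₂),

   with component mean exp(u + σ²/2) and 200× bootstrap standard
   errors; exponential decay fit A·e^(−λx) (mean apparent speed u = 1/λ)
   for the stationary population; two-sample KS comparison.
7. **ringstats** — circumferential autocorrelation
   p(r_k) = Σᵢ Zᵢ Zᵢ₊ₖ / Σᵢ Zᵢ², midcell fraction I_ring/I_cell, torus
   ring dimensions with quadrature deconvolution, pseudo time course.
8. **frap** — half-ring FRAP normalization (0 at first post-bleach
   frame, opposite-side late average = 1, outside-septum bleach
   correction), 1–2 phase recovery fits F(t) = F∞ − Σ aⱼ e^(−t ln2/τⱼ),
   and the diffusion timescale A/D.
9. **kymo** — kymographs (bicubic 20 nm/px, 11-px line, 4-frame moving
   average) and robust stripe-slope speeds.
10. **cli / pipeline** — `septatrack` command-line entry point and the
    end-to-end `run_pipeline`.

## Worked example

Run the full simulated pipeline (50 cells, sparse labeling, default
study conditions: 55% stationary with ~27 s dwells, 45% slow-processive
with log-normal speeds of mean 9.4 nm/s and ~15 s runs):

```python
from septatrack import PipelineConfig, run_pipeline

report = run_pipeline(PipelineConfig(seed=1), out_dir="septatrack_out")
print(report["n_segments"], report["pct_stationary"],
      report["mean_speed_nm_s"])
```

With seed 1 this prints 79 classified segments, 69.6% stationary and a
mean processive speed of 12.7 nm/s, against a ground-truth stationary
share of 51.9% among the same segments. The gap is real and documented:
at 30/50 nm localization noise, processive runs shorter than ~8 s are
statistically indistinguishable from stationary dwells (they fail the
R ≤ 0.4 test), which inflates the stationary share and — through
selection on short, noisy segments — the mean speed. Re-running with
`loc_noise_xy=0, loc_noise_z=0` recovers the truth: 50.0% stationary
vs. 51.2% truth and a 9.1 nm/s mean speed. See `docs/methods.md` for
the bias analysis.

Single stages are available as subcommands:

```
septatrack simulate --seed 2 locs.csv
septatrack localize --calib beads.csv --band 60 300 locs.csv locs_z.csv
septatrack track --max-disp 300 --max-gap 8 locs_z.csv tracks.csv
septatrack frap trace.csv frap_report.json
```

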