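# nucleoflow

Non-invasive measurement of **nuclear relative stiffness** in epithelial cell
monolayers from fluorescence time-lapse movies of tagged nuclei.

## The problem

In a confluent monolayer, cells continuously compress and stretch one
another.  Each cell's nucleus deforms together with the cell, but less so the
stiffer it is relative to the surrounding cytoplasm.  Probing that stiffness
usually requires contact techniques (AFM, micropipette aspiration) that
perturb the tissue.  `nucleoflow` instead extracts it purely from imaging:

1. **Segment and track** single fluorescent nuclei over time (edge-enhanced,
   seed-constrained watershed; Crocker–Grier-style linking; an
   intensity-based quality filter rejects unreliable segmentations).
2. **Reconstruct the tissue velocity field** by particle image velocimetry
   (PIV) and compute its local divergence ∇·v, which by continuity equals
   the local cell-area strain rate: ∇·v = ȧ_c.
3. **Correlate** the instantaneous single-nucleus area strain rate
   ȧ_n = (2/δt)·(A(t+δt) − A(t))/(A(t+δt) + A(t)) with the divergence
   interpolated at each nucleus center.  Near the origin the binned scatter
   is linear with zero intercept; its slope *m* is the ratio of nuclear to
   cellular strain rates, and

   **e_n = 1/m**   is the *relative stiffness* of the nucleus.

4. **Convert to a modulus ratio** with a series-elastic model of the cell
   (elastic nucleus, modulus E_n, in series with elastic cytoplasm, E_cy,
   under a common in-plane stress).  With β = ⟨A_n⟩/⟨A_c⟩ the nuclear area
   fraction,

   **E_n / E_cy = (e_n − β) / (1 − β)**.

Deformation amplitudes are characterized by the *mean square strain*
MSS(τ) = ⟨⟨Δa²(τ|t)⟩ₜ⟩ⱼ, fitted with
σ_w + ȧ₀τ_c(1 − e^(−τ/τ_c)); the short-time slope ȧ₀ is the characteristic
nuclear strain rate and σ_w absorbs delta-correlated measurement noise.

Because no public recordings accompany the method, the package ships a
first-class **synthetic-data generator**: textured elliptical nuclei advected
by a prescribed velocity field whose divergence drives their areas with a
known coupling *m*, plus realistic background, shot noise and stage jitter —
so every stage of the chain is testable against exact ground truth.

## Worked example

```python
from nucleoflow import SynthConfig, PipelineConfig, generate_movie, run_pipeline

# synthetic monolayer: 120 nuclei, 60 frames, 5 min/frame, known coupling
# m = 0.5 (true e_n = 2, true beta = 0.4 -> true E_n/E_cy = 2.67)
cfg = SynthConfig(n_nuclei=120, frame_shape=(384, 384), n_frames=60, seed=5)
seq, truth = generate_movie(cfg)

pipe = PipelineConfig(pixel_size_um=cfg.pixel_size_um, dt_min=cfg.dt_min,
                      n_windows=1, min_per_bin=20)
res = run_pipeline(seq, pipe, outdir="example_out")
print(res.results.summary())
```

prints (~70 s on one CPU):

```
Relative nuclear stiffness (series-elastic model)
==========================================================================
    window        m            e_n           beta       E_n/E_cy
--------------------------------------------------------------------------
0-4.91667h    0.474   2.111 ± 0.356   0.363 ± 0.002   2.745 ± 0.560
--------------------------------------------------------------------------
 adot0 (1/h)   0.0860
   sigma_div   0.4402
```

Reading the numbers: the fitted strain-rate/divergence slope m = 0.474
(truth 0.5) gives a relative stiffness e_n = 2.11 ± 0.36 (truth 2.0) — the
nucleus deforms about half as fast as the cell.  The measured nuclear area
fraction β = 0.363 converts this to a modulus ratio E_n/E_cy = 2.7 ± 0.6
(truth 2.67): the nucleus is roughly three times stiffer than the cytoplasm.
`example_out/` receives per-stage CSV tables, the stiffness report
(JSON + CSV) and a provenance record.

The same chain is available from the shell:

```bash
nucleoflow synth --out movie.tif --truth truth.csv --n-nuclei 120 --n-frames 60
nucleoflow run config.yaml movie.tif --outdir out/
```

with subcommands `synth | preprocess | segment | track | piv | run | report`
for the individual stages.

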