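# endotrack

Heterogeneity analysis for 2D single-particle tracking (SPT) data, built
around the statistics used to characterize intracellular vesicle
transport: endosomes and similar organelles move by anomalous diffusion,
with some particles jiggling in place (subdiffusive, "slow") while others
show bursts of motor-driven transport (superdiffusive, "fast"). The
package splits a trajectory ensemble into slow and fast movers, computes
the standard averaged observables and their *local* (time-resolved)
counterparts, and ships a heterogeneous fractional Brownian motion (hFBM)
simulator so that every estimator can be verified end-to-end against
known generating parameters — no microscopy data required.

It is intended for biophysicists and quantitative cell biologists who
have tracking output (track id, frame, time, x, y in a CSV) and want
reproducible MSD/VACF/propagator-level analysis of motion heterogeneity.

## What it computes

For trajectories r(t) = {x(t), y(t)} sampled at frame interval Δt:

* **Slow/fast splitting** — by maximum excursion max R(t) > ε with
  R(t) = |r(t) − r(0)| (default ε = 0.25 μm), or by runs of more than 4
  consecutive superdiffusive local exponents αL(t) > 1.
* **MSD estimators** — ensemble-averaged EMSD(t) = ⟨|r(t) − r(0)|²⟩/l²,
  single-trajectory time-averaged TMSD over overlapping windows, and
  their ensemble mean E-TMSD; power-law fits MSD = 4 D_α (t/τ)^α with
  l = 1 μm, τ = 1 s, yielding the anomalous exponent α and the
  dimensionless generalized diffusion coefficient D_α.
* **Local analysis** — a sliding window of N frames (N > 10, default 20)
  advanced one frame at a time; the first 10 lags of each windowed TMSD
  fitted with 4 D_L(t) (t′/τ)^{α_L(t)}, giving the time series of local
  anomalous exponents αL(t) and local diffusivities DL(t), their pooled
  distributions (exponential fits for αL, power-law fits for DL), and
  their rank correlation.
* **Velocity autocorrelation** — TVACF/E-TVACF of finite-difference
  velocities v = (r(t+τ_v) − r(t))/τ_v, with the analytic FBM reference
  C(t)/C(0) = (|t+τ_v|^{2H} + |t−τ_v|^{2H} − 2|t|^{2H})/(2τ_v^{2H}).
* **Propagators** — the PDF of the scaled displacement ξ = x/σ_x at a
  fixed lag; power-law tail fits PDF(ξ) ∝ |ξ|^{−1−2γ}; the analytic 2D
  obstructed-diffusion propagator ∝ |ξ|^{−0.108} exp(−|ξ|^{1.65}); and
  the superstatistics consistency check that a diffusivity density
  p(D_L) ∝ D_L^{−1−γ} must pair with a propagator tail of index γ
  (exponent magnitude = 1 + γ).
* **hFBM simulation** — fractional Gaussian noise by exact circulant
  embedding (Davies–Harte, with a Durbin–Levinson fallback), trajectory
  durations from a truncated power law φ(T) ∝ T^−1.85, duration-coupled
  diffusivities D = c·T^−0.6, optional two-state Hurst switching and
  Gaussian localization noise — the generative structure that reproduces
  the survival bias of live-cell tracking, where slow particles stay in
  the field of view longer.

## Worked example

Simulate a mildly mobile hFBM ensemble, split it, and fit the MSD of
long-lived trajectories:

```bash
$ endotrack simulate --n-traj 500 --seed 42 --coupling-c 0.01 --out demo.csv
wrote 500 trajectories to demo.csv (seed=42)

$ endotrack split demo.csv
slow=206 fast=294 discarded=0

$ endotrack msd demo.csv --min-duration 2.0 --fit-min 0.2 --fit-max 1.0
emsd: exponent=0.4607 coefficient=0.0038 r2=0.9657 lags=17

$ endotrack local demo_slow.csv
pooled n=8265 (window=20 frames); alpha exponential rate=2.257; D power-law exponent=1.998 on [0.00189,0.0184]
```

The EMSD exponent ≈ 0.46 of the duration-filtered ensemble reflects the
generating Hurst exponent H = 0.25 (MSD ∝ t^{2H} = t^{0.5}); the
coefficient is small because the diffusivity prefactor was set to
c = 0.01. The slow sub-ensemble's pooled local exponents follow an
exponential distribution (fitted rate 2.26) and its local diffusivities
a power law (fitted exponent magnitude 2.0 on the stated support) — the
heterogeneity fingerprint that motivates an hFBM description.

The same pipeline runs end-to-end from a YAML config
(`endotrack run --config run.yaml`), and `endotrack validate` executes
the full parameter-recovery suite.

The library API mirrors the CLI: `endotrack.read_trajectories`,
`split_ensemble`, `emsd`/`tmsd`/`etmsd` + `fit_power_law`,
`local_series` + distribution fits, `tvacf`/`etvacf`,
`propagator_pdf` + `fit_tail_exponent`, `simulate_hfbm_ensemble`.

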