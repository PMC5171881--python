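# synaptrack

Analysis of single-particle tracking PALM (sptPALM) and single-molecule
localization microscopy (SMLM) data for membrane proteins that switch
between diffusive states and concentrate in nanoclusters — the kind of
data produced by imaging syntaxin1A-mEos2 in live presynaptic terminals.
The package covers the two arms of such a study:

**Mobility arm** (trajectories at 33 Hz):

- per-track mean squared displacement,
  MSD(nΔt) = ⟨(x_{i+n} − x_i)² + (y_{i+n} − y_i)²⟩_i, with the
  overlapping time-averaged estimator;
- diffusion coefficients from ordinary least squares on the first four
  MSD lags, MSD(τ) = 4Dτ + a, the intercept *a* absorbing localization
  error and finite exposure;
- mobile/immobile classification (mobile iff D > 0.021 μm² s⁻¹),
  per-field mobile:immobile ratios and log₁₀ D distributions;
- hidden-Markov inference of discrete diffusive states from per-step
  squared displacements (exponential emissions with mean 4·D_k·Δt,
  Baum–Welch EM, BIC selection up to five states), Viterbi per-step
  annotation, and pooling of states into immobile / slow / fast classes.

**Nanocluster arm** (localization tables in nm):

- consolidation of repeated localizations (1 frame / 1 pixel), optional
  fiducial drift correction, 10 nm image rendering;
- radial auto-correlation g(r) by FFT image correlation or direct pair
  counts, and the cluster-model fit
  g(r) = 1 + exp(−r²/4σ²)/(4πρσ²) + A·exp(−r/ξ),
  giving the molecule density ρ, effective precision σ (image resolution
  σ/√2), cluster radius ξ and amplitude A, with molecules per cluster
  N = 2πρAξ²;
- Ripley's K / L functions with isotropic edge correction and
  Monte-Carlo CSR envelopes for cluster maps.

A synthetic-data module generates Markov-switching Brownian trajectories
and clustered, blinking localization patterns with full ground truth, so
every stage has a parameter-recovery test.

## Worked example

```python
import synaptrack as st

# simulate a resting terminal: ~3,500 tracks, mean 11 steps at 33 Hz
tracks, truth = st.simulate_trajectories(st.rest_trajectory_params(seed=7))

mob = st.MobilityModel(tracks).fit()
print(mob.summary())

hmm = st.DiffusiveStateHMM(tracks, max_states=5).fit(seed=1)
print(hmm.summary())
```

prints (abridged):

```
Mobility analysis (MSD linear fit)
============================================
tracks analysed        1983 (of 3500, min length 8)
threshold              0.021 um^2/s
median D               0.0361 um^2/s
mobile fraction        0.622
mobile:immobile ratio  1.644

Diffusive-state HMM (3 states, BIC-selected, max 5)
========================================================
 state  D_app_um2_s  occupancy ...
     0       0.0169     0.4693
     1       0.0696     0.3488
     2       0.3544     0.1819
pooled occupancy  immobile 0.469  slow 0.349  fast 0.182
```

The three inferred apparent coefficients sit at the immobile / slow /
fast scales injected by the simulator (0.005, 0.06, 0.35 μm² s⁻¹,
inflated by the 20 nm localization noise, σ²/Δt ≈ 0.013 μm² s⁻¹), and
the pooled occupancies recover the chain's stationary distribution.

For the cluster arm:

```python
locs, truth = st.simulate_clustered_localizations(st.rest_cluster_params(seed=7))
res = st.NanoclusterModel(locs, r_max=1000, bin_width=10).fit()
print(res.summary())
```

reports the fitted cluster radius ξ (80.9 nm at the resting preset,
whose true radius scale is 83.5 nm), the fitted molecule density
(79.3 μm⁻²), the image resolution σ/√2 (14.0 nm at 19.8 nm fitted
precision) and molecules per cluster (45.5 against a simulated 40).

A `synaptrack` command-line interface wraps the same steps
(`simulate-traj`, `simulate-locs`, `msd`, `hmm`, `cluster`, `run`,
`compare`); see `synaptrack --help`.

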