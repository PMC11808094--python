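# pcbssfp

In-silico-trained relaxometry for phase-cycled balanced SSFP (pc-bSSFP)
MRI: simulate the analytic steady-state signal, extract SSFP
configuration modes, and estimate voxelwise T1/T2 (and off-resonance)
either with small simulation-trained neural networks or with a
conventional golden-section-search fit, plus the Monte-Carlo machinery
to quantify estimator accuracy and precision and a digital brain-like
phantom for end-to-end testing. It is aimed at quantitative-MRI
researchers who want a scanner-free, fully reproducible sandbox for
pc-bSSFP relaxometry methods.

## The model

A balanced SSFP acquisition repeated with RF phase increments
φ(j) = π/N_pc·(2j−1), j = 1..N_pc, yields one complex steady-state
signal per cycle,

    S(φ) = M0 (1−E1)(1−E2 e^{−iψ}) sin α / (C cos ψ + D) · e^{−TE/T2} · e^{iθ·TE/TR}

with ψ = θ − φ, E_{1,2} = exp(−TR/T_{1,2}),
C = E2(E1−1)(1+cos α), D = (1−E1 cos α) − (E1−cos α)E2², actual flip
angle α = B1·α_nom, and off-resonance phase per TR θ (ΔB0 = θ/(2π·TR)).
A DFT along the phase-cycle dimension isolates the SSFP configuration
modes F_n = (1/N_pc)Σ_j S(φ_j) e^{−i n φ_j}; the three lowest-order
modes (F_−1, F_0, F_1) carry distinct T1/T2 sensitivity and are the
input to every estimator here. At small N_pc higher-order modes alias
into them, which makes the extracted modes θ-sensitive.

Estimators:

* `MiracleEstimator` — training-free iterative golden-section-search
  least-squares inversion of the magnitude modes (a MIRACLE-style
  baseline).
* `MLPRelaxometer` — a sigmoid-bounded two-hidden-layer MLP trained on
  simulated data, in four variants: supervised (`strategy='svnn'`) or
  physics-informed self-supervised (`strategy='pinn'`), each with
  magnitude inputs (|F_−1|,|F_0|,|F_1|,B1 → T1,T2; 4610 parameters) or
  complex inputs (Re/Im of the modes + B1 → T1,T2,θ; 68355 parameters).

Both follow the scikit-learn estimator protocol (`fit`, `predict`,
`get_params`) and compose with sklearn tooling.

## Worked example

```python
import numpy as np
import pcbssfp as p

seq = p.SequenceParams()                      # TR 4.8 ms, TE 2.4 ms, 15°, 12 cycles
rng = np.random.default_rng(0)

# simulate a training set and fit a supervised magnitude network
ds = p.build_dataset(p.uniform_distribution(), 30_000, seq, "magnitude", rng)
net = p.MLPRelaxometer(layout="magnitude", strategy="svnn",
                       max_epochs=60, random_state=0).fit(ds)

# white-matter-like voxel at 3 T, noise-free
wm = p.TissueParams(t1=939.0, t2=62.0, b1=1.0)
sig = p.simulate_pc_signal(wm, seq).values
print(net.predict_from_signal(sig[None, :], np.array([1.0])))
# [[923.74 61.77]]  -> T1/T2 estimates in ms (1.6% / 0.4% off)

gss = p.MiracleEstimator(seq=seq).fit()
print(gss.predict_from_signal(sig[None, :], np.array([1.0])))
# [[939.09 62.01]]  -> the iterative fit inverts its own model almost exactly
```

The quick network lands within a couple of percent of the ground truth
after half a minute of CPU training (accuracy keeps improving with
training size and epochs); the golden-section fit, which searches the
same forward model directly, recovers it to four significant figures. `monte_carlo` then quantifies each estimator's
accuracy (relative error of the MC mean) and precision (MC standard
deviation) under additive complex Gaussian noise of level
η = 0.074/(√2·SNR), and `theta_sweep` traces the error across the full
off-resonance range — magnitude-based estimators degrade at low N_pc
due to mode aliasing, while complex-input networks largely do not.

A thin CLI mirrors the library (`pcbssfp simulate|train|fit|validate|phantom`).

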