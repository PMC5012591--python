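# tumblekit

Tools for linking *E. coli* swimming behavior (tumble bias, effective
diffusion) to chemotaxis protein numbers (CheR, CheB), built around four
stages:

1. **`tumblekit.simulate`** — run-and-tumble trajectory simulator: a
   two-state flagellar motor (CCW/CW switching rates set by CheY-P through
   `k± = ε·exp(∓h)`, `h = (g/2)(1/2 − Yp/(Yp+K_D))`, defaults ε=1.3 s⁻¹,
   g=40, K_D=3.06 µM) driving 3D swimming at 20 µm/s with rotational
   diffusion (0.062 rad²/s), reflecting boundaries 10 µm apart, 10 Hz
   2D-projected sampling, and exact exponential event sampling for motor
   switches. Ground-truth run/tumble labels are carried on every sample.
2. **`tumblekit.tracks`** — kinematic features (speed, acceleration,
   angular acceleration, turn angles) and a three-state trivariate
   Gaussian-mixture behavioral classifier (swim / tumble / intermediate)
   with an iterative per-cell speed-normalization loop; per-cell motility
   summaries (tumble bias, mean run time, mean tumble-angle cosine).
3. **`tumblekit.diffusion`** — velocity autocorrelation and MSD curves,
   jointly fitted to `Cv(t) = v0²·e^(−t/τ)·cos(ωt)` and its exact
   Green-Kubo MSD partner; effective diffusion `D_eff = v0²τ/d` and the
   run-time approximation `D_apx = v²T/(d(1−θ))`.
4. **`tumblekit.pathway` / `tumblekit.noise` / `tumblekit.maps`** — a
   chemotaxis signaling model extended with CheB-dependent receptor
   deamidation (glutamine maturation), steady states and growth-arrest
   transients; correlated lognormal protein-number sampling, linear-noise-
   approximation covariances (Lyapunov equation) with a Gillespie oracle,
   and simulated population phenotypes; LOESS surfaces of mean tumble bias
   and residual SD over (log CheR, log CheB) plus the global fit
   `TB = a + b·log10(N_R/N_B^c)`.

## CLI

```bash
tumblekit simulate --tb 0.25 --n 100 --duration 300 --seed 1 --out tracks.csv
tumblekit analyze  --tracks tracks.csv --min-duration 10 --tol 0.01 --out analysis/
tumblekit diffuse  --tracks tracks.csv --out fits.csv
tumblekit model steady --cher 140 --cheb 240
tumblekit model transient --duration 3600 --cheb 100 --out transient.csv
tumblekit population --n 1000 --seed 1 --panel --out pop.csv
tumblekit map --cells pop.csv --bandwidth 0.2 --out maps/
tumblekit run --config run.cfg        # simulate -> analyze -> diffuse + manifest
```

All parameters are overridable through a flat `key = value` config file
(see `tumblekit/config.py` for the documented keys and a template).

## Notes on shipped model defaults

The signaling-model parameter table of the original study is not
recoverable; `PathwayParams` ships a documented default set assembled from
measured mean copy numbers (CheR 140, CheB 240, CheA 6700, CheY 8200,
CheZ 3200, receptors 15000 per 1.4 fL cell), the deamidation/demethylation
anchors `k_Q = 0.64 s⁻¹ = k_B/2`, and free energies that make a freshly
synthesized QEQE receptor exactly semi-active. With these defaults the
wild-type steady state gives tumble bias ≈ 0.25, the deamidation-capacity
threshold sits near 100 CheB molecules/cell, and growth-arrest transients
reproduce the expected decay/flat phenotypes. Steady-state tumble-bias
readouts default to an adaptive-motor curve (the switching logistic at
reduced gain 8); trajectory simulation uses the full g=40 switching
kinetics.
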