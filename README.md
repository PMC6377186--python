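# delaywta

A delayed winner-take-all population model of perceptual decision making.

Two mutually exciting firing-rate populations inhibit themselves with a
transmission delay; Hebbian synaptic weights follow the rates through a
quasi-steady (instantaneous-plasticity) approximation. The delay destabilizes
the symmetric resting state through a Hopf bifurcation, and the package
reproduces the resulting decision phenomenology:

- **`model_core`** — parameters, Hill transfer function, quasi-steady
  weights, deterministic right-hand side, resting fixed point.
- **`dde_solver`** — method-of-steps RK4 integration with cubic-Hermite
  delayed lookup; Euler–Maruyama integration of the noisy system (two
  independent Wiener processes); clamped-history and additive-input stimulus
  conventions; CSV trajectory I/O.
- **`decision`** — evidence accumulation (logistic transform of the running
  rate-difference integral), first-crossing decision rule at threshold 0.99,
  decision certainty `max_t |p1 - p2|`, certainty surfaces over stimulus
  magnitude and psychometric slope, and the stimulus-duration sweep that
  locates where perceptual ambivalence disappears.
- **`stability`** — symmetric/antisymmetric mode decomposition about the
  resting state (quasi-steady and frozen-weight linearizations), critical
  delay of the transcendental characteristic equation, and an
  analytic-vs-simulation classifier.
- **`noise_experiment`** — Monte-Carlo success-rate curves versus noise
  magnitude with randomized readout times in [5, 7] s.
- **`bold`** — balloon/windkessel hemodynamic forward model (plus a
  double-gamma convolution cross-check) applied to the summed population
  signal, and the weak-versus-strong stimulus variance comparison.
- **`cli_io`** — YAML configs, canonical named scenarios, and the CLI.

## CLI

```sh
delaywta list-scenarios                     # canonical parameter sets
delaywta simulate fig3c --out out/          # trajectory + evidence + decision
delaywta stability --tau 1.7 --json         # fixed point, gains, critical delays
delaywta certainty-map --out cmap.csv       # c(sigma, beta) matrix
delaywta duration-sweep --out sweep.csv     # ambivalence vs stimulus duration
delaywta noise-curve --n-iter 2000          # success rate vs noise magnitude
delaywta bold --out bold/                   # per-condition BOLD variances
```

`simulate` also accepts a YAML config with keys
`tau_r, tau_1, tau_2, I_1, I_2, beta, theta, T, sigma, t_on, t_max, mode,
target` (see `delaywta.cli_io.save_config`).

## Conventions worth knowing

- The weight time scale has no parameter: it is eliminated by the
  quasi-steady approximation (`w1 = w2 = hill(r1 * r2)` at all times).
- Firing rates are not rectified; transiently negative rates trigger a
  `NegativeRateWarning` and analyses restrict their windows instead of
  clipping.
- "Supercritical" refers to a delay above the critical (Hopf) delay, not to
  the bifurcation's normal-form type.
- The default stimulus convention for deterministic runs clamps the rates
  during the pulse window; stochastic runs always inject the stimulus
  additively (clamping is incompatible with noise increments).
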