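# pkdeconv

Non-parametric Bayesian input estimation for extended-release
pharmacokinetics.

## What problem this solves

When developing an extended-release (ER) formulation — e.g. an injectable
polymer-microsphere depot that releases drug over weeks — one routinely
needs the *in vivo* absorption-rate profile u(t) and the bioavailability F
of each candidate formulation, but can only measure plasma concentrations
C(t). If the pharmacokinetics were linear and fast, u could be obtained by
classical deconvolution. Exenatide (the motivating compound) has neither
property: its PK model includes nonlinear target-mediated drug disposition
(TMDD), and its ER profile spans timescales from hours to months with
multiple absorption peaks that defeat simple parametric release models.

`pkdeconv` treats the problem as general input estimation: the absorption
rate is an unknown non-negative function, modeled in the log domain on a
20-function Karhunen–Loève basis with a second-derivative smoothness prior,
and pushed through the TMDD model

  dC/dt = u(t)/V_c − (k_el + k_pt)C + k_tp·A_T/V_c − k_on(R_tot − RC)C + k_off·RC

(plus peripheral and receptor-complex equations). The full posterior over
the basis coefficients and the regularization parameter λ ~ Gamma(10⁻³,
10⁻³) is sampled by alternating simplified-manifold MALA (SMMALA) updates
with exact Gibbs draws of λ, under a robust proportional-error likelihood
(10% Student-t with 4 df by default). On week timescales the ODE system is
replaced by its algebraic steady-state solution, making posterior
evaluations thousands of times cheaper. Chain adequacy is assessed with the
Raftery–Lewis run-length diagnostic.

Intended users: PK modelers and formulation scientists who have an IV/PK
model and single-dose concentration profiles and want absorption profiles
with honest uncertainty — e.g. to rank formulations or build an in vitro–
in vivo correlation.

See `docs/methods.md` for the model, prior, sampler and validation details.

## Worked example

Simulate a sparse 12-week dataset from the built-in synthetic ER input
(two Erlang peaks plus an initial burst, pushed through the TMDD model with
10% t₄ noise), then estimate the absorption profile:

```bash
pkdeconv simulate --timescale long --schedule sparse --noise student_t \
    --seed 7 --out runs/sim
pkdeconv estimate runs/sim/long_sparse_noisy.csv --seed 1 --out runs/est
pkdeconv report runs/est --dose-mg 10 --out runs/rep
```

The estimate step prints per-100-iteration progress and finishes with

```
INFO pkdeconv.sampler: iteration 10000/10000, acceptance 0.38, lam 0.00102
INFO pkdeconv: estimate finished: mode=steady_state acceptance=0.38
runs/est/summary.json
```

`summary.json` records the posterior-mean input trajectory with pointwise
95% bands on the 200-node grid, the Raftery–Lewis report, and — because the
simulated dataset carries a truth sidecar — the mean posterior RMSE:

```
"mode": "steady_state",          # algebraic model, valid on week timescales
"acceptance_rate": 0.384,
"rmse_vs_truth": 55.15,          # pmol/week, per kg bodyweight
```

i.e. the average (over posterior draws) root-mean-square distance between
the reconstructed and the true absorption rate, whose peaks reach
~540 pmol/week — about a 10% average reconstruction error from 13 noisy
observations. The report step integrates the posterior draws into
fraction-absorbed curves and a bioavailability kernel-density estimate
(assuming 90 kg bodyweight and a 4186.6 g/mol molar mass):

```
F mean = 0.1244, 95% CI = [0.1119, 0.1396]
```

For a short-timescale (first 48 h) dataset the same commands run the
dynamic ODE model with forward sensitivities instead: use
`--timescale short` (and expect minutes instead of seconds).

`pkdeconv validate --out runs/val` runs the full eight-scenario synthetic
validation battery (timescale × sampling density × noise) and reports each
scenario's mean posterior RMSE against its reference value with a
factor-of-two tolerance band.

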