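# pippet

Continuous-time Bayesian filters that estimate the phase (and tempo) of a
hidden temporal process from the precise timing of discrete events, given
an expectation template — a background event rate plus Gaussian peaks
describing when events are expected and how strongly/precisely.

The package provides:

- **`pippet.templates`** — expectation templates `rate(phi) = lambda_0 +
  sum_i lam_i * N(phi; phi_i, v_i)`, periodic tiling, and builders for
  metronomic and swung-eighth-note templates.
- **`pippet.pippet_filter`** — the 1D phase filter: a Gaussian belief
  `(mu, V)` that follows a deterministic ODE between events and is reset
  at each event by exactly moment-matching the product of the belief and
  the template rate. Includes the multi-stream generalization (one
  template per labelled event stream) and a tap-planning helper.
- **`pippet.patippet_filter`** — the joint 2D phase/tempo filter with
  tempo-scaled event rate; event updates are analytic Gaussian moment
  matches of `tempo * rate(phase) * N(x; mu2, V2)`.
- **`pippet.generative`** — drift-diffusion phase/tempo path simulation,
  per-bin Bernoulli thinning of the inhomogeneous point process, and
  deterministic stimulus builders (metronomes, event/phase shifts,
  omissions, grid rhythms).
- **`pippet.experiments`** — scripted simulation experiments with pinned
  configs: single-event response surfaces, swing-rhythm tracking under
  perturbations, syncopation-driven tracking failure and its two rescues
  (lower phase noise; an added isochronous tap stream), tempo inference,
  the phase-correction fraction alpha as a function of inter-onset
  interval, and the filled-duration contrast.
- **`pippet.io` / `pippet.cli`** — CSV/YAML I/O, run manifests, and the
  `pippet` command-line tool.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: quadrature-
oracle equivalence of both event updates, the 2D→1D reduction on every
experiment stimulus, closed-form no-event limits, the analytic
single-peak response structure, and the experiment-level summary checks.

## CLI

```sh
# sample a hidden path + events from the generative model
pippet simulate --config config.yaml --template template.yaml --out out/ --seed 3

# run the filter over an event stream
pippet filter --config config.yaml --template template.yaml \
    --events out/events.csv --out filt/

# run a scripted experiment (writes tables, summary.csv, manifest.json)
pippet experiment alpha_vs_ioi --out exp/
pippet experiment syncopation --condition with_taps --out exp/
```

Configs are YAML; the presence of `sigma_theta` (or a 2D prior) selects
the phase/tempo filter. Template files carry `lambda_0`, optional
`period`, and `peaks: [{phi, v, lam}, ...]`. Every CLI run writes a
manifest (config echo, seed, version, warnings) sufficient to replay it.

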