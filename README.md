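# specdcm

Information-theoretic comparison of fMRI datasets through spectral dynamic
causal modelling (DCM) and hierarchical empirical Bayes.

## The problem

Resting-state and task fMRI protocols can both be used to estimate
*effective connectivity* — the directed, causal influence of one neural
population's activity on another's, in Hz — but which protocol yields
better data for that purpose? Likelihood-based statistics (Bayes factors,
F tests) cannot compare models fitted to *different* data. Bayesian data
comparison sidesteps this by asking how much each dataset taught us: the
datasets are scored by the precision of, and the information gained about,
the connectivity parameters of the same generative model fitted to each.

`specdcm` implements that pipeline end to end for region-level BOLD
timeseries, together with a synthetic rest/task generator with known
ground-truth coupling, so every stage is testable without access to any
restricted imaging data.

## The model and the indices

Per subject, neural activity follows first-order linear dynamics

    dz/dt = A z + C u(t) + v(t)

with coupling matrix `A` (between-region rates in Hz off the diagonal;
self-connections parameterized as −0.5·exp(s) Hz with unitless log-scalings
`s`), driving input `u` entering through weights `C`, and power-law
endogenous fluctuations `v`. Observed BOLD is the convolution of `z` with a
canonical haemodynamic kernel plus power-law measurement noise. The model
is fitted in the frequency domain (spectral DCM): the predicted
cross-spectral density

    G_y(f) = K(f) G_v(f) K(f)^H + G_e(f),   K(f) = h(f) (2πif·I − A)^{−1}

is matched to a multivariate-autoregressive estimate of the data
cross-spectra by variational Laplace under shrinkage priors
(A_ij ~ N(0, 1/64)), yielding a Gaussian posterior and a free energy.
Subjects are then re-inverted under grand-average priors, each dataset is
summarized by a parametric-empirical-Bayes (PEB) model
`θ_subject = Xβ + ε`, and datasets are compared through three statistics
of the group belief N(μ, Σ) over β, all in nats:

* **parameter certainty** — the negative entropy −½ ln|2πe·Σ|;
* **information gain over parameters** — KL(posterior ‖ prior);
* **information gain over models** — the discrete KL from a uniform prior
  over candidate network structures (connections switched on/off) to their
  posterior, with per-structure evidence from Bayesian model reduction.

Differences are reported relative to the worse dataset and labelled:
< 1.1 nats insufficient, 1.1–3 positive, 3–5 strong, > 5 very strong.

## Worked example

```python
from specdcm import PipelineConfig, SimulationConfig, run_pipeline

config = PipelineConfig(
    simulation=SimulationConfig(n_subjects=12, seed=0),
    output_dir="demo-out",
    seed=0,
)
report = run_pipeline(config)
for name, delta in report.differences.items():
    print(f"{name:>24}: {delta:7.3f} nats "
          f"({report.evidence_labels[name]}, best: {report.best[name]})")
```

prints (seed 0, 12 subjects per condition, task coupling 2× rest):

```
     parameter_certainty:   8.201 nats (very strong, best: rest)
    info_gain_parameters:   6.218 nats (very strong, best: task)
        info_gain_models:   0.454 nats (insufficient, best: rest)
```

Reading: the task-like dataset — stronger couplings plus a block-design
input — taught the model more about the connectivity parameters (KL gain
higher by ~6 nats, very strong evidence; the margin widens with cohort
size), while model *structures* were about equally discriminable under
both datasets. The
rest dataset's higher parameter certainty reflects that estimates of the
weaker rest couplings scatter less across subjects in absolute Hz terms,
so the group belief about them is tighter; see `docs/methods.md` for why
certainty tracks coupling scale at this run length. The same pipeline can
be pointed at real region-level TSV timeseries via the CLI
(`specdcm fit`, `specdcm compare`).

The equivalent shell session:

```bash
specdcm simulate --config config.yaml --out data/
specdcm fit --config config.yaml --data data/manifest_rest.json --rest --out fits_rest.json
specdcm fit --config config.yaml --data data/manifest_task.json --task --out fits_task.json
specdcm compare --fits-a fits_rest.json --fits-b fits_task.json \
    --label-a rest --label-b task --out report.json
specdcm report --report report.json
```

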