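# baroafferent

Modular models of baroreceptor afferent dynamics: blood pressure in,
firing rate out. A composite model chains three exchangeable stages:

1. **Arterial wall deformation** (`baroafferent.wall_models`) — pressure to
   circumferential wall strain via a linear elastic (Laplace-law) wall, a
   sigmoidal nonlinear elastic wall, or a standard-linear-solid (SLS)
   viscoelastic wall. All three are also expressible as a quasi-linear
   viscoelastic (QLV) convolution of a creep kernel with an elastic
   response, which the test suite uses as a cross-formulation oracle.
2. **Mechanoreceptor coupling** (`baroafferent.mechanoreceptors`) — wall
   strain to nerve-ending strain through 1–3 Voigt bodies in series with a
   spring, giving 1–3 adaptation timescales with closed-form
   characteristic polynomials.
3. **Firing-rate generation** (`baroafferent.neurons`) — an affine
   amplifier, or a leaky integrate-and-fire map with closed-form
   threshold-charging time, refractory ceiling, and an exact zero-rate
   branch for sub-threshold drive.

Six canonical compositions are named (`LE-V1-L` … `NLE-V2-IF`); the
preferred configuration — nonlinear wall, two Voigt bodies,
integrate-and-fire neuron — reproduces the full qualitative battery:
threshold, saturation, overshoot with two-timescale adaptation,
post-excitatory depression, hysteresis, and rectification
(`baroafferent.features` provides the detectors).

`baroafferent.estimation` implements the fitting methodology: residuals
normalized by mean firing rate, RMSE/R² costs, central finite-difference
sensitivities on log-scaled parameters, two-norm ranking, QR-SVD subset
ordering with correlation-capped greedy selection, and
Levenberg–Marquardt (smooth models) or Nelder–Mead (integrate-and-fire)
optimization, including simultaneous fits across several stimuli.
`baroafferent.fixtures_io` generates the six emulated recording protocols
(sinusoid, four pressure steps, square pulse) as seeded synthetic
datasets.

## CLI

```sh
# simulate the preferred model under a square pressure pulse
baroafferent simulate --model NLE-V2-IF --stimulus stim.json \
    --t0 0 --t1 20 --dt 0.005 --out trace.csv

# generate a synthetic dataset and fit a model to it
baroafferent make-data --protocol step4 --noise 0.02 --seed 42 --out data.csv
baroafferent fit --model LE-V2-L --data data.csv --stimulus step.json \
    --method lm --subset s1,s2,alpha1,beta1 --out fit.json

# sensitivity ranking + correlation matrix; qualitative feature report
baroafferent sensitivity --model LE-V2-L --stimulus step.json \
    --out-ranking ranking.csv --out-correlation corr.csv
baroafferent features --trace trace.csv --stimulus stim.json --out report.json
```

Stimulus/model configuration shapes are documented in
`src/baroafferent/schemas/config.schema.json`. A stimulus JSON looks like

```json
{"type": "square",
 "params": {"p_base": 140.0, "p_up": 180.0, "t_up": 4.6, "t_down": 8.7}}
```

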