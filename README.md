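# fracrad

Time-resolved modeling of tumor-cell response to **fractionated radiotherapy**.

Endpoint-only radiobiology models (the linear-quadratic family) relate dose to
a survival fraction but say nothing about *when* cells die. When live-cell
microscopy measures confluence every few hours for two weeks after treatment,
a dynamic model is needed. `fracrad` implements a two-compartment ordinary
differential equation model of glioma confluence under daily dose fractions,
together with everything required to use it as a predictive instrument: an
eight-member candidate family, AICc model selection, global bounded
least-squares calibration, delta-method prediction intervals, and held-out
validation with Pearson (PCC) and Lin concordance (CCC) coefficients. A
seeded synthetic-data generator emulates the experimental design so every
stage can be tested against known ground truth.

It is aimed at quantitative radiobiologists and mathematical oncologists who
want a tested, reproducible reference implementation of this class of model.

## The model

Untreated growth is logistic with an Allee factor,

```
dN/dt = k_p · N · (N/θ + A) · (1 − N/θ),
```

with proliferation rate `k_p` (1/hr), carrying capacity `θ` and Allee
coefficient `A` (both dimensionless; confluence is a fraction of well area).
Radiation delivered in fractions of dose `D` at times `t_i` adds three
mechanisms, each tied to a biological timescale:

- **Acute (early) death** — apoptosis driven by unrepaired double-strand
  breaks. The unrepaired fraction decays as `f_DSB(t) = exp(−k_repair(D)·t)`
  with `k_repair` linearly interpolated from a measured dose→rate table, so

  ```
  k_ed(t) = Σ_i k_acute(D, N0) · f_DSB(t_i) · tanh(s·f_DSB(t_i)),
  ```

  summed over delivered fractions (`t_i` = time since fraction `i`).
- **Accumulation (late) death** — mitotic catastrophe from accumulated
  misrepair, rising then fading as radiation efficacy decays at rate `r`:

  ```
  k_ld(t) = Σ_i k_accum(D, N0) · t_i · e^(−r·t_i)        (peak at t_i = 1/r).
  ```
- **Senescent conversion** — irreversible cell-cycle arrest moving cells from
  the proliferative compartment `N_p` into a non-dividing compartment `N_s`
  that still occupies space:

  ```
  dN_p/dt = (k_p − k_ld)·((N_p+N_s)/θ + A)·N_p·(1 − (N_p+N_s)/θ)
            − k_ed·N_p − k_ps(D_total)·N0·N_p
  dN_s/dt = k_ps(D_total)·N0·N_p.
  ```

The coefficients `k_acute` and `k_accum` may depend on dose, on seeding
density `N0`, on both (`(α·N0 + 1)·k_D·D`), or be absent; switching those
forms on and off yields the eight-model family. Model 3 — acute death driven
by density only, full late death, senescence — is the parsimonious member
typically selected on glioma data; with two total-dose arms it has six free
parameters (`k_acute_N`, `alpha_accum_N`, `k_accum_D`, `r`, `k_ps(16 Gy)`,
`k_ps(20 Gy)`). Integration is explicit forward Euler at 0.01 hr, verified
against an adaptive Runge–Kutta reference to <0.5%.

## Worked example

Calibrate the selected model on a synthetic training split (21% measurement
noise) and score held-out predictions:

```python
import fracrad as fr
from fracrad.model import FractionatedRadiationModel

truth = fr.default_truth(dt=0.05)              # synthetic ground truth
dataset = fr.generate_dataset(truth, seed=11)
train, val = fr.train_validation_split(dataset, seed=12)

line = truth.cell_lines["9L"]
curves = [c for c in train if c.cell_line == "9L"]
model = FractionatedRadiationModel(curves, fr.model_family()[2],
                                   line.growth, line.kinetics, dt=0.05)
result = model.fit(n_starts=3, seed=2, max_nfev=300)
print(result.summary())

metrics = fr.validate({"9L": result}, [c for c in val if c.cell_line == "9L"])
print(metrics.overall().to_string(index=False))
```

```
Fractionated radiation response calibration
==============================================================
model 3 (early:density_only)
curves: 36   observations: 2397   free parameters: 6
RSS: 2.22851   scale (RSS/dof): 0.000932042   converged: True
--------------------------------------------------------------
parameter           estimate     std err      [95% conf. int.]
k_acute_N            0.43623       0.009     0.4186     0.4539
alpha_accum_N     3.3313e-18       0.124    -0.2437     0.2437
k_accum_D         0.00015894     4.4e-06  0.0001503  0.0001676
r                   0.016772    0.000271    0.01624     0.0173
k_ps_16             0.034829     0.00154     0.0318    0.03786
k_ps_20             0.059929     0.00197    0.05606     0.0638

cell_line  pcc_mean   pcc_se  ccc_mean   ccc_se  n_replicates
       9L  0.891077 0.014981  0.816637 0.020756            12
```

Reading the output: the late-death parameters `k_accum_D` (per Gy per hr²)
and `r` (the efficacy-decay rate, ~0.017/hr ⇒ peak killing near 60 h after a
fraction) and the two conversion rates are sharply estimated; the
density-scale parameters are weakly identified because the initial condition
is itself a noisy measurement (`alpha_accum_N` collapses to its zero bound
and `k_acute_N` absorbs the difference). On the 12 held-out replicates the
predictions reach a mean PCC of 0.89 and CCC of 0.82: strong linear
association and good absolute agreement.

The same workflow is available from the shell:

```sh
fracrad pipeline --config demo.yaml --seed 1 --out out/
```

which generates data, splits 75/25 per condition, performs AICc selection
over all eight models per cell line, calibrates the winner, and writes
selection/calibration/validation reports (deterministic for a fixed
config + seed).

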