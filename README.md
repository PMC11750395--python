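# germflow

Seed germination and seedling tillering of field-sown cereals, modelled as
advection–dispersion transport along a **physiological axis** — with the
solvers, calibration machinery and synthetic field-trial generator needed to
fit the model to daily emergence and tiller counts.

## The model

A seed's development is tracked by a coordinate *x* that runs from the onset
of imbibition (*x* = 0) through seedling emergence (*x* = *L*₀ = 1) to
completed tillering (*x* = *L*₁ = 2).  Metabolic progress fluctuates with the
environment and varies between seeds, so the seed-density *n*(*x*, *t*)
obeys a drift–diffusion equation per stage:

    ∂n/∂t = D ∂²n/∂x² − u ∂n/∂x

where *u* (units day⁻¹) is the mean **germination speed** (drift) and *D*
(units² day⁻¹) the **dispersion coefficient** (seed heterogeneity plus
environmental fluctuation).  Seeds start as a pulse of *N*₀ at *x* = 0; the
advective outflux *u·n*(*L*₀, *t*) is the emergence rate, and each emerged
seedling seeds γ potential tillers into a second stage with its own
(*u_T*, *D_T*).  In dimensionless variables α = *D*/(*u L*₀), τ = *u t*/*L*₀
the cumulative emergence curve is, to leading order,

    E(τ) = ½ erfc((1 − τ) / √(4 α τ))

with an optional boundary-correction term (negligible for Péclet number
*u L*₀/*D* ≫ 1).  An explicit second-order finite-volume scheme integrates
the coupled two-stage system, respecting the advective CFL, cell-Péclet and
explicit-diffusion constraints.

Calibration follows the field procedure: grid search over (*u*, *D*)
maximising R² against pooled replicate counts, germination first, then
tillering with the germination parameters frozen.  Per-treatment speeds are
linked to drivers through the empirical response

    u_G = [a(T − T₀) − b(T − T₀)²] · Θ^β (Θ − Θ_r) (Θ₀ − Θ)^β

(*T* = time-averaged air temperature, Θ = soil water content as a fraction
of field capacity; the hump-shaped Θ factor captures the water-supply vs
oxygen-availability trade-off).  A classical hydrotime model with
Weibull-distributed base water potential is included as a comparison
baseline, and a random-walk micro-simulator provides an independent check of
the continuum limit.

Who it is for: crop-physiology and agronomy researchers fitting emergence
and tillering dynamics to drilling-trial counts, and modellers who want a
transparent mechanistic alternative to hydrothermal-time formulations that
runs on forecastable drivers (air temperature, topsoil water content).

## Worked example

```python
import numpy as np
from germflow import GerminationModel, ObservationSeries, synthetic

# daily counts of 100 seeds in a 1 m row section, truth u=0.10, D=0.005
days = np.arange(1.0, 21.0)
obs = synthetic.generate_observations(days, 0.10, 0.005, n_seeds=100, seed=1)

res = GerminationModel(obs).fit()
print(res.summary())
```

```
Germination stage calibration (grid search, R^2)
================================================
observations                20
u_G  [1/day]            0.0996
D_G  [1/day]           0.00477
Peclet u*L0/D             20.9
R^2                     0.9990
median emergence          9.59 days
refined                   True
```

The fitted speed 0.0996 day⁻¹ means the average seed advances ~10% of the
germination stage per day (median emergence near day 10); the dispersion
0.0048 spreads emergence over roughly a week; R² ≈ 0.999 is the fit quality
against the noisy counts, and both estimates sit close to the generating
truth (0.10, 0.005).  `EnvResponseModel` then maps per-treatment speeds
to temperature and moisture, and `TilleringModel`/`StudyModel` extend the
fit through tillering.  The same pipelines are scriptable from the shell:

```bash
germflow synth --out bundle --seed 3        # synthetic 3x3 drilling trial
germflow calibrate --bundle bundle --out params.csv
germflow fit-env --points points.csv --out env.yaml
germflow predict --drivers weather.csv --out forecast.csv
```

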