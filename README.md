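# aqbd

Analytical Quality by Design (AQbD) toolkit for chromatographic method
optimization: response-surface designs, quadratic factor–response models,
Monte Carlo design spaces, and robustness verification.

## The problem

Developing a robust HPLC method means more than finding one set of
conditions that works. AQbD asks for a *region* of operating conditions —
the design space, or method operable design region (MODR) — inside which
the method's critical attributes are met with high assurance, so routine
variation in instrument settings cannot silently break the separation.

This package implements that workflow for a method with controllable
**critical method parameters** (CMPs; e.g. mobile-phase organic fraction,
flow rate, column temperature) and measured **critical method attributes**
(CMAs; e.g. peak resolutions, run time):

1. **Design** — face-centred central composite (CCF) designs
   (`generate_ccf`: 2^k corners + 2k face points + centre replicates) and
   2-level full factorials for verification.
2. **Model** — per response, a quadratic polynomial in coded factors
   `y = b0 + Σ bᵢxᵢ + Σ bᵢᵢxᵢ² + Σ bᵢⱼxᵢxⱼ + e` fitted by OLS, pruned by
   hierarchy-preserving backward elimination (α = 0.05), and summarised by
   R², adjusted R², cross-validated Q² = 1 − PRESS/SS_tot, reproducibility
   1 − MS_pure-error/MS_total, and the regression ANOVA p-value.
3. **Design space** — the sweet spot (all criteria met at the model mean)
   and the MODR: Monte Carlo propagation of coefficient uncertainty (and
   replicate noise) gives the probability of jointly meeting all CMA
   criteria at each grid point; the region keeps points at ≥ 99% assurance.
4. **Optimize & verify** — grid + Nelder–Mead search for the operating
   point maximizing pass probability (ties broken by normalized margin to
   the limits), and per-run criteria checks for verification designs.

The package bundles the celecoxib impurity-method study as a worked
dataset: a 17-run CCF over acetonitrile % (42–50), flow rate
(0.5–1.0 mL/min) and column temperature (30–40 °C) with four CMAs — three
resolutions (R1 ≥ 2.3, R2 ≥ 3.2, R3 ≥ 2.0) and the retention time of the
last-eluting impurity (RT ≤ 45 min).

## Worked example

```python
from aqbd import backward_eliminate, fit_statistics, mc_pass_probability
from aqbd.datasets import celecoxib_cmas, load_celecoxib_ccf

design = load_celecoxib_ccf()
cmas = celecoxib_cmas()
models = [backward_eliminate(design, c.response_name) for c in cmas]
for m in models:
    s = fit_statistics(m, design)
    print(m.response_name, round(s.r2, 3), round(s.q2, 3),
          round(s.reproducibility, 4))
opt = {"acetonitrile": 44.918, "flow_rate": 0.795, "temperature": 39.998}
print("assurance:", mc_pass_probability(models, cmas, opt, seed=20200813))
```

prints

```
R1 0.999 0.997 0.9986
R2 0.999 0.998 1.0
R3 1.0 0.997 0.9995
RT 0.996 0.963 1.0
assurance: 1.0
```

— each response model explains (R²) and cross-predicts (Q²) its data
almost perfectly, centre replicates are tight (reproducibility ≈ 1), and
the probability of meeting all four criteria at the optimal conditions is
effectively 1, comfortably above the 99% assurance level.

The `examples/` directory walks through each capability (design
generation, model fitting, design-space mapping, verification and
recovery arithmetic, synthetic calibration); each script prints its
numbers with a short interpretation. A thin CLI mirrors the stages:
`aqbd design | simulate | fit | sweetspot | modr | optimize | verify |
report`, driven by a YAML study config (see
`src/aqbd/data/celecoxib.yaml`).

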