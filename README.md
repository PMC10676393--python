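# clpnet

Cross-lagged panel network (CLPN) analysis of dichotomous depression
symptoms in multi-wave panel data.

## The problem

Ageing-cohort studies typically track depression with a sum score over a
short symptom inventory (here the eight-item CES-D with yes/no responses),
which hides how individual symptoms drive one another over time. The
network approach instead asks, for every pair of symptoms *j* and *k*:
does endorsing *j* at wave *t* predict endorsing *k* two years later,
over and above all other wave-*t* symptoms? Answering that across eight
consecutive wave pairs reveals which symptoms are precursors (strong
outgoing paths), which are endpoints of symptom cascades (strong incoming
paths), and whether those roles are stable across 16 years of follow-up.

`clpnet` implements that analysis end to end for researchers working with
binary symptom panels: descriptive tables, missing-data handling (Little's
MCAR test, dropout models, chained-equations imputation), CLPN estimation,
cross-sectional Ising networks, bootstrap accuracy/stability machinery,
and cross-network consistency statistics. Because the motivating cohort
data are access-restricted, the package ships a calibrated synthetic-data
generator so the full pipeline is reproducible and testable against a
known ground truth.

## The model

For each consecutive wave pair *t → t+1* and each symptom *k*, a lasso
logistic regression

  logit P(yₖ,ₜ₊₁ = 1) = b₀ₖ + Σⱼ βⱼₖ yⱼ,ₜ + γ₁·gender + γ₂·ethnicity

is fit with the penalty chosen by stratified 10-fold cross-validated
deviance (one-standard-error rule by default). The matrix B = [βⱼₖ] is a
directed network on the log-odds scale: diagonal entries are
autoregressive paths, off-diagonal entries cross-lagged paths, and
exp(βⱼₖ) is the edge's odds ratio (OR 1 = no association). Node
centrality is cross-lagged expected influence: in-EI(k) = Σⱼ≠ₖ βⱼₖ
(how strongly a symptom is predicted by the others) and out-EI(j) =
Σₖ≠ⱼ βⱼₖ (how strongly it predicts the others). Edge accuracy comes from
nonparametric bootstrap percentile CIs, stability from case-drop
bootstrap with CS-coefficients, and formal contrasts from bootstrap edge
and centrality difference tests. See `docs/methods.md` for details and
design choices.

## Worked example

```python
import numpy as np
from clpnet import (default_ground_truth, simulate_panel, fit_clpn,
                    expected_influence)

spec = default_ground_truth(seed=42, n_waves=2)   # study-calibrated truth
panel = simulate_panel(spec, 5000, seed=42)       # 5000 subjects, 2 waves
net = fit_clpn(panel, wave=1, seed=42)            # node-wise CV lasso

cross = net.cross_lagged()                        # 8x8, log-odds
top = np.dstack(np.unravel_index(
    np.argsort(-np.abs(cross), axis=None), cross.shape))[0][:3]
for i, j in top:
    print(f"{net.outcome_labels[i]:>14} -> {net.outcome_labels[j]:<14} "
          f"OR = {np.exp(cross[i, j]):.2f}")
print(expected_influence(net).to_frame().round(2))
```

Output:

```
        effort -> depressed      OR = 1.60
        effort -> get_going      OR = 1.59
     get_going -> effort         OR = 1.45
                in_ei  out_ei  in_ei_z  out_ei_z
item
depressed        0.80    0.00     1.96     -0.88
effort           0.47    0.93     0.72      2.13
restless_sleep   0.00    0.10    -1.01     -0.57
happy            0.26    0.00    -0.06     -0.88
lonely           0.00    0.53    -1.01      0.84
enjoyed_life     0.00    0.26    -1.01     -0.06
sad              0.20    0.00    -0.28     -0.88
get_going        0.47    0.37     0.71      0.31
```

The strongest recovered paths are the reciprocal fatigue edges
(*everything was an effort* ↔ *could not get going*, ORs 1.45–1.60) that
the generator encodes; *feeling depressed* has the highest in-expected-
influence (z = 1.96) while *effort* dominates out-expected-influence
(z = 2.13) — it predicts other symptoms more than any other item. An edge
weight is a conditional two-year log-odds effect, so OR 1.60 means the
odds of feeling depressed at the next wave are 60% higher when everything
was an effort at this wave, holding the other seven symptoms fixed.

## The full analysis

The numbered drivers under `analysis/` run the complete story on a
simulated 9-wave cohort (n = 2,000, ~69% cumulative attrition) and write
all tables under `results/`:

    01_simulate.py       panel + attrition from the calibrated spec
    02_describe.py       endorsement / moments / alphas per wave
    03_missingness.py    Little's MCAR test, dropout model, imputation
    04_fit_networks.py   the eight CLPNs + expected-influence centrality
    05_ising.py          per-wave Ising networks vs temporal structure
    06_bootstrap.py      edge CIs, difference tests, case-drop stability
    07_compare.py        cross-network replication and correlations

`clpnet.run_pipeline(config, out_dir)` runs the same stages from a single
YAML config and writes a manifest, edge lists (log-odds and OR scales) and
GraphML files.

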