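# rfdti — random-forest threshold imputation for cognitive diagnosis data

Missing responses are endemic in cognitive diagnosis assessments
(targeted subtests, balanced incomplete blocks, examinee omissions), and
the missingness mechanism is usually unknown and possibly nonignorable.
`rfdti` implements two machine-learning imputation methods built for this
setting — **RFTI** (random forest threshold imputation) and its
generalisation **RFDTI** (random forest *dynamic* threshold imputation) —
plus everything needed to study them: DINA-model simulation and EM
estimation, MCAR/MAR/MNAR/MIXED missingness generators, four traditional
baseline imputers (person mean, two-way, EM, multiple imputation), and
attribute-classification scoring.

## The method in brief

Iterative chained random forests predict, for every missing cell, the
probability `p_ij` that the response is 1. Instead of rounding everything,
cells are imputed only when the forest is confident:

```
Y_ij = 1    if p_ij >= tau_u        (confident correct)
Y_ij = NA   if tau_l < p_ij < tau_u (left missing on purpose)
Y_ij = 0    if p_ij <= tau_l        (confident incorrect)
```

RFTI fixes `tau_l = 0.5`; RFDTI searches both thresholds on a grid. Each
candidate thresholding is scored by fitting the DINA model

```
P_j(alpha_i) = (1 - s_j)^{eta_ij} * g_j^{1 - eta_ij},
eta_ij = prod_k alpha_ik^{q_jk}
```

to the imputed matrix (remaining NA ignored) and computing the mean
adapted response-conformity person-fit index RCI_C-bar, which penalises
imputed responses that contradict the fitted model's ideal response
patterns; the grid pair minimising it wins. See `docs/methods.md` for the
full account.

## Worked example

```python
import numpy as np
from rfdti import (
    generate_q_matrix, simulate_profiles, simulate_item_params,
    simulate_responses, select_subsample, apply_mcar, rfdti, RFConfig,
    pca,
)
from rfdti.dina_core import fit_dina_em

q = generate_q_matrix(30, 3, seed=1)            # 30 items, 3 attributes
profiles = simulate_profiles(400, 3, seed=2)    # correlated mastery profiles
params = simulate_item_params(30, seed=3)       # s, g ~ U(0.05, 0.25)
complete = simulate_responses(profiles, q, params, seed=4)

sub = select_subsample(400, 0.8, seed=5)        # 320 examinees get missingness
missing = apply_mcar(complete, 0.10, sub, seed=6)
print(f"input missing rate: {100 * missing.missing_rate:.2f}%")

result = rfdti(missing, q, stepV=0.1, rf_config=RFConfig(n_trees=50), seed=7)
print(f"thresholds: tau_l={result.thresholds.tau_l:.2f}, "
      f"tau_u={result.thresholds.tau_u:.2f}")
print(f"RCI_C_bar: {result.rci_mean:.4f}")
print(f"remaining missing: {100 * result.remaining_missing_rate:.2f}%")
print(f"PCA vs truth: {pca(result.fit.map_profiles, profiles.profiles):.3f}")
```

Output:

```
input missing rate: 7.72%
thresholds: tau_l=0.30, tau_u=0.50
RCI_C_bar: 0.2444
remaining missing: 0.69%
PCA vs truth: 0.950
```

Reading: 10% MCAR missingness was imposed on the cells of an 80%
subsample (7.72% of all cells). The grid search settled on a narrow NA
band, imputing all but 0.69% of cells, and the refitted DINA model
recovers 95.0% of attribute patterns exactly. Cells left NA are ones the
forest could not call confidently; they are simply ignored by the
downstream EM.

The same workflow is scriptable from a shell:

```
rfdti impute --data missing.csv --q q.csv --method rfdti \
      --stepv 0.05 --seed 7 --out imputed.csv
rfdti simulate --config study.yaml --out results/
```

`impute` writes the imputed matrix plus a `*_grid.csv` with
(tau_l, tau_u, RCI_C_bar, remaining rate) per grid cell; `simulate` runs a
factorial mechanism x proportion x N x K study from a YAML config and
writes tidy and aggregated CSVs with a JSON run manifest.

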