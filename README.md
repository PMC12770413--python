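# oncosurv

Multimodal tumor analysis at desk scale: iterative encoder-decoder
segmentation, CNN/MLP feature fusion with cross-attention, lung-cancer
subtype classification, deep Cox proportional-hazards survival modelling
with elastic-weight-consolidation (EWC) updates, Gaussian-process UCB
hyperparameter tuning, and exact Shapley feature attribution — all
exercised end-to-end on seeded synthetic cohorts with known ground truth.

The package is aimed at method developers who want every stage of an
integrated imaging + genomics + survival pipeline to be testable on a
laptop, without any external data: the built-in simulator generates 2-D
grayscale "scans" with binary tumor masks, genomic vectors (mutation
flags + expression values), clinical covariates, three histology-like
subtypes and right-censored survival times drawn from a
proportional-hazards model whose linear predictor is retained as oracle
ground truth.

## Models

**Segmentation.** A depth-3 U-Net-style encoder/decoder (skip
connections, base 16 channels) trained with the combined loss
`L = CE(S(x), y) + α (1 − Dice(S(x), y))`. Inference iterates
`L_{t+1} = L_t + λ (f(x, σ(L_t)) − L_t)`: the previous soft mask re-enters
as a second channel and a λ-scaled correction updates the logits. The
loop stops when the relative Dice improvement falls below 0.5% or the
loss change below 0.001 for two consecutive iterations, or after six
cycles.

**Fusion and classification.** Spatial features come from a small CNN on
the mask-gated image, biological features from an MLP with a sigmoid
output embedding. Fusion modes: concatenation `[F_img; F_gen]`,
element-wise sum, or cross-attention
`softmax(QKᵀ/√d_k)` with four heads, producing
`F_fusion = Σ_m a_m F_m + F_img`; a softmax head yields subtype
probabilities.

**Survival.** A deep Cox model `h(t|x) = h0(t) exp(f(x))` with a neural
(or linear) risk network trained on the negative log partial likelihood
(Breslow ties), Breslow baseline cumulative hazard, Harrell's concordance
index, and hazard-ratio risk groups (low < 1.0 ≤ medium < 1.2 ≤ high).
EWC updates minimise `L_new(θ) + (λ/2) Σ F_i (θ_i − θ_i*)²` with a
diagonal empirical Fisher, so new patient batches refine the model
without catastrophic forgetting.

**Tuning and attribution.** GP-UCB Bayesian optimisation
(`α(x) = µ(x) + κ σ(x)`, squared-exponential surrogate) tunes
hyperparameters; Shapley values
`φ_i = Σ_S |S|!(n−|S|−1)!/n! (f(S∪{i}) − f(S))` with background-mean
imputation explain classifier and risk outputs, exactly for ≤ 15 features.

All neural components run on a compact numpy reverse-mode autodiff core
(`oncosurv._nn`), gradient-checked against finite differences.

## Worked example

```python
import numpy as np
from oncosurv import simulate, survival, explain

df = simulate.generate_survival_table(400, beta=(1.0, -0.8, 0.5),
                                      censor_fraction=0.3, seed=7)
x = df[["x1", "x2", "x3"]].to_numpy()
state = survival.fit_deepsurv(x, df["time"], df["event"], hidden=(), seed=7)
print("coefficients:", np.round(state.coefficients(), 3))
c = survival.concordance_index(state.hazard_ratios(x), df["time"], df["event"])
print("concordance index:", round(c, 3))

rep = explain.exact_shapley(lambda rows: state.risk_scores(rows), x[0], x,
                            feature_names=["x1", "x2", "x3"])
print("phi:", np.round(rep.phi, 3), "sum:", round(rep.overall_score, 3))
```

prints

```
coefficients: [ 0.93  -0.768  0.451]
concordance index: 0.772
phi: [ 0.101 -0.29  -0.109] sum: -0.297
```

The fitted linear risk network recovers the generating log-hazard
coefficients (1.0, −0.8, 0.5) to within sampling error; the concordance
index 0.772 says 77% of comparable patient pairs are ranked correctly by
predicted risk; the Shapley values decompose this patient's log hazard
ratio relative to the cohort mean, and sum exactly to
`f(x) − f(background)` (the efficiency property).

The same flow is available from the shell:

```bash
oncosurv simulate --out cohort/ --seed 1
oncosurv train-seg  --cohort cohort/ --out seg.npz   --seed 1
oncosurv train-clf  --cohort cohort/ --out clf.npz   --metrics clf.json --seed 1
oncosurv train-surv --cohort cohort/ --out surv.npz  --risk-csv risk.csv --seed 1
oncosurv explain    --model surv.npz --cohort cohort/ --patient P0001 --out shap.json
oncosurv run        --out run/ --seed 1        # full pipeline + metrics.json
```

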