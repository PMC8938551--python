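# isletraj

Continuous-time hidden Markov modelling of islet-autoantibody
progression toward type 1 diabetes.

Children at risk for type 1 diabetes are followed from infancy with
repeated measurements of three islet autoantibodies — GADA, IAA and
IA-2A.  Individual antibody histories are heterogeneous: some children
acquire several antibodies at once, others add IAA or GADA first, and
progression speed to clinical diabetes differs between these routes.
`isletraj` provides the full analysis stack to discover and
characterise such latent progression trajectories from irregularly
sampled binary antibody panels:

* a **continuous-time hidden Markov model (CT-HMM)**: the latent health
  state evolves as a Markov jump process with rate matrix `Q` (so
  transition probabilities over a visit gap `Δt` are `expm(Q Δt)`), and
  each state emits the three antibodies as independent Bernoulli
  variables.  Parameters are estimated by EM with
  endpoint-conditioned expected dwell times and jump counts, computed
  in closed form through the eigendecomposition of `Q`;
* **model-order selection** by repeated 70/30 participant-level splits
  scored with BIC and held-out predictive log-likelihood;
* **trajectory decomposition**: fitted states are pruned at a small
  rate threshold and split into disjoint ordered chains (TR1
  multiple-antibody-first, TR2 IAA-first, TR3 GADA-first), visits are
  labeled by Viterbi decoding, and participants are assigned to chains;
* **downstream statistics**: seroconversion ages, chi-square
  association tests, one-way ANOVA with Tukey HSD, Kaplan–Meier
  diabetes-free survival from state entry with log-rank tests;
* a **synthetic cohort generator** calibrated to the published 11-state
  / 3-trajectory model, so the entire pipeline runs and is tested
  without access to any protected study data.

The core estimator follows scikit-learn conventions (`CTHMM` with
`fit`, `predict`, `score`, `get_params`); module-level functions
(`em_fit`, `forward_backward`, `viterbi_label`, …) are thin wrappers.

## Worked example

```python
from isletraj import CTHMM, GroundTruthConfig, make_ground_truth_model, simulate_cohort
from isletraj.pipeline import analyze_cohort

sim = simulate_cohort(GroundTruthConfig(n_participants=500, seed=0))
cohort = [s for s in sim.participants if s.n_visits >= 2]

# estimate a CT-HMM from the antibody panels alone
model = CTHMM(n_states=11, n_restarts=5, random_state=11).fit(cohort)
print(f"mean per-visit loglik of the fit: {model.score(cohort):.3f}")

# trajectory + survival analysis, here with the calibrated 11-state model
params = make_ground_truth_model(sim.config)
result = analyze_cohort(params, cohort)
stats = result["stats"]
print("chain sizes:", stats["chain_sizes"])
print("ambiguous participants:", stats["exclusions"]["n_ambiguous"])
print("5-year diabetes-free survival by trajectory:")
for tr, s in sorted(stats["logrank_trajectory"]["survival_at_5y"].items()):
    print(f"  {tr}: {s['estimate']:.2f} ({s['ci_low']:.2f}-{s['ci_high']:.2f})")
print(f"overall log-rank p = {stats['logrank_trajectory']['overall']['p_value']:.2e}")
```

prints

```
mean per-visit loglik of the fit: -0.922
chain sizes: [3, 5, 3]
ambiguous participants: 0
5-year diabetes-free survival by trajectory:
  TR1: 0.26 (0.18-0.34)
  TR2: 0.73 (0.61-0.82)
  TR3: 0.85 (0.77-0.90)
overall log-rank p = 1.26e-32
```

Diabetes-free survival after entry into the first antibody-positive
state is ordered TR1 < TR2 < TR3, the ordering the generator is
calibrated to.  Analysing with the fitted model instead
(`analyze_cohort(model.params_, cohort)`) works the same way, but at
this cohort size EM fits often merge the three near-identical
antibody-negative start states, in which case the decomposition reports
fewer or joined chains (see `docs/methods.md`, Known limitations).

A command-line interface mirrors the pipeline:

```bash
isletraj simulate --seed 0 --n 500 --out cohort/
isletraj fit --cohort cohort/ --n-states 11 --out model.json
isletraj select --cohort cohort/ --states 8-14 --n-reps 5 --out sel/
isletraj analyze --cohort cohort/ --model model.json --out analysis/
isletraj report --cohort cohort/ --model model.json --out report/
```

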