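"""Bayesian sequential model-based optimisation of a hyperparameter.

A Gaussian-process surrogate (Matern 5/2) models the objective; each round
evaluates the candidate maximising expected improvement
EI(x) = E[max(f(x) - f*, 0)]. Demonstrated on a 1-D objective with a known
maximum, then on the random-forest depth for a small simulated cohort.
"""

from dataclasses import replace

import gaitstate as gs
from gaitstate.evaluation import confusion
from gaitstate.modeling import (
    ClassifierSpec, SearchSpace, smbo_optimize, split_70_30, train_classifier,
)

# known-optimum demonstration
best, trace = smbo_optimize(
    SearchSpace({"x": ("float", 0.0, 1.0)}),
    lambda p: 1.0 - (p["x"] - 0.62) ** 2,
    n_init=8, n_iter=22, seed=0,
)
print(f"quadratic argmax: found x={best['x']:.4f} (true 0.62) in {len(trace)} trials")

# tuning the forest depth on simulated data
on = replace(gs.ON_DEFAULT, duration_s=60.0)
off = replace(gs.OFF_DEFAULT, duration_s=60.0)
cohort, _ = gs.simulate_cohort(6, on, off, seed=3)
table = gs.featurize_cohort(cohort)
train, test = split_70_30(table, seed=3)


def objective(params):
    model = train_classifier(ClassifierSpec("random_forest", params), None, train, seed=3)
    cm = confusion(test["label"].to_numpy(), model.predict(test))
    return (cm.tp + cm.tn) / cm.total


best, trace = smbo_optimize(
    SearchSpace({"max_depth": ("int", 2, 16)}), objective, n_init=4, n_iter=6, seed=3
)
print(f"best max_depth {best['max_depth']} with held-out accuracy "
      f"{max(t.score for t in trace):.3f}")
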