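"""Learn the network structure with the adaptive group lasso.

Simulates a 2,000-subject cohort from the 5-condition truth, cross-validates
the penalty weight over the decade grid {0, 1, 10, ..., 1e6}, refits at the
selected value, and compares the recovered directed edges with the generating
model's six true edges.
"""

import numpy as np

import fctbn
from fctbn import fixtures
from fctbn.learning import DEFAULT_LAMBDA_GRID, cross_validate, fista_fit, \
    fit_unpenalized, make_penalty
from fctbn.postprocess import extract_structure

spec = fixtures.default_sim_spec(n_subjects=2000, horizon=10.0, seed=3)
cohort = fctbn.generate_cohort(spec)

cv = cross_validate(spec.structure, cohort, DEFAULT_LAMBDA_GRID, k_folds=3, seed=3)
print("lambda grid ", [f"{l:g}" for l in cv.lambdas])
print("cv error    ", [f"{e:.4f}" for e in cv.cv_errors])
print(f"selected lambda = {cv.best_lambda:g}  (held-out NLL per sojourn record)")

beta_tilde = fit_unpenalized(spec.structure, cohort, ridge=1e-8)
fit = fista_fit(spec.structure, cohort, make_penalty(beta_tilde, cv.best_lambda),
                init=beta_tilde)
graph = extract_structure(fit.coefficients)
print(f"\nrecovered edges (weight = acquisition hazard ratio at the mean profile):")
for u, v, d in sorted(graph.edges(data=True)):
    flag = "true" if (u, v) in fixtures.TRUE_EDGES else "spurious"
    print(f"  {u:5s}->{v:5s}  x{d['weight']:.2f}  [{flag}]")
missed = set(fixtures.TRUE_EDGES) - set(graph.edges)
print(f"missed true edges: {sorted(missed) if missed else 'none'}")
print("\nAn edge means the parent condition multiplies the child's onset rate;")
print("zeroed coefficient groups are edges the penalty removed entirely.")
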