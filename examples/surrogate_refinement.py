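"""Surrogate-guided refinement of model parameters.

The optimal-interpolation metamodel learns the mapping from parameters
to the campaign force response from a handful of simulator runs, then
proposes new parameters to evaluate.  Here the reduced order model
stands in for an expensive simulator and the two mapping scales
(p8, p9) are refined against a noiseless reference response: pooled R^2
reaches ~1 within ten simulator calls.
"""

from dataclasses import replace

import numpy as np

from pdlrom import SampleSet, builtin_test_table, generate_campaign, refine_loop
from pdlrom.hyperelastic import StressStrainMapping
from pdlrom.reference import campaign_fit_params

truth = campaign_fit_params()
protocols = builtin_test_table()


def response(params):
    recs = generate_campaign(params, protocols)
    return np.concatenate([r.forces[::20] for r in recs
                           if not r.protocol.discarded])


lo = np.array([truth.mapping.p8 * 0.5, truth.mapping.p9 * 0.5])
hi = np.array([truth.mapping.p8 * 1.5, truth.mapping.p9 * 1.5])


def simulator(unit_point):
    p8, p9 = lo + unit_point * (hi - lo)
    return response(replace(truth, mapping=StressStrainMapping(p8=p8, p9=p9)))


corners = np.array([[0.1, 0.1], [0.9, 0.1], [0.1, 0.9], [0.9, 0.9]])
samples = SampleSet(points=corners,
                    responses=np.stack([simulator(c) for c in corners]))
result = refine_loop(simulator, samples, response(truth), budget=10,
                     grid_points=21, seed=1)
best = lo + result.best_point * (hi - lo)
print("R2 after each simulator call:",
      " ".join(f"{r:.3f}" for r in result.history))
print(f"best: p8 = {best[0]:.5f} MPa/N, p9 = {best[1]:.4f} 1/mm "
      f"(truth {truth.mapping.p8}, {truth.mapping.p9})")
print(f"pooled R2 = {result.best_r2:.4f} after {result.n_evaluations} calls")
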