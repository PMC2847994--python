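"""Evolution-strategy parameter estimation against a reference time course.

A 5-species ODE model (translocation, association, export as mass-action
steps) generates a noiseless reference at known rates; the self-adaptive
(mu + lambda) ES then recovers those rates from the trajectory alone using
least-squares fitness.
"""

import numpy as np

from ddssa.dde import ODEModel5, integrate_ode5
from ddssa.fitting import ESConfig, FitProblem, es_optimize

truth = np.array([0.15, 0.002, 0.3])
init = {"A_c": 500.0, "B_n": 500.0}
grid = np.linspace(0.0, 60.0, 121)


def solve(theta):
    return integrate_ode5(ODEModel5.from_params(theta, init), 60.0, t_eval=grid)


problem = FitProblem(solve=solve, reference=solve(truth),
                     sample_times=grid[::2],
                     bounds=np.array([[0, 1.5], [0, 0.02], [0, 3.0]]))
config = ESConfig(mu=5, lam=30, generations=60, runs=3, seed=11)
best, fitness, traces = es_optimize(problem, config)

print("        truth   recovered")
for name, a, b in zip(("k_t1", "k_a ", "k_t2"), truth, best):
    print(f"{name}: {a:9.4f} {b:11.4f}")
print(f"\nfinal least-squares fitness: {fitness:.3g}")
print(f"best-so-far trace is non-increasing: "
      f"{all(y <= x for tr in traces for x, y in zip(tr, tr[1:]))}")
print("-> elitist ES with log-normal step adaptation recovers the generating rates")
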