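"""Build a translocation delay distribution from 1D first-passage statistics.

A particle diffuses on a 3.52 um interval with an absorbing wall at 0 and a
reflecting wall at the far end, starting 0.81 um from the reflecting wall.
Two independent routes to the arrival-time CDF -- 10,000 lattice random walks
and a finite-volume solve of the diffusion equation -- are compared by their
Kolmogorov-Smirnov distance.
"""

import numpy as np

from ddssa.delays import (Diffusion1DProblem, empirical_cdf, random_walk_1d,
                          solve_arrival_pde)

L, start_from_right, step, dt = 3.52, 0.81, 0.001, 0.001
x0 = L - start_from_right          # distance to the absorbing wall
D = step**2 / (2 * dt)             # walk and PDE share this physical clock

record = random_walk_1d(10_000, step, L, x0, rng_or_seed=42, dt=dt)
walks = empirical_cdf(record)

pde = solve_arrival_pde(
    Diffusion1DProblem(D=D, L=L, x0=x0, dx=0.01, dt_pde=4.0), t_end=80_000.0)

grid = np.sort(record.event_times)
ks = np.max(np.abs(walks.cdf(grid) - pde.cdf(grid)))

print(f"mean arrival time (walks):    {record.event_times.mean():10.1f} s")
print(f"analytic mean x0(2L-x0)/2D:   {x0 * (2 * L - x0) / (2 * D):10.1f} s")
print(f"median arrival (PDE):         {pde.median:10.1f} s")
print(f"KS distance walks vs PDE:     {ks:10.4f}  (1% bound: 0.0163)")
print("-> either CDF can now be fed to the delay-SSA as a translocation delay")
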