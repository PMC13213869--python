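"""Compare the three stack-of-spirals acquisition orderings.

Builds the full 350 s schedule for each ordering (fixed angle per slice
loop, rotation per TR with linear kz, rotation per TR with Gaussian
variable-density kz), sorts every TR into 25 cardiac phases under a
stochastic beat model, and prints the mean percentage of the 119 rotation
angles acquired at the central kz partition per phase.  The variable-
density ordering concentrates samples at the k-space center, roughly
doubling the central fill -- the motivation for using it.
"""

import numpy as np

from cineimoco.trajectory import (
    SCHEME_FIXED, SCHEME_PER_TR, SCHEME_VARIABLE,
    build_schedule, coverage_report, kz_density_profile,
)
from cineimoco.gating import cardiac_phase_labels
from cineimoco.phantom import simulate_ecg_triggers

P, A, TR, DURATION, C = 80, 119, 4.5, 350_000.0, 25
triggers = simulate_ecg_triggers(DURATION, 1000.0, 50.0,
                                 np.random.default_rng(101))

print(f"{'ordering':42s} central-partition fill (% of {A} angles/phase)")
for scheme, sigma in [(SCHEME_FIXED, None), (SCHEME_PER_TR, None),
                      (SCHEME_VARIABLE, 10.8)]:
    density = kz_density_profile(P, sigma) if sigma else None
    sched = build_schedule(scheme, P, A, TR, DURATION, density=density,
                           seed=1)
    labels = cardiac_phase_labels(sched.times, triggers, C)
    rep = coverage_report(sched, labels, n_phases=C)
    print(f"{scheme:42s} {rep.center_fill_percent:5.1f}")
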