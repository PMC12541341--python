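"""OPES-enhanced barrier crossing on a 1D double well.

A 12 kJ/mol barrier at 120 K (~12 kBT) is essentially never crossed by
plain overdamped dynamics; the adaptive OPES bias flattens the landscape
(bounded by the 30 kJ/mol barrier parameter) and makes crossings routine.
"""

import numpy as np

from calcipair import LangevinSpec, opes_run
from calcipair.sampling import OPESParams


class DoubleWell:
    """U(x) = h (x^2 - 1)^2 with minima at +-1."""

    def __init__(self, height):
        self.h = height

    def energy(self, x):
        return self.h * (np.asarray(x, float) ** 2 - 1.0) ** 2

    def force(self, x):
        x = np.asarray(x, float)
        return -4.0 * self.h * x * (x**2 - 1.0)


def count_transitions(x, a=-0.7, b=0.7):
    state, n = 0, 0
    for v in x:
        if v < a and state != -1:
            n += state == 1
            state = -1
        elif v > b and state != 1:
            n += state == -1
            state = 1
    return n


pot = DoubleWell(12.0)
spec = LangevinSpec(temperature=120.0, friction=1.0, timestep=0.001,
                    n_steps=500_000, seed=3, dims=1)
params = OPESParams(barrier=30.0, update_pace=500, bandwidth=0.1)
biased, state = opes_run(pot, params, [], spec, cv_range=(-1.6, 1.6), r0=-1.0)
quiet = OPESParams(barrier=30.0, update_pace=10**9, bandwidth=0.1)  # never deposits
unbiased, _ = opes_run(pot, quiet, [], spec, cv_range=(-1.6, 1.6), r0=-1.0)

print(f"transitions, unbiased : {count_transitions(unbiased.cv('x')):4d}")
print(f"transitions, OPES     : {count_transitions(biased.cv('x')):4d}")
print(f"deposited bias range  : {state.max_bias:6.1f} kJ/mol (cap {params.barrier})")
print(f"quasi-static converged: {state.converged}")
print()
print("The deposited bias approaches (1 - 1/gamma) * dF between the wells,")
print("turning a rare activated event into nearly free diffusion, while the")
print("recorded bias column lets the unbiased free-energy profile be")
print("recovered by reweighting.")
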