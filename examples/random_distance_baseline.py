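"""The analytic baseline for distances between unrelated response patterns.

In the standardized 14-dimensional discriminant subspace, unrelated
responses behave like random points on a hypersphere: their expected
normalized distance has a Gamma-function closed form, ~1.4017 for the
14-sphere, approaching sqrt(2) ~ 1.414 in high dimension.  Observed mean
distances near this value indicate that responses carry little shared
(correlated) signal.
"""

import numpy as np

from commrsa import expected_random_distance
from commrsa.distances import monte_carlo_random_distance

for n in (1, 2, 3, 14, 50):
    closed = expected_random_distance(n)
    mc = monte_carlo_random_distance(n, 200_000, seed=n)
    print(f"n={n:3d}: closed form {closed:.4f}   Monte-Carlo {mc:.4f}")
print(f"limit: sqrt(2) = {np.sqrt(2):.4f}")
# n=1 is the circle (4/pi ~ 1.2732), n=2 the ordinary sphere (4/3)
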