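"""Warm-start (abridged) update after a single component increase.

Starting from the fitted block partition of the base vector, raising one
component re-seeds only the block containing it: everything left of that
block is reused (with possible backward pooling) and everything right of it
is copied verbatim.  The number of averaging operations is bounded by
d + |P|, the previous block count plus the size of the touched block.
"""

import numpy as np

from pavaseq import Delta, WeightedVector, abridged_update, standard_pava

z = np.array([1.0, 3.0, 2.0, 0.0, -1.0, 1.0, 0.5, -1.0, 1.0])
data = WeightedVector(z)
base = standard_pava(data)
print("base fit   :", base.fitted, f"d = {base.state.d}")

# raise component 5 (1-based) from -1 to 1
res = abridged_update(base.state, data, Delta(4, 1.0))
print("updated fit:", res.fitted, f"d = {res.state.d}")
jo_block = base.state.block_of(4)
b = base.state.boundaries
bound = base.state.d + (b[jo_block + 1] - b[jo_block])
print(f"ops = {res.ops.total} (bound d + |P| = {bound}, m = {data.m})")
# The last two components (the block with mean 0) are reused without any
# work; from-scratch refitting would have paid for all nine.
scratch = standard_pava(data.replace(4, 1.0))
assert np.array_equal(res.fitted, scratch.fitted)
print("matches from-scratch refit:", True)
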