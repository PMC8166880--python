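"""Build the two rank matrices on a toy problem and show the tie averaging.

Three features with pairwise Euclidean distances sqrt(2) < 2*sqrt(2) <
3*sqrt(2) get ranks 1..3; a 2x2 pixel grid has four side pairs (distance 1)
and two diagonal pairs (sqrt(2)), so tied distances share average ranks
2.5 and 5.5.  The rank sum over the lower triangle is invariant to ties.
"""

import numpy as np

import tabimg as ti

data = ti.TabularDataset(np.array([[0.0, 1.0, 3.0], [0.0, 1.0, 3.0]]))
R = ti.feature_distance_rank_matrix(data)
print("feature rank matrix R:")
print(R.ranks)

Q = ti.pixel_distance_rank_matrix(ti.ImageGrid(2, 2))
print("pixel rank matrix Q for a 2x2 grid (average ranks for ties):")
print(Q.ranks)

print("lower-triangle rank sum:", Q.ranks[np.tril_indices(4, -1)].sum(),
      "= K(K+1)/2 for K=6 pairs:", 6 * 7 / 2)
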