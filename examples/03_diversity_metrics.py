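"""Diversity and dissimilarity metrics on a tiny worked community."""

import numpy as np

from divpart import CommunityMatrix, braycurtis_matrix, jaccard_matrix, richness, shannon

c = CommunityMatrix(
    ["north", "south"],
    ["Acrobeles", "Cephalobus", "Plectus", "Tylenchus"],
    [[4.0, 0.0, 6.0, 2.0], [2.0, 2.0, 6.0, 0.0]],
)

print("richness:", dict(zip(c.sites, map(int, richness(c)))))
print("Shannon H:", {s: round(float(h), 3) for s, h in zip(c.sites, shannon(c))})
print("Jaccard d:", round(jaccard_matrix(c).d[0, 1], 3))
print("Bray-Curtis d:", round(braycurtis_matrix(c).d[0, 1], 3))
# Jaccard counts shared vs unique genera (2 shared, 1 unique each -> 0.5);
# Bray-Curtis weighs abundance differences: sum|x_j - x_k| / sum(x_j + x_k).
assert np.isclose(jaccard_matrix(c).d[0, 1], 0.5)
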