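"""Sorted interatomic-distance descriptors and Boltzmann group descriptors.

Distances are labelled by their element pair, sorted within each label block,
and concatenated — an alignment-free encoding invariant to rigid motions and
to permutation of identical atoms.  Conformer ensembles are summarized by
the Boltzmann-weighted sum of member descriptors at 300 K, which parks the
group representation next to its most stable conformer.
"""

import numpy as np

from forcepath import Geometry, boltzmann_weights, group_descriptor, sorted_distance_descriptor

water_like = Geometry(
    (1, 1, 8),
    np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [0.36, 0.933, 0.0]]),
)
d = sorted_distance_descriptor(water_like)
print("layout:", d.layout)
print("values (Å):", np.round(d.values, 3))

perm = Geometry((8, 1, 1), water_like.coordinates[[2, 1, 0]])
print("permuted copy identical:", bool(np.array_equal(sorted_distance_descriptor(perm).values, d.values)))

stretched = Geometry((1, 1, 8), water_like.coordinates * 1.1)
energies = [0.0, 6.0]  # kJ/mol relative: the first conformer dominates
w = boltzmann_weights(energies, 300.0)
print("weights at 300 K:", np.round(w.weights, 4))
group = group_descriptor(
    [d, sorted_distance_descriptor(stretched)], energies, 300.0
)
print("group descriptor:", np.round(group.values, 3), "(close to the stable conformer)")
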