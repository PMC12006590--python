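"""The 13 unique 3D directions (half of the 26-neighbourhood) used by the
co-occurrence and run-length matrices at distance 1."""

import itertools

import numpy as np

DIRECTIONS_13 = tuple(
    d for d in itertools.product((-1, 0, 1), repeat=3)
    if d > (0, 0, 0)  # lexicographic positive half-space, excludes (0,0,0)
)
assert len(DIRECTIONS_13) == 13

def shifted_slices(shape, offset):
    """Slice pair (base, shifted) aligning each voxel with its neighbour at
    ``offset``; both views share the overlap region."""
    a, b = [], []
    for n, o in zip(shape, offset):
        a.append(slice(max(0, -o), n - max(0, o)))
        b.append(slice(max(0, o), n - max(0, -o)))
    return tuple(a), tuple(b)
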