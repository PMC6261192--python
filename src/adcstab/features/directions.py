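"""The 13 unique 3-D texture directions.

The 26-neighbourhood of a voxel contains 13 antiparallel offset pairs; one
representative per pair (the one whose first non-zero component is positive)
gives the 13 directions along which GLCMs and GLRLMs are built.  Because
both matrices are direction-symmetric (the GLCM is symmetrized, runs are
identical under reversal), the 13 canonical offsets cover the full
neighbourhood.
"""

from __future__ import annotations

import itertools


def direction_set() -> tuple[tuple[int, int, int], ...]:
    """Return the 13 canonical offsets at Chebyshev distance 1 modulo sign."""
    dirs = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        first = next(c for c in d if c != 0)
        if first > 0:
            dirs.append(d)
    return tuple(dirs)
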