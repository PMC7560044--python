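"""Shared brute-force oracles for the test suite."""

import numpy as np

from fqdesign import fields


def naive_descriptor_blocks(molecules, grid, probe):
    """O(molecules x points x atoms) triple loop over the similarity index."""
    pts = grid.points()
    out = {}
    for k in fields.FIELD_KINDS:
        B = np.zeros((len(molecules), len(pts)))
        for i, m in enumerate(molecules):
            w = fields.atom_weights(m, k)
            for j, p in enumerate(pts):
                s = 0.0
                for a in range(m.n_atoms):
                    r2 = float(np.sum((m.coords[a] - p) ** 2))
                    s += w[a] * np.exp(-probe.alpha * r2)
                B[i, j] = -probe.weight(k) * s
        out[k] = B
    return out
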