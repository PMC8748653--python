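"""Brute-force reference implementations shared across test modules."""

import numpy as np


def brute_force_nearest_surface(nucleus_labels, voxel_um):
    """Exhaustive oracle: per voxel, nearest labeled voxel in physical
    distance; ties to the lower label."""
    dz, dy, dx = voxel_um[2], voxel_um[1], voxel_um[0]
    ids = np.unique(nucleus_labels)
    ids = ids[ids > 0]
    coords = {
        i: np.argwhere(nucleus_labels == i) * np.array([dz, dy, dx]) for i in ids
    }
    out = np.zeros(nucleus_labels.shape, dtype=int)
    for z in range(nucleus_labels.shape[0]):
        for y in range(nucleus_labels.shape[1]):
            for x in range(nucleus_labels.shape[2]):
                p = np.array([z * dz, y * dy, x * dx])
                best, best_d = 0, np.inf
                for i in ids:
                    d = np.min(np.linalg.norm(coords[i] - p, axis=1))
                    if d < best_d - 1e-12:
                        best, best_d = i, d
                out[z, y, x] = best
    return out
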