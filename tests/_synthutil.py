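"""Shared helpers for building synthetic detection maps in tests."""

import numpy as np
from scipy.spatial import cKDTree

from synflux import simkit


def stamp_field(centers, amplitude, shape=(128, 128), sigma=1.5, rng=None,
                noise_sd=0.0):
    """One synthetic detection map: Gaussian spots + optional noise."""
    img = np.zeros(shape)
    stamp, r = simkit._psf_stamp(sigma)
    for (row, col) in centers:
        img[row - r:row + r + 1, col - r:col + r + 1] += amplitude * stamp
    if noise_sd > 0:
        img += rng.normal(0, noise_sd, shape)
    return np.clip(img, 0, None)


def grid_centers(shape=(128, 128), spacing=10, margin=10):
    rows = np.arange(margin, shape[0] - margin, spacing)
    cols = np.arange(margin, shape[1] - margin, spacing)
    return [(int(r), int(c)) for r in rows for c in cols]


def match_rate(detected, truth, tol=2.0):
    """(recall, precision) with one-to-one matching at ``tol`` pixels."""
    tree = cKDTree(truth)
    d, idx = tree.query(detected)
    hit = d <= tol
    n_matched = len(set(idx[hit]))
    return n_matched / len(truth), hit.sum() / len(detected)
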