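"""Shared fixtures: segmented synthetic wings reused across test modules."""

import numpy as np
import pytest

import wingasym as wa


@pytest.fixture(scope="session")
def wing_geometry():
    """Segmented default synthetic wing (no junctions attached)."""
    raw, _ = wa.generate_wing(wa.SynthConfig(seed=1))
    return wa.segment_all(wa.binarize(raw))


@pytest.fixture(scope="session")
def wing_with_junctions():
    """Segmented synthetic wing with detected junctions, plus ground truth."""
    raw, truth = wa.generate_wing(wa.SynthConfig(seed=1))
    bw = wa.binarize(raw)
    geom = wa.segment_all(bw)
    geom.junctions = wa.detect_junctions(wa.skeletonize(bw))
    return geom, truth


def random_blob_mask(rng, shape=(32, 40), p=0.45):
    """Random binary mask with blob structure (for flood-fill oracles)."""
    noise = rng.random(shape)
    from scipy import ndimage

    smooth = ndimage.uniform_filter(noise, size=3)
    return smooth > (1 - p)


def bfs_flood_fill(mask, seed):
    """Independent breadth-first 8-connected flood fill (oracle)."""
    from collections import deque

    h, w = mask.shape
    seen = {seed}
    queue = deque([seed])
    while queue:
        r, c = queue.popleft()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                nr, nc = r + dr, c + dc
                if (
                    (dr or dc)
                    and 0 <= nr < h
                    and 0 <= nc < w
                    and mask[nr, nc]
                    and (nr, nc) not in seen
                ):
                    seen.add((nr, nc))
                    queue.append((nr, nc))
    return seen


def exhaustive_nearest(ref_points, target_points):
    """O(n*m) nearest-neighbor matching (oracle)."""
    pairs = []
    for i, p in enumerate(ref_points):
        d = np.sqrt(((target_points - p) ** 2).sum(axis=1))
        j = int(np.argmin(d))
        pairs.append((i, j, float(d[j])))
    return pairs
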