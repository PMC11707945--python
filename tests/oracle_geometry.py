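"""Independent brute-force geometry oracle used by the test suite.

Distance: every boundary edge is densely sampled and the minimum
point-to-sample distance taken. Containment: classic even-odd ray
casting, implemented from scratch (no shapely).
"""

import numpy as np


def random_star_ring(rng, center, radius, n_vertices=None):
    """A random simple star-shaped polygon (vertex array).

    Angles are jittered regular spacings, which keeps every angular gap
    below π — the condition under which an angularly sorted vertex ring
    is guaranteed simple.
    """
    n = int(n_vertices if n_vertices is not None else rng.integers(8, 32))
    theta = 2 * np.pi * (np.arange(n) + rng.uniform(-0.3, 0.3, n)) / n
    r = radius * rng.uniform(0.5, 1.5, n)
    return np.asarray(center) + np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)


def dense_boundary_distance(point, rings, step_um=0.1):
    """Min distance from ``point`` to any ring, by sampling edges at ``step_um``."""
    p = np.asarray(point, float)
    best = np.inf
    for ring in rings:
        v = np.asarray(ring, float)
        a = v
        b = np.roll(v, -1, axis=0)
        for s, e in zip(a, b):
            length = np.linalg.norm(e - s)
            n = max(int(np.ceil(length / step_um)), 1)
            ts = np.linspace(0.0, 1.0, n + 1)
            samples = s[None, :] + ts[:, None] * (e - s)[None, :]
            d = np.min(np.linalg.norm(samples - p, axis=1))
            best = min(best, float(d))
    return best


def ray_cast_inside(point, ring):
    """Even-odd containment of ``point`` in one closed ring (horizontal ray)."""
    x, y = float(point[0]), float(point[1])
    v = np.asarray(ring, float)
    inside = False
    n = len(v)
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        if (y1 > y) != (y2 > y):
            x_cross = x1 + (y - y1) / (y2 - y1) * (x2 - x1)
            if x_cross > x:
                inside = not inside
    return inside


def brute_force_signed_distance(point, rings, step_um=0.1):
    """Signed distance: negative iff inside an odd number of rings."""
    d = dense_boundary_distance(point, rings, step_um)
    parity = sum(ray_cast_inside(point, r) for r in rings) % 2
    return -d if parity else d
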