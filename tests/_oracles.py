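"""Independent brute-force oracles used to check the package's fast paths.

These deliberately avoid the package's own vectorized implementations:
explicit Python loops and exhaustive searches only.
"""

from __future__ import annotations

import math

import numpy as np


def phasor_oracle(spectrum, harmonic=1):
    """Direct-summation spectral phasor of one spectrum (explicit loop)."""
    n = len(spectrum)
    total = g = s = 0.0
    for k in range(n):
        w = 2.0 * math.pi * harmonic * k / n
        total += spectrum[k]
        g += spectrum[k] * math.cos(w)
        s += spectrum[k] * math.sin(w)
    return g / total, s / total


def otsu_oracle(values, n_candidates=512):
    """Exhaustive between-class-variance search for the Otsu threshold."""
    values = np.asarray(values, dtype=float).ravel()
    lo, hi = values.min(), values.max()
    best_t, best_var = lo, -1.0
    for t in np.linspace(lo, hi, n_candidates)[1:-1]:
        w1 = values < t
        n1, n2 = w1.sum(), (~w1).sum()
        if n1 == 0 or n2 == 0:
            continue
        var = (n1 / values.size) * (n2 / values.size) * (values[w1].mean() - values[~w1].mean()) ** 2
        if var > best_var:
            best_var, best_t = var, t
    return best_t


def max_projection_oracle(volume):
    """Voxel-wise loop maximum over z."""
    nz, ny, nx = volume.shape
    out = np.full((ny, nx), -np.inf)
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if volume[z, y, x] > out[y, x]:
                    out[y, x] = volume[z, y, x]
    return out


def sphere_voxel_count_oracle(radius, pixel_size, z_step, extent=16.0):
    """Count voxel centers inside a sphere centered on a voxel center."""
    count = 0
    nz = int(extent / z_step)
    nxy = int(extent / pixel_size)
    for iz in range(-nz, nz + 1):
        for iy in range(-nxy, nxy + 1):
            for ix in range(-nxy, nxy + 1):
                d2 = (iz * z_step) ** 2 + (iy * pixel_size) ** 2 + (ix * pixel_size) ** 2
                if d2 <= radius**2:
                    count += 1
    return count


def permutation_t_pvalue(a, b, n_perm=20000, seed=0):
    """Two-sided permutation p-value for the difference of means."""
    rng = np.random.default_rng(seed)
    a, b = np.asarray(a, float), np.asarray(b, float)
    pooled = np.concatenate([a, b])
    observed = abs(a.mean() - b.mean())
    hits = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        if abs(pooled[: len(a)].mean() - pooled[len(a):].mean()) >= observed - 1e-12:
            hits += 1
    return hits / n_perm
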