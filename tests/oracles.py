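"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own implementations: connected
components by breadth-first search, TFCE by explicit threshold summation,
absorption probabilities in closed form, BH by the textbook step-up recipe,
and permutation p-values by full enumeration with explicit least squares.
"""
import itertools

import numpy as np

_NBRS26 = [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1) for k in (-1, 0, 1)
           if (i, j, k) != (0, 0, 0)]
_NBRS6 = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def flood_component(mask, start, connectivity=26):
    """Voxels of the connected component containing ``start`` (BFS)."""
    nbrs = _NBRS26 if connectivity == 26 else _NBRS6
    shape = mask.shape
    seen = {tuple(start)}
    queue = [tuple(start)]
    while queue:
        v = queue.pop()
        for off in nbrs:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if all(0 <= w[a] < shape[a] for a in range(3)) and w not in seen and mask[w]:
                seen.add(w)
                queue.append(w)
    return seen


def brute_tfce(stat_map, mask, height_exp, extent_exp, dh, voxel_volume=1.0,
               connectivity=26):
    """TFCE by explicit threshold summation with BFS-found components."""
    x = np.where(mask, np.asarray(stat_map, dtype=float), 0.0)
    out = np.zeros_like(x)
    top = x.max(initial=0.0)
    if top <= 0:
        return out
    k = 1
    while (k - 0.5) * dh < top:  # midpoint thresholds, as in the package
        h = (k - 0.5) * dh
        sup = (x >= h) & mask
        remaining = {tuple(v) for v in np.argwhere(sup)}
        while remaining:
            comp = flood_component(sup, next(iter(remaining)), connectivity)
            contrib = (len(comp) * voxel_volume) ** extent_exp * h ** height_exp * dh
            for v in comp:
                out[v] += contrib
            remaining -= comp
        k += 1
    return out


def ruin_absorption_right(p_step, start, n_states):
    """Gambler's-ruin absorption probability at the right boundary.

    A walker starts in state ``start`` of 0..n_states (both ends absorbing)
    and moves +1 with probability ``p_step``.
    """
    q = 1.0 - p_step
    if abs(p_step - q) < 1e-12:
        return start / n_states
    r = q / p_step
    return (1.0 - r ** start) / (1.0 - r ** n_states)


def bh_stepup(pvals):
    """Benjamini-Hochberg adjusted p-values by the textbook step-up recipe."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def exhaustive_freedman_lane(Y, x, Z, mask, voxel_volume, height_exp=2.0,
                             extent_exp=0.5, n_steps=100, connectivity=26):
    """Exact corrected p by enumerating every residual permutation.

    Y: (n, n_vox) in-mask data; x: regressor; Z: nuisance columns (with
    intercept).  Returns the corrected p-value per in-mask voxel.
    """
    n = Y.shape[0]
    X = np.column_stack([x, Z])
    gamma, *_ = np.linalg.lstsq(Z, Y, rcond=None)
    fitted = Z @ gamma
    resid = Y - fitted

    def tfce_of(Yp):
        beta, *_ = np.linalg.lstsq(X, Yp, rcond=None)
        r = Yp - X @ beta
        df = n - X.shape[1]
        sigma2 = (r ** 2).sum(axis=0) / df
        xtxi = np.linalg.inv(X.T @ X)
        se = np.sqrt(sigma2 * xtxi[0, 0])
        t = beta[0] / np.maximum(se, 1e-300)
        vol = np.zeros(mask.shape)
        vol[mask] = t
        enh = np.zeros(mask.shape)
        top = vol.max(initial=0.0)
        if top > 0:
            enh = brute_tfce(vol, mask, height_exp, extent_exp, top / n_steps,
                             voxel_volume, connectivity)
        neg = np.zeros(mask.shape)
        ntop = (-vol[mask]).max(initial=0.0)
        if ntop > 0:
            neg = brute_tfce(np.where(mask, -vol, 0.0), mask, height_exp,
                             extent_exp, ntop / n_steps, voxel_volume, connectivity)
        return (enh - neg)[mask]

    obs = tfce_of(Y)
    maxima = []
    for perm in itertools.permutations(range(n)):
        Yp = fitted + resid[list(perm)]
        maxima.append(tfce_of(Yp).max(initial=0.0))
    return obs, np.asarray(maxima)
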