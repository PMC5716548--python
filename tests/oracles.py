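"""Brute-force reference implementations, independent of the library paths.

Deliberately written as plain double/triple loops so they share no code with
the vectorized estimators they check.
"""

import numpy as np


def brute_force_contacts(models, cutoff, neighbor_exclusion):
    """All-pairs, all-models consensus contact set."""
    n_models, n_res, _ = models.shape
    pairs = set()
    for i in range(n_res):
        for j in range(i + neighbor_exclusion, n_res):
            ok = True
            for m in range(n_models):
                d = np.sqrt(np.sum((models[m, i] - models[m, j]) ** 2))
                if d >= cutoff:
                    ok = False
                    break
            if ok:
                pairs.add((i, j))
    return pairs


def brute_force_flux(ensemble, spec):
    """Enumerate every segment-plane intersection one by one.

    Conventions match the declared ones: upward passages count planes in
    (a, b], downward in [b, a); transverse boundary points go to the
    lower-index cell.
    """
    ndim = spec.ndim
    counts = [np.zeros(spec.dims) for _ in range(ndim)]
    origin = np.asarray(spec.origin)
    spacing = np.asarray(spec.spacing)
    for traj in ensemble.trajectories:
        u = (traj.frames - origin) / spacing
        for t in range(u.shape[0] - 1):
            for k in range(ndim):
                a, b = u[t, k], u[t + 1, k]
                if b > a:
                    planes = range(int(np.floor(a)) + 1, int(np.floor(b)) + 1)
                    sign = 1.0
                elif b < a:
                    planes = range(int(np.ceil(b)), int(np.ceil(a)))
                    sign = -1.0
                else:
                    continue
                for v in planes:
                    s = (v - a) / (b - a)
                    index = []
                    valid = 0 <= v < spec.dims[k]
                    for ax in range(ndim):
                        if ax == k:
                            index.append(v)
                            continue
                        pos = u[t, ax] + s * (u[t + 1, ax] - u[t, ax])
                        cell = int(np.ceil(pos - 0.5))
                        valid &= 0 <= cell < spec.dims[ax]
                        index.append(cell)
                    if valid:
                        counts[k][tuple(index)] += sign
    M = ensemble.n_trajectories
    tf = ensemble.mfpt
    flux = []
    for k in range(ndim):
        area = 1.0
        for ax in range(ndim):
            if ax != k:
                area *= spacing[ax]
        flux.append(counts[k] / (M * tf * area))
    return np.stack(flux)


def box_counting_dimension(mask, sizes):
    """Grid-aligned box-counting slope of a 2D boolean support."""
    counts = []
    for s in sizes:
        n0 = (mask.shape[0] // s) * s
        n1 = (mask.shape[1] // s) * s
        blocks = mask[:n0, :n1].reshape(n0 // s, s, n1 // s, s)
        counts.append(int(blocks.any(axis=(1, 3)).sum()))
    slope = np.polyfit(np.log(sizes), np.log(counts), 1)[0]
    return -slope
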