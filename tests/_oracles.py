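"""Independent reference implementations used to check the package.

These deliberately use brute force (path enumeration, recursive kinship,
direct GLS) and never call the code paths they verify.
"""

from itertools import product

import numpy as np


def brute_force_gp(H, L, switch, mu):
    """Genotype posteriors by exhaustive enumeration of all diploid state paths.

    H: (K, V) panel alleles; L: (V, 3) site likelihoods; switch: (V,)
    per-site switch probability (switch[0] ignored); mu: copying error.
    """
    H = np.asarray(H)
    L = np.asarray(L, dtype=float)
    K, V = H.shape

    def p_allele1(a):
        return 1.0 - mu if a == 1 else mu

    def site_genotype_weights(t, k, l):
        p1 = p_allele1(H[k, t])
        p2 = p_allele1(H[l, t])
        return (
            (1 - p1) * (1 - p2) * L[t, 0],
            ((1 - p1) * p2 + p1 * (1 - p2)) * L[t, 1],
            p1 * p2 * L[t, 2],
        )

    states = list(product(range(K), repeat=2))
    gp = np.zeros((V, 3))
    total = 0.0
    for path in product(states, repeat=V):
        w = 1.0 / K**2
        for t in range(1, V):
            s = switch[t]
            k0, l0 = path[t - 1]
            k1, l1 = path[t]
            w *= ((1 - s) * (k0 == k1) + s / K) * ((1 - s) * (l0 == l1) + s / K)
        if w == 0.0:
            continue
        evec = [site_genotype_weights(t, *path[t]) for t in range(V)]
        etot = [sum(v) for v in evec]
        pw = w
        for e in etot:
            pw *= e
        if pw == 0.0:
            continue
        total += pw
        for t in range(V):
            f = pw / etot[t]
            gp[t, 0] += f * evec[t][0]
            gp[t, 1] += f * evec[t][1]
            gp[t, 2] += f * evec[t][2]
    return gp / gp.sum(axis=1, keepdims=True)


def kinship_A(pedigree):
    """Numerator relationships via the recursive coancestry definition.

    pedigree: DataFrame with animal, sire, dam ("0" unknown).  Returns
    (A, ids) with A = 2 * coancestry and inbred diagonals.
    """
    ids = list(pedigree["animal"].astype(str))
    sire = dict(zip(ids, pedigree["sire"].astype(str)))
    dam = dict(zip(ids, pedigree["dam"].astype(str)))
    order = {a: i for i, a in enumerate(ids)}
    cache = {}

    def phi(a, b):
        if a == "0" or b == "0" or a not in order or b not in order:
            return 0.0
        if order[a] < order[b]:
            a, b = b, a
        key = (a, b)
        if key in cache:
            return cache[key]
        if a == b:
            val = 0.5 * (1.0 + phi(sire[a], dam[a]))
        else:
            # a is the younger (later) animal: recurse on its parents
            val = 0.5 * (phi(sire[a], b) + phi(dam[a], b))
        cache[key] = val
        return val

    n = len(ids)
    A = np.zeros((n, n))
    for i, a in enumerate(ids):
        for j, b in enumerate(ids):
            A[i, j] = 2.0 * phi(a, b)
    return A, np.array(ids, dtype=object)


def gls_blup(y, X, Z, K, sigma_g2, sigma_e2):
    """Direct generalized-least-squares solution of the animal model."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    V = sigma_g2 * (Z @ K @ Z.T) + sigma_e2 * np.eye(n)
    vinv = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ vinv @ X, X.T @ vinv @ y)
    u = sigma_g2 * K @ Z.T @ vinv @ (y - X @ beta)
    return beta, u
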