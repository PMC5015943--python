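import numpy as np
import pytest

import airwayqtl as aq


@pytest.fixture(scope="session")
def tiny_map():
    return aq.GenomeMap.uniform([("1", 100.0)], 50)


@pytest.fixture(scope="session")
def tiny_dosage(tiny_map):
    pop = aq.simulate_mosaics(20, tiny_map, switch_rate=0.05, heterozygosity=0.1, seed=11)
    return aq.mosaics_to_dosage(pop)


@pytest.fixture(scope="session")
def medium_dosage():
    gmap = aq.GenomeMap.uniform([("1", 100.0), ("2", 100.0)], 50)
    pop = aq.simulate_mosaics(60, gmap, switch_rate=0.05, heterozygosity=0.1, seed=7)
    return aq.mosaics_to_dosage(pop)


def brute_force_lod(y, dosages):
    """Independent LOD oracle: explicit normal equations per marker.

    Solves min ||y - X b|| with X = [1 | D_k] through the pseudo-inverse of
    the normal matrix, computes RSS by direct residual summation, and
    applies LOD = (n/2) log10(RSS0/RSS1).
    """
    y = np.asarray(y, float)
    n = len(y)
    rss0 = float(np.sum((y - y.mean()) ** 2))
    out = []
    for k in range(dosages.shape[0]):
        X = np.column_stack([np.ones(n), dosages[k]])
        b = np.linalg.pinv(X.T @ X) @ X.T @ y
        r = y - X @ b
        rss1 = float(r @ r)
        out.append((n / 2.0) * np.log10(rss0 / max(rss1, 1e-12 * rss0)))
    return np.array(out)


def bisection_root(alpha, beta1, beta2, threshold, lo, hi, tol=1e-12):
    """Independent root oracle: sign-change bisection of f(d) = curve - threshold."""
    f = lambda d: alpha + beta1 * d + beta2 * d * d - threshold
    if f(lo) * f(hi) > 0:
        return None
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if f(lo) * f(mid) <= 0:
            hi = mid
        else:
            lo = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def smallest_admissible_root_by_grid(alpha, beta1, beta2, threshold, cap):
    """Scan a fine grid for the first sign change, then bisect it."""
    grid = np.linspace(1e-9, cap, 20001)
    vals = alpha + beta1 * grid + beta2 * grid**2 - threshold
    sign = np.sign(vals)
    hits = np.where(np.diff(sign) != 0)[0]
    exact = np.where(vals == 0)[0]
    candidates = []
    if exact.size:
        candidates.append(grid[exact[0]])
    for i in hits[:1]:
        r = bisection_root(alpha, beta1, beta2, threshold, grid[i], grid[i + 1])
        if r is not None:
            candidates.append(r)
    return min(candidates) if candidates else None
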