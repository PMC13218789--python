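"""Independent oracles used by the tests.

These deliberately re-derive quantities from first principles — exhaustive
enumeration and dense grid search — rather than calling into the package's
own algorithms, so they can serve as cross-checks.
"""

from __future__ import annotations

import itertools
import math
from typing import Iterable, Sequence

import numpy as np

Call = tuple[str, str] | None
Hap = tuple[str, ...]


def brute_force_resolutions(
    calls: Sequence[Call], wildcards: Sequence[Iterable[str]]
) -> list[tuple[Hap, Hap]]:
    """All unordered haplotype pairs compatible with a genotype, by
    enumerating every haplotype over the per-site candidate alleles and
    filtering pairs against the genotype multisets."""
    site_alleles: list[list[str]] = []
    for i, call in enumerate(calls):
        if call is None:
            site_alleles.append(sorted(set(wildcards[i])))
        else:
            site_alleles.append(sorted(set(call)))
    haps = [tuple(h) for h in itertools.product(*site_alleles)]
    out = set()
    for h1 in haps:
        for h2 in haps:
            if h1 > h2:
                continue
            ok = True
            for i, call in enumerate(calls):
                if call is None:
                    continue
                if tuple(sorted((h1[i], h2[i]))) != call:
                    ok = False
                    break
            if ok:
                out.add((h1, h2))
    return sorted(out)


def hwe_loglik(
    per_sample_pairs: Sequence[Sequence[tuple[int, int]]], p: np.ndarray
) -> float:
    """Hardy–Weinberg cohort log-likelihood at frequency vector ``p``."""
    ll = 0.0
    for pairs in per_sample_pairs:
        tot = 0.0
        for k, l in pairs:
            c = 2.0 if k != l else 1.0
            tot += c * p[k] * p[l]
        ll += math.log(max(tot, 1e-300))
    return ll


def grid_search_hwe(
    records_calls: Sequence[Sequence[Call]],
    wildcards: Sequence[Iterable[str]],
    step: float = 1e-3,
) -> tuple[float, dict[Hap, float]]:
    """Maximize the Hardy–Weinberg likelihood over the haplotype simplex by
    grid search with final step ``step``.

    Support is built by brute-force enumeration.  For up to 3 free
    dimensions the full ``step`` grid is evaluated directly; for larger
    supports a coarse pass (step 5e-3) is refined locally to ``step``
    around the best coarse point, which is adequate for the smooth,
    low-dimensional likelihoods these tests use.
    """
    per_sample = [brute_force_resolutions(c, wildcards) for c in records_calls]
    support = sorted({h for pairs in per_sample for pair in pairs for h in pair})
    index = {h: k for k, h in enumerate(support)}
    pair_idx = [
        [(index[h1], index[h2]) for h1, h2 in pairs] for pairs in per_sample
    ]
    K = len(support)
    if K == 1:
        return hwe_loglik(pair_idx, np.array([1.0])), {support[0]: 1.0}

    def eval_grid(points: np.ndarray) -> np.ndarray:
        # points: (G, K) rows on the simplex
        ll = np.zeros(len(points))
        for pairs in pair_idx:
            tot = np.zeros(len(points))
            for k, l in pairs:
                c = 2.0 if k != l else 1.0
                tot += c * points[:, k] * points[:, l]
            ll += np.log(np.maximum(tot, 1e-300))
        return ll

    def simplex_points(m: int) -> np.ndarray:
        """All lattice points i/m on the K-simplex."""
        axes = [np.arange(m + 1, dtype=np.int32)] * (K - 1)
        grids = np.meshgrid(*axes, indexing="ij")
        flat = np.stack([g.ravel() for g in grids], axis=1)
        keep = flat.sum(axis=1) <= m
        flat = flat[keep]
        last = m - flat.sum(axis=1)
        pts = np.column_stack([flat, last]).astype(float) / m
        return pts

    m_fine = round(1.0 / step)
    if K <= 3:
        pts = simplex_points(m_fine)
        ll = eval_grid(pts)
        best = int(np.argmax(ll))
        p = pts[best]
        return float(ll[best]), {h: float(p[k]) for k, h in enumerate(support)}

    # coarse pass then local refinement at the fine step
    m_coarse = 200  # step 5e-3
    pts = simplex_points(m_coarse)
    ll = eval_grid(pts)
    center = pts[int(np.argmax(ll))]
    ratio = m_fine // m_coarse
    offsets = np.arange(-ratio, ratio + 1)
    axes = [offsets] * (K - 1)
    grids = np.meshgrid(*axes, indexing="ij")
    delta = np.stack([g.ravel() for g in grids], axis=1)
    base = np.rint(center[:-1] * m_fine).astype(int)
    cand = base + delta
    keep = (cand >= 0).all(axis=1) & (cand.sum(axis=1) <= m_fine)
    cand = cand[keep]
    last = m_fine - cand.sum(axis=1)
    fine_pts = np.column_stack([cand, last]).astype(float) / m_fine
    fine_ll = eval_grid(fine_pts)
    best = int(np.argmax(fine_ll))
    p = fine_pts[best]
    return float(fine_ll[best]), {h: float(p[k]) for k, h in enumerate(support)}
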