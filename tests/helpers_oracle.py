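"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's algorithms: the clustering
oracle re-scans the original distance matrix at every step instead of
using Lance–Williams updates, and the census/summary oracles are plain
double loops over records.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

import numpy as np
import pandas as pd


def naive_agglomerate(dist: pd.DataFrame, method: str = "complete") -> np.ndarray:
    """O(n^3) re-scan agglomeration: at each step recompute every
    between-cluster linkage from the original pairwise distances, merge the
    minimum (ties by lexicographically smallest sorted leaf-label pair)."""
    labels = [str(x) for x in dist.index]
    D0 = dist.to_numpy(dtype=float)
    clusters: Dict[int, List[int]] = {i: [i] for i in range(len(labels))}
    node = {i: i for i in range(len(labels))}
    merges = []
    next_id = len(labels)
    while len(clusters) > 1:
        best = None
        ids = sorted(clusters)
        for ia, a in enumerate(ids):
            for b in ids[ia + 1 :]:
                pairs = [D0[x, y] for x in clusters[a] for y in clusters[b]]
                if method == "complete":
                    d = max(pairs)
                elif method == "single":
                    d = min(pairs)
                else:
                    d = sum(pairs) / len(pairs)
                key = tuple(
                    sorted(
                        (
                            tuple(sorted(labels[x] for x in clusters[a])),
                            tuple(sorted(labels[x] for x in clusters[b])),
                        )
                    )
                )
                cand = (d, key, a, b)
                if best is None or cand < best:
                    best = cand
        d, _key, a, b = best
        merges.append(
            (
                min(node[a], node[b]),
                max(node[a], node[b]),
                d,
                len(clusters[a]) + len(clusters[b]),
            )
        )
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
        node[a] = next_id
        next_id += 1
    return np.array(merges, dtype=float)


def random_distance_frame(
    rng: np.random.Generator, n: int, dim: int = 3
) -> pd.DataFrame:
    pts = rng.normal(size=(n, dim))
    D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    labels = [f"L{i}" for i in range(n)]
    return pd.DataFrame(D, index=labels, columns=labels)


def brute_force_site_maxima(records, matrix: str) -> Dict[Tuple[str, str], float]:
    """Max recoded value per (site, chemical) by explicit iteration."""
    out: Dict[Tuple[str, str], float] = {}
    for r in records:
        if r.matrix != matrix:
            continue
        v = 0.0 if r.value is None else r.value
        key = (r.site_id, r.chemical_id)
        out[key] = max(out.get(key, 0.0), v)
    return out


def brute_force_census(exceeded: pd.DataFrame, river_of: Dict[str, str]) -> dict:
    sites = set()
    chems = set()
    for site in exceeded.index:
        for chem in exceeded.columns:
            if exceeded.loc[site, chem]:
                sites.add(site)
                chems.add(chem)
    rivers = {river_of[s] for s in sites}
    return {
        "n_sites_exceeding": len(sites),
        "n_rivers_exceeding": len(rivers),
        "chemicals_exceeded": sorted(chems),
    }
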