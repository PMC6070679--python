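"""Mantel correlogram for multivariate spatial autocorrelation.

Used to check the independence assumption behind the permutation tests: if
community dissimilarity is structured over distance along the stream, the
correlogram's short-range classes show positive, significant Mantel
correlations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix

__all__ = ["mantel_r", "MantelCorrelogram", "mantel_correlogram"]


def _triangle(d: np.ndarray) -> np.ndarray:
    i, j = np.triu_indices(d.shape[0], k=1)
    return d[i, j]


def mantel_r(D1, D2) -> float:
    """Pearson correlation of two distance matrices' upper triangles.

    Matrices must share labels in the same order.  Raises on a constant
    triangle (the correlation is undefined).
    """
    d1 = D1.data if isinstance(D1, DistanceMatrix) else np.asarray(D1, dtype=float)
    d2 = D2.data if isinstance(D2, DistanceMatrix) else np.asarray(D2, dtype=float)
    if isinstance(D1, DistanceMatrix) and isinstance(D2, DistanceMatrix):
        if tuple(D1.ids) != tuple(D2.ids):
            raise ValueError("distance matrices have mismatched labels")
    if d1.shape != d2.shape:
        raise ValueError("distance matrices have different sizes")
    v1, v2 = _triangle(d1), _triangle(d2)
    if np.allclose(v1, v1[0]) or np.allclose(v2, v2[0]):
        raise ValueError("zero variance in a distance-matrix triangle")
    return float(np.corrcoef(v1, v2)[0, 1])


@dataclass
class MantelCorrelogram:
    """Per-distance-class Mantel statistics, ready for plotting."""

    class_bounds: list[tuple[float, float]]
    mantel_r: np.ndarray
    p_value: np.ndarray           # raw two-sided permutation p
    p_corrected: np.ndarray       # progressive multiple-testing correction
    n_pairs: np.ndarray
    n_permutations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "class_lo": [b[0] for b in self.class_bounds],
                "class_hi": [b[1] for b in self.class_bounds],
                "mantel_r": self.mantel_r,
                "p_raw": self.p_value,
                "p_corrected": self.p_corrected,
                "n_pairs": self.n_pairs,
            },
            index=pd.RangeIndex(1, len(self.class_bounds) + 1, name="class"),
        )


def mantel_correlogram(
    D_community: DistanceMatrix,
    distances_along_stream,
    n_classes: int | None = None,
    n_permutations: int = 999,
    seed: int | np.random.Generator = 0,
) -> MantelCorrelogram:
    """Mantel correlogram of community dissimilarity against stream distance.

    Spatial separation ``|d_i - d_j|`` is binned into equal-width classes
    (Sturges' rule on the pair count by default).  Per class, the Mantel
    correlation between the community dissimilarities and the binary
    within-class indicator is tested by permuting site labels (two-sided).
    A progressive correction (class ``k``'s p multiplied by ``k``, capped at
    1 and monotonised) is reported alongside the raw p-values.  Classes with
    fewer than 2 pairs are merged into their left neighbour with a warning.
    """
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    pos = np.asarray(distances_along_stream, dtype=float)
    n = pos.size
    if n != D_community.shape[0]:
        raise ValueError("one stream distance per site is required")
    space = np.abs(pos[:, None] - pos[None, :])
    dcom = np.asarray(D_community.data, dtype=float)

    n_pairs_total = n * (n - 1) // 2
    if n_classes is None:
        n_classes = int(math.ceil(1 + math.log2(n_pairs_total)))
    tri = _triangle(space)
    lo, hi = tri.min(), tri.max()
    if hi <= lo:
        raise ValueError("all sites share one position; no spatial classes")
    edges = np.linspace(lo, hi, n_classes + 1)

    # class membership per pair; merge sparse classes leftwards
    idx = np.clip(np.digitize(tri, edges[1:-1], right=True), 0, n_classes - 1)
    bounds = [(edges[k], edges[k + 1]) for k in range(n_classes)]
    counts = np.bincount(idx, minlength=n_classes)
    while (counts < 2).any() and len(bounds) > 1:
        k = int(np.argmin(counts))
        warnings.warn(
            f"distance class {k + 1} has {counts[k]} pair(s); merged with a neighbour",
            UserWarning,
        )
        j = k - 1 if k > 0 else k + 1
        a, b = min(j, k), max(j, k)
        bounds[a] = (bounds[a][0], bounds[b][1])
        del bounds[b]
        idx = np.where(idx == b, a, idx)
        idx = np.where(idx > b, idx - 1, idx)
        counts = np.bincount(idx, minlength=len(bounds))

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    iu, ju = np.triu_indices(n, k=1)
    dvec = dcom[iu, ju]
    dvec_c = dvec - dvec.mean()
    dvec_ss = float((dvec_c**2).sum())

    def class_r(vec_c: np.ndarray, vec_ss: float, member: np.ndarray) -> float:
        m_c = member - member.mean()
        m_ss = float((m_c**2).sum())
        return float((vec_c * m_c).sum() / np.sqrt(vec_ss * m_ss))

    members = [(idx == k).astype(float) for k in range(len(bounds))]
    r_obs = np.array([class_r(dvec_c, dvec_ss, m) for m in members])

    hits = np.zeros(len(bounds), dtype=int)
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        dperm = dcom[np.ix_(perm, perm)][iu, ju]
        dperm_c = dperm - dperm.mean()
        dperm_ss = float((dperm_c**2).sum())
        for k, m in enumerate(members):
            if abs(class_r(dperm_c, dperm_ss, m)) >= abs(r_obs[k]) - 1e-12:
                hits[k] += 1
    p_raw = (1 + hits) / (1 + n_permutations)

    ks = np.arange(1, len(bounds) + 1)
    p_corr = np.minimum(p_raw * ks, 1.0)
    p_corr = np.maximum.accumulate(p_corr)  # monotone like Holm's step-down

    n_pairs = np.array([int(m.sum()) for m in members])
    return MantelCorrelogram(
        class_bounds=bounds,
        mantel_r=r_obs,
        p_value=p_raw,
        p_corrected=p_corr,
        n_pairs=n_pairs,
        n_permutations=n_permutations,
    )
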