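"""Diagnostics for deciding which PCO axes are nontrivial.

Four methods, applied to the positive eigenvalues of a Bray–Curtis PCoA of a
square-root-transformed community matrix:

1. broken stick — compare each axis' proportion of positive inertia with the
   expectation under a random split of total variance;
2. bootstrap — resample sites with replacement, flag leading axes whose 95%
   eigenvalue confidence intervals do not overlap the next rank;
3. permutation null — permute each taxon column independently to destroy
   inter-taxon correlation, flag observed eigenvalues above the null 97.5%
   bound;
4. relative percent — the variance explained by each ranked axis as a
   percentage of the variance left over at that rank (scree data).

A consensus rule combines the four boolean flags per axis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ordination import bray_curtis, pcoa, sqrt_transform

__all__ = [
    "broken_stick",
    "broken_stick_flags",
    "bootstrap_eigen_ci",
    "permutation_null_eigen",
    "relative_percent",
    "NontrivialityReport",
    "nontriviality_report",
    "nontrivial_axes",
]


def broken_stick(p: int) -> np.ndarray:
    """Broken-stick proportions ``b_k = (1/p) * sum_{i=k..p} 1/i``.

    The expected ordered fragment lengths when a stick of length 1 is broken
    at random into ``p`` pieces; they sum to 1 and strictly decrease.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    inv = 1.0 / np.arange(1, p + 1)
    return np.cumsum(inv[::-1])[::-1] / p


def _positive(eigenvalues: np.ndarray) -> np.ndarray:
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        raise ValueError("no positive eigenvalues")
    if np.any(np.diff(lam) > 1e-12):
        raise ValueError("eigenvalues must be sorted descending")
    return lam


def broken_stick_flags(eigenvalues: np.ndarray) -> np.ndarray:
    """Flag axes whose proportion of positive inertia strictly exceeds the
    broken-stick value of the same rank.

    Flags form a leading block: once an axis falls below its broken-stick
    value, later ranks are noise by assumption and are not flagged even if
    their proportion happens to exceed the (small) tail values.
    """
    lam = _positive(eigenvalues)
    props = lam / lam.sum()
    raw = props > broken_stick(lam.size)
    out = np.zeros_like(raw)
    for k, f in enumerate(raw):
        if not f:
            break
        out[k] = True
    return out


def relative_percent(eigenvalues: np.ndarray) -> np.ndarray:
    """Percent of the *remaining* variance explained at each rank:
    ``r_k = 100 * lam_k / sum_{i>=k} lam_i`` (the last axis is always 100)."""
    lam = _positive(eigenvalues)
    return 100.0 * lam / np.cumsum(lam[::-1])[::-1]


def _canonical_rows(values: np.ndarray) -> np.ndarray:
    # lexicographic row order, so replicate draws do not depend on the
    # caller's row ordering (flags must be row-order invariant at fixed seed)
    order = np.lexsort(values.T[::-1])
    return values[order]


def _eigen_desc(values: np.ndarray) -> np.ndarray:
    d = bray_curtis(pd.DataFrame(values)).data
    a = -0.5 * d**2
    b = a - a.mean(1, keepdims=True) - a.mean(0, keepdims=True) + a.mean()
    return np.sort(np.linalg.eigvalsh(b))[::-1]


@dataclass
class IntervalFlags:
    """Per-rank intervals plus the boolean flags they imply."""

    lower: np.ndarray
    upper: np.ndarray
    flags: np.ndarray
    n_skipped: int = 0


def bootstrap_eigen_ci(
    community: pd.DataFrame,
    B: int = 1000,
    seed: int | np.random.Generator = 0,
    n_ranks: int | None = None,
) -> IntervalFlags:
    """Bootstrap 95% percentile CIs for the ranked PCoA eigenvalues.

    Sites (rows) are resampled with replacement; each replicate goes through
    square-root transform, Bray–Curtis, and PCoA.  Rank ``k`` is flagged
    nontrivial while its CI is disjoint from rank ``k+1``'s, stopping at the
    first overlap (the leading-block reading: downstream use cares about the
    first few axes).  Degenerate replicates (all resampled rows identical)
    are skipped and counted.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    values = np.asarray(community, dtype=float)
    if values.shape[0] < 3:
        raise ValueError("need at least 3 sites")
    values = _canonical_rows(values)
    n = values.shape[0]
    if n_ranks is None:
        n_ranks = n
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    draws = []
    skipped = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # double-zero pairs in resamples
        for _ in range(B):
            idx = rng.integers(0, n, n)
            sub = values[idx]
            if np.all(sub == sub[0]):
                skipped += 1
                continue
            draws.append(_eigen_desc(np.sqrt(sub))[:n_ranks])
    if skipped:
        warnings.warn(f"{skipped} degenerate bootstrap replicates skipped", UserWarning)
    if not draws:
        k = min(n_ranks, n)
        zero = np.zeros(k)
        return IntervalFlags(zero, zero, np.zeros(k, dtype=bool), skipped)
    mat = np.vstack(draws)
    lower = np.percentile(mat, 2.5, axis=0)
    upper = np.percentile(mat, 97.5, axis=0)

    flags = np.zeros(mat.shape[1], dtype=bool)
    for k in range(mat.shape[1] - 1):
        if lower[k] > upper[k + 1]:
            flags[k] = True
        else:
            break
    return IntervalFlags(lower, upper, flags, skipped)


def permutation_null_eigen(
    community: pd.DataFrame,
    B: int = 999,
    seed: int | np.random.Generator = 0,
    n_ranks: int | None = None,
) -> IntervalFlags:
    """Null eigenvalue envelope from independently permuted taxon columns.

    Each replicate permutes every taxon column independently, destroying
    inter-taxon correlation while preserving each column's multiset of
    values, then recomputes the transform → Bray–Curtis → PCoA eigenvalues.
    An observed eigenvalue above its rank's 97.5% null bound is flagged
    nontrivial.
    """
    if B < 100:
        raise ValueError("B must be >= 100")
    values = _canonical_rows(np.asarray(community, dtype=float))
    n = values.shape[0]
    if n_ranks is None:
        n_ranks = n
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    observed = _eigen_desc(np.sqrt(values))[:n_ranks]
    draws = np.empty((B, observed.size))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for b in range(B):
            perm = rng.permuted(values, axis=0)
            draws[b] = _eigen_desc(np.sqrt(perm))[:n_ranks]
    lower = np.percentile(draws, 2.5, axis=0)
    upper = np.percentile(draws, 97.5, axis=0)
    flags = observed > upper
    return IntervalFlags(lower, upper, flags)


@dataclass
class NontrivialityReport:
    """Per-axis diagnostics from all four methods, ready for export."""

    eigenvalues: np.ndarray          # positive eigenvalues, descending
    proportions: np.ndarray
    broken_stick_values: np.ndarray
    broken_stick_flag: np.ndarray
    bootstrap: IntervalFlags
    null: IntervalFlags
    relative_percent: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        k = self.eigenvalues.size
        return pd.DataFrame(
            {
                "eigenvalue": self.eigenvalues,
                "proportion": self.proportions,
                "broken_stick": self.broken_stick_values,
                "broken_stick_flag": self.broken_stick_flag,
                "bootstrap_lo": self.bootstrap.lower[:k],
                "bootstrap_hi": self.bootstrap.upper[:k],
                "bootstrap_flag": self.bootstrap.flags[:k],
                "null_lo": self.null.lower[:k],
                "null_hi": self.null.upper[:k],
                "null_flag": self.null.flags[:k],
                "relative_percent": self.relative_percent,
                # the scree criterion is visual; the automated proxy flags
                # axes clearing the equal-share line of the remaining ranks
                "relative_flag": self._relative_flags(),
            },
            index=pd.RangeIndex(1, k + 1, name="axis"),
        )

    def _relative_flags(self) -> np.ndarray:
        k = self.eigenvalues.size
        remaining = k - np.arange(k)
        return self.relative_percent > 100.0 / np.maximum(remaining, 1)

    def flags_matrix(self) -> np.ndarray:
        k = self.eigenvalues.size
        return np.column_stack(
            [
                self.broken_stick_flag,
                self.bootstrap.flags[:k],
                self.null.flags[:k],
                self._relative_flags(),
            ]
        )


def nontriviality_report(
    community: pd.DataFrame,
    bootstrap_B: int = 1000,
    null_B: int = 999,
    seed: int | np.random.Generator = 0,
) -> NontrivialityReport:
    """Run all four axis diagnostics on one community matrix."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ordn = pcoa(bray_curtis(sqrt_transform(community)))
    lam = ordn.eigenvalues[ordn.eigenvalues > 0]
    k = lam.size
    return NontrivialityReport(
        eigenvalues=lam,
        proportions=lam / lam.sum(),
        broken_stick_values=broken_stick(k),
        broken_stick_flag=broken_stick_flags(lam),
        bootstrap=bootstrap_eigen_ci(community, B=bootstrap_B, seed=rng, n_ranks=k),
        null=permutation_null_eigen(community, B=null_B, seed=rng, n_ranks=k),
        relative_percent=relative_percent(lam),
    )


def nontrivial_axes(report: NontrivialityReport, rule: str = "majority") -> list[int]:
    """Combine the four methods' flags into a leading block of axis numbers.

    ``rule`` is ``any`` (>=1 method), ``majority`` (>=2 of 4, the default)
    or ``all`` (4 of 4).  The selection is a contiguous block starting at
    axis 1; if nothing is flagged a warning is emitted and the caller should
    fall back to axis 1.
    """
    thresholds = {"any": 1, "majority": 2, "all": 4}
    if rule not in thresholds:
        raise ValueError(f"unknown rule {rule!r}; choose from {sorted(thresholds)}")
    votes = report.flags_matrix().sum(axis=1)
    selected: list[int] = []
    for k, v in enumerate(votes, start=1):
        if v >= thresholds[rule]:
            selected.append(k)
        else:
            break
    if not selected:
        warnings.warn(
            "no axis flagged nontrivial under rule "
            f"{rule!r}; downstream analyses default to axis 1",
            UserWarning,
        )
    return selected
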