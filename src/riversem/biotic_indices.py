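"""Biotic indices for interpreting ordination axes.

Shannon diversity, EPT (Ephemeroptera, Plecoptera, Trichoptera) richness and
abundance, and the SIGNAL score (Stream Invertebrate Grade Number – Average
Level: the mean pollution-sensitivity grade of the taxa present).  SIGNAL
grades vary by jurisdiction and are user-supplied, never bundled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TaxonAnnotation",
    "read_annotations",
    "shannon",
    "ept_metrics",
    "signal_score",
    "site_index_table",
    "axis_index_association",
    "community_axis_heat_table",
]

EPT_ORDERS = frozenset({"Ephemeroptera", "Plecoptera", "Trichoptera"})


@dataclass(frozen=True)
class TaxonAnnotation:
    """Order-group membership and optional SIGNAL grade for one taxon."""

    taxon: str
    order_group: str = "other"
    signal_grade: float | None = None

    def __post_init__(self) -> None:
        if self.signal_grade is not None and not 1 <= self.signal_grade <= 10:
            raise ValueError(f"SIGNAL grade for {self.taxon!r} must be in [1, 10]")


def read_annotations(path) -> dict[str, TaxonAnnotation]:
    """Read a ``taxon, order_group, signal_grade`` delimited file."""
    df = pd.read_csv(path)
    df.columns = [c.strip().lower() for c in df.columns]
    out = {}
    for _, row in df.iterrows():
        grade = row.get("signal_grade")
        grade = None if pd.isna(grade) else float(grade)
        out[str(row["taxon"])] = TaxonAnnotation(
            str(row["taxon"]), str(row.get("order_group", "other")), grade
        )
    return out


def shannon(abundances) -> float:
    """Shannon diversity ``H = -sum p_i ln p_i`` over taxa present.

    Natural log; maximal (ln S) at perfectly even abundances, 0 for a
    single taxon.
    """
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("abundances must be non-negative")
    x = x[x > 0]
    if x.size == 0:
        raise ValueError("all-zero abundance row")
    p = x / x.sum()
    return float(-(p * np.log(p)).sum())


def _annotation_for(taxon: str, annotations: dict[str, TaxonAnnotation]) -> TaxonAnnotation:
    ann = annotations.get(taxon)
    if ann is None:
        warnings.warn(f"taxon {taxon!r} not annotated; treated as 'other'", UserWarning)
        ann = TaxonAnnotation(taxon)
    return ann


def ept_metrics(
    abundances: pd.Series, annotations: dict[str, TaxonAnnotation]
) -> tuple[int, int]:
    """(EPT richness, EPT abundance) for one site row.

    Richness counts EPT taxa with positive abundance; abundance sums their
    counts.  Unannotated taxa count as 'other' with a warning.
    """
    richness = 0
    total = 0
    for taxon, count in abundances.items():
        if count > 0 and _annotation_for(str(taxon), annotations).order_group in EPT_ORDERS:
            richness += 1
            total += int(count)
    return richness, total


def signal_score(
    abundances: pd.Series,
    annotations: dict[str, TaxonAnnotation],
    weighted: bool = False,
) -> float:
    """SIGNAL score of one site row.

    By default the unweighted arithmetic mean of grades over taxa present
    (presence-based); ``weighted=True`` weights grades by abundance.  Taxa
    without a grade are excluded with a warning.
    """
    grades, weights = [], []
    missing = []
    for taxon, count in abundances.items():
        if count <= 0:
            continue
        ann = _annotation_for(str(taxon), annotations)
        if ann.signal_grade is None:
            missing.append(str(taxon))
            continue
        grades.append(ann.signal_grade)
        weights.append(float(count))
    if missing:
        warnings.warn(f"taxa without SIGNAL grades excluded: {missing}", UserWarning)
    if not grades:
        raise ValueError("no graded taxa present in this row")
    grades = np.asarray(grades)
    if weighted:
        w = np.asarray(weights)
        return float((grades * w).sum() / w.sum())
    return float(grades.mean())


def site_index_table(
    community: pd.DataFrame,
    annotations: dict[str, TaxonAnnotation],
    weighted_signal: bool = False,
) -> pd.DataFrame:
    """One row per site: Shannon, EPT richness, EPT abundance, SIGNAL.

    Rows where an index is undefined (all-zero site, no graded taxa) get
    NaN with a warning.
    """
    rows = []
    for site, row in community.iterrows():
        rec: dict[str, float] = {}
        try:
            rec["shannon"] = shannon(row.to_numpy())
        except ValueError:
            warnings.warn(f"site {site!r}: all-zero row, Shannon undefined", UserWarning)
            rec["shannon"] = np.nan
        rec["ept_richness"], rec["ept_abundance"] = ept_metrics(row, annotations)
        try:
            rec["signal"] = signal_score(row, annotations, weighted=weighted_signal)
        except ValueError:
            warnings.warn(f"site {site!r}: no graded taxa, SIGNAL undefined", UserWarning)
            rec["signal"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows, index=community.index)


def axis_index_association(
    pco_scores: pd.DataFrame, index_values: pd.Series
) -> pd.DataFrame:
    """Association between each PCO axis and one biotic index.

    Per axis: OLS slope with its t-test p-value, R², and Spearman rank
    correlation with its p-value.  Spearman is invariant under strictly
    monotone transforms, so it complements the linear slope test.
    """
    y = np.asarray(index_values, dtype=float)
    if len(y) != len(pco_scores):
        raise ValueError("index values not aligned with scores")
    if len(y) < 4:
        raise ValueError("need at least 4 observations")
    if np.allclose(y, y[0]):
        raise ValueError("index is constant")
    rows = []
    for axis in pco_scores.columns:
        x = pco_scores[axis].to_numpy(dtype=float)
        fit = stats.linregress(x, y)
        rho, rho_p = stats.spearmanr(x, y)
        rows.append(
            {
                "axis": axis,
                "slope": fit.slope,
                "slope_p": fit.pvalue,
                "r_squared": fit.rvalue**2,
                "spearman_rho": rho,
                "spearman_p": rho_p,
            }
        )
    return pd.DataFrame(rows).set_index("axis")


def community_axis_heat_table(
    community: pd.DataFrame, pco_scores: pd.DataFrame, axis: str | int = 0
) -> pd.DataFrame:
    """Community matrix ordered for a heat map along one ordination axis.

    Sites are sorted by their score on the chosen axis; taxa are sorted by
    their Pearson correlation with it, so taxa driving the gradient collect
    at the extremes.  Plain data export: rendering is left to the caller.
    """
    col = pco_scores.columns[axis] if isinstance(axis, int) else axis
    scores = pco_scores[col]
    site_order = scores.sort_values(kind="stable").index
    vals = community.to_numpy(dtype=float)
    s = scores.to_numpy(dtype=float)
    s_c = s - s.mean()
    denom = np.sqrt(((vals - vals.mean(0)) ** 2).sum(0)) * np.sqrt((s_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (vals - vals.mean(0)).T @ s_c
        corr = np.where(denom > 0, corr / np.where(denom > 0, denom, 1.0), 0.0)
    taxa_order = community.columns[np.argsort(corr, kind="stable")]
    return community.loc[site_order, taxa_order]
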