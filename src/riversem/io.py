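"""Delimited-text readers and writers for the pipeline's tabular formats."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix

__all__ = [
    "read_community",
    "read_site_table",
    "read_dissimilarity",
    "write_dissimilarity",
    "check_alignment",
]


def _sep(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_community(path) -> pd.DataFrame:
    """Read a sites x taxa abundance matrix.

    First column: site id (index); header row: taxon names.  Values must be
    non-negative.
    """
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    values = df.to_numpy(dtype=float)
    if (values < 0).any():
        raise ValueError(f"{path}: negative abundances")
    df.index = df.index.astype(str)
    return df


def read_site_table(path) -> pd.DataFrame:
    """Read a per-site covariate table (first column site id)."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    df.index = df.index.astype(str)
    if "effluent" in df.columns:
        vals = set(pd.unique(df["effluent"]))
        if not vals <= {0, 1}:
            raise ValueError(f"{path}: effluent column must be binary 0/1, got {sorted(vals)}")
    return df


def check_alignment(community: pd.DataFrame, site_table: pd.DataFrame) -> None:
    """Raise with the full list of mismatched site ids, if any."""
    a, b = list(community.index), list(site_table.index)
    if a != b:
        only_c = sorted(set(a) - set(b))
        only_s = sorted(set(b) - set(a))
        detail = []
        if only_c:
            detail.append(f"only in community: {only_c}")
        if only_s:
            detail.append(f"only in site table: {only_s}")
        if not detail:
            detail.append("same ids, different order")
        raise ValueError("community/site-table site ids misaligned: " + "; ".join(detail))


def read_dissimilarity(path) -> DistanceMatrix:
    """Read a square labelled dissimilarity matrix from delimited text."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=[str(i) for i in df.index])


def write_dissimilarity(D: DistanceMatrix, path) -> None:
    pd.DataFrame(D.data, index=list(D.ids), columns=list(D.ids)).to_csv(
        path, sep=_sep(path)
    )
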