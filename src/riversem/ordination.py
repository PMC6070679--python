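"""Community dissimilarity, principal co-ordinate analysis (PCoA), and
distance-based redundancy analysis (dbRDA) with conditioning.

Community matrices are pandas DataFrames (rows = sites, columns = taxa,
index = site ids).  Dissimilarity matrices are scikit-bio
:class:`~skbio.stats.distance.DistanceMatrix` objects, which enforce
symmetry and a zero diagonal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats
from scipy.spatial.distance import pdist, squareform
from skbio.stats.distance import DistanceMatrix

__all__ = [
    "OrdinationResult",
    "DbRDAResult",
    "AliasedPredictorsError",
    "sqrt_transform",
    "bray_curtis",
    "pcoa",
    "dbrda",
    "residual_pattern_check",
    "build_design",
]

_EIG_TOL = 1e-9  # relative threshold deciding a "positive" eigenvalue


class AliasedPredictorsError(ValueError):
    """The predictor design is rank-deficient (collinear columns)."""

    def __init__(self, aliased: list[str]):
        self.aliased = list(aliased)
        super().__init__(f"aliased (collinear) predictor columns: {self.aliased}")


def sqrt_transform(community: pd.DataFrame) -> pd.DataFrame:
    """Element-wise square root of an abundance matrix.

    The classical variance-stabilising transform applied before computing
    Bray–Curtis dissimilarities, down-weighting dominant taxa.
    """
    values = np.asarray(community, dtype=float)
    if (values < 0).any():
        raise ValueError("abundances must be non-negative")
    return pd.DataFrame(np.sqrt(values), index=community.index, columns=community.columns)


def bray_curtis(community: pd.DataFrame) -> DistanceMatrix:
    """Bray–Curtis dissimilarity between sites.

    ``d(i,j) = sum_t |x_it - x_jt| / sum_t (x_it + x_jt)``, in [0, 1].
    A pair of all-zero rows is undefined (0/0) and is set to 0 with a
    warning, so that empty samples compare as identical rather than
    propagating NaN.
    """
    values = np.asarray(community, dtype=float)
    if (values < 0).any():
        raise ValueError("abundances must be non-negative")
    if values.shape[0] < 2:
        raise ValueError("need at least two sites")
    with np.errstate(invalid="ignore"):
        d = squareform(pdist(values, metric="braycurtis"))
    if np.isnan(d).any():
        warnings.warn(
            "double-zero site pairs found; their Bray-Curtis dissimilarity is set to 0",
            UserWarning,
            stacklevel=2,
        )
        d = np.nan_to_num(d, nan=0.0)
    return DistanceMatrix(d, ids=[str(i) for i in community.index])


@dataclass
class OrdinationResult:
    """Eigenvalues and site scores from a principal co-ordinate analysis.

    ``eigenvalues`` keeps the full spectrum (negatives included — Bray–Curtis
    is not Euclidean-embeddable in general); ``scores`` holds one column per
    *positive* eigenvalue, scaled so each column's sum of squares equals its
    eigenvalue.  ``trace`` is the sum of positive eigenvalues (the total
    inertia used in downstream decompositions).
    """

    eigenvalues: np.ndarray
    scores: pd.DataFrame
    trace: float

    @property
    def proportions(self) -> np.ndarray:
        """Per-positive-axis proportion of positive inertia."""
        lam = self.eigenvalues[self.eigenvalues > 0]
        return lam / lam.sum()


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _fix_signs(scores: np.ndarray) -> np.ndarray:
    # eigenvector sign is arbitrary; force the largest-magnitude loading
    # of each axis positive for deterministic output
    for k in range(scores.shape[1]):
        col = scores[:, k]
        if col[np.argmax(np.abs(col))] < 0:
            scores[:, k] = -col
    return scores


def pcoa(D: DistanceMatrix, lingoes: bool = False) -> OrdinationResult:
    """Classical principal co-ordinate analysis (Gower 1966).

    Eigendecomposes the Gower-centred matrix ``-1/2 J D^2 J``.  Axes are
    ordered by eigenvalue, descending.  With ``lingoes=True`` a Lingoes
    correction (adding a constant to squared off-diagonal dissimilarities)
    removes negative eigenvalues first; off by default.
    """
    d = np.asarray(D.data, dtype=float)
    b = _gower_center(d)
    lam, vec = np.linalg.eigh(b)
    order = np.argsort(lam)[::-1]
    lam, vec = lam[order], vec[:, order]

    if lingoes and lam[-1] < 0:
        c = -lam[-1]
        d2 = d**2 + 2 * c
        np.fill_diagonal(d2, 0.0)
        b = _gower_center(np.sqrt(d2))
        lam, vec = np.linalg.eigh(b)
        order = np.argsort(lam)[::-1]
        lam, vec = lam[order], vec[:, order]

    tol = _EIG_TOL * max(abs(lam[0]), 1.0)
    pos = lam > tol
    scores = vec[:, pos] * np.sqrt(lam[pos])
    scores = _fix_signs(scores)
    cols = [f"PCO{k + 1}" for k in range(scores.shape[1])]
    return OrdinationResult(
        eigenvalues=lam,
        scores=pd.DataFrame(scores, index=list(D.ids), columns=cols),
        trace=float(lam[pos].sum()),
    )


def build_design(table: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Assemble a design matrix (no intercept column) from term strings.

    A term is either a column name or a ``a:b`` / ``a:b:c`` product of
    columns (an interaction).  The intercept is handled implicitly by
    centring inside the fitting routines.
    """
    cols = {}
    for term in terms:
        parts = [p.strip() for p in term.split(":")]
        for p in parts:
            if p not in table.columns:
                raise KeyError(f"design term {term!r}: column {p!r} not in table")
        col = table[parts[0]].astype(float).to_numpy().copy()
        for p in parts[1:]:
            col = col * table[p].astype(float).to_numpy()
        cols[term] = col
    return pd.DataFrame(cols, index=table.index)


def _orth_basis(x: np.ndarray, names: list[str]) -> tuple[np.ndarray, int]:
    """Column-pivoted QR orthonormal basis; raises naming aliased columns."""
    if x.shape[1] == 0:
        return np.empty((x.shape[0], 0)), 0
    q, r, piv = sla.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = max(x.shape) * np.finfo(float).eps * (diag[0] if diag.size else 0.0)
    rank = int((diag > tol).sum())
    if rank < x.shape[1]:
        aliased = [names[j] for j in piv[rank:]]
        raise AliasedPredictorsError(aliased)
    return q[:, :rank], rank


@dataclass
class DbRDAResult:
    """Inertia decomposition and permutation test from a dbRDA fit.

    ``conditional + constrained + residual`` equals the total positive
    inertia of the underlying PCoA.  ``pseudo_F`` compares constrained to
    residual inertia per degree of freedom; ``permutation_p`` uses
    ``(1 + #{F_perm >= F_obs}) / (1 + n_permutations)``.
    """

    constrained_inertia: float
    conditional_inertia: float
    residual_inertia: float
    total_inertia: float
    pseudo_F: float
    permutation_p: float
    n_permutations: int
    df_constrained: int
    df_condition: int
    df_residual: int
    constrained_axis_scores: pd.DataFrame
    residual_scores: pd.DataFrame
    fitted_scores: pd.DataFrame
    coefficients: pd.DataFrame = field(repr=False, default=None)
    ordination: OrdinationResult = field(repr=False, default=None)


def dbrda(
    D: DistanceMatrix | OrdinationResult,
    predictors: pd.DataFrame,
    condition: pd.DataFrame | None = None,
    n_permutations: int = 999,
    seed: int | np.random.Generator = 0,
) -> DbRDAResult:
    """Distance-based redundancy analysis with optional conditioning.

    The dissimilarity matrix is embedded by PCoA; the positive-eigenvalue
    site scores are (1) residualised on the centred ``condition`` columns if
    given, then (2) projected onto the span of the (equally residualised,
    centred) ``predictors``.  The permutation test permutes rows of the
    conditioned response scores with the predictors fixed (reduced-model
    permutation).

    ``D`` may be a precomputed :class:`OrdinationResult` to avoid repeating
    the PCoA when several models share one dissimilarity matrix.
    """
    ordn = D if isinstance(D, OrdinationResult) else pcoa(D)
    y = ordn.scores.to_numpy()
    n = y.shape[0]
    ids = list(ordn.scores.index)
    if list(map(str, predictors.index)) != list(map(str, ids)):
        raise ValueError("predictor rows are not aligned with the dissimilarity labels")
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")

    y = y - y.mean(axis=0)  # PCoA scores are centred already; keep exact
    x = predictors.to_numpy(dtype=float)
    x = x - x.mean(axis=0)
    x_names = list(predictors.columns)

    cond_inertia = 0.0
    c = 0
    if condition is not None and condition.shape[1] > 0:
        if list(map(str, condition.index)) != list(map(str, ids)):
            raise ValueError("condition rows are not aligned with the dissimilarity labels")
        z = condition.to_numpy(dtype=float)
        z = z - z.mean(axis=0)
        qz, c = _orth_basis(z, list(condition.columns))
        proj = qz @ (qz.T @ y)
        cond_inertia = float((proj**2).sum())
        y = y - proj
        x = x - qz @ (qz.T @ x)

    qx, q = _orth_basis(x, x_names)
    if n < q + c + 2:
        raise ValueError(f"too few rows (n={n}) for {q} predictors and {c} condition columns")

    coefs_y = qx.T @ y
    fitted = qx @ coefs_y
    constrained = float((coefs_y**2).sum())
    residual = float((y**2).sum()) - constrained
    residual = max(residual, 0.0)
    df_resid = n - q - c - 1
    f_obs = (constrained / q) / (residual / df_resid) if residual > 0 else np.inf

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    hits = 0
    denom = residual + constrained  # invariant under row permutation of y
    for _ in range(n_permutations):
        yp = y[rng.permutation(n)]
        cperm = float(((qx.T @ yp) ** 2).sum())
        rperm = denom - cperm
        f_perm = (cperm / q) / (rperm / df_resid) if rperm > 0 else np.inf
        if f_perm >= f_obs:
            hits += 1
    perm_p = (1 + hits) / (1 + n_permutations)

    # constrained axes: SVD of the fitted scores
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    keep = s > _EIG_TOL * max(s[0] if s.size else 0.0, 1.0)
    axes = _fix_signs(u[:, keep] * s[keep])
    axis_cols = [f"dbRDA{k + 1}" for k in range(axes.shape[1])]

    resid_scores = y - fitted
    # regression coefficients of scores on the (residualised) raw predictors
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    coefficients = pd.DataFrame(beta, index=x_names, columns=list(ordn.scores.columns))

    return DbRDAResult(
        constrained_inertia=constrained,
        conditional_inertia=cond_inertia,
        residual_inertia=residual,
        total_inertia=float(ordn.trace),
        pseudo_F=float(f_obs),
        permutation_p=float(perm_p),
        n_permutations=n_permutations,
        df_constrained=q,
        df_condition=c,
        df_residual=df_resid,
        constrained_axis_scores=pd.DataFrame(axes, index=ids, columns=axis_cols),
        residual_scores=pd.DataFrame(resid_scores, index=ids, columns=list(ordn.scores.columns)),
        fitted_scores=pd.DataFrame(fitted, index=ids, columns=list(ordn.scores.columns)),
        coefficients=coefficients,
        ordination=ordn,
    )


def residual_pattern_check(
    result: DbRDAResult,
    site_table: pd.DataFrame,
    distance_col: str = "distance",
    time_col: str = "time",
) -> pd.DataFrame:
    """Test each residual axis for leftover spatial or temporal trend.

    For every residual-score axis, an ordinary least-squares slope test
    against distance and against time.  A well-specified spatiotemporal
    model leaves residuals with no trend, so these p-values should look
    uniform.  Constant (zero-variance) residual axes get ``p = 1`` by
    convention, with a warning.
    """
    rows = []
    for axis in result.residual_scores.columns:
        resid = result.residual_scores[axis].to_numpy()
        row: dict[str, float | str] = {"axis": axis}
        for label, col in (("distance", distance_col), ("time", time_col)):
            xvals = site_table[col].to_numpy(dtype=float)
            if np.allclose(resid, resid[0]) or np.allclose(xvals, xvals[0]):
                warnings.warn(
                    f"residual axis {axis} (or {label}) is constant; p set to 1",
                    UserWarning,
                    stacklevel=2,
                )
                row[f"{label}_slope"] = 0.0
                row[f"{label}_p"] = 1.0
            else:
                fit = stats.linregress(xvals, resid)
                row[f"{label}_slope"] = float(fit.slope)
                row[f"{label}_p"] = float(fit.pvalue)
        rows.append(row)
    return pd.DataFrame(rows).set_index("axis")
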