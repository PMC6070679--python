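"""Piecewise structural equation modelling over a causal diagram.

Each child node in the diagram gets a structural equation: an ordinary
least-squares regression on its parents (with declared interaction or
derived terms) for environmental variables, or a dbRDA on the community
dissimilarity matrix for the multivariate community node.  The diagram's
*missing* arrows are tested through its basis set of d-separation
statements — nested-F tests for pairs of environmental variables,
conditioned dbRDA permutation tests when the community is involved — and the
local p-values are combined into Fisher's C, chi-square with 2k degrees of
freedom under the composite null.  A diagram that survives both local and
global tests supports intervention (do-operator) prediction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .causal_graph import BasisSet, CausalDiagram, DSepStatement, basis_set
from .ordination import (
    AliasedPredictorsError,
    DbRDAResult,
    OrdinationResult,
    bray_curtis,
    build_design,
    dbrda,
    pcoa,
    sqrt_transform,
)

__all__ = [
    "COMMUNITY",
    "StructuralEquation",
    "CITestResult",
    "FisherCResult",
    "ModelEvaluation",
    "derive_structural_equations",
    "fit_equation",
    "local_ci_test",
    "fishers_c",
    "evaluate_model",
    "predict_intervention",
    "kfold_predictive_r2",
]

COMMUNITY = "COMMUNITY"

_P_FLOOR = 1e-300  # analytic underflow clamp keeping Fisher's C finite

# a derived design column: table -> values, plus the diagram variables it uses
DerivedFeatures = Mapping[str, Callable[[pd.DataFrame], np.ndarray]]


@dataclass
class StructuralEquation:
    """One equation of the piecewise SEM.

    ``terms`` are the design columns (main effects, ``a:b`` interactions, or
    derived columns present in the site table) representing the child's
    direct causes.  For the community node the fit is a dbRDA rather than a
    univariate regression.
    """

    child: str
    parents: tuple[str, ...]
    terms: tuple[str, ...]
    multivariate: bool = False
    coefficients: pd.Series | None = None
    residual_sd: float | None = None
    results: object = field(default=None, repr=False)   # statsmodels or DbRDAResult
    anova: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def is_fitted(self) -> bool:
        return self.results is not None


def derive_structural_equations(
    diagram: CausalDiagram,
    formulas: Mapping[str, Sequence[str]] | None = None,
    community_node: str = COMMUNITY,
) -> list[StructuralEquation]:
    """Read one structural equation per non-exogenous node off the diagram.

    Parents come straight from the arrows; ``formulas`` may override the
    default main-effect terms with interaction or derived-column terms
    (their functional form is part of the causal hypothesis).  Exogenous
    nodes get no equation.
    """
    formulas = dict(formulas or {})
    equations = []
    for node in diagram.topological_order:
        parents = diagram.parents(node)
        if not parents:
            continue
        ordered = tuple(sorted(parents, key=diagram.nodes.index))
        terms = tuple(formulas.get(node, ordered))
        equations.append(
            StructuralEquation(
                child=node,
                parents=ordered,
                terms=terms,
                multivariate=(node == community_node),
            )
        )
    return equations


def _with_derived(table: pd.DataFrame, derived: DerivedFeatures | None) -> pd.DataFrame:
    if not derived:
        return table
    table = table.copy()
    for name, func in derived.items():
        table[name] = np.asarray(func(table), dtype=float)
    return table


def fit_equation(
    eq: StructuralEquation,
    site_table: pd.DataFrame,
    community: pd.DataFrame | None = None,
    derived: DerivedFeatures | None = None,
    n_permutations: int = 999,
    seed: int | np.random.Generator = 0,
) -> StructuralEquation:
    """Fit one structural equation.

    Univariate children use OLS (statsmodels) with a sequential ANOVA
    decomposition; the community child is fitted by dbRDA on the Bray–Curtis
    matrix of the square-root-transformed abundances.
    """
    table = _with_derived(site_table, derived)
    if eq.multivariate:
        if community is None:
            raise ValueError(f"equation for {eq.child!r} needs a community matrix")
        D = bray_curtis(sqrt_transform(community))
        res = dbrda(
            D,
            build_design(table, list(eq.terms)),
            n_permutations=n_permutations,
            seed=seed,
        )
        coefs = res.coefficients.iloc[:, 0] if res.coefficients is not None else None
        return replace(eq, results=res, coefficients=coefs)

    design = build_design(table, list(eq.terms))
    x = sm.add_constant(design, has_constant="add")
    rank = np.linalg.matrix_rank(x.to_numpy())
    if rank < x.shape[1]:
        # name the columns that do not add rank, scanning left to right
        aliased, kept = [], []
        for colname in x.columns:
            trial = kept + [colname]
            if np.linalg.matrix_rank(x[trial].to_numpy()) == len(trial):
                kept = trial
            else:
                aliased.append(colname)
        raise AliasedPredictorsError(aliased)
    y = table[eq.child].astype(float)
    if len(y) < x.shape[1] + 1:
        raise ValueError(f"too few rows ({len(y)}) to fit {eq.child!r}")
    fit = sm.OLS(y, x).fit()

    # sequential (type I) ANOVA decomposition over the declared terms
    rows = []
    rss_prev = float(((y - y.mean()) ** 2).sum())
    cols = ["const"]
    for term in design.columns:
        cols.append(term)
        sub = sm.OLS(y, x[cols]).fit()
        rss = float(sub.ssr)
        rows.append({"term": term, "sum_sq": rss_prev - rss, "df": 1})
        rss_prev = rss
    anova = pd.DataFrame(rows).set_index("term")
    anova["mean_sq"] = anova["sum_sq"] / anova["df"]
    mse = fit.ssr / fit.df_resid if fit.df_resid > 0 else np.nan
    anova["F"] = anova["mean_sq"] / mse
    anova["p"] = stats.f.sf(anova["F"], anova["df"], fit.df_resid)

    return replace(
        eq,
        results=fit,
        coefficients=fit.params,
        residual_sd=float(np.sqrt(fit.ssr / fit.df_resid)) if fit.df_resid > 0 else 0.0,
        anova=anova,
    )


def partial_regression_data(
    eq: StructuralEquation,
    site_table: pd.DataFrame,
    derived: DerivedFeatures | None = None,
) -> dict[str, pd.DataFrame]:
    """Added-variable (partial regression) data per term, for plotting.

    For each term, the residuals of the response and of the term after
    regressing both on the remaining terms.  The slope of each cloud equals
    the term's multiple-regression coefficient.
    """
    if not eq.is_fitted or eq.multivariate:
        raise ValueError("needs a fitted univariate equation")
    table = _with_derived(site_table, derived)
    design = build_design(table, list(eq.terms))
    y = table[eq.child].astype(float).to_numpy()
    out = {}
    for term in design.columns:
        others = sm.add_constant(design.drop(columns=[term]), has_constant="add").to_numpy()
        xv = design[term].to_numpy()
        beta_y, *_ = np.linalg.lstsq(others, y, rcond=None)
        beta_x, *_ = np.linalg.lstsq(others, xv, rcond=None)
        out[term] = pd.DataFrame(
            {"x_resid": xv - others @ beta_x, "y_resid": y - others @ beta_y},
            index=table.index,
        )
    return out


@dataclass
class CITestResult:
    """Outcome of one local conditional-independence test."""

    statement: DSepStatement
    test_kind: str              # "nested_F" or "conditioned_dbrda"
    statistic: float
    df: tuple
    p_value: float
    response: str
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "statement": str(self.statement),
            "test_kind": self.test_kind,
            "statistic": float(self.statistic),
            "df": [int(v) for v in self.df],
            "p_value": float(self.p_value),
            "response": self.response,
            "note": self.note,
        }


def _conditioning_terms(
    statement: DSepStatement,
    response: str,
    diagram: CausalDiagram,
    formulas: Mapping[str, Sequence[str]] | None,
) -> list[str]:
    """Design columns for the conditioning set of one statement.

    The response's declared equation terms stand in for its parents
    (retaining their functional form, as in piecewise SEM d-sep tests);
    conditioning variables not among the response's parents enter as main
    effects.
    """
    formulas = dict(formulas or {})
    resp_parents = diagram.parents(response) if response in diagram._parents else frozenset()
    terms = list(formulas.get(response, sorted(resp_parents, key=diagram.nodes.index)))
    order = {n: i for i, n in enumerate(diagram.nodes)}
    extra = sorted(statement.given - resp_parents, key=lambda v: order[v])
    for v in extra:
        if v not in terms:
            terms.append(v)
    return terms


def _nested_f(
    y: np.ndarray, z_design: np.ndarray, x_new: np.ndarray
) -> tuple[float, tuple, float, str]:
    """F test of adding one column to a least-squares fit."""
    n = y.size
    ones = np.ones((n, 1))
    reduced = np.hstack([ones, z_design]) if z_design.size else ones
    full = np.hstack([reduced, x_new[:, None]])
    rank_r = np.linalg.matrix_rank(reduced)
    rank_f = np.linalg.matrix_rank(full)
    df2 = n - rank_f
    if df2 < 1:
        raise ValueError("zero residual degrees of freedom")
    beta_r, *_ = np.linalg.lstsq(reduced, y, rcond=None)
    rss_r = float(((y - reduced @ beta_r) ** 2).sum())
    if rank_f == rank_r:
        return 0.0, (0, df2), 1.0, "added variable aliased with conditioning set"
    beta_f, *_ = np.linalg.lstsq(full, y, rcond=None)
    rss_f = float(((y - full @ beta_f) ** 2).sum())
    scale = float((y**2).sum()) + 1.0
    if rss_r <= 1e-12 * scale:
        return 0.0, (1, df2), 1.0, "response has no residual variance given the conditioning set"
    f_stat = max((rss_r - rss_f) / (rss_f / df2), 0.0) if rss_f > 0 else np.inf
    p = float(stats.f.sf(f_stat, 1, df2))
    return float(f_stat), (1, df2), max(p, _P_FLOOR), ""


def local_ci_test(
    statement: DSepStatement,
    diagram: CausalDiagram,
    site_table: pd.DataFrame,
    community: pd.DataFrame | None = None,
    formulas: Mapping[str, Sequence[str]] | None = None,
    derived: DerivedFeatures | None = None,
    n_permutations: int = 199,
    seed: int | np.random.Generator = 0,
    community_node: str = COMMUNITY,
    ordination: OrdinationResult | None = None,
) -> CITestResult:
    """Test one d-separation statement against data.

    Two environmental variables: a nested-model F test of adding the earlier
    variable to the regression of the later (topological order; conditional
    independence is symmetric but the F test needs a response).  Community
    involved: a conditioned dbRDA permutation test of the other variable
    with the conditioning design as ``condition``.  ``ordination`` may carry
    a precomputed PCoA shared across statements.
    """
    table = _with_derived(site_table, derived)
    x, y = statement.x, statement.y

    if community_node in (x, y):
        other = y if x == community_node else x
        if community is None and ordination is None:
            raise ValueError("statement involves the community but no community data given")
        cond_terms = _conditioning_terms(statement, community_node, diagram, formulas)
        ordn = ordination
        if ordn is None:
            ordn = pcoa(bray_curtis(sqrt_transform(community)))
        cond = build_design(table, cond_terms) if cond_terms else None
        pred = build_design(table, [other])
        pred.index = ordn.scores.index
        if cond is not None:
            cond.index = ordn.scores.index
        res = dbrda(ordn, pred, condition=cond, n_permutations=n_permutations, seed=seed)
        return CITestResult(
            statement=statement,
            test_kind="conditioned_dbrda",
            statistic=res.pseudo_F,
            df=(res.df_constrained, res.df_residual, n_permutations),
            p_value=res.permutation_p,
            response=community_node,
        )

    pos = {n: i for i, n in enumerate(diagram.topological_order)}
    response, added = (y, x) if pos[y] > pos[x] else (x, y)
    cond_terms = _conditioning_terms(statement, response, diagram, formulas)
    z = build_design(table, cond_terms).to_numpy() if cond_terms else np.empty((len(table), 0))
    yv = table[response].astype(float).to_numpy()
    xv = table[added].astype(float).to_numpy()
    f_stat, dfs, p, note = _nested_f(yv, z, xv)
    if note:
        warnings.warn(f"{statement}: {note}; p set to 1", UserWarning, stacklevel=2)
    return CITestResult(
        statement=statement,
        test_kind="nested_F",
        statistic=f_stat,
        df=dfs,
        p_value=p,
        response=response,
        note=note,
    )


@dataclass
class FisherCResult:
    """Fisher's C over k local p-values: ``C = -2 sum ln p``, chi-square 2k."""

    C: float
    k: int
    df: int
    p_value: float

    def to_dict(self) -> dict:
        return {"C": self.C, "k": self.k, "df": self.df, "p_value": self.p_value}


def fishers_c(p_values: Sequence[float]) -> FisherCResult:
    """Combine local conditional-independence p-values into a global test.

    ``C = -2 * sum(ln p_i)`` follows a chi-square distribution with ``2k``
    degrees of freedom when every tested independence holds.  Zero p-values
    (analytic underflow) are clamped at 1e-300 with a warning.
    """
    ps = np.asarray(list(p_values), dtype=float)
    if ps.size == 0:
        raise ValueError("need at least one p-value")
    if (ps < 0).any() or (ps > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    if (ps == 0).any():
        warnings.warn("p-value of 0 clamped to 1e-300", UserWarning, stacklevel=2)
        ps = np.maximum(ps, _P_FLOOR)
    c = float(-2.0 * np.log(ps).sum())
    k = int(ps.size)
    return FisherCResult(C=c, k=k, df=2 * k, p_value=float(stats.chi2.sf(c, 2 * k)))


@dataclass
class ModelEvaluation:
    """Joint outcome of all local tests plus the global Fisher's C test."""

    diagram: CausalDiagram
    results: list[CITestResult]
    untestable: list[DSepStatement]
    fisher: FisherCResult | None
    alpha: float
    status: str                 # "tested" | "vacuously_consistent" | "nothing_testable"

    @property
    def consistent(self) -> bool | None:
        if self.fisher is None:
            return True if self.status == "vacuously_consistent" else None
        return self.fisher.p_value > self.alpha

    def to_dict(self) -> dict:
        return {
            "status": self.status,
            "alpha": self.alpha,
            "consistent": self.consistent,
            "fisher_c": self.fisher.to_dict() if self.fisher else None,
            "local_tests": [r.to_dict() for r in self.results],
            "untestable": [str(s) for s in self.untestable],
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def to_text(self) -> str:
        lines = [f"Model evaluation (alpha = {self.alpha})", "-" * 46]
        for r in self.results:
            flag = "*" if r.p_value <= self.alpha else " "
            lines.append(
                f"{flag} {r.statement}  [{r.test_kind}]  stat={r.statistic:.4g}  p={r.p_value:.4g}"
            )
        for s in self.untestable:
            lines.append(f"  {s}  [untestable]")
        if self.fisher:
            f = self.fisher
            lines.append("-" * 46)
            lines.append(f"Fisher's C = {f.C:.4f}, df = {f.df}, p = {f.p_value:.4g}")
            verdict = "consistent with the data" if self.consistent else "rejected"
            lines.append(f"Causal structure {verdict} at alpha = {self.alpha}.")
        else:
            lines.append(f"status: {self.status}")
        return "\n".join(lines)


def evaluate_model(
    diagram: CausalDiagram,
    site_table: pd.DataFrame,
    community: pd.DataFrame | None = None,
    formulas: Mapping[str, Sequence[str]] | None = None,
    derived: DerivedFeatures | None = None,
    alpha: float = 0.05,
    n_permutations: int = 199,
    seed: int = 0,
    community_node: str = COMMUNITY,
) -> ModelEvaluation:
    """Test every basis-set statement and combine them with Fisher's C.

    Statements referencing variables with no data column (latent constructs,
    or the community node when no community matrix is supplied) are itemised
    as untestable and excluded from ``k``; they are never silently dropped.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    basis = basis_set(diagram)
    if len(basis) == 0:
        return ModelEvaluation(diagram, [], [], None, alpha, "vacuously_consistent")

    table = _with_derived(site_table, derived)
    available = set(table.columns)
    if community is not None:
        available.add(community_node)

    testable, untestable = [], []
    for st in basis:
        vars_needed = {st.x, st.y} | set(st.given)
        if vars_needed <= available:
            testable.append(st)
        else:
            untestable.append(st)
    if not testable:
        return ModelEvaluation(diagram, [], untestable, None, alpha, "nothing_testable")

    ordn = None
    if community is not None and any(community_node in (s.x, s.y) for s in testable):
        ordn = pcoa(bray_curtis(sqrt_transform(community)))

    seeds = np.random.SeedSequence(seed).spawn(len(testable))
    results = []
    for st, ss in zip(testable, seeds):
        results.append(
            local_ci_test(
                st,
                diagram,
                table,
                community=community,
                formulas=formulas,
                derived=None,  # already applied
                n_permutations=n_permutations,
                seed=np.random.default_rng(ss),
                community_node=community_node,
                ordination=ordn,
            )
        )
    fisher = fishers_c([r.p_value for r in results])
    return ModelEvaluation(diagram, results, untestable, fisher, alpha, "tested")


def predict_intervention(
    equations: Sequence[StructuralEquation],
    diagram: CausalDiagram,
    intervention: Mapping[str, float],
    site_table: pd.DataFrame,
    derived: DerivedFeatures | None = None,
    community_node: str = COMMUNITY,
    model_accepted: bool = True,
) -> dict[str, pd.Series | pd.DataFrame]:
    """Predict the effect of a do-intervention through the fitted equations.

    Arrows into intervened nodes are cut by construction: the intervened
    columns are fixed at their assigned values and every downstream equation
    is evaluated in topological order on the *propagated* parent values
    (derived design columns are recomputed at each step).  The community
    node's response is returned as the predicted shift in its fitted
    ordination scores.  An empty intervention reproduces the observational
    fitted values.
    """
    node_set = set(diagram.nodes)
    for v in intervention:
        if v not in node_set:
            raise KeyError(f"cannot intervene on undefined variable {v!r}")
        if v == community_node:
            raise ValueError("cannot intervene on the community node")
    if not model_accepted:
        warnings.warn(
            "intervention predicted from a model that was not accepted by the "
            "conditional-independence tests; interpret causally with caution",
            UserWarning,
        )
    by_child = {eq.child: eq for eq in equations}
    for eq in equations:
        if not eq.is_fitted:
            raise ValueError(f"equation for {eq.child!r} is not fitted")

    base = _with_derived(site_table, derived)
    table = site_table.copy()
    for v, val in intervention.items():
        table[v] = val

    predictions: dict[str, pd.Series | pd.DataFrame] = {}
    for node in diagram.topological_order:
        if node in intervention:
            predictions[node] = pd.Series(table[node], index=table.index, name=node)
            continue
        eq = by_child.get(node)
        if eq is None:
            continue
        work = _with_derived(table, derived)
        design = build_design(work, list(eq.terms))
        if eq.multivariate:
            res: DbRDAResult = eq.results
            base_design = build_design(base, list(eq.terms))
            delta = design.to_numpy() - base_design.to_numpy()
            shift = delta @ res.coefficients.to_numpy()
            predictions[node] = pd.DataFrame(
                shift, index=table.index, columns=list(res.coefficients.columns)
            )
        else:
            x = sm.add_constant(design, has_constant="add")
            x = x[list(eq.results.params.index)]
            yhat = x.to_numpy() @ eq.results.params.to_numpy()
            predictions[node] = pd.Series(yhat, index=table.index, name=node)
            table[node] = yhat
    return predictions


def kfold_predictive_r2(
    eq: StructuralEquation,
    site_table: pd.DataFrame,
    k: int = 5,
    seed: int = 0,
    derived: DerivedFeatures | None = None,
) -> float:
    """Generic k-fold out-of-sample R² for one univariate equation.

    A model-revision aid only: an interpretation of the cross-validation
    step, not part of the conditional-independence machinery.
    """
    if eq.multivariate:
        raise ValueError("cross-validation utility covers univariate equations only")
    table = _with_derived(site_table, derived)
    design = sm.add_constant(build_design(table, list(eq.terms)), has_constant="add")
    x = design.to_numpy()
    y = table[eq.child].astype(float).to_numpy()
    n = len(y)
    rng = np.random.default_rng(seed)
    folds = np.array_split(rng.permutation(n), k)
    press = 0.0
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        beta, *_ = np.linalg.lstsq(x[mask], y[mask], rcond=None)
        press += float(((y[fold] - x[fold] @ beta) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / tss
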