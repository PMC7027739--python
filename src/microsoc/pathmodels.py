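"""Piecewise structural equation modelling on a directed acyclic graph.

A path model is a DAG of causal hypotheses among plot-level variables.
Each endogenous vertex is fitted as a linear mixed model on its parents
(block random intercept, ML), giving raw and standardized path
coefficients.  Overall model fit uses the test of directed separation: the
DAG implies one conditional-independence claim per non-adjacent vertex
pair (conditioning on the union of both vertices' parents); each claim is
tested by regressing the later vertex (in topological order) on the
earlier plus the conditioning set, and the claim p-values are combined
into Fisher's C = -2 sum(ln p) ~ chi-squared with 2k degrees of freedom.
Model comparison uses the likelihood-free AIC of this framework,
AIC = C + 2K, and its small-sample variant AICc = C + 2K n/(n-K-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .designstats import (DEFAULT_TRANSFORMS, apply_transform, fit_lmm,
                          significance_code)
from .errors import GraphError, SchemaError, UndefinedValueError
from .lmm import LMMResults

__all__ = [
    "PathModel",
    "DsepClaim",
    "basis_set",
    "dsep_pvalue",
    "fishers_c",
    "PiecewiseSEM",
    "SEMResults",
    "default_path_model",
]


@dataclass(frozen=True)
class DsepClaim:
    """An implied conditional independence: x is independent of y given cond."""

    x: str
    y: str
    cond: tuple[str, ...]

    def __str__(self) -> str:
        given = ", ".join(self.cond) if self.cond else "{}"
        return f"{self.x} _||_ {self.y} | {given}"


class PathModel:
    """DAG of causal hypotheses with per-vertex transform labels.

    Edges are ordered (cause, effect) pairs.  Vertices with no parents are
    exogenous; every endogenous vertex is fitted on its parent set.
    """

    def __init__(self, edges, transforms: dict[str, str] | None = None):
        g = nx.DiGraph()
        g.add_edges_from(edges)
        if len(g) == 0:
            raise GraphError("path model has no edges")
        if not nx.is_directed_acyclic_graph(g):
            raise GraphError("path model contains a cycle (not a DAG)")
        self.graph = g
        self.transforms = dict(transforms or {})
        # deterministic causal ordering
        self.order: list[str] = list(nx.lexicographical_topological_sort(g))
        self._rank = {v: i for i, v in enumerate(self.order)}

    @property
    def vertices(self) -> list[str]:
        return self.order

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted(self.graph.edges(), key=lambda e: (self._rank[e[0]],
                                                         self._rank[e[1]]))

    @property
    def endogenous(self) -> list[str]:
        return [v for v in self.order if self.graph.in_degree(v) > 0]

    @property
    def exogenous(self) -> list[str]:
        return [v for v in self.order if self.graph.in_degree(v) == 0]

    def parents(self, v: str) -> list[str]:
        return sorted(self.graph.predecessors(v), key=self._rank.get)

    @classmethod
    def from_text(cls, text: str) -> "PathModel":
        """Parse a plain-text edge list, one ``cause -> effect`` per line.

        Lines starting with ``# transforms:`` declare per-vertex transforms
        as ``name=log`` pairs; other ``#`` lines are comments.
        """
        if isinstance(text, Path) or (isinstance(text, str) and "\n" not in text
                                      and text.endswith(".txt")):
            text = Path(text).read_text()
        edges, transforms = [], {}
        for raw in text.splitlines():
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("transforms:"):
                    for pair in body.split(":", 1)[1].replace(",", " ").split():
                        name, _, tr = pair.partition("=")
                        if not tr:
                            raise SchemaError(f"bad transform spec {pair!r}")
                        transforms[name.strip()] = tr.strip()
                continue
            if "->" not in line:
                raise SchemaError(f"bad edge line {line!r}")
            cause, effect = (s.strip() for s in line.split("->", 1))
            if not cause or not effect:
                raise SchemaError(f"bad edge line {line!r}")
            edges.append((cause, effect))
        return cls(edges, transforms)

    def to_text(self) -> str:
        lines = []
        if self.transforms:
            pairs = " ".join(f"{k}={v}" for k, v in sorted(self.transforms.items()))
            lines.append(f"# transforms: {pairs}")
        lines += [f"{a} -> {b}" for a, b in self.edges]
        return "\n".join(lines) + "\n"


def default_path_model() -> PathModel:
    """The plant-diversity -> soil-carbon causal chain used by the pipeline.

    log species richness drives root carbon input, microbial growth and
    microbial biomass; root carbon feeds growth and biomass; growth feeds
    biomass and respiration; biomass drives soil organic carbon.
    """
    edges = [
        ("psr_log", "root_c"),
        ("psr_log", "growth"),
        ("root_c", "growth"),
        ("psr_log", "cmic"),
        ("growth", "cmic"),
        ("root_c", "cmic"),
        ("growth", "respiration"),
        ("cmic", "soc"),
    ]
    transforms = {"root_c": "log", "growth": "sqrt"}
    return PathModel(edges, transforms)


def basis_set(model: PathModel) -> list[DsepClaim]:
    """The d-separation basis set of a DAG.

    One claim per non-adjacent vertex pair, conditioning on the union of
    the parents of both vertices; the later vertex in topological order is
    treated as the response when the claim is tested.
    """
    claims = []
    order = model.order
    g = model.graph
    for i, x in enumerate(order):
        for y in order[i + 1:]:
            if g.has_edge(x, y) or g.has_edge(y, x):
                continue
            cond = (set(g.predecessors(x)) | set(g.predecessors(y))) - {x, y}
            claims.append(DsepClaim(x, y, tuple(sorted(cond, key=model._rank.get))))
    return claims


def dsep_pvalue(claim: DsepClaim, data: pd.DataFrame,
                groups: str = "block") -> float:
    """Two-sided p-value for one independence claim.

    The claim's response is modelled on the earlier vertex plus the
    conditioning set with a block random intercept; the p-value of the
    earlier vertex's coefficient tests the implied independence.  Variables
    must already be on their analysis (transformed) scale.
    """
    res = fit_lmm(data, claim.y, [claim.x, *claim.cond], groups=groups)
    return float(res.pvalues[claim.x])


def fishers_c(pvalues, eps: float = 1e-16) -> tuple[float, int, float]:
    """Fisher's C over k independence-claim p-values.

    ``C = -2 sum(ln p_i)`` compared to chi-squared with ``2k`` degrees of
    freedom.  Zero p-values are floored at ``eps`` (with a warning wired at
    the call sites) to keep C finite.
    """
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return 0.0, 0, 1.0
    if np.any((p < 0) | (p > 1)):
        raise UndefinedValueError("claim p-values must be in [0, 1]")
    p = np.clip(p, eps, 1.0)
    C = float(-2.0 * np.log(p).sum())
    df = 2 * p.size
    return C, df, float(stats.chi2.sf(C, df))


class PiecewiseSEM:
    """Piecewise SEM of a :class:`PathModel` on plot-level data.

    Parameters
    ----------
    model : PathModel
        The causal DAG.  Per-vertex transforms come from the model, falling
        back to the package-wide defaults.
    data : DataFrame
        One row per plot; must contain every model vertex plus the random
        intercept column.
    groups : str
        Column holding the block labels (default ``'block'``).
    """

    def __init__(self, model: PathModel, data: pd.DataFrame,
                 groups: str = "block"):
        self.model = model
        self.groups = groups
        missing = [v for v in model.vertices if v not in data.columns]
        if missing:
            raise SchemaError(f"data lacks model vertex column(s): "
                              f"{', '.join(missing)}")
        if groups not in data.columns:
            raise SchemaError(f"data lacks groups column {groups!r}")
        reg = {**DEFAULT_TRANSFORMS, **model.transforms}
        self.data = data[[groups]].copy()
        for v in model.vertices:
            self.data[v] = apply_transform(data[v], reg.get(v, "identity"))

    def fit(self, dsep: bool = True, alpha_missing: float = 0.05) -> "SEMResults":
        """Fit every submodel; optionally run the d-separation test."""
        n = len(self.data)
        sds = self.data[self.model.vertices].std(ddof=1)
        rows, submodels, r2_rows = [], {}, []
        k_params = 0
        for v in self.model.endogenous:
            parents = self.model.parents(v)
            res = fit_lmm(self.data, v, parents, groups=self.groups)
            submodels[v] = res
            k_params += res.k_fe
            r2_rows.append({"response": v, "r2_marginal": res.r2_marginal,
                            "r2_conditional": res.r2_conditional})
            for p_ in parents:
                coef = res.params[p_]
                beta = coef * sds[p_] / sds[v]
                rows.append({
                    "cause": p_, "effect": v, "coef": coef, "beta": beta,
                    "se": res.bse[p_], "p": res.pvalues[p_],
                    "code": significance_code(res.pvalues[p_]),
                })
        paths = pd.DataFrame(rows)

        claims = basis_set(self.model) if dsep else []
        claim_ps = [dsep_pvalue(c, self.data, self.groups) for c in claims]
        C, dof, p_c = fishers_c(claim_ps) if dsep else (np.nan, 0, np.nan)
        if dsep and not claims:
            C, dof, p_c = 0.0, 0, 1.0  # saturated model: perfect-fit sentinel
        aic = C + 2 * k_params if dsep else np.nan
        aicc = (C + 2 * k_params * n / (n - k_params - 1)
                if dsep and n > k_params + 1 else None)
        missing_paths = [
            (c, p_) for c, p_ in zip(claims, claim_ps) if p_ < alpha_missing
        ]
        return SEMResults(
            model=self.model, paths=paths, submodels=submodels,
            r2=pd.DataFrame(r2_rows), claims=claims,
            claim_pvalues=claim_ps, fisher_c=C, dsep_df=dof, dsep_p=p_c,
            k_params=k_params, nobs=n, aic=aic, _aicc=aicc,
            missing_paths=missing_paths,
        )


@dataclass
class SEMResults:
    """Fitted piecewise SEM.

    ``paths`` holds one row per edge with raw coefficient, standardized
    beta (raw x SD(cause)/SD(effect) on the analysis scale), standard
    error, p-value and significance code.  ``missing_paths`` lists the
    independence claims rejected at the 5% level — candidate edges,
    reported for the analyst's judgement, never added automatically.
    """

    model: PathModel
    paths: pd.DataFrame
    submodels: dict[str, LMMResults]
    r2: pd.DataFrame
    claims: list[DsepClaim]
    claim_pvalues: list[float]
    fisher_c: float
    dsep_df: int
    dsep_p: float
    k_params: int
    nobs: int
    aic: float
    _aicc: float | None
    missing_paths: list = field(default_factory=list)

    @property
    def aicc(self) -> float:
        if self._aicc is None:
            raise UndefinedValueError(
                f"AICc undefined: n={self.nobs} <= K+1={self.k_params + 1}")
        return self._aicc

    def beta(self, cause: str, effect: str) -> float:
        """Standardized coefficient of one edge."""
        sel = self.paths[(self.paths["cause"] == cause)
                         & (self.paths["effect"] == effect)]
        if sel.empty:
            raise GraphError(f"no edge {cause} -> {effect}")
        return float(sel["beta"].iloc[0])

    def indirect_effects(self, source: str, target: str) -> tuple[pd.DataFrame, float]:
        """All mediated (length >= 2) directed paths from source to target.

        Each path's effect is the product of the standardized coefficients
        along it; returns the per-path table and the summed total.  An
        absent route yields an empty table and total 0.
        """
        g = self.model.graph
        if source not in g or target not in g:
            raise GraphError(f"unknown vertex in ({source!r}, {target!r})")
        rows = []
        if source != target:
            for path in nx.all_simple_paths(g, source, target):
                if len(path) < 3:  # direct edge, not an indirect route
                    continue
                effect = 1.0
                for a, b in zip(path, path[1:]):
                    effect *= self.beta(a, b)
                rows.append({"path": " -> ".join(path), "effect": effect})
        table = pd.DataFrame(rows, columns=["path", "effect"])
        total = float(table["effect"].sum()) if len(table) else 0.0
        return table, total

    def summary(self) -> str:
        lines = [
            "Piecewise structural equation model",
            f"  n = {self.nobs}, K = {self.k_params}",
            f"  Fisher's C = {self.fisher_c:.2f}, df = {self.dsep_df}, "
            f"p = {self.dsep_p:.3f}",
            f"  AIC = {self.aic:.2f}"
            + (f", AICc = {self._aicc:.2f}" if self._aicc is not None else ""),
            "",
            f"  {'path':<28}{'coef':>9}{'beta':>8}{'p':>10}  sig",
        ]
        for _, r in self.paths.iterrows():
            lines.append(
                f"  {r['cause'] + ' -> ' + r['effect']:<28}"
                f"{r['coef']:>9.4f}{r['beta']:>8.3f}{r['p']:>10.4g}  {r['code']}"
            )
        lines.append("")
        for _, r in self.r2.iterrows():
            lines.append(f"  R2 {r['response']:<14} marginal = "
                         f"{r['r2_marginal']:.3f}, conditional = "
                         f"{r['r2_conditional']:.3f}")
        if self.missing_paths:
            lines.append("")
            lines.append("  candidate missing paths (d-sep p < .05):")
            for claim, p in self.missing_paths:
                lines.append(f"    {claim}  (p = {p:.4g})")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serialisable summary of the fit."""
        out = {
            "n": self.nobs,
            "K": self.k_params,
            "fisher_c": self.fisher_c,
            "dsep_df": self.dsep_df,
            "dsep_p": self.dsep_p,
            "aic": self.aic,
            "aicc": self._aicc,
            "paths": self.paths.to_dict(orient="records"),
            "r2": self.r2.to_dict(orient="records"),
            "claims": [
                {"claim": str(c), "p": p}
                for c, p in zip(self.claims, self.claim_pvalues)
            ],
            "missing_paths": [
                {"claim": str(c), "p": p} for c, p in self.missing_paths
            ],
        }
        return out
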