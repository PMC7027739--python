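"""Plot-level statistics for the randomized-block diversity design.

Implements the study-design statistics used throughout the package:

* ``block_correct`` — removes additive block effects by recentring every
  block on the grand mean (within-block deviations are preserved),
* ``sequential_lr_tests`` — the sequential likelihood-ratio testing scheme
  over sown plant species richness (log-transformed), plant functional
  group richness, and the four functional-group identity flags, each tested
  by adding one term to a nested ML mixed model with block as random
  intercept,
* ``correlation_matrix`` — Pearson correlations of block-corrected
  variables with two-sided t-distribution p-values,
* a per-variable transform registry (log / sqrt) applied before linear
  modelling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DesignError, SchemaError, UndefinedValueError
from .lmm import LMMResults, RandomInterceptLM

__all__ = [
    "DEFAULT_TRANSFORMS",
    "TRANSFORM_FUNCS",
    "apply_transform",
    "block_correct",
    "fit_lmm",
    "sequential_lr_tests",
    "correlation_matrix",
    "significance_code",
]

TRANSFORM_FUNCS = {
    "identity": lambda x: x,
    "log": np.log,
    "log10": np.log10,
    "sqrt": np.sqrt,
}

# transforms applied before linear modelling, mirroring the diagnostic
# regressions: root C and biomass-specific growth on a log scale, growth on
# a sqrt scale, the fungal:bacterial necromass ratio on a log scale
DEFAULT_TRANSFORMS = {
    "root_c": "log",
    "growth": "sqrt",
    "q_growth": "log",
    "turnover_time": "log",
    "fb_ratio": "log",
}

IDENTITY_TERMS = ["has_small_herbs", "has_tall_herbs", "has_grasses", "has_legumes"]
TERM_LABELS = {
    "psr_log": "PSR_log",
    "pfgr": "PFGR",
    "has_small_herbs": "SH",
    "has_tall_herbs": "TH",
    "has_grasses": "GR",
    "has_legumes": "LEG",
}


def apply_transform(values, name: str):
    """Apply a registered variable transform ('identity', 'log', 'sqrt', ...)."""
    try:
        fn = TRANSFORM_FUNCS[name]
    except KeyError:
        raise SchemaError(f"unknown transform {name!r}") from None
    return fn(np.asarray(values, dtype=float))


def block_correct(values, blocks):
    """Remove additive block effects from a plot-level variable.

    Each value is shifted by (grand mean - its block mean), so every
    corrected block mean equals the grand mean, the grand mean itself is
    unchanged and within-block deviations are preserved.  The operation is
    idempotent.
    """
    values = np.asarray(values, dtype=float)
    blocks = np.asarray(blocks)
    if values.shape[0] != blocks.shape[0]:
        raise DesignError("values and blocks must have equal length")
    if values.shape[0] == 0:
        raise DesignError("empty design")
    grand = values.mean()
    out = values.copy()
    for b in pd.unique(blocks):
        mask = blocks == b
        if not mask.any():  # pragma: no cover - unique() guarantees nonempty
            raise DesignError(f"empty block {b!r}")
        out[mask] += grand - values[mask].mean()
    return out


def fit_lmm(data: pd.DataFrame, response: str, fixed_terms,
            groups: str = "block") -> LMMResults:
    """ML fit of ``response ~ fixed_terms`` with a block random intercept."""
    return RandomInterceptLM.from_dataframe(data, response, fixed_terms,
                                            groups=groups).fit()


def significance_code(p: float) -> str:
    """Significance code for a p-value: *** <=.001, ** <=.01, * <=.05, dagger <=.1.

    Boundary values map to the stronger code.
    """
    if not 0 <= p <= 1:
        raise UndefinedValueError(f"p-value outside [0, 1]: {p}")
    for threshold, code in ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "†")):
        if p <= threshold:
            return code
    return ""


def _prepare(data: pd.DataFrame, response: str,
             transforms: dict | None) -> pd.DataFrame:
    required = ["block", "psr_sown", "pfgr", *IDENTITY_TERMS, response]
    missing = [c for c in required if c not in data.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    reg = dict(DEFAULT_TRANSFORMS)
    if transforms:
        reg.update(transforms)
    df = data[required].copy()
    df["psr_log"] = np.log(df["psr_sown"].astype(float))
    df[response] = apply_transform(df[response], reg.get(response, "identity"))
    for c in IDENTITY_TERMS:
        df[c] = df[c].astype(float)
    df["pfgr"] = df["pfgr"].astype(float)
    return df


def sequential_lr_tests(data: pd.DataFrame, response: str,
                        order: str = "psr-first",
                        transforms: dict | None = None) -> pd.DataFrame:
    """Sequential likelihood-ratio tests of diversity terms on one response.

    Six single-degree-of-freedom tests per response, each comparing nested
    ML mixed models with a block random intercept:

    1. log species richness (PSR) added to the intercept-only model,
    2. functional group richness (PFGR) added to the PSR model,
    3-6. each functional-group identity flag (small herbs, tall herbs,
       grasses, legumes) added, one at a time, to the PSR + PFGR model.

    ``order='pfgr-first'`` swaps steps 1 and 2 (PFGR tested first, PSR
    added to the PFGR model), reproducing the reversed-sequence analysis.

    Returns a tidy frame with the LR statistic, df, p-value, significance
    code and the sign of the fitted coefficient for each term.
    """
    if order not in ("psr-first", "pfgr-first"):
        raise SchemaError(f"unknown order {order!r}")
    df = _prepare(data, response, transforms)
    first, second = (("psr_log", "pfgr") if order == "psr-first"
                     else ("pfgr", "psr_log"))

    base = fit_lmm(df, response, [])
    m1 = fit_lmm(df, response, [first])
    m2 = fit_lmm(df, response, [first, second])

    rows = []

    def add_row(term, full: LMMResults, reduced: LMMResults):
        L, dof, p = full.lr_test(reduced)
        rows.append({
            "response": response,
            "term": TERM_LABELS[term],
            "L": L,
            "df": dof,
            "p": p,
            "code": significance_code(p),
            "direction": int(np.sign(full.params[term])),
        })

    add_row(first, m1, base)
    add_row(second, m2, m1)
    for flag in IDENTITY_TERMS:
        full = fit_lmm(df, response, ["psr_log", "pfgr", flag])
        add_row(flag, full, m2)
    out = pd.DataFrame(rows)
    if order == "pfgr-first":  # report in the canonical term order anyway
        out = out.iloc[[1, 0, 2, 3, 4, 5]].reset_index(drop=True)
    return out


def correlation_matrix(data: pd.DataFrame, variables,
                       blocks=None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pearson correlation matrix with two-sided p-values.

    If ``blocks`` (a column name or label vector) is given, every variable
    is block-corrected first.  Returns ``(r, p)`` DataFrames; the diagonal
    of ``r`` is 1 and of ``p`` is 0.  A zero-variance variable makes its
    pairs undefined and raises.
    """
    variables = list(variables)
    missing = [v for v in variables if v not in data.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    n = len(data)
    if n < 3:
        raise DesignError("need at least 3 observations for correlations")
    if isinstance(blocks, str):
        blocks = data[blocks].to_numpy()
    cols = {}
    for v in variables:
        x = data[v].to_numpy(dtype=float)
        if blocks is not None:
            x = block_correct(x, blocks)
        if np.std(x) == 0:
            raise UndefinedValueError(f"zero-variance variable {v!r}")
        cols[v] = x
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            res = stats.pearsonr(cols[variables[i]], cols[variables[j]])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    idx = pd.Index(variables)
    return (pd.DataFrame(r, index=idx, columns=idx),
            pd.DataFrame(p, index=idx, columns=idx))
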