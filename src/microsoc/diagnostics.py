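"""Basic diagnostic plots: variable vs log species richness panels."""

from __future__ import annotations

import numpy as np

from .designstats import DEFAULT_TRANSFORMS, apply_transform
from .errors import SchemaError

__all__ = ["richness_regression_panel"]


def richness_regression_panel(plots, variables, path=None, ncols=3,
                              transforms=None):
    """Scatter each variable against log sown richness with an OLS line.

    A quick visual check of the linearity assumption behind the mixed
    models; variables are drawn on their registered analysis scale.
    Returns the matplotlib figure; saves it when ``path`` is given.
    """
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    variables = list(variables)
    missing = [v for v in variables if v not in plots.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    reg = {**DEFAULT_TRANSFORMS, **(transforms or {})}
    x = np.log(plots["psr_sown"].astype(float))
    nrows = int(np.ceil(len(variables) / ncols))
    fig, axes = plt.subplots(nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows),
                             squeeze=False)
    for ax in axes.ravel()[len(variables):]:
        ax.set_visible(False)
    for ax, v in zip(axes.ravel(), variables):
        tr = reg.get(v, "identity")
        y = apply_transform(plots[v], tr)
        ax.scatter(x, y, s=12, alpha=0.7)
        slope, intercept = np.polyfit(x, y, 1)
        grid = np.linspace(x.min(), x.max(), 50)
        ax.plot(grid, intercept + slope * grid, color="k", lw=1)
        label = v if tr == "identity" else f"{v} ({tr})"
        ax.set_ylabel(label, fontsize=8)
        ax.set_xlabel("ln(sown richness)", fontsize=8)
        ax.tick_params(labelsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
    return fig
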