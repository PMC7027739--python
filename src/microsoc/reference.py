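"""Published per-level summary statistics used to calibrate the generator.

``REFERENCE_SUMMARY`` holds the reported means and standard deviations of
the key plot-level variables of the grassland biodiversity experiment,
by sown plant species richness (PSR) level, with the replication of the
design (15, 16, 16, 16, 14, 4 plots; 81 in total).  Units follow the
published convention: SOC in mg C g^-1 soil DW, root C in g C m^-2,
microbial biomass C (cmic) in ug C g^-1 DW, growth and respiration in
ug C g^-1 DW day^-1, fungal necromass C in mg C g^-1 DW; C:N ratios are
dimensionless.

The synthetic-data generator rescales its standardized latent variables to
the pooled mean/SD of this table, and the headline between-level ratios
(percent increase and fold change from monocultures to the 60-species
mixtures) are computed from it by :func:`microsoc.pipeline.psr_ratios`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["REFERENCE_SUMMARY", "pooled_stats", "reference_long"]

_LEVELS = [1, 2, 4, 8, 16, 60]
_N = [15, 16, 16, 16, 14, 4]

# variable -> list of (mean, sd) per PSR level, in _LEVELS order
_CELLS = {
    "soc": [(20.4, 2.7), (20.8, 2.6), (22.2, 2.3), (21.9, 1.9),
            (24.1, 2.4), (26.3, 2.9)],
    "soil_cn": [(10.7, 0.5), (10.8, 0.6), (10.8, 0.4), (10.9, 0.5),
                (11.1, 0.7), (11.1, 0.2)],
    "root_c": [(17.2, 10.9), (26.5, 24.1), (41.7, 33.6), (23.9, 15.3),
               (47.7, 25.1), (49.1, 28.5)],
    "root_cn": [(40.4, 11.9), (40.8, 10.1), (45.0, 10.1), (46.2, 9.6),
                (44.7, 11.2), (46.3, 2.6)],
    "cmic": [(744.2, 167.6), (838.1, 122.0), (958.8, 142.5), (952.0, 130.5),
             (1103.8, 118.4), (1175.8, 103.9)],
    "growth": [(7.0, 4.6), (10.1, 4.4), (10.8, 3.5), (10.8, 4.6),
               (12.1, 3.2), (13.9, 2.3)],
    "respiration": [(14.6, 6.0), (18.2, 4.4), (16.6, 7.2), (19.8, 6.1),
                    (19.8, 5.4), (21.1, 7.4)],
    "necromass_fungal": [(3.9, 0.6), (4.0, 0.4), (4.4, 0.5), (4.3, 0.5),
                         (4.7, 0.6), (5.1, 0.7)],
}


def reference_long() -> pd.DataFrame:
    """The reference summary in long form: psr, n, variable, mean, sd."""
    rows = []
    for var, cells in _CELLS.items():
        for psr, n, (mean, sd) in zip(_LEVELS, _N, cells):
            rows.append({"psr": psr, "n": n, "variable": var,
                         "mean": mean, "sd": sd})
    return pd.DataFrame(rows)


REFERENCE_SUMMARY = reference_long()


def pooled_stats(variable: str) -> tuple[float, float]:
    """Pooled mean and total SD of a variable across all PSR levels.

    The total variance combines the replication-weighted within-level
    variances with the between-level spread of the means.
    """
    sub = REFERENCE_SUMMARY[REFERENCE_SUMMARY["variable"] == variable]
    if sub.empty:
        raise KeyError(f"no reference statistics for {variable!r}")
    n = sub["n"].to_numpy(float)
    m = sub["mean"].to_numpy(float)
    s = sub["sd"].to_numpy(float)
    w = n / n.sum()
    grand = float(np.sum(w * m))
    total_var = float(np.sum(w * (s**2 + (m - grand) ** 2)))
    return grand, np.sqrt(total_var)
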