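"""Synthetic datasets with the experiment's design and causal structure.

The generator emulates the grassland biodiversity experiment end to end:

1. **Design** — 4 blocks, sown plant species richness (PSR) levels
   {1, 2, 4, 8, 16, 60} with replication (15, 16, 16, 16, 14, 4) = 81
   plots, functional-group richness drawn uniformly from 1..min(PSR, 4)
   and exactly that many functional-group presence flags set.
2. **Latent variables** — a linear recursive system on the standardized
   analysis scale: log PSR drives root carbon, microbial growth, microbial
   biomass; these propagate to respiration and soil organic carbon, plus
   fungal necromass, per the standardized path coefficients in
   ``path_beta``.  Each vertex receives a block intercept and residual
   noise sized so its standardized variance is 1 (so the configured betas
   ARE the standardized coefficients a correct analysis recovers), then is
   rescaled to the published means/SDs and back-transformed to natural
   units.  Positivity is enforced by redrawing residuals (never clipping).
3. **Raw instrument tables** — the measurement equations are inverted so
   the processing pipeline recovers the latent values exactly: headspace
   CO2 from respiration (ideal gas law), 18O excess and DNA pools from
   growth, fumigation pairs from biomass, amino-sugar concentrations from
   the necromass split.

All randomness flows from one root seed through named substreams, so an
identical configuration yields byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS
from .errors import ConfigError
from .reference import pooled_stats
from .stoichiometry import GLUCOSAMINE_TO_C, M_GLUCOSAMINE, M_MURAMIC, MURAMIC_TO_C

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate_design",
           "generate_latent", "generate_raw_tables", "generate_dataset",
           "scale_replication"]

FUNCTIONAL_GROUPS = ["grasses", "legumes", "small_herbs", "tall_herbs"]

# standardized path coefficients of the causal chain (defaults reproduce the
# reported direct effects .25 / .42 / .68 and indirect effects .15 / .09 /
# .06; see docs/methods.md for the derivation of the remaining values)
DEFAULT_PATH_BETA = {
    ("psr_log", "root_c"): 0.40,
    ("psr_log", "growth"): 0.25,
    ("root_c", "growth"): 0.375,
    ("psr_log", "cmic"): 0.42,
    ("growth", "cmic"): 0.225,
    ("root_c", "cmic"): 0.15,
    ("growth", "respiration"): 0.35,
    ("cmic", "soc"): 0.68,
    ("psr_log", "necromass_fungal"): 0.45,
}

# generation order and per-variable scale handling; 'log'/'sqrt' variables
# are generated on the transformed scale and back-transformed, so the
# causal system is linear on the scale the analysis uses
_VERTEX_ORDER = ["root_c", "growth", "respiration", "cmic", "soc",
                 "necromass_fungal", "necromass_bacterial"]
_GEN_TRANSFORMS = {"root_c": "log", "growth": "sqrt"}

# substream labels -> fixed offsets under the root seed
_STREAMS = {"design": 1, "latent": 2, "tables": 3}


def _default_scale_params() -> dict[str, tuple[float, float]]:
    params = {v: pooled_stats(v) for v in
              ["soc", "root_c", "cmic", "growth", "respiration",
               "necromass_fungal", "soil_cn", "root_cn"]}
    # bacterial necromass is not in the published summary; its pool is known
    # to be flat across PSR with a fungal:bacterial ratio around 1.3-1.4
    params["necromass_bacterial"] = (3.0, 0.45)
    return params


@dataclass(frozen=True)
class SyntheticConfig:
    """All knobs of the generator; defaults are the study conditions."""

    seed: int = 0
    n_per_psr: dict = field(default_factory=lambda: {1: 15, 2: 16, 4: 16,
                                                     8: 16, 16: 14, 60: 4})
    n_blocks: int = 4
    path_beta: dict = field(default_factory=lambda: dict(DEFAULT_PATH_BETA))
    block_sd: float = 0.15
    noise_sd: dict = field(default_factory=dict)  # per-vertex overrides
    scale_params: dict = field(default_factory=_default_scale_params)
    identity_effects: bool = False  # grasses +, legumes - on root carbon
    identity_effect_size: float = 0.15
    # measurement layer
    f_dna: float = 50.0
    k_ec: float = 0.45
    dw_g: float = 2.0
    t_hr: float = 24.0
    temp_k: float = 295.15
    p_kpa: float = 101.325
    vhs_l: float = 0.02
    atpct_label: float = 97.0
    atpct_na: float = 0.2
    o_total_ug: float = 10.0
    c_unfumigated: float = 140.0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_per_psr.values()) or self.n_blocks < 1:
            raise ConfigError("replication counts and n_blocks must be positive")
        if any(abs(b) >= 1 for b in self.path_beta.values()):
            raise ConfigError("standardized path coefficients must satisfy |beta| < 1")
        if self.block_sd < 0:
            raise ConfigError("block_sd must be nonnegative")
        if any(s <= 0 for s in self.noise_sd.values()):
            raise ConfigError("noise SDs must be positive")
        if any(sd <= 0 for _, sd in self.scale_params.values()):
            raise ConfigError("scale SDs must be positive")

    def with_seed(self, seed: int) -> "SyntheticConfig":
        return replace(self, seed=seed)

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])

    @property
    def n_plots(self) -> int:
        return sum(self.n_per_psr.values())


def scale_replication(n_per_psr: dict, total: int) -> dict:
    """Rescale per-level replication to a new total (largest remainder).

    Keeps the design's proportions while changing the number of plots, e.g.
    for power or recovery simulations at larger n.  Every level keeps at
    least one plot.
    """
    if total < len(n_per_psr):
        raise ConfigError("total smaller than the number of richness levels")
    levels = sorted(n_per_psr)
    base = sum(n_per_psr.values())
    quotas = {k: n_per_psr[k] * total / base for k in levels}
    out = {k: max(int(np.floor(quotas[k])), 1) for k in levels}
    remainder = total - sum(out.values())
    by_frac = sorted(levels, key=lambda k: quotas[k] - np.floor(quotas[k]),
                     reverse=True)
    i = 0
    while remainder > 0:
        out[by_frac[i % len(levels)]] += 1
        remainder -= 1
        i += 1
    return out


def generate_design(cfg: SyntheticConfig) -> pd.DataFrame:
    """Randomized-block design table with functional-group composition."""
    rng = cfg.rng("design")
    rows = []
    counter = 0
    for psr in sorted(cfg.n_per_psr):
        for i in range(cfg.n_per_psr[psr]):
            counter += 1
            pfgr = int(rng.integers(1, min(psr, 4) + 1))
            groups = rng.choice(FUNCTIONAL_GROUPS, size=pfgr, replace=False)
            row = {
                "plot_id": f"P{counter:03d}",
                # round-robin within each richness level balances blocks
                "block": (i % cfg.n_blocks) + 1,
                "psr_sown": psr,
                "pfgr": pfgr,
            }
            for g in FUNCTIONAL_GROUPS:
                row[f"has_{g}"] = g in groups
            rows.append(row)
    return pd.DataFrame(rows)


def _transformed_scale(var: str, cfg: SyntheticConfig) -> tuple[float, float]:
    """Mean/SD on the generation (analysis) scale, via the delta method."""
    mean, sd = cfg.scale_params[var]
    tr = _GEN_TRANSFORMS.get(var, "identity")
    if tr == "log":
        return np.log(mean), sd / mean
    if tr == "sqrt":
        return np.sqrt(mean), sd / (2.0 * np.sqrt(mean))
    return mean, sd


def _back_transform(var: str, u: np.ndarray) -> np.ndarray:
    tr = _GEN_TRANSFORMS.get(var, "identity")
    if tr == "log":
        return np.exp(u)
    if tr == "sqrt":
        return u**2
    return u


def generate_latent(design: pd.DataFrame, cfg: SyntheticConfig,
                    max_resample: int = 200) -> pd.DataFrame:
    """Per-plot latent values of the causal system, in natural units.

    Implements the standardized linear recursive system described in the
    module docstring.  The implied covariance matrix of the standardized
    variables is tracked as vertices are added so each vertex's residual SD
    can be sized to give unit total variance; an infeasible coefficient
    combination (implied variance >= 1 after the block share) raises
    :class:`~microsoc.errors.ConfigError`.
    """
    rng = cfg.rng("latent")
    n = len(design)
    out = design.copy()
    out["psr_log"] = np.log(out["psr_sown"].astype(float))

    z = {"psr_log": ((out["psr_log"] - out["psr_log"].mean())
                     / out["psr_log"].std(ddof=1)).to_numpy()}
    # implied covariance among standardized variables, grown vertex by vertex
    cov = {("psr_log", "psr_log"): 1.0}
    blocks = out["block"].to_numpy()
    block_codes = pd.factorize(blocks)[0]

    ident = np.zeros(n)
    if cfg.identity_effects:
        ident = cfg.identity_effect_size * (
            out["has_grasses"].to_numpy(float)
            - out["has_legumes"].to_numpy(float)
        )

    for v in _VERTEX_ORDER:
        parents = [(c, b) for (c, e), b in cfg.path_beta.items() if e == v]
        struct = np.zeros(n)
        var_struct = 0.0
        for (p_name, b) in parents:
            struct += b * z[p_name]
            for (q_name, b2) in parents:
                var_struct += b * b2 * cov[tuple(sorted((p_name, q_name)))]
        resid_var = 1.0 - var_struct - cfg.block_sd**2
        if resid_var <= 0:
            raise ConfigError(
                f"{v}: implied variance {var_struct + cfg.block_sd**2:.3f} >= 1; "
                "path coefficients infeasible")
        resid_sd = cfg.noise_sd.get(v, np.sqrt(resid_var))
        block_eff = rng.normal(0.0, cfg.block_sd, cfg.n_blocks)[block_codes]
        eps = rng.normal(0.0, resid_sd, n)
        extra = ident if v == "root_c" else 0.0
        mu_t, sd_t = _transformed_scale(v, cfg)

        def natural(e):
            u = mu_t + sd_t * (struct + block_eff + e + extra)
            return _back_transform(v, u), u

        x, u = natural(eps)
        bad = (x <= 0) | ((u <= 0) if _GEN_TRANSFORMS.get(v) == "sqrt" else False)
        tries = 0
        while bad.any():
            tries += 1
            if tries > max_resample:
                raise ConfigError(f"{v}: could not generate positive values")
            eps[bad] = rng.normal(0.0, resid_sd, int(bad.sum()))
            x, u = natural(eps)
            bad = (x <= 0) | ((u <= 0) if _GEN_TRANSFORMS.get(v) == "sqrt"
                              else False)

        zv = struct + block_eff + eps + extra
        z[v] = zv
        # extend the implied covariance (block and noise are independent)
        for u_name in list(z):
            if u_name == v:
                continue
            c = sum(b * cov[tuple(sorted((p_name, u_name)))]
                    for p_name, b in parents)
            cov[tuple(sorted((v, u_name)))] = c
        cov[(v, v)] = 1.0
        out[v] = x

    # non-causal covariates: block + noise around their published scales
    for v in ("soil_cn", "root_cn"):
        mean, sd = cfg.scale_params[v]
        block_eff = rng.normal(0.0, cfg.block_sd, cfg.n_blocks)[block_codes]
        out[v] = mean + sd * (block_eff + rng.normal(0.0, np.sqrt(
            max(1 - cfg.block_sd**2, 0.1)), n))
    return out


def generate_raw_tables(latent: pd.DataFrame,
                        cfg: SyntheticConfig) -> dict[str, pd.DataFrame]:
    """Instrument-level tables whose processing recovers the latent values.

    Inverts every measurement conversion exactly (to floating-point
    round-off): the returned dict holds the ``incubation``, ``isotope``,
    ``cfe``, ``dna`` and ``aminosugars`` tables, one composite sample per
    plot with ``sample_id`` equal to ``plot_id``.
    """
    c = DEFAULT_CONSTANTS
    ids = latent["plot_id"].to_numpy()
    resp = latent["respiration"].to_numpy(float)
    growth = latent["growth"].to_numpy(float)
    cmic = latent["cmic"].to_numpy(float)
    nec_b = latent["necromass_bacterial"].to_numpy(float)
    nec_f = latent["necromass_fungal"].to_numpy(float)

    n_gas = cfg.p_kpa * cfg.vhs_l / (c.R * cfg.temp_k)
    dco2 = resp * cfg.dw_g * (cfg.t_hr / 24.0) / (n_gas * c.M_C)
    incubation = pd.DataFrame({
        "sample_id": ids, "plot_id": ids, "DCO2_ppm": dco2,
        "DW_g": cfg.dw_g, "t_hr": cfg.t_hr, "p_kPa": cfg.p_kpa,
        "T_K": cfg.temp_k, "Vhs_L": cfg.vhs_l,
    })

    dna_prod = growth * cfg.dw_g * (cfg.t_hr / 24.0) / cfg.f_dna
    factor = (cfg.o_total_ug / 100.0) * (100.0 / cfg.atpct_label) \
        * (100.0 / c.f_O_DNA)
    excess = dna_prod / factor
    labeled = cfg.atpct_na + excess
    if np.any(labeled > min(cfg.atpct_label, 100.0)):
        raise ConfigError("required at% excess exceeds the label strength; "
                          "growth scale not representable")
    isotope = pd.DataFrame({
        "sample_id": ids, "O_total_ug": cfg.o_total_ug,
        "atpct_labeled": labeled, "atpct_NA": cfg.atpct_na,
        "atpct_label": cfg.atpct_label,
    })

    cfe = pd.DataFrame({
        "sample_id": ids,
        "C_fumigated": cfg.c_unfumigated + cmic * cfg.k_ec,
        "C_unfumigated": cfg.c_unfumigated,
        "k_EC": cfg.k_ec,
    })
    dna = pd.DataFrame({"sample_id": ids, "dna_ug_g": cmic / cfg.f_dna})

    muramic = nec_b * 1000.0 / MURAMIC_TO_C
    fungal_glcn = nec_f * 1000.0 / GLUCOSAMINE_TO_C
    glcn_total = fungal_glcn + (muramic / M_MURAMIC) * M_GLUCOSAMINE
    aminosugars = pd.DataFrame({
        "sample_id": ids,
        "muramic_acid_ug_g": muramic,
        "glucosamine_total_ug_g": glcn_total,
    })
    return {"incubation": incubation, "isotope": isotope, "cfe": cfe,
            "dna": dna, "aminosugars": aminosugars}


@dataclass
class SyntheticDataset:
    """A complete generated dataset plus its ground truth."""

    config: SyntheticConfig
    design: pd.DataFrame
    latent: pd.DataFrame
    tables: dict[str, pd.DataFrame]

    def truth(self) -> dict:
        return {
            "seed": self.config.seed,
            "path_beta": {f"{a}->{b}": v
                          for (a, b), v in self.config.path_beta.items()},
            "block_sd": self.config.block_sd,
            "f_dna": self.config.f_dna,
        }

    def write_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        design_cols = ["plot_id", "block", "psr_sown", "pfgr",
                       *(f"has_{g}" for g in FUNCTIONAL_GROUPS),
                       "soc", "soil_cn", "root_c", "root_cn"]
        self.latent[design_cols].to_csv(outdir / "design.csv", index=False)
        for name, df in self.tables.items():
            df.to_csv(outdir / f"{name}.csv", index=False)
        import json

        (outdir / "truth.json").write_text(
            json.dumps({**self.truth(),
                        "latent": self.latent.to_dict(orient="list")},
                       indent=2, default=str))


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Design + latent values + invertible raw tables under one seed."""
    design = generate_design(cfg)
    latent = generate_latent(design, cfg)
    tables = generate_raw_tables(latent, cfg)
    return SyntheticDataset(cfg, design, latent, tables)
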