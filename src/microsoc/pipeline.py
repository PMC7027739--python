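"""End-to-end orchestration: raw tables -> physiology -> statistics -> SEM.

``run_pipeline`` binds the stages together: measurement conversions,
biomass/necromass stoichiometry, the per-plot join, the sequential
likelihood-ratio tests, the block-corrected correlation matrix and the
piecewise SEM, writing every stage's table plus a run manifest.  The
synthetic generator can stand in for the raw CSVs, making a complete run
reproducible from a single seed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .designstats import correlation_matrix, sequential_lr_tests, significance_code
from .errors import SchemaError
from .measurements import derive_physiology
from .pathmodels import PathModel, PiecewiseSEM, default_path_model
from .stoichiometry import derive_biomass_necromass
from .synthdata import SyntheticConfig, generate_dataset

__all__ = ["RunConfig", "run_pipeline", "build_plot_table",
           "summarize_by_psr", "psr_ratios"]

RAW_TABLES = ["design", "incubation", "isotope", "cfe", "dna", "aminosugars"]

DEFAULT_RESPONSES = [
    "soc", "root_c", "root_cn", "cmic", "growth", "q_growth", "turnover_time",
    "respiration", "q_resp", "uptake", "q_uptake", "cue",
    "necromass_fungal", "necromass_bacterial", "necromass_total",
]

CORRELATION_VARIABLES = ["soc", "cmic", "growth", "q_growth", "cue",
                         "respiration", "q_resp", "root_c", "necromass_total"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Either ``data_dir`` (holding the six raw CSVs) or ``simulate`` must be
    provided.  ``mode`` selects strict/lenient handling of physically
    impossible raw values (negative isotopic excess, negative fumigation
    flush).
    """

    outdir: Path
    data_dir: Path | None = None
    simulate: SyntheticConfig | None = None
    seed: int | None = None
    order: str = "psr-first"
    mode: str = "lenient"
    model_file: Path | None = None
    responses: list = field(default_factory=lambda: list(DEFAULT_RESPONSES))

    def __post_init__(self) -> None:
        if (self.data_dir is None) == (self.simulate is None):
            raise SchemaError("provide exactly one of data_dir or simulate")
        if self.mode not in ("strict", "lenient"):
            raise SchemaError(f"unknown mode {self.mode!r}")
        if self.seed is not None and self.simulate is not None:
            self.simulate = self.simulate.with_seed(self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        sim = raw.pop("simulate", None)
        if sim is not None:
            sim = SyntheticConfig(**sim)
        for key in ("outdir", "data_dir", "model_file"):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        return cls(simulate=sim, **raw)


def _load_raw(cfg: RunConfig) -> dict[str, pd.DataFrame]:
    if cfg.simulate is not None:
        ds = generate_dataset(cfg.simulate)
        design_cols = ["plot_id", "block", "psr_sown", "pfgr",
                       "has_grasses", "has_legumes", "has_small_herbs",
                       "has_tall_herbs", "soc", "soil_cn", "root_c", "root_cn"]
        return {"design": ds.latent[design_cols], **ds.tables}
    tables = {}
    for name in RAW_TABLES:
        path = Path(cfg.data_dir) / f"{name}.csv"
        if not path.exists():
            raise SchemaError(f"missing input table {path}")
        tables[name] = pd.read_csv(path)
    return tables


def build_plot_table(tables: dict[str, pd.DataFrame],
                     mode: str = "lenient") -> pd.DataFrame:
    """Join raw tables into the merged per-plot analysis table.

    Samples are processed individually, then aggregated to plots by
    arithmetic mean (the design pools cores into one composite sample per
    plot, but replicate samples are supported).
    """
    design = tables["design"]
    if "plot_id" not in design.columns:
        raise SchemaError("design: missing column(s) plot_id")
    bn = derive_biomass_necromass(tables["cfe"], tables["aminosugars"],
                                  tables["dna"], mode=mode)
    phys = derive_physiology(tables["incubation"], tables["isotope"],
                             f_dna=bn["f_dna"], cmic=bn["cmic"], mode=mode)
    sample_tbl = phys.join(bn, how="inner")
    plot_of = tables["incubation"].set_index("sample_id")["plot_id"]
    sample_tbl["plot_id"] = plot_of.reindex(sample_tbl.index)
    per_plot = sample_tbl.groupby("plot_id").mean(numeric_only=True)
    merged = design.merge(per_plot, on="plot_id", how="inner")
    merged["psr_log"] = np.log(merged["psr_sown"].astype(float))
    return merged


def summarize_by_psr(plots: pd.DataFrame, variables=None) -> pd.DataFrame:
    """Per-PSR-level summary (n, mean, SD) in long form.

    One row per (psr, variable); levels with no plots are omitted.
    """
    if variables is None:
        variables = [c for c in plots.columns
                     if c not in ("plot_id", "block", "psr_sown", "pfgr",
                                  "psr_log")
                     and plots[c].dtype.kind in "fi"]
    rows = []
    for psr, grp in plots.groupby("psr_sown"):
        for v in variables:
            rows.append({"psr": psr, "n": len(grp), "variable": v,
                         "mean": grp[v].mean(), "sd": grp[v].std(ddof=1)})
    return pd.DataFrame(rows)


def psr_ratios(summary: pd.DataFrame) -> pd.DataFrame:
    """Fold changes and percent increases from the lowest to highest level.

    Expects the long summary shape (psr, variable, mean); compares the
    monoculture level against the most species-rich one.
    """
    lo, hi = summary["psr"].min(), summary["psr"].max()
    rows = []
    for v, grp in summary.groupby("variable"):
        m = grp.set_index("psr")["mean"]
        if lo not in m.index or hi not in m.index or m[lo] == 0:
            continue
        fold = m[hi] / m[lo]
        rows.append({"variable": v, "psr_low": lo, "psr_high": hi,
                     "fold_change": fold,
                     "percent_increase": (fold - 1.0) * 100.0})
    return pd.DataFrame(rows)


def _manifest(cfg: RunConfig) -> dict:
    def enc(o):
        if isinstance(o, Path):
            return str(o)
        if isinstance(o, SyntheticConfig):
            return {k: enc(v) for k, v in vars(o).items()}
        if isinstance(o, dict):
            return {str(k): enc(v) for k, v in o.items()}
        if isinstance(o, (list, tuple)):
            return [enc(v) for v in o]
        return o

    payload = enc(vars(cfg))
    digest = hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()).hexdigest()
    return {"config": payload, "config_sha256": digest,
            "package_version": __version__}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage and write the results bundle to ``cfg.outdir``.

    Returns a dict with the in-memory results: ``plots``, ``summary``,
    ``ratios``, ``lmm_tests``, ``correlations`` (r, p), ``sem`` (the
    :class:`~microsoc.pathmodels.SEMResults`).
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tables = _load_raw(cfg)
    plots = build_plot_table(tables, mode=cfg.mode)

    phys_cols = ["plot_id", "respiration", "growth", "uptake", "cue",
                 "q_growth", "q_resp", "q_uptake", "turnover_time"]
    plots[phys_cols].to_csv(outdir / "physiology.csv", index=False)
    bn_cols = ["plot_id", "cmic", "f_dna", "necromass_bacterial",
               "necromass_fungal", "necromass_total", "fb_ratio"]
    plots[bn_cols].to_csv(outdir / "biomass_necromass.csv", index=False)
    plots.to_csv(outdir / "plots.csv", index=False)

    tests = pd.concat(
        [sequential_lr_tests(plots, r, order=cfg.order)
         for r in cfg.responses if r in plots.columns],
        ignore_index=True,
    )
    tests.to_csv(outdir / "lmm_tests.csv", index=False)

    corr_vars = [v for v in CORRELATION_VARIABLES if v in plots.columns]
    r, p = correlation_matrix(plots, corr_vars, blocks="block")
    codes = p.map(significance_code)
    np.fill_diagonal(codes.values, "")
    r.to_csv(outdir / "correlations.csv")
    p.to_csv(outdir / "correlations_p.csv")
    codes.to_csv(outdir / "correlations_codes.csv")

    model = (PathModel.from_text(Path(cfg.model_file).read_text())
             if cfg.model_file else default_path_model())
    sem = PiecewiseSEM(model, plots).fit()
    (outdir / "sem_fit.json").write_text(json.dumps(sem.to_dict(), indent=2))
    sem.paths.to_csv(outdir / "sem_paths.csv", index=False)

    summary = summarize_by_psr(plots)
    ratios = psr_ratios(summary)
    summary.to_csv(outdir / "summary_by_psr.csv", index=False)
    ratios.to_csv(outdir / "psr_ratios.csv", index=False)

    (outdir / "manifest.json").write_text(json.dumps(_manifest(cfg), indent=2))
    return {"plots": plots, "summary": summary, "ratios": ratios,
            "lmm_tests": tests, "correlations": (r, p), "sem": sem}
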