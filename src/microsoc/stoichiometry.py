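"""Microbial biomass and necromass from extraction and amino-sugar data.

Three standard soil conversions:

* chloroform fumigation extraction (CFE): microbial biomass C is the
  fumigated-minus-unfumigated extractable C flush divided by the extraction
  efficiency k_EC (default 0.45),
* f_DNA: the per-sample conversion factor from soil DNA content to
  microbial biomass C (ug C per ug DNA), the ratio of the CFE biomass to
  the DNA content of the same sample,
* amino-sugar necromass partition: muramic acid occurs only in bacterial
  cell walls where it pairs 1:1 (molar) with glucosamine, so bacterial
  glucosamine is subtracted (on a molar basis) from total glucosamine to
  leave the fungal share.  Mass-based conversion factors of 45 (muramic
  acid -> bacterial necromass C) and 9 (fungal glucosamine -> fungal
  necromass C) then yield necromass carbon pools, reported in mg C g^-1 DW.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import MeasurementError, SchemaError, UndefinedValueError

__all__ = [
    "K_EC",
    "M_MURAMIC",
    "M_GLUCOSAMINE",
    "MURAMIC_TO_C",
    "GLUCOSAMINE_TO_C",
    "NecromassResult",
    "cfe_biomass_c",
    "f_dna",
    "necromass_partition",
    "fb_necromass_ratio",
    "derive_biomass_necromass",
]

K_EC = 0.45  # CFE extraction efficiency
M_MURAMIC = 251.23  # g/mol
M_GLUCOSAMINE = 179.17  # g/mol
MURAMIC_TO_C = 45.0  # ug bacterial necromass C per ug muramic acid
GLUCOSAMINE_TO_C = 9.0  # ug fungal necromass C per ug fungal glucosamine


def _as_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class NecromassResult:
    """Bacterial/fungal necromass C partition for one sample (mg C g^-1 DW)."""

    sample_id: str
    necromass_bacterial: float
    necromass_fungal: float

    @property
    def necromass_total(self) -> float:
        return self.necromass_bacterial + self.necromass_fungal

    @property
    def fb_ratio(self) -> float:
        return fb_necromass_ratio(self.necromass_fungal, self.necromass_bacterial)


def cfe_biomass_c(c_fumigated, c_unfumigated, k_ec=K_EC, mode: str = "strict"):
    """Microbial biomass C from a fumigation pair: (C_fum - C_unfum) / k_EC.

    Inputs in ug C g^-1 DW.  A negative flush (fumigated below unfumigated)
    raises in strict mode; lenient mode clamps it to zero with a warning.
    """
    c_fum, c_unf, k_ec = map(_as_array, (c_fumigated, c_unfumigated, k_ec))
    if np.any(c_unf < 0):
        raise MeasurementError("unfumigated extract must be nonnegative")
    if np.any((k_ec <= 0) | (k_ec > 1)):
        raise MeasurementError("k_EC must be in (0, 1]")
    flush = c_fum - c_unf
    if np.any(flush < 0):
        if mode == "strict":
            raise MeasurementError("fumigated extract below unfumigated extract")
        warnings.warn("negative CFE flush clamped to 0", stacklevel=2)
        flush = np.clip(flush, 0.0, None)
    out = flush / k_ec
    return float(out) if out.ndim == 0 else out


def f_dna(cmic, dna_content):
    """Per-sample biomass-C : DNA conversion factor (ug C per ug DNA).

    Both arguments are soil contents (per g DW), so the ratio is invariant
    under joint rescaling.
    """
    cmic, dna_content = _as_array(cmic), _as_array(dna_content)
    if np.any(dna_content <= 0):
        raise MeasurementError("DNA content must be strictly positive")
    if np.any(cmic < 0):
        raise MeasurementError("biomass C must be nonnegative")
    out = cmic / dna_content
    return float(out) if out.ndim == 0 else out


def necromass_partition(
    muramic_acid,
    glucosamine_total,
    m_mur: float = M_MURAMIC,
    m_glcn: float = M_GLUCOSAMINE,
):
    """Partition amino-sugar pools into bacterial and fungal necromass C.

    Parameters are soil concentrations in ug g^-1 DW.  Bacterial
    glucosamine equals muramic acid on a molar basis (1:1 in bacterial cell
    walls); the remainder of total glucosamine is fungal.  Returns
    ``(necromass_bacterial, necromass_fungal)`` in mg C g^-1 DW.
    """
    mur, glcn = _as_array(muramic_acid), _as_array(glucosamine_total)
    if np.any(mur < 0) or np.any(glcn < 0):
        raise MeasurementError("amino-sugar concentrations must be nonnegative")
    mol_mur = mur / m_mur  # umol g^-1
    mol_glcn = glcn / m_glcn
    if np.any(mol_glcn - mol_mur < -1e-12 * np.maximum(mol_glcn, 1.0)):
        raise MeasurementError(
            "molar glucosamine below molar muramic acid: fungal share negative"
        )
    fungal_glcn_mass = np.clip(mol_glcn - mol_mur, 0.0, None) * m_glcn  # ug g^-1
    nec_bact = mur * MURAMIC_TO_C / 1000.0  # mg C g^-1
    nec_fung = fungal_glcn_mass * GLUCOSAMINE_TO_C / 1000.0
    if nec_bact.ndim == 0:
        return float(nec_bact), float(nec_fung)
    return nec_bact, nec_fung


def fb_necromass_ratio(necromass_fungal, necromass_bacterial):
    """Fungal : bacterial necromass C ratio (dimensionless)."""
    f, b = _as_array(necromass_fungal), _as_array(necromass_bacterial)
    if np.any(b <= 0):
        raise UndefinedValueError("F:B ratio undefined with zero bacterial necromass")
    out = f / b
    return float(out) if out.ndim == 0 else out


_CFE_COLS = ["sample_id", "C_fumigated", "C_unfumigated"]
_AMINO_COLS = ["sample_id", "muramic_acid_ug_g", "glucosamine_total_ug_g"]
_DNA_COLS = ["sample_id", "dna_ug_g"]


def _require_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {', '.join(missing)}")


def derive_biomass_necromass(
    cfe: pd.DataFrame,
    aminosugars: pd.DataFrame,
    dna: pd.DataFrame,
    mode: str = "strict",
) -> pd.DataFrame:
    """Biomass and necromass table from the three raw tables.

    Expects the ``cfe.csv`` (optionally with a ``k_EC`` column),
    ``aminosugars.csv`` and ``dna.csv`` schemas; joins on sample_id.
    Returns cmic (ug C g^-1 DW), f_dna, necromass pools (mg C g^-1 DW) and
    the F:B ratio.
    """
    _require_columns(cfe, _CFE_COLS, "cfe")
    _require_columns(aminosugars, _AMINO_COLS, "aminosugars")
    _require_columns(dna, _DNA_COLS, "dna")
    cfe = cfe.set_index("sample_id")
    amino = aminosugars.set_index("sample_id")
    dna = dna.set_index("sample_id")
    ids = cfe.index.intersection(amino.index).intersection(dna.index)
    cfe, amino, dna = cfe.loc[ids], amino.loc[ids], dna.loc[ids]

    k_ec = cfe["k_EC"].values if "k_EC" in cfe.columns else K_EC
    cmic = cfe_biomass_c(
        cfe["C_fumigated"].values, cfe["C_unfumigated"].values, k_ec, mode
    )
    fdna = f_dna(cmic, dna["dna_ug_g"].values)
    nec_b, nec_f = necromass_partition(
        amino["muramic_acid_ug_g"].values, amino["glucosamine_total_ug_g"].values
    )
    return pd.DataFrame(
        {
            "cmic": cmic,
            "f_dna": fdna,
            "necromass_bacterial": nec_b,
            "necromass_fungal": nec_f,
            "necromass_total": nec_b + nec_f,
            "fb_ratio": fb_necromass_ratio(nec_f, nec_b),
        },
        index=pd.Index(ids, name="sample_id"),
    )
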