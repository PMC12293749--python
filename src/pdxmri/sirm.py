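"""Stable-isotope-resolved metabolomics arithmetic from NMR peak tables.

Input is a table of integrated 1H peak areas from tissue extracts of
[U-13C]glucose-labeled tumors: for each metabolite, the central (12C-bound
proton) area and the summed 13C satellite area, plus an internal
concentration standard.  Spectral processing, peak picking and satellite
assignment happen upstream; this module consumes integrals only.

Fractional enrichment FE = satellite / (satellite + central) is the fraction
of the proton-observed pool carrying 13C.  Absolute levels follow from
proton-normalized comparison with the reference standard.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Required columns of a peak table, one row per metabolite.
PEAK_TABLE_COLUMNS = [
    "metabolite",
    "central_area",
    "satellite_area",
    "proton_count",
    "tissue_mass_g",
    "reference_area",
    "reference_conc_mm",
    "reference_protons",
    "extract_volume_ml",
]

NATURAL_ABUNDANCE_13C = 0.011  # per carbon


def validate_peak_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PEAK_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"peak table missing columns: {missing}")
    if (table["central_area"] < 0).any() or (table["satellite_area"] < 0).any():
        raise ValueError("peak areas must be non-negative")
    if (table["proton_count"] < 1).any():
        raise ValueError("proton_count must be >= 1")
    if (table["tissue_mass_g"] <= 0).any():
        raise ValueError("tissue_mass_g must be positive")
    if (table["reference_area"] <= 0).any():
        raise ValueError("reference_area must be positive")
    return table


def fractional_enrichment(
    satellite_area: float,
    central_area: float,
    natural_abundance_carbons: int = 0,
) -> float:
    """FE = satellite / (central + satellite), in [0, 1].

    With ``natural_abundance_carbons`` > 0, the expected 1.1 %-per-carbon
    background 13C signal is removed:
    FE' = (FE - c*0.011) / (1 - c*0.011), floored at 0.  Off by default.
    Both areas zero -> NaN (undefined enrichment).
    """
    if satellite_area < 0 or central_area < 0:
        raise ValueError("areas must be non-negative")
    total = satellite_area + central_area
    if total == 0:
        return float("nan")
    fe = satellite_area / total
    if natural_abundance_carbons:
        na = natural_abundance_carbons * NATURAL_ABUNDANCE_13C
        fe = max(0.0, (fe - na) / (1.0 - na))
    return float(fe)


def metabolite_concentration(
    central_area: float,
    satellite_area: float,
    proton_count: float,
    reference_area: float,
    reference_protons: float,
    reference_conc_mm: float,
    extract_volume_ml: float,
    tissue_mass_g: float,
) -> float:
    """Metabolite level in umol per g tissue, against the internal standard.

    ((central + satellite) / protons) / (ref_area / ref_protons)
    * ref_conc (mM) * extract volume (mL) / tissue mass (g); mM * mL = umol.
    """
    if reference_area <= 0:
        raise ValueError("reference_area must be positive")
    if tissue_mass_g <= 0:
        raise ValueError("tissue mass must be positive")
    per_proton = (central_area + satellite_area) / proton_count
    ref_per_proton = reference_area / reference_protons
    umol = per_proton / ref_per_proton * reference_conc_mm * extract_volume_ml
    return float(umol / tissue_mass_g)


def analyze_peak_table(
    table: pd.DataFrame, natural_abundance_correction: bool = False
) -> pd.DataFrame:
    """Per-row FE and concentration; adds ``fe`` and ``conc_umol_per_g``.

    The natural-abundance flag uses a ``carbon_count`` column when present,
    else 1 carbon per metabolite.
    """
    table = validate_peak_table(table.copy())
    carbons = table["carbon_count"] if "carbon_count" in table.columns else 1
    fes, concs = [], []
    for i, row in table.iterrows():
        nc = int(carbons[i]) if np.ndim(carbons) else int(carbons)
        fes.append(
            fractional_enrichment(
                row["satellite_area"],
                row["central_area"],
                natural_abundance_carbons=nc if natural_abundance_correction else 0,
            )
        )
        concs.append(
            metabolite_concentration(
                row["central_area"],
                row["satellite_area"],
                row["proton_count"],
                row["reference_area"],
                row["reference_protons"],
                row["reference_conc_mm"],
                row["extract_volume_ml"],
                row["tissue_mass_g"],
            )
        )
    table["fe"] = fes
    table["conc_umol_per_g"] = concs
    return table
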