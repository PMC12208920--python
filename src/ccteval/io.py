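"""Municipal panel CSV dialect.

One flat comma-separated table, UTF-8, header row, one record per
municipality-year.  The column dictionary below is the contract every
stage of the pipeline reads and writes; ``read_panel`` enforces it.
"""

from __future__ import annotations

import warnings

import pandas as pd

#: Column dictionary of the panel dialect.  Values document units.
COLUMNS = {
    "municipality": "opaque municipality identifier (string)",
    "year": "calendar year (integer)",
    "population": "total resident population (count)",
    "pop_under5": "population younger than 5 years (count)",
    "pop_5_69": "population aged 5-69 years (count)",
    "pop_70plus": "population aged 70 years and older (count)",
    "livebirths": "registered livebirths (count; under-5 rate denominator)",
    "estimated_births": "demographically estimated births (count)",
    "deaths": "all-cause deaths, all ages (count)",
    "deaths_under5": "deaths younger than 5 years (count)",
    "deaths_5_69": "deaths aged 5-69 years (count)",
    "deaths_70plus": "deaths aged 70 years and older (count)",
    "ill_defined_deaths": "deaths with ill-defined cause (count)",
    "hospitalisations": "all-cause hospitalisations, all ages (count)",
    "hosp_under5": "hospitalisations younger than 5 years (count)",
    "hosp_5_69": "hospitalisations aged 5-69 years (count)",
    "hosp_70plus": "hospitalisations aged 70 years and older (count)",
    "bfp_enrolled": "families enrolled in the cash-transfer programme (count)",
    "bfp_eligible": "programme-eligible families (count)",
    "bfp_transferred": "total monthly amount transferred (BRL)",
    "poverty_rate": "poverty rate (%)",
    "illiteracy_rate": "illiteracy rate, over-15s (%)",
    "gini": "Gini index (0-100 scale)",
    "urbanization_rate": "urbanisation rate (%)",
    "piped_water": "households with piped water (%)",
    "sanitation": "households with adequate sanitation (%)",
    "physicians_per_1000": "physicians per 1000 individuals (rate)",
    "beds_per_1000": "hospital beds per 1000 individuals (rate)",
    "bpc_coverage": "social-pension programme coverage (%)",
    "esf_coverage": "primary-health-care programme coverage (%)",
    "fertility_rate": "total fertility rate (births per woman)",
}

KEY_COLUMNS = ["municipality", "year"]

COUNT_COLUMNS = [
    "population", "pop_under5", "pop_5_69", "pop_70plus", "livebirths",
    "estimated_births", "deaths", "deaths_under5", "deaths_5_69",
    "deaths_70plus", "ill_defined_deaths", "hospitalisations", "hosp_under5",
    "hosp_5_69", "hosp_70plus", "bfp_enrolled", "bfp_eligible",
]

#: Named socioeconomic / health-system adjusting covariates.
COVARIATE_COLUMNS = [
    "poverty_rate", "illiteracy_rate", "gini", "urbanization_rate",
    "piped_water", "sanitation", "physicians_per_1000", "beds_per_1000",
    "bpc_coverage", "esf_coverage", "fertility_rate",
]


class PanelValidationError(ValueError):
    """Raised when a panel violates the dialect contract."""


def validate_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Validate a panel against the column dictionary.

    Checks key uniqueness and count non-negativity; warns on unknown
    columns.  Returns the panel (with ``year`` coerced to int) so the
    call can be chained.
    """
    missing = [c for c in KEY_COLUMNS if c not in panel.columns]
    if missing:
        raise PanelValidationError(f"panel is missing key column(s): {missing}")
    unknown = [c for c in panel.columns if c not in COLUMNS]
    if unknown:
        warnings.warn(f"unknown panel column(s) ignored by the dialect: {unknown}",
                      stacklevel=2)
    panel = panel.copy()
    panel["year"] = panel["year"].astype(int)

    dup = panel.duplicated(subset=KEY_COLUMNS, keep=False)
    if dup.any():
        keys = panel.loc[dup, KEY_COLUMNS].drop_duplicates()
        first = tuple(keys.iloc[0])
        raise PanelValidationError(
            f"duplicate (municipality, year) key(s), first: {first} "
            f"({len(keys)} duplicated key(s) total)")

    for col in COUNT_COLUMNS:
        if col not in panel.columns:
            continue
        bad = panel.index[panel[col] < 0]
        if len(bad):
            rows = list(bad[:5])
            raise PanelValidationError(
                f"negative values in count column '{col}' at row(s) {rows}")
    return panel


def read_panel(path) -> pd.DataFrame:
    """Read and validate a panel CSV in the documented dialect."""
    panel = pd.read_csv(path, dtype={"municipality": str})
    return validate_panel(panel)


def write_panel(panel: pd.DataFrame, path) -> None:
    """Write a panel CSV; floats kept at full precision for round-trips."""
    panel.to_csv(path, index=False)
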