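"""Packaged reference tables.

``chile_2021_services.csv`` carries the published per-health-service child
populations and age-sex-adjusted school ASD prevalences from the 2021
Chilean school registry study; these drive the generator defaults and the
reporting layer.  ``standard_population_synthetic.csv`` is a synthetic
stand-in for the census projection used as the standardization reference
(the real projection table is not redistributable): band x sex products of
the published registry marginals.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

CLINICAL_SERVICE = "Araucanía Sur"
AGE_BANDS = ("6-8", "9-11", "12-14", "15-18")
FEE_BANDS = ("Free", "1.15-11.50", "11.51-28.75", "28.76-57.51",
             "57.52-115.01", ">115.02", "Missing")


def _path(name: str):
    return resources.files("prevlink.data").joinpath(name)


def load_service_table() -> pd.DataFrame:
    """Per-service population and adjusted school prevalence (percent)."""
    with _path("chile_2021_services.csv").open("r", encoding="utf-8") as f:
        return pd.read_csv(f)


def load_standard_population() -> pd.DataFrame:
    """Synthetic age-band x sex standard population (columns age_band, sex, weight)."""
    with _path("standard_population_synthetic.csv").open("r", encoding="utf-8") as f:
        return pd.read_csv(f)


def registry_counts() -> dict:
    """Published headline counts of the 2021 registry and the clinical linkage."""
    with _path("chile_2021_counts.json").open("r", encoding="utf-8") as f:
        return json.load(f)
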