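"""Packaged reference measurements used as calibration and validation targets.

Four small tables ship with the package, transcribed from published
rat-aortic smooth muscle cell culture experiments and the model predictions
fit to them:

``unstrained_density_day3``
    Cell densities (cells/mm^2) at seeding and after 3 unstrained days on
    PDMS, three replicated cultures; plus the fitted model's predictions.
``pdms_strained_fold_change``
    Fold change in cell number at 24 h and 72 h on PDMS under 4-6%, 2-8%
    and 0-10% cyclic strain; observed mean +/- SD and fitted model values.
``krotc_fold_change``
    72 h fold change under 0-10% strain for a sweep of the strain-regime
    rotation constant.
``structured_fold_change_10day``
    10-day fold change on structured collagenous substrates aligned
    perpendicular or parallel to a 0-10% strain, for fiber concentrations
    kappa in {2, 5, 8, 100}.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

__all__ = ["load_table", "TABLES"]

TABLES = (
    "unstrained_density_day3",
    "pdms_strained_fold_change",
    "krotc_fold_change",
    "structured_fold_change_10day",
)


def load_table(name: str) -> pd.DataFrame:
    """Load one of the packaged reference tables by name."""
    if name not in TABLES:
        raise KeyError(f"unknown reference table {name!r}; available: {TABLES}")
    resource = files("vsmcabm.data").joinpath(f"{name}.csv")
    with resource.open("r") as handle:
        return pd.read_csv(handle)
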