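"""Curated reference tables of the troponin recoupling study conditions.

These CSVs hold the published condition-level statistics the package
works against: MD-derived helix A/B angle, hinge angle, interdomain
distance and salt-bridge occupancy summaries per troponin variant x
ligand x phosphorylation state; ligand attachment fractions and
externally supplied MMPBSA energies; motility EC50s and coupling
calls; and myocyte ttb90 responses to dobutamine.  They serve two
roles: targets for the synthetic-data generators (each generator
plants the condition's statistics) and inputs to report assembly and
the arithmetic-convention checks (delta sign convention, EC50 ratio
convention, recoupling tick pattern).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_table", "TABLES"]

TABLES = (
    "ab_angle_metrics",
    "hinge_angle_metrics",
    "interdomain_metrics",
    "attachment_mmpbsa",
    "motility_ec50",
    "myocyte_lusitropy",
)


def load_table(name: str) -> pd.DataFrame:
    """Load one of the shipped reference tables by name."""
    if name not in TABLES:
        raise KeyError(f"unknown reference table {name!r}; available: {TABLES}")
    ref = resources.files("tncoupling.refdata").joinpath(f"{name}.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path)
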