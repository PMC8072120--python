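"""Bundled published summary tables for the Ligeriinae study system.

These are transcriptions of published per-species summaries (specimen
counts, pollination types, qualitative patterning-mode labels, and the
mode × pollination-type contingency counts) for 34 Ligeriinae species.
The underlying petal images are not publicly deposited; pipelines are
exercised on the :mod:`petalign.synthetic` generator instead.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import SpecimenTable, load_specimen_table

__all__ = [
    "load_ligeriinae_specimens",
    "load_ligeriinae_modes",
    "load_ligeriinae_contingency",
]


def _data_path(name: str):
    return resources.files("petalign.data").joinpath(name)


def load_ligeriinae_specimens() -> SpecimenTable:
    """Per-species specimen counts, pollination types and accessions."""
    with resources.as_file(_data_path("ligeriinae_specimens.csv")) as p:
        return load_specimen_table(p)


def load_ligeriinae_modes() -> pd.DataFrame:
    """Qualitative patterning-mode labels per species.

    Columns: ``species``, ``variegated`` (vascular/random/none) and
    ``gradient`` (distal/proximal/none).
    """
    with resources.as_file(_data_path("ligeriinae_modes.csv")) as p:
        return pd.read_csv(p)


def load_ligeriinae_contingency(family: str) -> pd.DataFrame:
    """Published mode × pollination-type contingency counts.

    ``family`` is ``"variegated"`` or ``"gradient"``.  Note these printed
    counts are not exactly re-derivable from the per-species tables (one
    hummingbird species more than the species list carries); they are kept
    verbatim as the statistical input of record.
    """
    if family not in ("variegated", "gradient"):
        raise ValueError("family must be 'variegated' or 'gradient'")
    with resources.as_file(_data_path(f"contingency_{family}.csv")) as p:
        df = pd.read_csv(p)
    return df.set_index("pollination_type")
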