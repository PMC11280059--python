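"""Packaged reference data: study tables, anatomy, tissue composition.

The source model relies on software-internal system parameters that are not
printed anywhere; the reference anatomy shipped here is a standard 70-kg adult
organ volume / blood-flow table (ICRP-style values, see docs/methods.md), and
the tissue composition table carries the fractional water / neutral-lipid /
phospholipid contents used by the tissue-composition partitioning method.

All files are plain CSV/YAML under ``vildapbpk/data`` and are verified against
SHA-256 checksums on load.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

_DATA_PKG = "vildapbpk.data"


class FixtureIntegrityError(RuntimeError):
    """Raised when a packaged data file does not match its recorded checksum."""


def _data_path(name: str) -> Path:
    return Path(resources.files(_DATA_PKG).joinpath(name))


def _verify(name: str) -> Path:
    path = _data_path(name)
    manifest = json.loads(_data_path("CHECKSUMS.json").read_text())
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if manifest.get(name) != digest:
        raise FixtureIntegrityError(
            f"checksum mismatch for packaged data file {name!r}"
        )
    return path


def load_reference_anatomy() -> pd.DataFrame:
    """70-kg adult compartment volumes (L) and blood-flow fractions of CO."""
    return pd.read_csv(_verify("reference_anatomy.csv"), index_col="compartment")


def load_tissue_composition() -> pd.DataFrame:
    """Fractional water/neutral-lipid/phospholipid content per tissue."""
    return pd.read_csv(_verify("tissue_composition.csv"), index_col="tissue")


def load_drug_yaml() -> dict:
    """Raw default vildagliptin parameter mapping (literature + input values)."""
    return yaml.safe_load(_verify("drug_vildagliptin.yaml").read_text())


def load_fixture_tables() -> dict:
    """Return the packaged study tables as structured records.

    Keys: ``table1`` (observed/predicted PK parameters with ratios),
    ``table2`` (average fold errors), ``table3`` (study demographics),
    ``table4`` (drug parameter mapping). Files are checksummed.
    """
    return {
        "table1": pd.read_csv(_verify("table1_pk_ratios.csv")),
        "table2": pd.read_csv(_verify("table2_afe.csv")),
        "table3": pd.read_csv(_verify("table3_studies.csv")),
        "table4": load_drug_yaml(),
    }
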