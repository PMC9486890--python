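"""Readers and writers for serology CSV and AIRR-style repertoire TSV.

Serology tables are plain CSV with the documented header; repertoire
tables are tab-separated with AIRR Rearrangement-style column names
(``cell_id``, ``clone_id``, ``c_call``, ...).  Every writer records the
generator seed and package version in a JSON sidecar next to the data
file.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .repertoire import ISOTYPE_ORDER
from .serology import TITRE_LADDER

__all__ = [
    "read_serology",
    "write_serology",
    "read_repertoire",
    "write_repertoire",
    "load_config",
    "write_sidecar",
]

SEROLOGY_COLUMNS = ["patient_id", "sample_id", "material", "days_from_onset",
                    "ot_status", "resection_day",
                    "titre_IgM", "titre_IgA", "titre_IgG"]
_TITRE_COLUMNS = ["titre_IgM", "titre_IgA", "titre_IgG"]
REPERTOIRE_COLUMNS = ["cell_id", "sample_id", "tissue", "clone_id",
                      "v_mutation_count", "v_length_nt"]


def _validate_titres(frame: pd.DataFrame, path) -> None:
    ladder = set(TITRE_LADDER) | {0, 1}  # 1 encodes "undiluted positive" (CSF)
    for col in _TITRE_COLUMNS:
        bad = ~frame[col].isin(ladder)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: row {row}: off-ladder titre {frame[col].iloc[row]!r} "
                f"in column {col!r}")


def read_serology(path) -> pd.DataFrame:
    """Read a serology samples table (CSV or TSV, sniffed from the suffix).

    Validates the required header and checks every titre against the
    dilution ladder (0 codes negative).  Unknown columns are preserved.
    """
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".tab"} else ","
    frame = pd.read_csv(path, sep=sep)
    missing = [c for c in SEROLOGY_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    if (frame["days_from_onset"] < 0).any():
        raise ValueError(f"{path}: days_from_onset must be >= 0")
    _validate_titres(frame, path)
    return frame


def write_serology(frame: pd.DataFrame, path, seed: int | None = None) -> None:
    path = Path(path)
    sep = "\t" if path.suffix in {".tsv", ".tab"} else ","
    frame.to_csv(path, sep=sep, index=False)
    write_sidecar(path, seed=seed, kind="serology", n_rows=len(frame))


def read_repertoire(path) -> pd.DataFrame:
    """Read an AIRR-style repertoire TSV into a cell table.

    Accepts either per-isotype expression columns (IGHM, IGHD, ...) or a
    pre-computed ``c_call`` column; at least one of the two must be
    present.  ``c_call``-only files bypass the dominant-isotype call and
    the labels are taken verbatim.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in REPERTOIRE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    has_expression = any(g in frame.columns for g in ISOTYPE_ORDER)
    if "c_call" not in frame.columns and not has_expression:
        raise ValueError(f"{path}: need either a c_call column or "
                         "constant-region expression columns")
    if (frame["v_mutation_count"] < 0).any():
        raise ValueError(f"{path}: v_mutation_count must be >= 0")
    if (frame["v_length_nt"] <= 0).any():
        raise ValueError(f"{path}: v_length_nt must be positive")
    return frame


def write_repertoire(frame: pd.DataFrame, path, seed: int | None = None) -> None:
    path = Path(path)
    frame.to_csv(path, sep="\t", index=False)
    write_sidecar(path, seed=seed, kind="repertoire", n_rows=len(frame))


def write_sidecar(data_path, **metadata) -> Path:
    """Write a ``<file>.meta.json`` sidecar recording seed and provenance."""
    data_path = Path(data_path)
    sidecar = data_path.with_suffix(data_path.suffix + ".meta.json")
    from . import __version__
    payload = {"file": data_path.name, "package_version": __version__, **metadata}
    sidecar.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return sidecar


def load_config(path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as handle:
        config = yaml.safe_load(handle)
    if not isinstance(config, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return config
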