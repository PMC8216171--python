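"""CSV readers/writers and flat-file configuration.

All interchange is plain CSV with an ``NA`` token for unknown values.
Column names in external files vary between deposits, so both readers
accept a ``column_map`` translating file columns to the canonical names
used throughout the package.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import validate_pedigree
from .synthetic_data import SimulationConfig

__all__ = [
    "AnalysisConfig",
    "read_phenotype_table",
    "write_phenotype_table",
    "read_pedigree_table",
    "write_pedigree_table",
    "read_flat_config",
    "read_sim_config",
    "read_analysis_config",
]

_NA = "NA"
_STR_COLS = ("id", "dam", "sire", "brood", "sex", "generation", "treatment", "population")
_CONC_COLS = ("linamarin", "lotaustralin", "total")


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, keep_default_na=False, na_values=[_NA, ""], dtype=str)


def _apply_map(df: pd.DataFrame, column_map) -> pd.DataFrame:
    return df.rename(columns=dict(column_map)) if column_map else df


def read_phenotype_table(path, column_map=None) -> pd.DataFrame:
    """Read a phenotype CSV into the canonical layout.

    Requires an ``id`` column plus ``linamarin`` and ``lotaustralin``
    concentrations (percent dry mass).  ``total`` is recomputed as their
    sum; if the file carries its own total column it is checked against
    the recomputed one to 1e-6.  Negative concentrations and duplicate
    ids are rejected with the offending row number.
    """
    df = _apply_map(_read_csv(path), column_map)
    if "id" not in df.columns:
        raise ValueError(f"{path}: missing mandatory column 'id'")
    for col in ("linamarin", "lotaustralin"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing mandatory column {col!r}")
    dupes = df["id"][df["id"].duplicated()]
    if len(dupes):
        raise ValueError(f"{path}: duplicate ids: {sorted(set(dupes))}")
    out = df.copy()
    for col in df.columns:
        if col not in _STR_COLS:
            out[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("linamarin", "lotaustralin"):
        bad = out.index[out[col] < 0]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise ValueError(f"{path}: negative {col} at file row {bad[0] + 2}")
    recomputed = out["linamarin"] + out["lotaustralin"]
    if "total" in out.columns:
        diff = (out["total"] - recomputed).abs()
        bad = out.index[diff.notna() & (diff > 1e-6)]
        if len(bad):
            raise ValueError(
                f"{path}: total != linamarin + lotaustralin at file row {bad[0] + 2}"
            )
    out["total"] = recomputed
    return out


def _format_frame(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype == object:
            out[col] = out[col].where(out[col].notna(), _NA)
    return out


def write_phenotype_table(df: pd.DataFrame, path) -> None:
    _format_frame(df).to_csv(path, index=False, na_rep=_NA, float_format="%.12g")


def read_pedigree_table(path, column_map=None) -> pd.DataFrame:
    """Read and validate a pedigree CSV (columns id, dam, sire, sex,
    generation; ``NA`` marks an unknown parent, making founders)."""
    df = _apply_map(_read_csv(path), column_map)
    if "phantom" in df.columns:
        df["phantom"] = df["phantom"].map(
            {"True": True, "False": False, "1": True, "0": False}
        ).fillna(False)
    return validate_pedigree(df)


def write_pedigree_table(df: pd.DataFrame, path) -> None:
    _format_frame(df).to_csv(path, index=False, na_rep=_NA)


# ---------------------------------------------------------------------------
# flat key=value configuration


def read_flat_config(path) -> dict:
    """Parse a flat ``key = value`` text file.  Values are coerced to
    int, float, bool or a tuple (comma-separated) where possible."""
    out = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value'")
        key, val = (s.strip() for s in line.split("=", 1))
        out[key] = _coerce(val)
    return out


def _coerce(val: str):
    if "," in val:
        return tuple(_coerce(v.strip()) for v in val.split(","))
    low = val.lower()
    if low in ("true", "false"):
        return low == "true"
    for cast in (int, float):
        try:
            return cast(val)
        except ValueError:
            pass
    return val


def _from_flat(cls, mapping: dict, path):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(mapping) - names)
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys {unknown}")
    return cls(**mapping)


def read_sim_config(path) -> SimulationConfig:
    """Simulation config from a flat key=value file.  A two-integer tuple
    for ``offspring_per_brood`` is a (low, high) range; a longer tuple is
    a per-brood sequence."""
    return _from_flat(SimulationConfig, read_flat_config(path), path)


@dataclass
class AnalysisConfig:
    """End-to-end analysis settings for the command-line pipeline."""

    phenotypes: str = ""
    pedigree: str = ""
    trait: str = "total"
    model: int = 1
    denominator: str = "text-convention"
    n_boot: int = 1000
    seed: int = 0
    out_dir: str = "heliquant_out"
    verbosity: int = 1

    def __post_init__(self):
        if self.trait not in ("total", "linamarin", "lotaustralin"):
            raise ValueError("trait must be total, linamarin or lotaustralin")
        if self.model not in (1, 2):
            raise ValueError("model must be 1 or 2")
        if self.denominator not in ("text-convention", "full"):
            raise ValueError("denominator must be 'text-convention' or 'full'")


def read_analysis_config(path) -> AnalysisConfig:
    return _from_flat(AnalysisConfig, read_flat_config(path), path)
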