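"""Readers/writers for the pedigree text formats and run configuration.

Pedigrees travel as a three-column text table (individual, sire, dam;
``0`` or ``NA`` marks an unknown parent) with a companion attribute
table (id, sex, birth_year, sampled, sample_year, known_dead), both
comma- or whitespace-delimited with a header row.  Run configuration is
a single YAML file validated against a flat schema; unknown keys are
rejected so typos fail loudly.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimator import PedigreeTable

__all__ = [
    "read_pedigree",
    "write_pedigree",
    "read_attributes",
    "write_attributes",
    "read_pedigree_table",
    "write_pedigree_table",
    "RunConfig",
    "run_manifest",
]

_SEP = re.compile(r"[,\s]+")


class ParseError(ValueError):
    """Malformed line in a pedigree or attribute file."""


def _read_table(path, columns: list[str]) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    body = [(i + 1, ln) for i, ln in enumerate(lines) if ln and not ln.startswith("#")]
    if not body:
        raise ParseError(f"{path}: empty file")
    header = _SEP.split(body[0][1])
    if [h.lower() for h in header[: len(columns)]] == columns:
        body = body[1:]
    for lineno, ln in body:
        parts = _SEP.split(ln)
        if len(parts) != len(columns):
            raise ParseError(
                f"{path}:{lineno}: expected {len(columns)} fields, got {len(parts)}"
            )
        rows.append(parts)
    return pd.DataFrame(rows, columns=columns)


def read_pedigree(path) -> pd.DataFrame:
    """Three-column pedigree text; 0/NA parents become NaN; ids stay tokens."""
    df = _read_table(path, ["id", "sire", "dam"])
    for col in ("sire", "dam"):
        df[col] = df[col].map(
            lambda v: np.nan if str(v).strip().upper() in {"0", "NA", "NAN", ""} else v
        )
    return df


def write_pedigree(frame: pd.DataFrame, path) -> None:
    out = frame[["id", "sire", "dam"]].copy()
    for col in ("sire", "dam"):
        out[col] = out[col].map(lambda v: "0" if pd.isna(v) else v)
    out.to_csv(path, sep=" ", index=False)


_ATTR_COLUMNS = ["id", "sex", "birth_year", "sampled", "sample_year", "known_dead"]
_TRUE = {"1", "TRUE", "T", "YES"}


def read_attributes(path) -> pd.DataFrame:
    df = _read_table(path, _ATTR_COLUMNS)
    df["birth_year"] = df["birth_year"].astype(int)
    for col in ("sampled", "known_dead"):
        df[col] = df[col].map(lambda v: str(v).strip().upper() in _TRUE)
    df["sample_year"] = df["sample_year"].map(
        lambda v: np.nan if str(v).strip().upper() in {"NA", "NAN", ""} else float(v)
    )
    return df


def write_attributes(frame: pd.DataFrame, path) -> None:
    out = frame[_ATTR_COLUMNS].copy()
    for col in ("sampled", "known_dead"):
        out[col] = out[col].map(lambda v: "1" if v else "0")
    out["sample_year"] = out["sample_year"].map(
        lambda v: "NA" if pd.isna(v) else f"{int(v)}"
    )
    out.to_csv(path, sep=" ", index=False)


def read_pedigree_table(pedigree_path, attributes_path, validate: bool = True) -> PedigreeTable:
    ped = read_pedigree(pedigree_path)
    attrs = read_attributes(attributes_path)
    return PedigreeTable.from_components(ped, attrs, validate=validate)


def write_pedigree_table(table: PedigreeTable, pedigree_path, attributes_path) -> None:
    write_pedigree(table.frame, pedigree_path)
    write_attributes(table.frame, attributes_path)


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """One scenario: simulator, sampling and estimator settings."""

    name: str = "default"
    seed: int = 0
    n0: int = 659
    burn_in: int = 20
    years: int = 5
    area_width_km: float = 50.0
    area_height_km: float = 33.0
    cell_size_km: float = 1.0
    rates_path: str | None = None
    scheme: str = "population"
    fraction: float | None = 0.5
    n_cells: int | None = None
    iterations: int = 20
    alpha0: float = 1.0
    beta0: float = 1.0
    n_boot: int = 2000
    ci_level: float = 0.95
    adult_age_threshold: int = 2
    sigma_annual_f: float = 1.0
    sigma_annual_m: float = 1.5
    sigma_winter_f: float = 0.40
    sigma_winter_m: float = 0.55

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {unknown}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_manifest(config: RunConfig, out_dir: Path, extra: dict | None = None) -> Path:
    """Write a manifest tying outputs to (config, seed)."""
    from . import __version__

    manifest = {
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
        "version": __version__,
    }
    if extra:
        manifest.update(extra)
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
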