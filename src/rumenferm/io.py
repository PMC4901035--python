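"""Table readers/writers with schema validation, and the run manifest.

All tables are plain UTF-8 CSV/TSV with a one-line header; units live in
the schema definitions below, not in column names.  Reading validates
the header against the schema and coerces dtypes; a write -> read
round-trip is the identity on values.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from .exceptions import ValidationError

#: name -> {column: dtype}; required columns per table kind.
SCHEMAS: dict[str, dict[str, str]] = {
    "vfa_long": {"sample_id": "str", "treatment": "str", "replicate": "int",
                 "acid": "str", "amount": "float", "unit": "str"},
    "methane": {"sample_id": "str", "ch4_mmol_d": "float"},
    "vessels": {"sample_id": "str", "treatment": "str", "replicate": "int",
                "acetate": "float", "propionate": "float", "butyrate": "float",
                "isobutyrate": "float", "valerate": "float",
                "isovalerate": "float", "methane": "float",
                "nan_outflow": "float", "ammonia_outflow": "float",
                "om_disappearance": "float", "ammonia_enrichment": "float",
                "bacterial_enrichment": "float", "nan_enrichment": "float"},
    "pressures": {"bottle_id": "str", "time_h": "float",
                  "pressure_kpa": "float", "is_blank": "bool"},
    "release": {"tube_id": "str", "time_h": "float", "pct_released": "float"},
    "otu_counts": {},      # wide matrix: first column sample_id, rest OTU ids
    "metadata": {"sample_id": "str", "forage": "str", "vitamin_e": "str",
                 "time_point": "str", "inoculum_animal": "str"},
}

VALID_UNITS = {"mmol/d", "mmol", "mM", "mg/d"}


def read_table(path: str | Path, schema: str, sep: str | None = None
               ) -> pd.DataFrame:
    """Read and validate a CSV/TSV table against a named schema."""
    path = Path(path)
    if schema not in SCHEMAS:
        raise ValidationError(f"unknown schema {schema!r}")
    if sep is None:
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    cols = SCHEMAS[schema]
    if cols:
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise ValidationError(
                f"{path.name}: schema {schema!r} missing columns {missing}")
        for c, dtype in cols.items():
            try:
                df[c] = df[c].astype(dtype)
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"{path.name}: column {c!r} not coercible to {dtype}: "
                    f"{exc}") from exc
    if schema == "vfa_long":
        bad = sorted(set(df["unit"]) - VALID_UNITS)
        if bad:
            raise ValidationError(f"{path.name}: unknown unit(s) {bad}")
    return df


def write_table(df: pd.DataFrame, path: str | Path, sep: str | None = None,
                index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if sep is None:
        sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df.to_csv(path, sep=sep, index=index)
    return path


@dataclass
class RunManifest:
    """Provenance record written alongside every output directory."""

    command: str
    seed: int | None
    config_hash: str
    inputs: list[str] = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)
    package_version: str = ""
    timestamp: str = ""

    def __post_init__(self):
        if not self.package_version:
            from . import __version__
            self.package_version = __version__
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def write(self, outdir: str | Path) -> Path:
        out = Path(outdir) / "manifest.json"
        out.parent.mkdir(parents=True, exist_ok=True)
        out.write_text(json.dumps(asdict(self), indent=2) + "\n")
        return out


def config_hash(obj) -> str:
    """Stable short hash of a configuration mapping or dataclass."""
    try:
        payload = json.dumps(obj, sort_keys=True, default=str)
    except TypeError:
        payload = repr(obj)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
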