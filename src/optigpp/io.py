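"""Schema-validated CSV IO, unit conversion, run configuration and manifests.

All tables are comma-delimited UTF-8 with a header row; dates are
ISO-8601; site and plot labels are free text. Validation is strict:
missing columns, unparseable values and unit-range violations raise
``SchemaError`` with the offending column and (1-based data) line number.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import constants as c

__all__ = [
    "SchemaError",
    "SCHEMAS",
    "read_table",
    "write_table",
    "unit_convert",
    "RunConfig",
    "write_manifest",
    "write_bundle",
    "read_bundle",
]


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


#: column -> (dtype, (min, max) or None). None bounds mean unbounded.
SCHEMAS: dict[str, dict] = {
    "forcing": {
        "site": (str, None),
        "year": (int, (1900, 2100)),
        "month": (int, (1, 12)),
        "tc": (float, (-10.0, 60.0)),
        "vpd": (float, (0.0, None)),
        "co2": (float, (100.0, 2000.0)),
        "patm": (float, (30000.0, 120000.0)),
        "ppfd": (float, (0.0, None)),
    },
    "gas_exchange": {
        "site": (str, None),
        "species": (str, None),
        "plot": (str, None),
        "asat": (float, (None, None)),
        "amax": (float, (None, None)),
        "tleaf": (float, (0.0, 50.0)),
        "ppfd_meas": (float, (0.0, None)),
        "leaf_class": (str, None),
        "basal_area_frac": (float, (0.0, 1.0)),
    },
    "isotope": {
        "site": (str, None),
        "species": (str, None),
        "plot": (str, None),
        "delta13c_leaf": (float, (-60.0, 0.0)),
        "delta13c_air": (float, (-20.0, 0.0)),
    },
    "fapar": {
        "site": (str, None),
        "date": (str, None),
        "value": (float, (0.0, 1.0)),
        "source": (str, None),
        "cloud_state": (str, None),
    },
    "gpp_components": {
        "site": (str, None),
        "plot": (str, None),
        "component": (str, None),
        "value": (float, (0.0, None)),
        "sigma": (float, (0.0, None)),
    },
    "pft": {
        "pft": (str, None),
        "fraction": (float, (0.0, 1.0)),
        "gpp": (float, (0.0, None)),
        "is_forest": (bool, None),
    },
    "product_gpp": {
        "site": (str, None),
        "product": (str, None),
        "gpp": (float, (0.0, None)),
    },
}


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a CSV against a named schema."""
    if schema not in SCHEMAS:
        raise KeyError(f"unknown schema {schema!r}; known: {sorted(SCHEMAS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spec = SCHEMAS[schema]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [col for col in spec if col not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {missing} for schema {schema!r}")
    out = pd.DataFrame(index=df.index)
    for col, (dtype, bounds) in spec.items():
        raw = df[col]
        if dtype is str:
            out[col] = raw.astype(str)
            continue
        if dtype is bool:
            out[col] = raw.str.lower().map({"true": True, "false": False,
                                            "1": True, "0": False})
            if out[col].isna().any():
                line = int(out[col].isna().idxmax()) + 1
                raise SchemaError(f"{path.name}: unparseable bool in {col!r} at data line {line}")
            continue
        converted = pd.to_numeric(raw, errors="coerce")
        if converted.isna().any():
            line = int(converted.isna().idxmax()) + 1
            raise SchemaError(
                f"{path.name}: unparseable value {raw[converted.isna()].iloc[0]!r} "
                f"in column {col!r} at data line {line}"
            )
        if bounds is not None:
            lo, hi = bounds
            bad = pd.Series(False, index=converted.index)
            if lo is not None:
                bad |= converted < lo
            if hi is not None:
                bad |= converted > hi
            if bad.any():
                line = int(bad.idxmax()) + 1
                raise SchemaError(
                    f"{path.name}: value {converted[bad].iloc[0]} out of range "
                    f"{bounds} in column {col!r} at data line {line}"
                )
        out[col] = converted.astype(int) if dtype is int else converted.astype(float)
    # carry through optional extra columns (e.g. measured ci), numerically
    # parsed where possible
    for col in df.columns:
        if col not in out.columns:
            try:
                out[col] = pd.to_numeric(df[col])
            except (ValueError, TypeError):
                out[col] = df[col]
    return out


def write_table(df: pd.DataFrame, path: str | Path, schema: str | None = None) -> None:
    """Write a CSV (validating against a schema first when one is named)."""
    if schema is not None:
        missing = [col for col in SCHEMAS[schema] if col not in df.columns]
        if missing:
            raise SchemaError(f"cannot write {schema!r} table: missing column(s) {missing}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def unit_convert(gpp_gc_m2: float) -> float:
    """gC m-2 yr-1 -> MgC ha-1 yr-1 (exact factor 0.01)."""
    return gpp_gc_m2 * c.GC_M2_TO_MGC_HA


@dataclass
class RunConfig:
    """Bindings and policies for a pipeline run."""

    sites: list[str]
    year_range: tuple[int, int] = (2011, 2016)
    paths: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)
    policies: dict = field(default_factory=lambda: {
        "fapar_filter": "exclude_significant",
        "rd_frac_of_vcmax": 0.015,
        "ci_ratio_400": 0.7,
        "ci_ratio_2000": 0.9,
    })
    seed: int = 0

    def __post_init__(self) -> None:
        if self.year_range[1] < self.year_range[0]:
            raise ValueError("empty year range")
        for name, p in self.paths.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"config path {name!r} -> {p} not resolvable")

    def to_dict(self) -> dict:
        return {
            "sites": list(self.sites),
            "year_range": list(self.year_range),
            "paths": {k: str(v) for k, v in self.paths.items()},
            "params": dict(self.params),
            "policies": dict(self.policies),
            "seed": self.seed,
        }


def write_manifest(path: str | Path, config: RunConfig | dict, seed: int) -> dict:
    """Write a reproducibility manifest (config hash, seed, versions)."""
    cfg = config.to_dict() if isinstance(config, RunConfig) else dict(config)
    payload = json.dumps(cfg, sort_keys=True)
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(payload.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


_BUNDLE_FILES = {
    "forcing_field": "forcing_field.csv",
    "forcing_product": "forcing_product.csv",
    "gas_exchange": "gas_exchange.csv",
    "isotope": "isotope.csv",
    "fapar_insitu": "fapar_insitu.csv",
    "fapar_satellite": "fapar_satellite.csv",
    "gpp_components": "gpp_components.csv",
}
_BUNDLE_SCHEMAS = {
    "forcing_field": "forcing",
    "forcing_product": "forcing",
    "gas_exchange": "gas_exchange",
    "isotope": "isotope",
    "fapar_insitu": "fapar",
    "fapar_satellite": "fapar",
    "gpp_components": "gpp_components",
}


def write_bundle(bundle, out_dir: str | Path) -> Path:
    """Write a synthetic site bundle to a directory of schema CSVs."""
    out = Path(out_dir) / bundle.site
    out.mkdir(parents=True, exist_ok=True)
    for attr, fname in _BUNDLE_FILES.items():
        write_table(getattr(bundle, attr), out / fname, _BUNDLE_SCHEMAS[attr])
    meta = {"site": bundle.site, "seed": bundle.seed,
            "gpp_truth": bundle.template.gpp_truth,
            "designed_fapar_bias_pct": bundle.design["fapar_bias_pct"]}
    (out / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return out


def read_bundle(site_dir: str | Path) -> dict[str, pd.DataFrame]:
    """Read the CSVs of one site bundle back as validated DataFrames."""
    site_dir = Path(site_dir)
    return {attr: read_table(site_dir / fname, _BUNDLE_SCHEMAS[attr])
            for attr, fname in _BUNDLE_FILES.items()}
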