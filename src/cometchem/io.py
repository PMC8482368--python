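"""CSV/YAML input-output contracts, config handling, and run manifests.

All tabular I/O is plain CSV (UTF-8, '.' decimal); configuration is YAML.
Readers validate schema and value domains up front and report offending rows,
so downstream stages can assume clean tables.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from .mass_model import PeptideSpec
from .peptides import PEPTIDES
from .simulator import SimulationConfig

__all__ = [
    "MS1_COLUMNS",
    "MS2_COLUMNS",
    "read_channel_csv",
    "read_fragment_csv",
    "write_csv",
    "load_config",
    "peptide_from_config",
    "simulation_config_from_dict",
    "RunManifest",
]

MS1_COLUMNS = ("time_min", "replicate", "channel_id", "intensity")
MS2_COLUMNS = ("time_min", "replicate", "group_id", "ion_label", "mz_theoretical", "intensity")


def _validate_table(
    df: pd.DataFrame,
    required: Sequence[str],
    numeric: Sequence[str],
    path: str | Path,
    known_channels: Sequence[str] | None = None,
    channel_col: str = "channel_id",
) -> pd.DataFrame:
    missing = set(required) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in numeric:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()] if df[col].isna().any() else df.index[vals.isna()]
        if len(bad):
            rows = (bad[:5] + 2).tolist()  # 1-based incl. header
            raise ValueError(f"{path}: non-numeric {col!r} values at lines {rows}")
        df[col] = vals
    if (df["intensity"] < 0).any():
        rows = (df.index[df["intensity"] < 0][:5] + 2).tolist()
        raise ValueError(f"{path}: negative intensity at lines {rows}")
    if known_channels is not None:
        unknown = set(df[channel_col]) - set(known_channels)
        if unknown:
            rows = (df.index[df[channel_col].isin(unknown)][:5] + 2).tolist()
            raise ValueError(
                f"{path}: unknown {channel_col} values {sorted(unknown)} at lines {rows}"
            )
    return df


def read_channel_csv(
    path: str | Path, known_channels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Read and validate an MS1 channel-intensity table."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty channel table")
    return _validate_table(
        df, MS1_COLUMNS, ("time_min", "intensity"), path, known_channels
    )


def read_fragment_csv(
    path: str | Path, known_groups: Sequence[str] | None = None
) -> pd.DataFrame:
    """Read and validate an MS2 fragment-intensity table."""
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: empty fragment table")
    return _validate_table(
        df, MS2_COLUMNS, ("time_min", "mz_theoretical", "intensity"), path,
        known_groups, channel_col="group_id",
    )


def write_csv(df: pd.DataFrame, path: str | Path, float_digits: int = 12) -> Path:
    """Write a table as CSV with enough digits for lossless round-trips."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=f"%.{float_digits}g")
    return path


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top-level YAML must be a mapping")
    return cfg


def peptide_from_config(cfg: Mapping, name: str) -> PeptideSpec:
    """Look up a peptide in the config's ``peptides`` section or built-ins."""
    section = cfg.get("peptides", {}) if cfg else {}
    if name in section:
        p = section[name]
        return PeptideSpec(
            name=name,
            sequence=p["sequence"],
            sites=tuple(p["sites"]),
            residue_offset=int(p.get("residue_offset", 1)),
            nterm_acetyl=bool(p.get("nterm_acetyl", False)),
        )
    if name in PEPTIDES:
        return PEPTIDES[name]
    raise KeyError(f"peptide {name!r} not defined in config or built-ins")


def simulation_config_from_dict(cfg: Mapping, peptide: PeptideSpec) -> SimulationConfig:
    sim = dict(cfg.get("simulation", {}))
    overrides = {}
    for item in sim.pop("context_overrides", []):
        overrides[(item["kind"], int(item["site"]), frozenset(item.get("context", [])))] = float(item["rate"])
    kwargs = dict(
        peptide=peptide,
        acetylation_rates=tuple(sim.get("acetylation_rates", SimulationConfig().acetylation_rates)),
        deacetylation_rates=tuple(sim.get("deacetylation_rates", SimulationConfig().deacetylation_rates)),
        context_overrides=overrides,
    )
    for key in (
        "label_fraction_max", "label_ramp_tau_h", "n_replicates", "noise_cv",
        "noise_floor", "seed", "natural_abundance", "charge", "coalescence_tol",
        "base_intensity", "ms2_base_intensity",
    ):
        if key in sim:
            kwargs[key] = sim[key]
    if "time_grid_min" in sim:
        kwargs["time_grid_min"] = tuple(float(t) for t in sim["time_grid_min"])
    return SimulationConfig(**kwargs)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance of one pipeline run: versions, hashes, seeds, timestamps."""

    tool_version: str
    config_hash: str
    input_hashes: dict = field(default_factory=dict)
    seeds: dict = field(default_factory=dict)
    timestamp: str = ""

    @classmethod
    def create(
        cls,
        config: Mapping | None,
        inputs: Mapping[str, str | Path],
        seeds: Mapping[str, int] | None = None,
    ) -> "RunManifest":
        from . import __version__

        cfg_bytes = json.dumps(config or {}, sort_keys=True, default=str).encode()
        return cls(
            tool_version=__version__,
            config_hash=hashlib.sha256(cfg_bytes).hexdigest(),
            input_hashes={k: _sha256(Path(v)) for k, v in inputs.items()},
            seeds=dict(seeds or {}),
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        )

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path
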