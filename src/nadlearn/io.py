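"""Readers, writers, regressor export, configuration and run manifests.

Trial-level RT tables are tidy CSV/TSV (or XLSX workbooks, mapped through a
:class:`ColumnMap` so arbitrary source layouts can be ingested without code
changes).  Trial-wise prediction regressors are written as BIDS-style
``events.tsv`` files (onset/duration in seconds, modulators z-scored within
block) ready for fMRI GLM tooling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .fitting import included_mask
from .group_stats import REQUIRED_COLUMNS, validate_records
from .models import ModelTrace
from .paradigm import BlockDesign, TimingConfig, design_from_frame


@dataclass
class ColumnMap:
    """Mapping of canonical RT-record fields to source column names."""

    columns: dict[str, str] = field(default_factory=dict)
    sheet: str | int = 0

    def resolve(self) -> dict[str, str]:
        mapping = {c: c for c in REQUIRED_COLUMNS + ("responded", "order")}
        mapping.update(self.columns)
        return mapping

    @classmethod
    def from_yaml(cls, path) -> "ColumnMap":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(columns=data.get("columns", {}), sheet=data.get("sheet", 0))


def _read_any(path: Path, sheet) -> pd.DataFrame:
    suffix = path.suffix.lower()
    if suffix in (".csv",):
        return pd.read_csv(path)
    if suffix in (".tsv", ".txt"):
        return pd.read_csv(path, sep="\t")
    if suffix in (".xlsx", ".xls"):
        return pd.read_excel(path, sheet_name=sheet)
    raise ValueError(f"unsupported table format: {path.suffix}")


def read_rt_table(path, colmap: ColumnMap | None = None) -> pd.DataFrame:
    """Read and validate a trial-level RT table; compute inclusion flags.

    Row-level problems (non-numeric RTs, unknown labels) are reported with
    1-based data row numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = colmap or ColumnMap()
    raw = _read_any(path, colmap.sheet)
    mapping = colmap.resolve()
    missing = [src for canon, src in mapping.items()
               if canon in REQUIRED_COLUMNS and src not in raw.columns]
    if missing:
        raise ValueError(f"missing required column(s) in {path.name}: {missing}")
    rename = {src: canon for canon, src in mapping.items() if src in raw.columns}
    records = raw.rename(columns=rename)
    errors = []
    rt = pd.to_numeric(records["rt"], errors="coerce")
    bad_rt = records.index[records["rt"].notna() & rt.isna()]
    errors += [f"row {i + 1}: non-numeric RT {records.at[i, 'rt']!r}" for i in bad_rt]
    records["rt"] = rt
    for col, allowed in (("condition", {"NADs", "Random"}), ("tnt", {"Target", "NoTarget"})):
        bad = records.index[~records[col].isin(allowed)]
        errors += [f"row {i + 1}: unknown {col} label {records.at[i, col]!r}" for i in bad]
    if errors:
        raise ValueError(f"{path.name}: " + "; ".join(errors[:20]))
    if "responded" not in records.columns:
        records["responded"] = records["rt"].notna()
    records["correct"] = records["correct"].astype(bool)
    records["responded"] = records["responded"].astype(bool)
    records["trial_index"] = records["trial_index"].astype(int)
    records["included"] = included_mask(records)
    keep = [c for c in REQUIRED_COLUMNS + ("responded", "order", "included")
            if c in records.columns]
    return validate_records(records[keep])


def write_rt_table(records: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    records.to_csv(path, sep=sep, index=False)


def write_design(design: BlockDesign, path) -> None:
    design.to_frame().to_csv(path, index=False)


def read_design(path, seed: int = -1) -> BlockDesign:
    return design_from_frame(pd.read_csv(path), seed=seed)


# ---------------------------------------------------------------------------
# regressor export
# ---------------------------------------------------------------------------


def _zscore_strict(v: np.ndarray, what: str) -> np.ndarray:
    sd = np.nanstd(v, ddof=1)
    if not np.isfinite(sd) or sd == 0.0:
        raise ValueError(f"cannot z-score {what}: zero variance")
    return (v - np.nanmean(v)) / sd


def export_regressors(design: BlockDesign, trace: ModelTrace, rts, path) -> pd.DataFrame:
    """Write a BIDS-style events.tsv with trial-wise parametric modulators.

    Columns: onset and duration in seconds (phrase onset grid), ``z_p_first``
    (the learner's prediction strength, z-scored within block) and
    ``z_inv_rt`` (the RT z-scored within block and sign-flipped so larger
    values mean faster responses).  Missing RTs (timeouts) are set to the
    block mean (0 after z-scoring).
    """
    rts = np.asarray(rts, dtype=float)
    p = trace.p_first
    if not (design.n_trials == p.size == rts.size):
        raise ValueError("design, trace and RT vector lengths must match")
    z_p = _zscore_strict(p, "p_first")
    z_rt = -_zscore_strict(rts, "rt")
    z_rt = np.where(np.isnan(z_rt), 0.0, z_rt)
    events = pd.DataFrame(
        {
            "onset": design.onsets_s(),
            "duration": np.full(design.n_trials, design.timing.phrase_duration_ms / 1000.0),
            "z_p_first": z_p,
            "z_inv_rt": z_rt,
        }
    )
    events.to_csv(path, sep="\t", index=False)
    return events


# ---------------------------------------------------------------------------
# config and manifest
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    """Load a YAML config; returns {} for a missing/None path."""
    if path is None:
        return {}
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValueError("config must be a YAML mapping")
    return data


def timing_from_config(cfg: dict) -> TimingConfig:
    t = cfg.get("timing", {})
    return TimingConfig(
        phrase_duration_ms=t.get("phrase_duration_ms", 1460.0),
        iti_mode=t.get("iti_mode", "fixed"),
        iti_ms=t.get("iti_ms", 1000.0),
        iti_jitter_ms=tuple(t.get("iti_jitter_ms", (1500.0, 3000.0))),
    )


def write_manifest(path, command: str, seed: int | None, config: dict, outputs: list[str]) -> None:
    manifest = {
        "package": "nadlearn",
        "version": __version__,
        "command": command,
        "seed": seed,
        "config": config,
        "outputs": sorted(outputs),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
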