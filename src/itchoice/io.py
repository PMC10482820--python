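"""CSV schemas and run manifests.

The single interchange format is a UTF-8 CSV with header
``participant_id,x_ss,t_ss,x_ll,t_ll,choice,time_unit,subset`` (one row per
participant x item; ``choice`` is 1 when the larger-later option was
chosen; ``subset`` may be empty and the column may be absent entirely).
Truth sidecars are long-format CSVs keyed by participant and parameter.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .population import ChoiceDataset

REQUIRED_COLUMNS = ("participant_id", "x_ss", "t_ss", "x_ll", "t_ll",
                    "choice", "time_unit")


def read_dataset(path) -> ChoiceDataset:
    """Read and validate a choice dataset CSV (schema errors name the row)."""
    df = pd.read_csv(path, dtype={"participant_id": str, "subset": str,
                                  "time_unit": str})
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    if "subset" not in df.columns:
        df["subset"] = ""
    df["subset"] = df["subset"].fillna("")
    try:
        return ChoiceDataset(df)
    except ValueError as err:
        raise ValueError(f"{path}: {err}") from err


def write_dataset(dataset: ChoiceDataset, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    dataset.df.to_csv(path, index=False)


def write_truth_sidecar(truth, path) -> None:
    """Long-format ground-truth parameters next to a simulated dataset."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    truth.to_frame().to_csv(path, index=False)


def read_truth_sidecar(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"participant_id": str, "parameter": str})


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path, config: dict, seed: int, outputs: list[str]) -> None:
    """Reproducibility manifest: config hash, seed, package version, outputs."""
    from . import __version__

    manifest = {
        "config": config,
        "config_hash": config_hash(config),
        "seed": seed,
        "itchoice_version": __version__,
        "outputs": outputs,
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))
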