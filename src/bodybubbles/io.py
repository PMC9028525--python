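"""Readers and writers for the package's on-disk formats.

Images and masks are 8-bit grayscale PNG (masks 0/255 with a JSON sidecar
naming the parts); trial logs and pattern tables are plain CSV; session
configuration is YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .bubbles import TrialRecord
from .synthetic import SyntheticBody

__all__ = [
    "save_body",
    "save_body_set",
    "trial_log_frame",
    "save_trial_log",
    "save_patterns",
    "load_patterns",
    "load_config",
    "save_config",
]


def save_body(body: SyntheticBody, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out_dir / f"{body.body_id}.png", body.image.astype(np.uint8))
    parts = {}
    for name, mask in body.part_masks.items():
        fname = f"{body.body_id}_mask_{name}.png"
        iio.imwrite(out_dir / fname, (mask.astype(np.uint8)) * 255)
        parts[name] = fname
    diag_name = f"{body.body_id}_mask_diagnostic.png"
    iio.imwrite(out_dir / diag_name, body.diagnostic_mask.astype(np.uint8) * 255)
    sidecar = {
        "body_id": body.body_id,
        "actor": body.actor,
        "emotion": body.emotion,
        "part_masks": parts,
        "diagnostic_mask": diag_name,
    }
    (out_dir / f"{body.body_id}.json").write_text(json.dumps(sidecar, indent=2))


def save_body_set(bodies, out_dir: Path) -> None:
    for b in bodies:
        save_body(b, out_dir)


def trial_log_frame(trials: list[TrialRecord]) -> pd.DataFrame:
    n_bands = len(trials[0].mask.centers) if trials else 0
    rows = []
    for t in trials:
        row = {
            "trial": t.trial,
            "body_id": t.body_id,
            "expression": t.expression,
            "response": t.response,
            "correct": int(t.correct),
            "n_bubbles": t.n_bubbles,
        }
        for k in range(n_bands):
            row[f"n_bubbles_band{k + 1}"] = int(len(t.mask.centers[k]))
        rows.append(row)
    return pd.DataFrame(rows)


def save_trial_log(trials: list[TrialRecord], path: Path) -> None:
    trial_log_frame(trials).to_csv(path, index=False)


def save_patterns(table: pd.DataFrame, path: Path) -> None:
    table.to_csv(path, index=False)


def load_patterns(path: Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path: Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=False)
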