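"""Feature-table readers, view splitting, config handling and checkpoints.

CSV/TSV is the interchange format for features and reports; datasets and
model weights are stored as compressed array bundles next to a JSON echo of
the configuration that produced them, so every artifact is reproducible
from its sidecar plus the seed.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .gaze import ESEE_FEATURES, SEED_FEATURES, FeatureTable
from .model import ICTDModel, ModelConfig
from .synthetic import DualModalityDataset
from .training import TrainConfig, TrainedICTD

__all__ = [
    "read_feature_table", "split_views", "default_view_map",
    "save_checkpoint", "load_checkpoint", "load_run_config",
]

_DIALECT_CATALOG = {"seed": SEED_FEATURES, "eseed": ESEE_FEATURES}


def read_feature_table(path: str | Path, dialect: str = "free"
                       ) -> FeatureTable:
    """Read a trial-by-feature CSV/TSV with `label` and `subject` columns.

    `dialect="seed"` / `"eseed"` compares the feature names against the
    respective catalog and warns with the exact delta on mismatch;
    `"free"` accepts any numeric columns.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    for col in ("label", "subject"):
        if col not in df.columns:
            raise ValueError(f"missing column: {col}")
    feature_cols = [c for c in df.columns if c not in ("label", "subject")]
    for c in feature_cols:
        numeric = pd.to_numeric(df[c], errors="coerce")
        bad = numeric.isna() & df[c].notna()
        if bad.any():
            raise ValueError(
                f"non-numeric value in feature {c!r} at row {int(bad.idxmax())}")
        df[c] = numeric
    if dialect != "free":
        if dialect not in _DIALECT_CATALOG:
            raise ValueError(f"unknown dialect: {dialect!r}")
        catalog = set(_DIALECT_CATALOG[dialect])
        have = set(feature_cols)
        if have != catalog:
            missing = sorted(catalog - have)
            extra = sorted(have - catalog)
            warnings.warn(
                f"{dialect} dialect mismatch - missing: {missing}, "
                f"unexpected: {extra}", stacklevel=2)
    return FeatureTable(df[feature_cols], df["label"].to_numpy(np.int64),
                        df["subject"].to_numpy(np.int64))


def default_view_map(feature_names: list[str]) -> dict[str, str]:
    """Pupil-diameter features form the pupil view; the rest are gaze."""
    return {name: ("pupil" if name.startswith("pupil") else "gaze")
            for name in feature_names}


def split_views(table: FeatureTable,
                view_map: dict[str, str] | None = None) -> DualModalityDataset:
    """Partition feature columns into the gaze and pupil views."""
    if view_map is None:
        view_map = default_view_map(table.feature_names)
    unassigned = [f for f in table.feature_names if f not in view_map]
    if unassigned:
        raise ValueError(f"feature not assigned to a view: {unassigned[0]}")
    bad = {v for v in view_map.values()} - {"gaze", "pupil"}
    if bad:
        raise ValueError(f"unknown view name: {sorted(bad)[0]}")
    gaze_cols = [f for f in table.feature_names if view_map[f] == "gaze"]
    pupil_cols = [f for f in table.feature_names if view_map[f] == "pupil"]
    if not gaze_cols or not pupil_cols:
        raise ValueError("both views must receive at least one feature")
    return DualModalityDataset(
        table.data[gaze_cols].to_numpy(float),
        table.data[pupil_cols].to_numpy(float),
        table.labels.copy(), table.subject_ids.copy())


# ----------------------------------------------------------------------
def save_checkpoint(trained: TrainedICTD, path: str | Path,
                    extra: dict | None = None) -> None:
    """Weights + scaler as an array bundle, configs as a JSON echo."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = trained.model.state_arrays()
    m1, s1, m2, s2 = trained.scaler
    arrays.update({"scaler_m1": m1, "scaler_s1": s1,
                   "scaler_m2": m2, "scaler_s2": s2})
    np.savez_compressed(path / "weights.npz", **arrays)
    meta = {
        "model_cfg": trained.model.cfg.to_dict(),
        "train_cfg": trained.train_cfg.to_dict(),
        "view_dims": list(trained.model.view_dims),
        "n_classes": trained.model.n_classes,
        "log": trained.log,
    }
    if extra:
        meta.update(extra)
    (path / "config.json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path: str | Path) -> TrainedICTD:
    path = Path(path)
    meta = json.loads((path / "config.json").read_text())
    model = ICTDModel(tuple(meta["view_dims"]), meta["n_classes"],
                      cfg=ModelConfig.from_dict(meta["model_cfg"]))
    with np.load(path / "weights.npz") as z:
        arrays = {k: z[k] for k in z.files}
    scaler = (arrays.pop("scaler_m1"), arrays.pop("scaler_s1"),
              arrays.pop("scaler_m2"), arrays.pop("scaler_s2"))
    model.load_state_arrays(arrays)
    model.eval()
    trained = TrainedICTD(model, scaler,
                          TrainConfig.from_dict(meta["train_cfg"]),
                          log=meta.get("log", []))
    return trained


# ----------------------------------------------------------------------
_KNOWN_BLOCKS = {"model", "train", "seed", "out_dir", "log_level"}


def load_run_config(path: str | Path) -> dict:
    """YAML run config with `model` / `train` blocks; unknown keys rejected."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - _KNOWN_BLOCKS
    if unknown:
        raise ValueError(f"unknown config key: {sorted(unknown)[0]}")
    out: dict = {"seed": raw.get("seed", 0)}
    out["model"] = ModelConfig.from_dict(raw.get("model", {}))
    out["train"] = TrainConfig.from_dict(raw.get("train", {}))
    out["out_dir"] = raw.get("out_dir")
    out["log_level"] = raw.get("log_level", "info")
    return out


def write_config_echo(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=str))
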