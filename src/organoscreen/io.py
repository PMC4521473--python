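"""File formats: multi-page TIFF stacks, plate-map / feature CSVs, JSON.

One TIFF per well per channel, 16-bit, page order = z order; plate maps and
feature tables as CSV; ground truth and selection / clustering results as
JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import GroundTruth, ImageStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_plate_map",
    "read_plate_map",
    "write_ground_truth",
    "write_feature_table",
    "read_feature_table",
    "write_label_stack",
    "write_json",
    "read_json",
]


def write_stack(stack: ImageStack, directory: Path) -> dict[str, Path]:
    """Write one well's two channels as multi-page 16-bit TIFFs."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for channel in ("actin", "nuclei"):
        path = directory / f"{stack.well}_{channel}.tif"
        tifffile.imwrite(path, getattr(stack, channel))
        paths[channel] = path
    return paths


def read_stack(directory: Path, well: str) -> ImageStack:
    directory = Path(directory)
    actin = tifffile.imread(directory / f"{well}_actin.tif")
    nuclei = tifffile.imread(directory / f"{well}_nuclei.tif")
    return ImageStack(well=well, actin=actin, nuclei=nuclei)


def write_label_stack(labels: np.ndarray, path: Path) -> None:
    tifffile.imwrite(Path(path), labels.astype(np.int32))


def write_plate_map(plate_map: pd.DataFrame, path: Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    plate_map.to_csv(path, index=False)


def read_plate_map(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"well": str, "role": str, "treatment": str},
                       keep_default_na=False, na_values=[""])


def write_ground_truth(truth: GroundTruth, path: Path) -> None:
    """Ground truth as JSON (specs, nuclei records, per-section mask areas).

    The full label volume is stored separately as a TIFF when needed; the
    JSON keeps the bookkeeping that tests and audits consume.
    """
    payload = {
        "well": truth.well,
        "class_label": truth.class_label,
        "specs": [dataclasses.asdict(s) for s in truth.specs],
        "nuclei": [dataclasses.asdict(n) for n in truth.nuclei],
        "per_section_areas": {
            str(i): {
                str(oid): int((truth.labels[i] == oid).sum())
                for oid in np.unique(truth.labels[i]) if oid
            }
            for i in range(truth.labels.shape[0])
        },
    }
    write_json(payload, path)


def write_feature_table(table: pd.DataFrame, path: Path, normalized: bool) -> None:
    """Feature CSV with a stable header; missing values as empty fields."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = table.copy()
    out.insert(0, "normalized", int(normalized))
    out.to_csv(path, index=True, index_label="well", na_rep="")


def read_feature_table(path: Path) -> tuple[pd.DataFrame, bool]:
    df = pd.read_csv(path, index_col="well")
    normalized = bool(df.pop("normalized").iloc[0]) if "normalized" in df else False
    return df, normalized


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.Series):
        return obj.to_dict()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def write_json(payload: dict, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1, default=_jsonable))


def read_json(path: Path) -> dict:
    return json.loads(Path(path).read_text())
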