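"""File I/O: masks (PNG/TIFF/text), feature tables (CSV), reports (JSON).

All numeric output is serialised at 6 significant digits so reruns diff
cleanly.  Feature CSV column order is fixed:

    id,area_mm2,solidity,compactness,roundness,eccentricity,
    perimeter_mm,hull_perimeter_mm,feret_max_mm,feret_min_mm
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .geometry import FazMask, ShapeFeatures
from .segmentation import OctaImage
from .synthetic import SubjectRecord

__all__ = [
    "FEATURE_CSV_COLUMNS",
    "read_mask",
    "write_mask",
    "read_octa_image",
    "write_octa_image",
    "features_frame",
    "records_frame",
    "write_records_csv",
    "read_records_csv",
    "write_json",
    "sig6",
]

FEATURE_CSV_COLUMNS = [
    "id",
    "area_mm2",
    "solidity",
    "compactness",
    "roundness",
    "eccentricity",
    "perimeter_mm",
    "hull_perimeter_mm",
    "feret_max_mm",
    "feret_min_mm",
]


def sig6(x: float) -> float:
    """Round to 6 significant digits (stable text serialisation)."""
    return float(f"{x:.6g}")


def _default_pixel_size(shape: tuple[int, int], scan_size_mm: float) -> tuple[float, float]:
    # protocol scans cover a fixed square field, so mm-per-pixel follows
    # from the raster size
    return (scan_size_mm / shape[0], scan_size_mm / shape[1])


def read_mask(
    path: str | Path,
    pixel_size_mm: tuple[float, float] | None = None,
    scan_size_mm: float = 3.0,
) -> FazMask:
    """Load a binary mask from PNG/TIFF (value > 0 = foreground) or a 0/1
    text grid (``.txt``/``.tsv``).  Without an explicit pixel size the scan
    is assumed to cover ``scan_size_mm`` per image side."""
    path = Path(path)
    if path.suffix.lower() in (".txt", ".tsv"):
        grid = np.loadtxt(path, dtype=int)
    else:
        img = np.asarray(iio.imread(path))
        if img.ndim == 3:
            img = img[..., 0]
        grid = (img > 0).astype(np.uint8)
    if pixel_size_mm is None:
        pixel_size_mm = _default_pixel_size(grid.shape, scan_size_mm)
    return FazMask(grid.astype(np.uint8), pixel_size_mm, id=path.stem)


def write_mask(path: str | Path, mask: FazMask) -> None:
    """Write a mask as an 8-bit PNG/TIFF (foreground = 255)."""
    iio.imwrite(Path(path), (mask.grid * 255).astype(np.uint8))


def read_octa_image(
    path: str | Path,
    pixel_size_mm: tuple[float, float] | None = None,
    scan_size_mm: float = 3.0,
) -> OctaImage:
    """Load a grayscale en-face image, rescaled to [0, 1]."""
    path = Path(path)
    img = np.asarray(iio.imread(path)).astype(float)
    if img.ndim == 3:
        img = img[..., 0]
    if img.max() > 1:
        img = img / 255.0
    if pixel_size_mm is None:
        pixel_size_mm = _default_pixel_size(img.shape, scan_size_mm)
    return OctaImage(np.clip(img, 0.0, 1.0), pixel_size_mm, id=path.stem)


def write_octa_image(path: str | Path, image: OctaImage) -> None:
    iio.imwrite(Path(path), np.round(image.pixels * 255).astype(np.uint8))


def features_frame(
    ids: Sequence[str], features: Sequence[ShapeFeatures]
) -> pd.DataFrame:
    """Shape-feature table in the canonical column order."""
    rows = []
    for i, f in zip(ids, features):
        rows.append(
            {
                "id": i,
                "area_mm2": sig6(f.area_mm2),
                "solidity": sig6(f.solidity),
                "compactness": sig6(f.compactness),
                "roundness": sig6(f.roundness),
                "eccentricity": sig6(f.eccentricity),
                "perimeter_mm": sig6(f.perimeter_mm),
                "hull_perimeter_mm": sig6(f.hull_perimeter_mm),
                "feret_max_mm": sig6(f.feret_max_mm),
                "feret_min_mm": sig6(f.feret_min_mm),
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_CSV_COLUMNS)


def records_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Full per-subject table: features joined with covariates and label."""
    df = features_frame([r.id for r in records], [r.features for r in records])
    df.insert(1, "label", [r.label for r in records])
    df.insert(2, "age", [sig6(r.age) for r in records])
    df.insert(3, "sex", [r.sex for r in records])
    return df


def write_records_csv(path: str | Path, records: Sequence[SubjectRecord]) -> None:
    records_frame(records).to_csv(Path(path), index=False)


def read_records_csv(path: str | Path) -> list[SubjectRecord]:
    """Rebuild subject records from a table written by
    :func:`write_records_csv`.  Rows with missing covariates are rejected."""
    df = pd.read_csv(Path(path))
    needed = {"id", "label", "age", "sex"} | set(FEATURE_CSV_COLUMNS) - {"id"}
    missing_cols = needed - set(df.columns)
    if missing_cols:
        raise ValueError(f"missing columns: {sorted(missing_cols)}")
    if df[list(needed)].isna().any().any():
        bad = df[df[list(needed)].isna().any(axis=1)]["id"].tolist()
        raise ValueError(f"records with missing values: {bad}")
    records = []
    for row in df.itertuples(index=False):
        feats = ShapeFeatures(
            area_mm2=row.area_mm2,
            solidity=row.solidity,
            compactness=row.compactness,
            roundness=row.roundness,
            eccentricity=row.eccentricity,
            perimeter_mm=row.perimeter_mm,
            hull_perimeter_mm=row.hull_perimeter_mm,
            feret_max_mm=row.feret_max_mm,
            feret_min_mm=row.feret_min_mm,
        )
        records.append(
            SubjectRecord(
                id=str(row.id),
                features=feats,
                age=float(row.age),
                sex=int(row.sex),
                label=str(row.label),  # type: ignore[arg-type]
            )
        )
    return records


def write_json(path: str | Path, payload: dict) -> None:
    """Deterministic JSON: sorted keys, floats already rounded upstream."""

    def _round(obj):
        if isinstance(obj, float):
            return sig6(obj)
        if isinstance(obj, dict):
            return {k: _round(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_round(v) for v in obj]
        return obj

    Path(path).write_text(
        json.dumps(_round(payload), indent=2, sort_keys=True) + "\n"
    )
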