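"""Shared fixtures: canonical shapes, masks and a small synthetic cohort."""

from __future__ import annotations

import numpy as np
import pytest

from fazrad.geometry import ContourPolygon, FazMask, ShapeFeatures
from fazrad.synthetic import CohortParams, SubjectRecord, generate_cohort


def disk_mask(radius_px: int, pixel_mm: float = 0.01, margin: int = 5) -> FazMask:
    """Digitized disk: pixel centres within ``radius_px`` of the centre."""
    n = 2 * radius_px + 2 * margin
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    grid = ((xx - c) ** 2 + (yy - c) ** 2 <= radius_px**2).astype(np.uint8)
    return FazMask(grid, (pixel_mm, pixel_mm), id=f"disk{radius_px}")


def ellipse_mask(a_px: int, b_px: int, pixel_mm: float = 0.01) -> FazMask:
    n = 2 * max(a_px, b_px) + 10
    yy, xx = np.mgrid[0:n, 0:n]
    c = (n - 1) / 2.0
    grid = (((xx - c) / a_px) ** 2 + ((yy - c) / b_px) ** 2 <= 1.0).astype(np.uint8)
    return FazMask(grid, (pixel_mm, pixel_mm), id="ellipse")


def star_polygon(
    r_outer: float = 1.0, r_inner: float = 0.35, arms: int = 4
) -> ContourPolygon:
    """Non-convex star with ``2 * arms`` vertices (tips at the outer radius)."""
    angles = np.arange(2 * arms) * np.pi / arms
    radii = np.where(np.arange(2 * arms) % 2 == 0, r_outer, r_inner)
    return ContourPolygon(
        np.column_stack([radii * np.cos(angles), radii * np.sin(angles)])
    )


def regular_polygon(n: int, radius: float = 1.0) -> ContourPolygon:
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return ContourPolygon(np.column_stack([radius * np.cos(t), radius * np.sin(t)]))


def make_record(
    id: str,
    label: str,
    area: float = 0.3,
    solidity: float = 0.95,
    compactness: float = 0.85,
    roundness: float = 0.9,
    eccentricity: float = 0.4,
    age: float = 68.0,
    sex: int = 0,
) -> SubjectRecord:
    """Hand-built record with internally consistent carrier fields."""
    perim = float(np.sqrt(4 * np.pi * area / compactness))
    hull_perim = float(np.sqrt(4 * np.pi * area / roundness))
    fmax = 2.2 * float(np.sqrt(area / np.pi))
    fmin = fmax * float(np.sqrt(1 - eccentricity**2))
    feats = ShapeFeatures(
        area_mm2=area,
        solidity=solidity,
        compactness=compactness,
        roundness=roundness,
        eccentricity=eccentricity,
        perimeter_mm=perim,
        hull_perimeter_mm=hull_perim,
        feret_max_mm=fmax,
        feret_min_mm=fmin,
    )
    return SubjectRecord(id=id, features=feats, age=age, sex=sex, label=label)  # type: ignore[arg-type]


@pytest.fixture(scope="session")
def default_cohort():
    """One default 85-scan training cohort (31 AD / 54 NC)."""
    records, masks = generate_cohort(CohortParams.training_default(seed=42))
    return records, masks


@pytest.fixture(scope="session")
def default_records(default_cohort):
    return default_cohort[0]
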