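"""Per-cell organelle features: counts, intensities, occupied area.

These are the simple readouts of a fixed-cell screen — how many marker
structures a cell contains, how much marker signal they carry, and how
much area they occupy — reported per cell and aggregated per treatment
relative to the negative control.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import CellRecord, FragmentSet, ImageCalibration, ValidationError, as_float_image

logger = logging.getLogger(__name__)

FEATURE_COLUMNS = [
    "image",
    "cell_id",
    "treatment",
    "n_structures",
    "total_intensity",
    "mean_intensity",
    "occupied_area_px",
    "occupied_area_um2",
]


def count_structures(fragments: FragmentSet, min_area_px: float = 0.0) -> int:
    """Number of structures, optionally re-filtered by minimum area."""
    if min_area_px <= 0:
        return len(fragments)
    return int((fragments.areas >= min_area_px).sum())


def intensity_per_cell(
    cell: CellRecord, structures_mask: np.ndarray, channel: np.ndarray
) -> tuple[float, float]:
    """(total, mean) marker intensity over structure pixels inside the cell.

    No background subtraction is applied by default — the total is the
    raw integrated signal. Zero structure pixels gives (0, 0) with a
    log note rather than a NaN.
    """
    img = as_float_image(channel)
    mask = np.asarray(structures_mask, dtype=bool) & cell.cell_mask
    n = int(mask.sum())
    if n == 0:
        logger.info("cell %s: no structure pixels; intensity reported as 0", cell.cell_id)
        return 0.0, 0.0
    total = float(img[mask].sum())
    return total, total / n


def occupied_area(fragments: FragmentSet, calibration: ImageCalibration) -> float:
    """Summed fragment area in µm²."""
    return float(fragments.areas.sum()) * calibration.pixel_size ** 2


def cell_feature_table(
    cells: list[CellRecord],
    fragment_sets: list[FragmentSet],
    calibration: ImageCalibration,
    image: str = "",
) -> pd.DataFrame:
    """Tidy per-cell feature table (one row per cell)."""
    by_id = {fs.cell_id: fs for fs in fragment_sets}
    rows = []
    for cell in cells:
        fs = by_id.get(cell.cell_id, FragmentSet(cell_id=cell.cell_id))
        total = float(fs.intensities.sum())
        area_px = float(fs.areas.sum())
        rows.append(
            {
                "image": image,
                "cell_id": cell.cell_id,
                "treatment": cell.treatment,
                "n_structures": len(fs),
                "total_intensity": total,
                "mean_intensity": total / area_px if area_px > 0 else 0.0,
                "occupied_area_px": area_px,
                "occupied_area_um2": area_px * calibration.pixel_size ** 2,
            }
        )
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def normalize_features(
    treatment_means: pd.DataFrame, control: str = "NEG"
) -> pd.DataFrame:
    """Divide each treatment's feature means by the control's.

    ``treatment_means`` is indexed by treatment with one numeric column
    per feature. Raises when the control row is absent, when any
    requested treatment is missing, or when a control feature mean is 0
    (the ratio would be undefined).
    """
    if control not in treatment_means.index:
        raise ValidationError(f"control treatment {control!r} missing")
    ctrl = treatment_means.loc[control]
    zero = ctrl[ctrl == 0]
    if len(zero) > 0:
        raise ValidationError(
            f"control mean is zero for feature(s): {', '.join(map(str, zero.index))}"
        )
    return treatment_means.div(ctrl, axis=1)


def summarize_features(
    per_cell: pd.DataFrame,
    features: list[str] | None = None,
    control: str = "NEG",
    treatments: list[str] | None = None,
) -> pd.DataFrame:
    """Per-treatment feature means normalised to the negative control."""
    feats = features or ["n_structures", "total_intensity", "mean_intensity", "occupied_area_um2"]
    present = set(per_cell["treatment"])
    wanted = treatments if treatments is not None else sorted(present)
    missing = [t for t in wanted if t not in present]
    if missing:
        raise ValidationError(f"missing treatment rows: {', '.join(missing)}")
    means = per_cell[per_cell["treatment"].isin(wanted)].groupby("treatment")[feats].mean()
    return normalize_features(means, control=control)


def line_profile(channel: np.ndarray, start: tuple[float, float], end: tuple[float, float],
                 n_points: int = 200) -> pd.DataFrame:
    """Intensity along a straight line between two (x, y) points.

    Plotting convenience only (bilinear sampling via map_coordinates).
    """
    from scipy import ndimage

    img = as_float_image(channel)
    x = np.linspace(start[0], end[0], n_points)
    y = np.linspace(start[1], end[1], n_points)
    vals = ndimage.map_coordinates(img, np.vstack([y, x]), order=1)
    dist = np.hypot(x - x[0], y - y[0])
    return pd.DataFrame({"distance_px": dist, "intensity": vals})
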