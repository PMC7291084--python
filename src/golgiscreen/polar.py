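"""The Golgi polar distribution score (PDS).

The score quantifies how anisotropically the fragments of an organelle
are arranged around a cell's centre. Fragment centroids are converted
to polar angles about the cell centroid, rotated so that their circular
mean is zero, and binned into eight equal angular sectors. The score is

    PDS = Σ_k | f_k − 1/8 |

where f_k is the fraction of fragments in sector k. It is 0 when the
eight sector frequencies are exactly equal (a uniform ring) and reaches
its maximum of 2·(1 − 1/8) = 1.75 when every fragment falls in a single
sector (a tight juxtanuclear cluster). Per-treatment means are reported
normalised to the negative (non-silencing) control: values below 1 read
as "dispersed", above 1 as "compacted".

Binning convention: after zero-mean rotation the sectors are centred on
the mean direction — the first bin spans [−π/8, π/8) — so a perfectly
concentrated cluster occupies exactly one bin and attains the nominal
maximum. Bins are half-open; an angle exactly on an edge belongs to the
bin above it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import CellRecord, FragmentSet, ValidationError

logger = logging.getLogger(__name__)

#: resultant lengths below this are treated as a degenerate circular mean
DEGENERATE_RESULTANT = 1e-9

TWO_PI = 2.0 * math.pi


def fragment_angles(
    fragments: FragmentSet, center: tuple[float, float]
) -> np.ndarray:
    """Polar angles (radians, in (−π, π]) of fragment centroids about ``center``.

    The radius is discarded — the score depends only on angular
    position. A fragment exactly at the centre has no defined angle and
    is dropped with a warning.
    """
    pts = fragments.centroids
    if pts.shape[0] == 0:
        raise ValidationError("fragment_angles requires at least one fragment")
    dx = pts[:, 0] - center[0]
    dy = pts[:, 1] - center[1]
    at_center = (dx == 0) & (dy == 0)
    if at_center.any():
        logger.warning(
            "cell %s: dropping %d fragment(s) exactly at the polar centre",
            fragments.cell_id,
            int(at_center.sum()),
        )
        dx, dy = dx[~at_center], dy[~at_center]
    return np.arctan2(dy, dx)


def circular_mean(angles: np.ndarray) -> tuple[float, float]:
    """Resultant-vector circular mean and resultant length R ∈ [0, 1].

    Returns ``(mean, R)``. When R is ~0 (e.g. two antipodal angles) the
    mean direction is undefined; by convention 0.0 is returned and the
    caller should treat the result as degenerate (check R).
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValidationError("circular_mean requires at least one angle")
    s, c = np.sin(angles).mean(), np.cos(angles).mean()
    r = math.hypot(s, c)
    if r < DEGENERATE_RESULTANT:
        return 0.0, r
    return math.atan2(s, c), r


def wrap_angle(angles: np.ndarray) -> np.ndarray:
    """Wrap into [−π, π)."""
    return np.mod(np.asarray(angles, dtype=float) + math.pi, TWO_PI) - math.pi


def normalize_angles(angles: np.ndarray, mean_angle: float) -> np.ndarray:
    """Rotate angles so the given circular mean maps to zero, wrapped."""
    return wrap_angle(np.asarray(angles, dtype=float) - mean_angle)


@dataclass
class PolarHistogram:
    """Frequencies of fragments over equal angular sectors."""

    n_bins: int
    frequencies: np.ndarray
    counts: np.ndarray
    bin_centers: np.ndarray  # sector centres, first at 0

    @property
    def bin_width(self) -> float:
        return TWO_PI / self.n_bins


def polar_histogram(normalized_angles: np.ndarray, n_bins: int = 8) -> PolarHistogram:
    """Bin zero-mean angles into ``n_bins`` equal sectors centred on 0.

    Sector k is the half-open arc [c_k − π/n, c_k + π/n) around centre
    c_k = k·2π/n (taken mod 2π); an angle exactly on an interior edge is
    assigned to the upper sector.
    """
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    angles = np.asarray(normalized_angles, dtype=float)
    if angles.size == 0:
        raise ValidationError("polar_histogram requires at least one angle")
    width = TWO_PI / n_bins
    idx = np.floor(np.mod(angles + width / 2.0, TWO_PI) / width).astype(int)
    counts = np.bincount(idx, minlength=n_bins).astype(float)
    centers = wrap_angle(np.arange(n_bins) * width)
    return PolarHistogram(
        n_bins=n_bins,
        frequencies=counts / counts.sum(),
        counts=counts,
        bin_centers=centers,
    )


def polar_distribution_score(hist: PolarHistogram) -> float:
    """Sum of absolute deviations of sector frequencies from 1/n_bins.

    Bounded by [0, 2·(1 − 1/n_bins)]; 1.75 for the default 8 sectors.
    """
    if hist.counts.sum() == 0:
        raise ValidationError("polar_distribution_score undefined for 0 fragments")
    return float(np.abs(hist.frequencies - 1.0 / hist.n_bins).sum())


@dataclass
class PolarScoreResult:
    cell_id: int
    n_fragments: int
    mean_angle: float
    resultant_length: float
    degenerate: bool
    pds: float
    histogram: PolarHistogram = field(repr=False, default=None)
    treatment: str = ""


def pds_for_cell(
    cell: CellRecord,
    fragments: FragmentSet,
    n_bins: int = 8,
    center: str = "cell",
) -> PolarScoreResult:
    """Full per-cell score: angles → zero-mean rotation → histogram → PDS.

    ``center`` selects the polar origin: the cell-mask centroid
    (default) or the nucleus centroid (``"nucleus"``). Cells whose
    circular mean is degenerate (resultant ≈ 0, e.g. perfectly
    symmetric fragment rings) are scored with the mean pinned at 0 and
    flagged.
    """
    if len(fragments) == 0:
        raise ValidationError(f"cell {cell.cell_id}: no fragments to score")
    if center == "cell":
        origin = cell.cell_centroid
    elif center == "nucleus":
        origin = cell.nucleus_centroid
    else:
        raise ValidationError(f"unknown polar centre {center!r}")
    angles = fragment_angles(fragments, origin)
    mean, resultant = circular_mean(angles)
    degenerate = resultant < DEGENERATE_RESULTANT
    hist = polar_histogram(normalize_angles(angles, mean), n_bins=n_bins)
    return PolarScoreResult(
        cell_id=cell.cell_id,
        n_fragments=int(angles.size),
        mean_angle=mean,
        resultant_length=resultant,
        degenerate=degenerate,
        pds=polar_distribution_score(hist),
        histogram=hist,
        treatment=cell.treatment,
    )


def score_cells(
    pairs: list[tuple[CellRecord, FragmentSet]],
    n_bins: int = 8,
    center: str = "cell",
) -> pd.DataFrame:
    """Score many cells; cells with zero fragments are skipped with a log line.

    Returns a tidy frame with columns ``cell_id, treatment,
    n_fragments, mean_angle_rad, degenerate_flag, pds``.
    """
    rows = []
    for cell, frags in pairs:
        if len(frags) == 0:
            logger.info("cell %s excluded from PDS: zero fragments", cell.cell_id)
            continue
        res = pds_for_cell(cell, frags, n_bins=n_bins, center=center)
        rows.append(
            {
                "cell_id": res.cell_id,
                "treatment": res.treatment,
                "n_fragments": res.n_fragments,
                "mean_angle_rad": res.mean_angle,
                "degenerate_flag": res.degenerate,
                "pds": res.pds,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cell_id", "treatment", "n_fragments", "mean_angle_rad",
                 "degenerate_flag", "pds"],
    )


def normalize_pds(
    treatment_means: "pd.Series | dict[str, float]", control_mean: float
) -> pd.Series:
    """Per-treatment mean PDS divided by the negative-control mean."""
    if not control_mean > 0:
        raise ValidationError("control mean PDS must be > 0 to normalize")
    means = pd.Series(treatment_means, dtype=float)
    return means / control_mean


def treatment_summary(per_cell: pd.DataFrame, control: str = "NEG") -> pd.DataFrame:
    """Aggregate per-cell scores to per-treatment means normalised to control."""
    if control not in set(per_cell["treatment"]):
        raise ValidationError(f"control treatment {control!r} missing from table")
    grouped = per_cell.groupby("treatment")["pds"]
    means = grouped.mean()
    out = pd.DataFrame(
        {
            "treatment": means.index,
            "mean_pds": means.values,
            "normalized_pds": normalize_pds(means, means[control]).values,
            "n_cells": grouped.size().values,
        }
    ).reset_index(drop=True)
    return out
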