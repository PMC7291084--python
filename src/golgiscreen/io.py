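"""Scene and table I/O.

Images travel as multi-page grayscale TIFF — one page per channel for
fixed-cell scenes, one page per frame per channel (channel-major) for
time-lapses. Ground truth rides in a sidecar CSV (``object_id,
cell_id, frame, x_px, y_px, area_px, type``), truth label maps as
16-bit TIFF, and the generation config as a flat key: value YAML that
doubles as the run log.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synthetic import SceneBundle, TruthTrack
from .types import CellRecord, Fragment, FragmentSet, ImageCalibration, ValidationError

TRUTH_COLUMNS = ["object_id", "cell_id", "frame", "x_px", "y_px", "area_px", "type"]


def _truth_table(scene: SceneBundle) -> pd.DataFrame:
    rows = []
    oid = 0
    for cell in scene.truth_cells:
        oid += 1
        rows.append(
            {
                "object_id": oid,
                "cell_id": cell.cell_id,
                "frame": -1,
                "x_px": cell.cell_centroid[0],
                "y_px": cell.cell_centroid[1],
                "area_px": float(cell.cell_mask.sum()),
                "type": "cell",
            }
        )
        oid += 1
        rows.append(
            {
                "object_id": oid,
                "cell_id": cell.cell_id,
                "frame": -1,
                "x_px": cell.nucleus_centroid[0],
                "y_px": cell.nucleus_centroid[1],
                "area_px": 0.0,
                "type": "nucleus",
            }
        )
    for kind, sets in (("fragment", scene.truth_fragments), ("punctum", scene.truth_puncta)):
        for fs in sets:
            for frag in fs.fragments:
                oid += 1
                rows.append(
                    {
                        "object_id": oid,
                        "cell_id": fs.cell_id,
                        "frame": -1,
                        "x_px": frag.centroid[0],
                        "y_px": frag.centroid[1],
                        "area_px": frag.area,
                        "type": kind,
                    }
                )
    px = scene.calibration.pixel_size
    for track in scene.truth_tracks:
        for f, (x_um, y_um) in zip(track.frames, track.positions_um):
            oid += 1
            rows.append(
                {
                    "object_id": oid,
                    "cell_id": track.carrier_id,
                    "frame": int(f),
                    "x_px": x_um / px,
                    "y_px": y_um / px,
                    "area_px": track.length_um,  # carrier rows reuse this slot for length (µm)
                    "type": "carrier",
                }
            )
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def write_scene(scene: SceneBundle, prefix: str | Path, overwrite: bool = False) -> dict[str, Path]:
    """Write ``<prefix>.tif``, ``<prefix>_truth.csv``, ``<prefix>_meta.yaml``
    (+ ``<prefix>_cells.tif`` / ``_nuclei_centroids``-bearing truth rows).

    Returns the written paths. Refuses to clobber unless ``overwrite``.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": prefix.with_suffix(".tif"),
        "truth": prefix.parent / f"{prefix.name}_truth.csv",
        "meta": prefix.parent / f"{prefix.name}_meta.yaml",
    }
    if scene.truth_cells:
        paths["cell_labels"] = prefix.parent / f"{prefix.name}_cells.tif"
    for p in paths.values():
        if p.exists() and not overwrite:
            raise ValidationError(f"refusing to overwrite existing {p}")

    names = list(scene.channels)
    pages = []
    for name in names:  # channel-major page order
        arr = scene.channels[name]
        pages.extend(arr[None] if arr.ndim == 2 else arr)
    tifffile.imwrite(
        paths["image"], np.asarray(pages, dtype=np.float32), photometric="minisblack"
    )

    _truth_table(scene).to_csv(paths["truth"], index=False)

    if scene.truth_cells:
        labels = np.zeros(scene.shape, dtype=np.uint16)
        for cell in scene.truth_cells:
            labels[cell.cell_mask] = cell.cell_id
        tifffile.imwrite(paths["cell_labels"], labels)

    first = scene.channels[names[0]]
    meta = dict(scene.config)
    meta.update(
        {
            "channels": ",".join(names),
            "n_frames": int(first.shape[0]) if first.ndim == 3 else 1,
            "height": int(first.shape[-2]),
            "width": int(first.shape[-1]),
            "pixel_size": scene.calibration.pixel_size,
            "frame_interval": scene.calibration.frame_interval,
        }
    )
    with open(paths["meta"], "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return paths


def read_scene(prefix: str | Path) -> SceneBundle:
    """Reload a scene written by :func:`write_scene` (images + truth)."""
    prefix = Path(prefix)
    meta_path = prefix.parent / f"{prefix.name}_meta.yaml"
    if not meta_path.exists():
        raise ValidationError(f"no scene metadata at {meta_path}")
    with open(meta_path) as fh:
        meta = yaml.safe_load(fh)
    names = meta["channels"].split(",")
    n_frames = int(meta["n_frames"])
    pages = tifffile.imread(prefix.with_suffix(".tif"))
    if pages.ndim == 2:
        pages = pages[None]
    channels = {}
    for i, name in enumerate(names):
        block = pages[i * n_frames : (i + 1) * n_frames].astype(float)
        channels[name] = block[0] if n_frames == 1 else block
    calibration = ImageCalibration(
        pixel_size=float(meta["pixel_size"]), frame_interval=float(meta["frame_interval"])
    )
    scene = SceneBundle(channels=channels, calibration=calibration, config=dict(meta))

    truth = pd.read_csv(prefix.parent / f"{prefix.name}_truth.csv")
    labels_path = prefix.parent / f"{prefix.name}_cells.tif"
    labels = tifffile.imread(labels_path) if labels_path.exists() else None
    nuclei = {
        int(r.cell_id): (r.x_px, r.y_px) for r in truth[truth["type"] == "nucleus"].itertuples()
    }
    for r in truth[truth["type"] == "cell"].itertuples():
        cid = int(r.cell_id)
        mask = (labels == cid) if labels is not None else np.zeros(scene.shape, dtype=bool)
        scene.truth_cells.append(
            CellRecord(
                cell_id=cid,
                cell_mask=mask,
                cell_centroid=(r.x_px, r.y_px),
                nucleus_centroid=nuclei.get(cid, (r.x_px, r.y_px)),
                treatment=str(meta.get("treatment", "") or ""),
            )
        )
    for kind, store in (("fragment", scene.truth_fragments), ("punctum", scene.truth_puncta)):
        sub = truth[truth["type"] == kind]
        for cid, grp in sub.groupby("cell_id"):
            fs = FragmentSet(cell_id=int(cid))
            for r in grp.itertuples():
                fs.fragments.append(Fragment((r.x_px, r.y_px), r.area_px))
            store.append(fs)
    px = calibration.pixel_size
    carriers = truth[truth["type"] == "carrier"]
    for cid, grp in carriers.groupby("cell_id"):
        grp = grp.sort_values("frame")
        scene.truth_tracks.append(
            TruthTrack(
                carrier_id=int(cid),
                frames=grp["frame"].to_numpy(dtype=int),
                positions_um=np.column_stack([grp["x_px"] * px, grp["y_px"] * px]),
                length_um=float(grp["area_px"].iloc[0]),
                speed_um_s=float("nan"),
                truncated=bool(len(grp) < n_frames),
            )
        )
    return scene


def read_config(path: str | Path) -> dict:
    """Flat key: value run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValidationError(f"config {path} must be a flat mapping")
    return cfg
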