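"""Reading and writing the package's interchange formats.

The canonical annotation format is a delimited text table with one row per
placed vertex::

    annotator_id, image_id, session, region_index, vertex_index, x, y

vertices ordered by ``vertex_index`` within each region.  Everything else —
masks (8-bit PNG, 0/255), consensus maps (text lattice + JSON sidecar),
annotator metadata (annotator_id, age, group) — is derived from it.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd
from PIL import Image

from .consensus import ConsensusMap
from .geometry import BinaryMask, ImageGrid, OutlineRecord, Polygon

__all__ = [
    "ANNOTATION_COLUMNS",
    "records_to_table",
    "table_to_records",
    "read_annotations",
    "write_annotations",
    "read_metadata",
    "write_metadata",
    "mask_filename",
    "write_mask_png",
    "read_mask_png",
    "write_consensus_map",
    "read_consensus_map",
    "load_backdrop",
]

ANNOTATION_COLUMNS = ["annotator_id", "image_id", "session", "region_index", "vertex_index", "x", "y"]
METADATA_COLUMNS = ["annotator_id", "age", "group"]


def records_to_table(records: Sequence[OutlineRecord]) -> pd.DataFrame:
    """Flatten outline records into the canonical vertex table."""
    rows = []
    for rec in records:
        for r_idx, region in enumerate(rec.regions):
            for v_idx, (x, y) in enumerate(region.points):
                rows.append((rec.annotator_id, rec.image_id, rec.session, r_idx, v_idx, x, y))
    return pd.DataFrame(rows, columns=ANNOTATION_COLUMNS)


def table_to_records(table: pd.DataFrame) -> tuple[list[OutlineRecord], int]:
    """Rebuild outline records from a vertex table.

    Malformed rows (non-finite coordinates, missing identifiers) are
    skipped with a warning, as are regions left with fewer than 3 vertices;
    the number of skipped rows is returned alongside the records.  A
    (annotator, image, session) submission whose every region is malformed
    is dropped entirely.
    """
    missing = set(ANNOTATION_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"annotation table missing columns {sorted(missing)}")
    df = table.copy()
    df["x"] = pd.to_numeric(df["x"], errors="coerce")
    df["y"] = pd.to_numeric(df["y"], errors="coerce")
    bad = df["x"].isna() | df["y"].isna() | df["annotator_id"].isna() | df["image_id"].isna()
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(f"skipped {n_bad} malformed annotation row(s)", stacklevel=2)
    df = df[~bad]

    records: list[OutlineRecord] = []
    for (ann, img, sess), sub in df.groupby(["annotator_id", "image_id", "session"],
                                            dropna=False, sort=True):
        regions = []
        for _, reg in sub.groupby("region_index", sort=True):
            reg = reg.sort_values("vertex_index")
            if len(reg) < 3:
                warnings.warn(
                    f"region with <3 vertices in ({ann}, {img}) skipped", stacklevel=2
                )
                n_bad += len(reg)
                continue
            regions.append(Polygon(reg[["x", "y"]].to_numpy(float)))
        if regions:
            session = None if pd.isna(sess) else int(sess)
            records.append(OutlineRecord(str(ann), str(img), regions, session))
    return records, n_bad


def read_annotations(path: Union[str, Path]) -> pd.DataFrame:
    """Read a canonical annotation table from delimited text."""
    df = pd.read_csv(path)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_annotations(
    data: Union[pd.DataFrame, Sequence[OutlineRecord]], path: Union[str, Path]
) -> None:
    df = data if isinstance(data, pd.DataFrame) else records_to_table(data)
    df.to_csv(path, index=False)


def read_metadata(path: Union[str, Path]) -> pd.DataFrame:
    """Annotator metadata: annotator_id, age, group (citizen|expert)."""
    df = pd.read_csv(path)
    if "annotator_id" not in df.columns:
        raise ValueError(f"{path}: metadata needs an annotator_id column")
    return df


def write_metadata(metadata: pd.DataFrame, path: Union[str, Path]) -> None:
    metadata.to_csv(path, index=False)


def mask_filename(image_id: str, annotator_id: str, suffix: str = ".png") -> str:
    return f"{image_id}__{annotator_id}{suffix}"


def write_mask_png(mask: BinaryMask, path: Union[str, Path]) -> None:
    """Export a mask as single-channel 8-bit PNG (0 background, 255 segment)."""
    arr = np.where(mask.pixels, 255, 0).astype(np.uint8)
    Image.fromarray(arr, mode="L").save(path)


def read_mask_png(path: Union[str, Path]) -> BinaryMask:
    arr = np.asarray(Image.open(path).convert("L"))
    return BinaryMask(ImageGrid(arr.shape[0], arr.shape[1]), arr >= 128)


def write_consensus_map(
    cmap: ConsensusMap, path: Union[str, Path], *, image_id: str = "", panel: str = ""
) -> None:
    """Write the vote-count lattice as text plus a JSON metadata sidecar.

    ``path`` names the lattice file; the sidecar is ``path`` with a
    ``.json`` suffix appended.  Counts (not fractions) are stored so the
    lattice round-trips exactly.
    """
    path = Path(path)
    np.savetxt(path, cmap.counts, fmt="%d")
    meta = {
        "image_id": image_id,
        "panel": panel,
        "n_annotators": cmap.n_annotators,
        "height": cmap.grid.height,
        "width": cmap.grid.width,
        "pixel_spacing": cmap.grid.pixel_spacing,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=2))


def read_consensus_map(path: Union[str, Path]) -> tuple[ConsensusMap, dict]:
    path = Path(path)
    meta = json.loads(Path(str(path) + ".json").read_text())
    counts = np.loadtxt(path, dtype=np.int64, ndmin=2)
    spacing = meta.get("pixel_spacing")
    grid = ImageGrid(meta["height"], meta["width"],
                     tuple(spacing) if spacing else None)
    return ConsensusMap(grid=grid, counts=counts, n_annotators=meta["n_annotators"]), meta


def load_backdrop(path: Union[str, Path]) -> np.ndarray:
    """Load a grayscale backdrop image for visualization only.

    Common raster formats go through Pillow; ``.dcm`` files through pydicom
    when it is installed.  Geometry never depends on anything read here
    beyond the pixel array's shape.
    """
    path = Path(path)
    if path.suffix.lower() == ".dcm":
        try:
            import pydicom
        except ImportError as exc:  # pragma: no cover
            raise ImportError("reading DICOM backdrops requires pydicom") from exc
        return np.asarray(pydicom.dcmread(path).pixel_array, dtype=float)
    return np.asarray(Image.open(path).convert("L"), dtype=float)
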