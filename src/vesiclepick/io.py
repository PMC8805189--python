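"""File I/O and result tables: micrograph reading, the results workbook
(summary + one table per image), and the programmatic correction API that
replaces interactive proof-reading."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .detector import VesicleDetection
from .micrograph import NATIVE_PIXEL_SIZE_NM, Micrograph
from .morphometry import estimate_area, nearest_neighbor_distances

__all__ = [
    "read_micrograph",
    "write_micrograph",
    "ResultsWorkbook",
    "build_workbook",
    "write_results",
    "read_results",
    "apply_corrections",
]

log = logging.getLogger(__name__)

_COLUMNS = ["vesicle_id", "x_px", "y_px", "nnd_nm", "area_nm2"]


def _read_gray_array(path: Path) -> np.ndarray:
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path))
    return arr


def read_micrograph(path, pixel_size_nm: float, mask_path=None) -> Micrograph:
    """Read an 8- or 16-bit grayscale TIFF/PNG, scaled to [0, 1].

    Multi-channel images are rejected.  The optional mask image is
    binarized at half its dynamic range (nonblack = excluded is the
    caller's convention: mask pixels >= 0.5 are treated as excluded).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = _read_gray_array(path)
    if arr.ndim == 3:
        raise ValueError(
            f"{path.name}: expected a single-channel image, got {arr.shape[-1]} channels"
        )
    if arr.dtype == np.uint8:
        pixels = arr.astype(np.float32) / 255.0
    elif arr.dtype == np.uint16:
        pixels = arr.astype(np.float32) / 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        pixels = arr.astype(np.float32)
        if pixels.max() > 1.0:
            pixels = pixels / pixels.max()
    else:
        raise ValueError(f"{path.name}: unsupported dtype {arr.dtype}")
    mask = None
    if mask_path is not None:
        marr = _read_gray_array(Path(mask_path)).astype(np.float32)
        if marr.ndim != 2:
            raise ValueError("mask must be single-channel")
        if marr.shape != pixels.shape:
            raise ValueError(
                f"mask shape {marr.shape} does not match image shape {pixels.shape}"
            )
        scale = 255.0 if marr.max() > 1.0 else 1.0
        mask = marr / scale >= 0.5
    return Micrograph(pixels, pixel_size_nm, mask=mask)


def write_micrograph(path, mg: Micrograph | np.ndarray) -> None:
    """Write as 8-bit grayscale TIFF or PNG (by extension)."""
    pixels = mg.pixels if isinstance(mg, Micrograph) else np.asarray(mg)
    data = (np.clip(pixels, 0, 1) * 255).round().astype(np.uint8)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, data)
    else:
        from PIL import Image

        Image.fromarray(data).save(path)


@dataclass
class ResultsWorkbook:
    """Detection results: a summary table plus one table per image.

    Each per-image table has columns vesicle_id, x_px, y_px, nnd_nm,
    area_nm2 (original-image pixels, 0-based; nnd is NaN when the image has
    a single vesicle).
    """

    per_image: dict[str, pd.DataFrame] = field(default_factory=dict)
    pixel_size_nm: float = NATIVE_PIXEL_SIZE_NM

    @property
    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "image_name": list(self.per_image),
                "vesicle_count": [len(df) for df in self.per_image.values()],
            }
        )

    def validate(self) -> None:
        for name, df in self.per_image.items():
            if list(df.columns) != _COLUMNS:
                raise ValueError(f"{name}: unexpected columns {list(df.columns)}")
            if len(df) == 1 and not np.isnan(df["nnd_nm"].iloc[0]):
                raise ValueError(f"{name}: single vesicle must have missing nnd")
            if len(df) and (df["area_nm2"].dropna() <= 0).any():
                raise ValueError(f"{name}: non-positive area")


def build_workbook(
    detections_per_image: dict[str, list[VesicleDetection]],
    pixel_size_nm: float,
) -> ResultsWorkbook:
    wb = ResultsWorkbook(pixel_size_nm=pixel_size_nm)
    for name, detections in detections_per_image.items():
        wb.per_image[name] = pd.DataFrame(
            {
                "vesicle_id": np.arange(1, len(detections) + 1),
                "x_px": [d.x_px for d in detections],
                "y_px": [d.y_px for d in detections],
                "nnd_nm": [np.nan if d.nnd_nm is None else d.nnd_nm for d in detections],
                "area_nm2": [np.nan if d.area_nm2 is None else d.area_nm2
                             for d in detections],
            }
        )
    return wb


def _formatted(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    out["x_px"] = out["x_px"].round().astype(int)
    out["y_px"] = out["y_px"].round().astype(int)
    out["nnd_nm"] = out["nnd_nm"].round(2)
    out["area_nm2"] = out["area_nm2"].round(2)
    return out


def write_results(wb: ResultsWorkbook, path, fmt: str = "csv-dir") -> None:
    """Write the workbook as a directory of CSVs (canonical) or one XLSX.

    csv-dir: ``summary.csv`` plus ``<image>.csv`` per image.  xlsx: one
    summary sheet plus one sheet per image.  Coordinates are written as
    integers, nnd/area with two decimals; rows are ordered by vesicle_id.
    """
    wb.validate()
    path = Path(path)
    if fmt == "csv-dir":
        path.mkdir(parents=True, exist_ok=True)
        summary = wb.summary
        summary["pixel_size_nm"] = wb.pixel_size_nm
        summary.to_csv(path / "summary.csv", index=False)
        for name, df in wb.per_image.items():
            _formatted(df.sort_values("vesicle_id")).to_csv(
                path / f"{Path(name).stem}.csv", index=False
            )
    elif fmt == "xlsx":
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            summary = wb.summary
            summary["pixel_size_nm"] = wb.pixel_size_nm
            summary.to_excel(writer, sheet_name="summary", index=False)
            for name, df in wb.per_image.items():
                _formatted(df.sort_values("vesicle_id")).to_excel(
                    writer, sheet_name=Path(name).stem[:31], index=False
                )
    else:
        raise ValueError(f"unknown format {fmt!r} (use 'csv-dir' or 'xlsx')")


def read_results(path) -> ResultsWorkbook:
    """Read back a csv-dir workbook."""
    path = Path(path)
    summary = pd.read_csv(path / "summary.csv")
    pixel_size = float(summary["pixel_size_nm"].iloc[0]) if len(summary) else NATIVE_PIXEL_SIZE_NM
    wb = ResultsWorkbook(pixel_size_nm=pixel_size)
    for name in summary["image_name"]:
        df = pd.read_csv(path / f"{Path(name).stem}.csv")
        wb.per_image[name] = df[_COLUMNS]
    return wb


def _recompute_nnd(df: pd.DataFrame, pixel_size_nm: float) -> pd.DataFrame:
    df = df.copy()
    points = df[["x_px", "y_px"]].to_numpy(dtype=float)
    df["nnd_nm"] = nearest_neighbor_distances(points, pixel_size_nm)
    return df


def apply_corrections(
    wb: ResultsWorkbook,
    image: str,
    additions=(),
    removals=(),
    img_rescaled: Micrograph | None = None,
    scale_factor: float = 1.0,
) -> ResultsWorkbook:
    """Manual proof-reading: drop false positives, add missed vesicles.

    ``removals`` are vesicle_ids; ``additions`` are (x, y) original-image
    pixel coordinates, whose areas are measured on the rescaled
    (2.27 nm/px) image when it is provided.  All nnd values for the image
    are recomputed and ids renumbered.  Returns a new workbook.
    """
    if image not in wb.per_image:
        raise KeyError(f"unknown image {image!r}")
    df = wb.per_image[image].copy()
    removals = list(removals)
    unknown = set(removals) - set(df["vesicle_id"].tolist())
    if unknown:
        raise KeyError(f"unknown vesicle ids: {sorted(unknown)}")
    df = df[~df["vesicle_id"].isin(removals)]
    new_rows = []
    for x, y in additions:
        if img_rescaled is not None:
            h, w = img_rescaled.shape
            ry, rx = y * scale_factor, x * scale_factor
            if not (0 <= ry < h and 0 <= rx < w):
                raise ValueError(f"addition ({x}, {y}) outside image bounds")
            fit = estimate_area(img_rescaled.pixels, (rx, ry),
                                img_rescaled.pixel_size_nm)
            area = fit.area_nm2
        else:
            area = np.nan
        new_rows.append({"x_px": x, "y_px": y, "nnd_nm": np.nan, "area_nm2": area})
    if new_rows:
        df = pd.concat([df, pd.DataFrame(new_rows)], ignore_index=True)
    df["vesicle_id"] = np.arange(1, len(df) + 1)
    df = _recompute_nnd(df[_COLUMNS], wb.pixel_size_nm)
    out = ResultsWorkbook(dict(wb.per_image), wb.pixel_size_nm)
    out.per_image[image] = df
    return out
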