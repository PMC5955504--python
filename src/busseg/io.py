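"""Disk formats: 8-bit grayscale PNG images, {0,255} PNG masks, CSV manifest,
32-bit float TIFF probability/vote-fraction maps."""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .phantom import BModeImage, SegmentationMask

__all__ = [
    "save_image_png", "load_image_png", "save_mask_png", "load_mask_png",
    "save_float_tiff", "load_float_tiff", "write_manifest", "read_manifest",
    "save_dataset", "load_dataset",
]


def save_image_png(image, path) -> None:
    arr = np.asarray(getattr(image, "pixels", image), dtype=np.float64)
    hi = arr.max()
    scaled = np.zeros_like(arr) if hi == 0 else arr / hi
    Image.fromarray((scaled * 255).round().astype(np.uint8), mode="L").save(path)


def load_image_png(path, patient_id: str = "") -> BModeImage:
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.float64)
    return BModeImage(arr, patient_id=patient_id or Path(path).stem, source="file")


def save_mask_png(mask, path) -> None:
    m = np.asarray(getattr(mask, "pixels", mask)).astype(np.uint8)
    Image.fromarray(m * 255, mode="L").save(path)


def load_mask_png(path, role: str = "truth") -> SegmentationMask:
    arr = np.asarray(Image.open(path).convert("L"))
    return SegmentationMask((arr > 127).astype(np.uint8), role=role)


def save_float_tiff(arr, path) -> None:
    tifffile.imwrite(path, np.asarray(getattr(arr, "pixels", arr), dtype=np.float32))


def load_float_tiff(path) -> np.ndarray:
    return tifffile.imread(path)


def write_manifest(rows: list[dict], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["filename", "patient_id", "role",
                                                "class"])
        writer.writeheader()
        for row in rows:
            writer.writerow({"class": "", **row})


def read_manifest(path) -> list[dict]:
    with open(path, newline="") as fh:
        return list(csv.DictReader(fh))


def save_dataset(dataset, out_dir) -> Path:
    """Write (image, mask) pairs as PNGs plus an indexing manifest.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, msk) in enumerate(dataset):
        img_name, msk_name = f"img{i:04d}.png", f"img{i:04d}_mask.png"
        save_image_png(img, out / img_name)
        save_mask_png(msk, out / msk_name)
        rows.append({"filename": img_name, "patient_id": img.patient_id,
                     "role": "image", "class": img.meta.get("class", "")})
        rows.append({"filename": msk_name, "patient_id": img.patient_id,
                     "role": "truth", "class": img.meta.get("class", "")})
    write_manifest(rows, out / "manifest.csv")
    return out / "manifest.csv"


def load_dataset(manifest_path) -> list[tuple[BModeImage, SegmentationMask]]:
    root = Path(manifest_path).parent
    rows = read_manifest(manifest_path)
    images = {r["filename"]: r for r in rows if r["role"] == "image"}
    out = []
    for name, row in images.items():
        img = load_image_png(root / name, patient_id=row["patient_id"])
        if row.get("class"):
            img.meta["class"] = row["class"]
        mask_name = name.replace(".png", "_mask.png")
        msk = load_mask_png(root / mask_name)
        out.append((img, msk))
    return out
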