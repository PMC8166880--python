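"""Rendering samples as grayscale images under an optimized feature layout.

Rendering is a pure permutation: pixel ``p`` (row-major) of sample ``m``
holds the value of feature ``ordering.permutation[p]``.  Intensities are
kept in [0, 1] internally (per-feature min-max across samples, so a fixed
pixel is comparable across images) and scaled to 8-bit on PNG export.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
from PIL import Image

from .dataset import TabularDataset
from .ranking import ImageGrid

__all__ = [
    "FeatureOrdering",
    "SampleImage",
    "normalize_features",
    "render_images",
    "export_images",
    "load_image_archive",
]


@dataclass
class FeatureOrdering:
    """Assignment of features to row-major pixel positions.

    ``permutation[p]`` is the original feature index shown at linear pixel
    position ``p``, i.e. image row ``p // n_cols``, column ``p % n_cols``
    — the same linearization used for the pixel rank matrix.
    """

    permutation: np.ndarray
    grid: ImageGrid

    def __post_init__(self) -> None:
        self.permutation = np.asarray(self.permutation, dtype=int)
        n = self.grid.size
        if self.permutation.shape != (n,) or not np.array_equal(
            np.sort(self.permutation), np.arange(n)
        ):
            raise ValueError(f"permutation must be a bijection on 0..{n - 1}")

    def to_frame(self, feature_names: list[str]) -> pd.DataFrame:
        """Tabulate the layout: one row per pixel position."""
        p = np.arange(self.grid.size)
        return pd.DataFrame({
            "feature_name": [feature_names[j] for j in self.permutation],
            "pixel_row": p // self.grid.n_cols,
            "pixel_col": p % self.grid.n_cols,
            "linear_index": p,
        })


@dataclass
class SampleImage:
    """One rendered sample: an Nr-by-Nc intensity array plus its sample ID."""

    intensities: np.ndarray
    sample_id: str

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D")


def normalize_features(data: TabularDataset, mode: str = "minmax") -> TabularDataset:
    """Scale each feature to [0, 1] across samples (``minmax``) or pass through (``none``).

    Constant features map to 0 under minmax.
    """
    if mode == "none":
        return data
    if mode != "minmax":
        raise ValueError("mode must be 'minmax' or 'none'")
    lo = data.values.min(axis=0)
    hi = data.values.max(axis=0)
    span = hi - lo
    safe = np.where(span == 0, 1.0, span)
    values = (data.values - lo) / safe
    values[:, span == 0] = 0.0
    return TabularDataset(values, sample_ids=list(data.sample_ids),
                          feature_names=list(data.feature_names))


def render_images(data: TabularDataset, ordering: FeatureOrdering) -> list[SampleImage]:
    """One image per sample, filling the grid row-major through the ordering."""
    if data.n_features != ordering.grid.size:
        raise ValueError(
            f"table has {data.n_features} features but the grid holds "
            f"{ordering.grid.size} pixels"
        )
    arranged = data.values[:, ordering.permutation]
    stack = arranged.reshape(data.n_samples, ordering.grid.n_rows, ordering.grid.n_cols)
    return [SampleImage(stack[m], data.sample_ids[m]) for m in range(data.n_samples)]


def _to_uint8(intensities: np.ndarray) -> np.ndarray:
    # half-up rounding of intensity*255, clipped to the 8-bit range
    return np.clip(np.floor(intensities * 255.0 + 0.5), 0, 255).astype(np.uint8)


def export_images(images: list[SampleImage], directory, fmt: str = "png8") -> Path:
    """Write images and return the path of the manifest CSV.

    ``png8``: one 8-bit grayscale PNG per sample.  ``array_archive``: a
    single HDF5 file holding all images at full precision (lossless round
    trip) plus the manifest.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    if fmt == "png8":
        for m, img in enumerate(images):
            fname = f"{m:05d}_{_safe_filename(img.sample_id)}.png"
            path = directory / fname
            try:
                Image.fromarray(_to_uint8(img.intensities), mode="L").save(path)
            except OSError as exc:
                raise OSError(f"failed writing image for sample {img.sample_id!r}: {exc}") from exc
            rows.append({"sample_id": img.sample_id, "path": fname})
    elif fmt == "array_archive":
        path = directory / "images.h5"
        stack = np.stack([img.intensities for img in images])
        try:
            with h5py.File(path, "w") as f:
                f.create_dataset("images", data=stack)
                f.create_dataset(
                    "sample_ids",
                    data=np.array([img.sample_id for img in images], dtype="S"),
                )
        except OSError as exc:
            raise OSError(f"failed writing image archive: {exc}") from exc
        rows = [{"sample_id": img.sample_id, "path": "images.h5"} for img in images]
    else:
        raise ValueError("fmt must be 'png8' or 'array_archive'")
    manifest = directory / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_image_archive(path) -> list[SampleImage]:
    """Read back an ``array_archive`` written by :func:`export_images`."""
    with h5py.File(path, "r") as f:
        stack = f["images"][()]
        ids = [s.decode() for s in f["sample_ids"][()]]
    return [SampleImage(stack[m], ids[m]) for m in range(stack.shape[0])]


def _safe_filename(sample_id: str) -> str:
    keep = "".join(c if c.isalnum() or c in "-_." else "_" for c in sample_id)
    if not keep:
        keep = hashlib.md5(sample_id.encode()).hexdigest()[:8]
    return keep
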