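"""Patch cutting, painted-pixel rates and 21-level coverage classes.

Training and evaluation operate on square 64x64-pixel windows ("pieces") cut
from plot images.  For each window and category, the rate of painted pixels
r_p on the category map is computed and discretized into one of 21 class
values {0, 5, ..., 100} percent, in 5-point steps.  The discretization is
banker's rounding of ``r_p * 20`` (round half to even), which produces the
asymmetric open/closed boundary pattern of the class table: 0.125 -> 10
(2.5 rounds down to 2) but 0.175 -> 20 (3.5 rounds up to 4).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .io import PlotRecord, measured_coverage

PATCH_SIDE = 64
#: Width of the right-hand strip reserved for validation pieces.
VALIDATION_STRIP = 128
#: Default number of randomly cut training pieces per plot.
TRAIN_PATCHES_PER_PLOT = 4000
#: Backbone input side after nearest-neighbour upscaling.
RESIZED_SIDE = 256

#: The 21 class values, percent.
CLASS_VALUES: tuple[int, ...] = tuple(range(0, 101, 5))
N_CLASSES = len(CLASS_VALUES)


@dataclass(frozen=True)
class PatchWindow:
    """A square window on a plot image; 0-based, top-left origin, half-open
    extent ``[x0, x0+side) x [y0, y0+side)``."""

    plot_id: str
    x0: int
    y0: int
    side: int = PATCH_SIDE


@dataclass
class LabeledPatch:
    """A window plus, per category, its painted-pixel rate and class value."""

    window: PatchWindow
    rp: dict[str, float] = field(default_factory=dict)
    class_value: dict[str, int] = field(default_factory=dict)


def bin_class(rp: float) -> int:
    """Map a painted-pixel rate in [0, 1] to its class value in {0, 5, .., 100}.

    Implemented as ``5 * round(rp * 20)`` with round-half-to-even, so interval
    boundaries at even multiples of 0.025 are closed and odd ones open.
    """
    rp = float(rp)
    if not 0.0 <= rp <= 1.0:
        raise ValueError(f"painted-pixel rate {rp} outside [0, 1]")
    return 5 * int(round(rp * 20))


def _interval_rows() -> list[tuple[float, float, bool, int]]:
    # (lower, upper, closed?, class value); closed rows are the even ones.
    rows = []
    for i, value in enumerate(CLASS_VALUES):
        # boundaries are exact multiples of 0.025; divide integers so that
        # e.g. row 50's lower bound is the float 0.475, not 19 * float(0.025)
        lo = max(0, (2 * i - 1) * 25) / 1000.0
        hi = min(1000, (2 * i + 1) * 25) / 1000.0
        rows.append((lo, hi, i % 2 == 0, value))
    return rows


#: Explicit interval form of the class table, shipped alongside the closed
#: form as a guard against platform rounding drift.
CLASS_INTERVALS: tuple[tuple[float, float, bool, int], ...] = tuple(_interval_rows())


def bin_class_interval(rp: float) -> int:
    """Class value by direct lookup in the 21-row interval table."""
    rp = float(rp)
    if not 0.0 <= rp <= 1.0:
        raise ValueError(f"painted-pixel rate {rp} outside [0, 1]")
    for lo, hi, closed, value in CLASS_INTERVALS:
        if (lo <= rp <= hi) if closed else (lo < rp < hi):
            return value
    raise AssertionError("interval table does not cover [0, 1]")  # pragma: no cover


def class_index(value: int) -> int:
    """Index 0..20 of a class value (value = 5 * index)."""
    if value % 5 or not 0 <= value <= 100:
        raise ValueError(f"{value} is not a class value")
    return value // 5


def patch_rp(category_map: np.ndarray, window: PatchWindow) -> float:
    """Painted-pixel rate of the map inside the window."""
    h, w = category_map.shape[:2]
    if window.x0 < 0 or window.y0 < 0 or window.x0 + window.side > w or window.y0 + window.side > h:
        raise ValueError(
            f"window ({window.x0},{window.y0})+{window.side} outside {w}x{h} map"
        )
    sub = category_map[window.y0:window.y0 + window.side, window.x0:window.x0 + window.side]
    return float(np.count_nonzero(sub)) / (window.side * window.side)


def label_window(record: PlotRecord, window: PatchWindow) -> LabeledPatch:
    """Compute r_p and class value for every category of the record."""
    patch = LabeledPatch(window=window)
    for cat, m in record.maps.items():
        rp = patch_rp(m, window)
        patch.rp[cat] = rp
        patch.class_value[cat] = bin_class(rp)
    return patch


def extract_patch(image: np.ndarray, window: PatchWindow) -> np.ndarray:
    """Pixel block of the window from an image or map raster."""
    return image[window.y0:window.y0 + window.side, window.x0:window.x0 + window.side]


def sample_training_patches(
    record: PlotRecord,
    n: int = TRAIN_PATCHES_PER_PLOT,
    strip_width: int = VALIDATION_STRIP,
    side: int = PATCH_SIDE,
    seed: int | None = None,
) -> list[LabeledPatch]:
    """Randomly cut ``n`` labeled training windows from a plot.

    Windows are uniform (with replacement) over all positions whose extent
    avoids the right-hand validation strip: ``x0 + side <= W - strip_width``
    and ``y0 + side <= H``.  Deterministic for a fixed seed.
    """
    h, w = record.shape
    max_x0 = w - strip_width - side
    max_y0 = h - side
    if max_x0 < 0 or max_y0 < 0:
        raise ValueError(
            f"plot {record.plot_id!r} ({w}x{h}) too small for a {side}px window "
            f"left of a {strip_width}px strip"
        )
    rng = np.random.default_rng(seed)
    xs = rng.integers(0, max_x0 + 1, size=n)
    ys = rng.integers(0, max_y0 + 1, size=n)
    return [
        label_window(record, PatchWindow(record.plot_id, int(x), int(y), side))
        for x, y in zip(xs, ys)
    ]


def _tile(plot_id: str, x_start: int, width: int, height: int, side: int) -> list[PatchWindow]:
    # row-major from the top-left; partial windows at the edges dropped
    return [
        PatchWindow(plot_id, x_start + col * side, row * side, side)
        for row in range(height // side)
        for col in range(width // side)
    ]


def tile_validation_patches(
    record: PlotRecord, strip_width: int = VALIDATION_STRIP, side: int = PATCH_SIDE
) -> list[LabeledPatch]:
    """Non-overlapping windows tiling the right-hand validation strip, cut in
    order from the strip's upper left."""
    if strip_width < side:
        raise ValueError(f"validation strip ({strip_width}px) narrower than window ({side}px)")
    h, w = record.shape
    windows = _tile(record.plot_id, w - strip_width, strip_width, h, side)
    return [label_window(record, win) for win in windows]


def tile_evaluation_patches(record: PlotRecord, side: int = PATCH_SIDE) -> list[LabeledPatch]:
    """Non-overlapping row-major grid over the whole plot image; the remainder
    at the right/bottom edges is not used."""
    h, w = record.shape
    if h < side or w < side:
        raise ValueError(f"plot {record.plot_id!r} ({w}x{h}) smaller than one {side}px window")
    return [label_window(record, win) for win in _tile(record.plot_id, 0, w, h, side)]


def resize_patch(patch: np.ndarray, out_side: int = RESIZED_SIDE) -> np.ndarray:
    """Nearest-neighbour upscale of a square patch to ``out_side``.

    For the canonical 64 -> 256 case every input pixel becomes an exact 4x4
    block, so the colour histogram scales by exactly 16.
    """
    h, w = patch.shape[:2]
    if h != w:
        raise ValueError(f"patch must be square, got {w}x{h}")
    if out_side % h == 0:
        k = out_side // h
        return np.repeat(np.repeat(patch, k, axis=0), k, axis=1)
    resized = Image.fromarray(patch).resize((out_side, out_side), Image.NEAREST)
    return np.asarray(resized)


# ---------------------------------------------------------------------------
# Datasets
# ---------------------------------------------------------------------------

@dataclass
class PatchDataset:
    """A set of labeled patches with their pixels, ready for training.

    ``images`` is ``(n, side, side, 3)`` uint8; ``labels`` a frame with one
    row per patch (plot_id, x0, y0, rp_<cat>, class_<cat> per category).
    """

    images: np.ndarray
    labels: pd.DataFrame
    categories: tuple[str, ...]
    source_plots: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.labels)

    def class_indices(self, category: str) -> np.ndarray:
        """Integer class indices 0..20 for one category."""
        return (self.labels[f"class_{category}"].to_numpy() // 5).astype(np.int64)


def _patches_to_dataset(
    record: PlotRecord, patches: Sequence[LabeledPatch]
) -> tuple[np.ndarray, list[dict[str, object]]]:
    imgs = np.stack([extract_patch(record.image, p.window) for p in patches])
    rows = []
    for p in patches:
        row: dict[str, object] = {"plot_id": p.window.plot_id, "x0": p.window.x0, "y0": p.window.y0}
        for cat in record.categories:
            row[f"rp_{cat}"] = p.rp[cat]
            row[f"class_{cat}"] = p.class_value[cat]
        rows.append(row)
    return imgs, rows


def build_training_dataset(
    records: Sequence[PlotRecord],
    n_per_plot: int = TRAIN_PATCHES_PER_PLOT,
    strip_width: int = VALIDATION_STRIP,
    side: int = PATCH_SIDE,
    seed: int | None = None,
) -> tuple[PatchDataset, PatchDataset]:
    """Build the (training, validation) dataset pair for one plot or a group.

    A group dataset is the concatenation of each plot's ``n_per_plot`` random
    training pieces (per-plot provenance kept in the label table); validation
    pieces tile each plot's right-hand strip without overlap.
    """
    if not records:
        raise ValueError("no plot records given")
    cats = records[0].categories
    ss = np.random.SeedSequence(seed).spawn(len(records))
    train_imgs, train_rows, val_imgs, val_rows = [], [], [], []
    for rec, child in zip(records, ss):
        if rec.categories != cats:
            raise ValueError(f"plot {rec.plot_id!r} category set differs from {cats}")
        rec_seed = int(child.generate_state(1)[0] % (2**31))
        tr = sample_training_patches(rec, n_per_plot, strip_width, side, seed=rec_seed)
        va = tile_validation_patches(rec, strip_width, side)
        imgs, rows = _patches_to_dataset(rec, tr)
        train_imgs.append(imgs)
        train_rows.extend(rows)
        imgs, rows = _patches_to_dataset(rec, va)
        val_imgs.append(imgs)
        val_rows.extend(rows)
    plot_ids = tuple(r.plot_id for r in records)
    train = PatchDataset(
        np.concatenate(train_imgs), pd.DataFrame(train_rows), cats, plot_ids
    )
    val = PatchDataset(np.concatenate(val_imgs), pd.DataFrame(val_rows), cats, plot_ids)
    return train, val


def save_dataset(dataset: PatchDataset, out_dir: str | Path, write_images: bool = False) -> Path:
    """Serialize a dataset as a label table (CSV) and optional patch PNGs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels_path = out / "labels.csv"
    dataset.labels.to_csv(labels_path, index=False)
    if write_images:
        img_dir = out / "patches"
        img_dir.mkdir(exist_ok=True)
        for i, img in enumerate(dataset.images):
            Image.fromarray(img).save(img_dir / f"patch_{i:06d}.png")
    meta = pd.Series(
        {"categories": ",".join(dataset.categories), "source_plots": ",".join(dataset.source_plots)}
    )
    meta.to_csv(out / "manifest.csv", header=False)
    return labels_path
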