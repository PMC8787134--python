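"""Plot image / category-map I/O and map-derived ("measured") coverage.

A *plot* is one experimental sward plot photographed from above: an 8-bit RGB
image plus one binary map per vegetation category (e.g. timothy grass ``TY``,
white clover ``WC``, background ``Bg``).  Each map is a raster of the same
height and width as the image whose nonzero pixels mark ground covered by that
category.  The fraction of painted pixels on a map is the plot's *measured*
coverage for that category; the breeder's visual estimate, when available, is
the *scored* coverage.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image

#: Canonical category layout of the timothy / white-clover study.
DEFAULT_CATEGORIES: tuple[str, ...] = ("TY", "WC", "Bg")


class DimensionMismatchError(ValueError):
    """A category map's raster size differs from its plot image."""


class UnknownCategoryError(KeyError):
    """A category was requested that the plot record does not carry."""


@dataclass
class PlotRecord:
    """One plot: image, per-category binary maps, and metadata.

    Attributes
    ----------
    plot_id, group_id, cultivar
        Identifiers from the field-trial layout.
    image
        ``(H, W, 3)`` uint8 RGB raster.
    maps
        category -> ``(H, W)`` uint8 raster with values in ``{0, 1}``.
    scored
        category -> breeder-scored coverage percent in [0, 100]; may be empty.
    """

    plot_id: str
    group_id: str = ""
    cultivar: str = ""
    image: np.ndarray = field(default_factory=lambda: np.zeros((0, 0, 3), np.uint8))
    maps: dict[str, np.ndarray] = field(default_factory=dict)
    scored: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        h, w = self.image.shape[:2]
        for cat, m in self.maps.items():
            if m.shape[:2] != (h, w):
                raise DimensionMismatchError(
                    f"map {cat!r} of plot {self.plot_id!r} is "
                    f"{m.shape[1]}x{m.shape[0]}, image is {w}x{h}"
                )
        for cat, v in self.scored.items():
            if not 0.0 <= float(v) <= 100.0:
                raise ValueError(f"scored coverage {cat}={v} outside [0, 100]")

    @property
    def categories(self) -> tuple[str, ...]:
        return tuple(self.maps)

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of the plot image."""
        return self.image.shape[:2]


def _binarize(raster: np.ndarray) -> np.ndarray:
    """Any nonzero channel value counts as painted (hand-painted PNG layers
    may carry antialiased edge values)."""
    if raster.ndim == 3:
        raster = raster.max(axis=2)
    return (raster > 0).astype(np.uint8)


def load_plot(
    image_path: str | Path,
    map_paths: Mapping[str, str | Path],
    metadata: Mapping[str, object] | None = None,
) -> PlotRecord:
    """Read a plot image and its category maps from PNG files.

    Parameters
    ----------
    image_path
        RGB plot image.
    map_paths
        category -> path of the binary map layer; maps are binarized on load
        and must match the image dimensions pixel-for-pixel.
    metadata
        Optional mapping with keys ``plot_id``, ``group_id``, ``cultivar``
        and ``scored_<category>`` percent values.
    """
    meta = dict(metadata or {})
    image = np.asarray(Image.open(image_path).convert("RGB"))
    maps: dict[str, np.ndarray] = {}
    for cat, p in map_paths.items():
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(f"missing map for category {cat!r}: {p}")
        maps[cat] = _binarize(np.asarray(Image.open(p)))
    scored = {
        k[len("scored_"):]: float(v)
        for k, v in meta.items()
        if k.startswith("scored_") and v is not None and not pd.isna(v)
    }
    return PlotRecord(
        plot_id=str(meta.get("plot_id", Path(image_path).stem)),
        group_id=str(meta.get("group_id", "")),
        cultivar=str(meta.get("cultivar", "")),
        image=image,
        maps=maps,
        scored=scored,
    )


def save_plot(record: PlotRecord, out_dir: str | Path) -> dict[str, Path]:
    """Write the plot image and maps as PNG; returns the written paths.

    Maps are stored as 8-bit grayscale with painted pixels at 255 so they are
    viewable; :func:`load_plot` re-binarizes them.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    img_path = out / f"{record.plot_id}.png"
    Image.fromarray(record.image).save(img_path)
    paths["image"] = img_path
    for cat, m in record.maps.items():
        p = out / f"{record.plot_id}_map_{cat}.png"
        Image.fromarray((m * 255).astype(np.uint8)).save(p)
        paths[cat] = p
    return paths


def measured_coverage(record: PlotRecord, category: str) -> float:
    """Percent of painted pixels on the category map, over the full image.

    This is the plot's measured coverage: ``100 * painted / total``.
    """
    if category not in record.maps:
        raise UnknownCategoryError(
            f"plot {record.plot_id!r} has no map for category {category!r} "
            f"(has {sorted(record.maps)})"
        )
    m = record.maps[category]
    if m.size == 0:
        raise ValueError(f"plot {record.plot_id!r} has an empty map")
    return 100.0 * float(np.count_nonzero(m)) / m.size


def round_display(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up used for presentation tables (51.25 -> 51.3)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def summarize_coverage(records: Sequence[PlotRecord]) -> pd.DataFrame:
    """Per-category mean and range (max - min) of scored and measured coverage.

    Returns a tidy frame with columns ``category, kind, mean, range`` where
    ``kind`` is ``scored`` or ``measured``; values rounded to one decimal for
    display.  Scored statistics cover only plots that carry a score for the
    category.
    """
    if len(records) == 0:
        raise ValueError("summarize_coverage needs at least one plot record")
    cats: list[str] = []
    for r in records:
        for c in r.categories:
            if c not in cats:
                cats.append(c)
    rows = []
    for cat in cats:
        measured = [measured_coverage(r, cat) for r in records if cat in r.maps]
        scored = [r.scored[cat] for r in records if cat in r.scored]
        for kind, vals in (("scored", scored), ("measured", measured)):
            if not vals:
                continue
            rows.append(
                {
                    "category": cat,
                    "kind": kind,
                    "mean": round_display(float(np.mean(vals))),
                    "range": round_display(float(np.max(vals) - np.min(vals))),
                }
            )
    return pd.DataFrame(rows, columns=["category", "kind", "mean", "range"])


# ---------------------------------------------------------------------------
# Study metadata tables
# ---------------------------------------------------------------------------

def load_study_table(table_path: str | Path) -> list[PlotRecord]:
    """Load every plot listed in a study metadata table (CSV).

    Expected columns: ``plot_id, group_id, cultivar, image_path,
    map_<cat>_path`` per category and optional ``scored_<cat>`` columns.
    Relative paths resolve against the table's directory.
    """
    table_path = Path(table_path)
    df = pd.read_csv(table_path)
    base = table_path.parent
    records = []
    for _, row in df.iterrows():
        map_paths = {
            col[len("map_"):-len("_path")]: base / str(row[col])
            for col in df.columns
            if col.startswith("map_") and col.endswith("_path")
        }
        records.append(load_plot(base / str(row["image_path"]), map_paths, row.to_dict()))
    return records


def save_study_table(
    records: Iterable[PlotRecord], out_dir: str | Path, name: str = "plots.csv"
) -> Path:
    """Write plot images/maps plus a metadata table referencing them."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in records:
        paths = save_plot(rec, out)
        row: dict[str, object] = {
            "plot_id": rec.plot_id,
            "group_id": rec.group_id,
            "cultivar": rec.cultivar,
            "image_path": paths["image"].name,
        }
        for cat in rec.categories:
            row[f"map_{cat}_path"] = paths[cat].name
        for cat, v in rec.scored.items():
            row[f"scored_{cat}"] = v
        rows.append(row)
    table = out / name
    pd.DataFrame(rows).to_csv(table, index=False)
    return table
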