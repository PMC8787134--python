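"""Synthetic mixed-sward plot generator with exact ground-truth maps.

Generates top-down plot images that emulate the structure of UAV sward
imagery at ~1 mm/pixel: thin-bladed grass (timothy, ``TY``) drawn as
hard-edged elongated rectangles, white clover (``WC``) as trifoliate unions
of three discs, over a soil/litter background.  Because organs are drawn
with hard edges, the per-category binary maps are exactly the rasterized
footprints of the drawn organs — there is no anti-aliasing ambiguity, and
the measured coverage of a generated plot equals the generator's achieved
coverage to the pixel.

Organs are added one at a time to whichever category is furthest below its
target coverage until every target is reached; later organs occlude earlier
ones (and steal their pixels), as leaves do in a real canopy.  A single
organ covers far less than 1% of a plot, so achieved coverage lands within
the 3-point guarantee band above the target.

An optional *withered grass* mode draws a fraction of the grass in a
senescent brown palette; those blades can be left out of the TY map (they
then count as background), reproducing the labelling ambiguity that makes
grass/background discrimination hard on autumn imagery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from skimage import draw as skdraw

from .io import PlotRecord
from .patches import TRAIN_PATCHES_PER_PLOT

# owner-raster codes
_BG, _TY, _WC, _WITHERED = 0, 1, 2, 3

COVERAGE_TOLERANCE = 0.03  # guaranteed |achieved - target| per category


@dataclass
class SwardParams:
    """Parameters of one synthetic plot (study-scale image size by default)."""

    width: int = 2000
    height: int = 3000
    #: category -> target coverage fraction; Bg is the complement.
    target_coverage: dict[str, float] = field(
        default_factory=lambda: {"TY": 0.40, "WC": 0.20}
    )
    grass_length: tuple[int, int] = (30, 60)
    grass_width: tuple[int, int] = (1, 3)
    clover_radius: tuple[int, int] = (8, 14)
    clover_lobes: int = 3
    #: fraction of grass blades drawn in a senescent brown palette
    withered_fraction: float = 0.0
    #: paint withered blades in the TY map (False reproduces the
    #: withered-grass-labelled-as-background ambiguity)
    paint_withered: bool = True
    seed: int = 0


# palettes (RGB); chosen so ExG-ExR separates vegetation from soil/litter
_GRASS_COLOR = np.array([70, 115, 40])
_WITHERED_COLOR = np.array([150, 125, 70])
_CLOVER_COLOR = np.array([120, 180, 100])
_SOIL_COLOR = np.array([110, 80, 50])
_LITTER_COLOR = np.array([160, 140, 95])


def _background(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    """Soil with scattered litter patches and per-pixel colour noise."""
    litter = rng.random((h, w)) < 0.25
    base = np.where(litter[..., None], _LITTER_COLOR, _SOIL_COLOR).astype(np.float64)
    base += rng.normal(0.0, 12.0, size=(h, w, 3))
    return np.clip(base, 0, 255).astype(np.uint8)


def _grass_footprint(
    h: int, w: int, params: SwardParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel rows/cols of one randomly placed, rotated thin blade."""
    length = rng.integers(params.grass_length[0], params.grass_length[1] + 1)
    width = rng.integers(params.grass_width[0], params.grass_width[1] + 1)
    theta = rng.uniform(0, np.pi)
    cy, cx = rng.uniform(0, h), rng.uniform(0, w)
    dy, dx = np.sin(theta), np.cos(theta)
    ny, nx = -dx, dy  # unit normal
    half_l, half_w = length / 2.0, max(width / 2.0, 0.5)
    corners_y = [cy + sy * half_l * dy + sw * half_w * ny
                 for sy, sw in ((-1, -1), (-1, 1), (1, 1), (1, -1))]
    corners_x = [cx + sy * half_l * dx + sw * half_w * nx
                 for sy, sw in ((-1, -1), (-1, 1), (1, 1), (1, -1))]
    return skdraw.polygon(corners_y, corners_x, shape=(h, w))


def _clover_footprint(
    h: int, w: int, params: SwardParams, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel rows/cols of one trifoliate clover: a union of round lobes."""
    radius = rng.integers(params.clover_radius[0], params.clover_radius[1] + 1)
    cy, cx = rng.uniform(0, h), rng.uniform(0, w)
    phase = rng.uniform(0, 2 * np.pi)
    rows, cols = [], []
    for k in range(params.clover_lobes):
        ang = phase + 2 * np.pi * k / params.clover_lobes
        ly = cy + 0.9 * radius * np.sin(ang)
        lx = cx + 0.9 * radius * np.cos(ang)
        rr, cc = skdraw.disk((ly, lx), radius, shape=(h, w))
        rows.append(rr)
        cols.append(cc)
    rr = np.concatenate(rows)
    cc = np.concatenate(cols)
    flat = np.unique(rr.astype(np.int64) * w + cc.astype(np.int64))
    return flat // w, flat % w


def generate_plot(
    params: SwardParams,
    plot_id: str = "synthetic",
    group_id: str = "",
    cultivar: str = "",
    scored: dict[str, float] | None = None,
) -> PlotRecord:
    """Render one synthetic plot and its exact category maps.

    Deterministic for a fixed ``params.seed``.  Raises on images smaller
    than 256x256 or on infeasible targets (vegetation targets summing
    above 1).
    """
    h, w = params.height, params.width
    if h < 256 or w < 256:
        raise ValueError(f"plot must be at least 256x256, got {w}x{h}")
    targets = dict(params.target_coverage)
    veg_cats = [c for c in targets if c != "Bg"]
    for cat, t in targets.items():
        if not 0.0 <= t <= 1.0:
            raise ValueError(f"target coverage {cat}={t} outside [0, 1]")
    veg_sum = sum(targets[c] for c in veg_cats)
    if veg_sum > 1.0:
        raise ValueError(
            f"infeasible targets: vegetation coverages sum to {veg_sum:.2f} > 1"
        )

    rng = np.random.default_rng(params.seed)
    image = _background(h, w, rng)
    owner = np.zeros((h, w), dtype=np.uint8)
    total = h * w
    counts = np.zeros(4, dtype=np.int64)  # by owner code
    counts[_BG] = total

    def deficit(cat: str) -> float:
        code = _TY if cat == "TY" else _WC
        return targets.get(cat, 0.0) - counts[code] / total

    max_organs = 2_000_000
    for _ in range(max_organs):
        cat = max(veg_cats, key=deficit, default=None)
        if cat is None or deficit(cat) <= 0:
            break
        if cat == "TY":
            rr, cc = _grass_footprint(h, w, params, rng)
            withered = rng.random() < params.withered_fraction
            color = _WITHERED_COLOR if withered else _GRASS_COLOR
            code = _TY if (not withered or params.paint_withered) else _WITHERED
        else:
            rr, cc = _clover_footprint(h, w, params, rng)
            color = _CLOVER_COLOR
            code = _WC
        if rr.size == 0:
            continue
        counts -= np.bincount(owner[rr, cc], minlength=4)
        owner[rr, cc] = code
        counts[code] += rr.size
        jitter = rng.normal(0.0, 8.0, size=3)
        image[rr, cc] = np.clip(color + jitter, 0, 255).astype(np.uint8)
    else:  # pragma: no cover - organ budget guard
        raise RuntimeError("organ budget exhausted before reaching target coverage")

    maps = {
        "TY": (owner == _TY).astype(np.uint8),
        "WC": (owner == _WC).astype(np.uint8),
        # background is everything not painted as a vegetation category
        "Bg": ((owner != _TY) & (owner != _WC)).astype(np.uint8),
    }
    for cat in veg_cats:
        achieved = counts[_TY if cat == "TY" else _WC] / total
        assert abs(achieved - targets[cat]) <= COVERAGE_TOLERANCE, (
            f"{cat}: achieved {achieved:.4f} vs target {targets[cat]:.4f}"
        )
    return PlotRecord(
        plot_id=plot_id,
        group_id=group_id,
        cultivar=cultivar,
        image=image,
        maps=maps,
        scored=dict(scored or {}),
    )


# ---------------------------------------------------------------------------
# Twelve-plot study layout
# ---------------------------------------------------------------------------

#: Within each group, the three plots span low / mid / high legume coverage
#: so that single-plot vs. group training comparisons are meaningful.
_WC_LEVELS = (0.08, 0.18, 0.32)
_TY_LEVELS = (0.44, 0.40, 0.36)
_CULTIVARS = ("Cultivar A", "Cultivar B", "Cultivar C")


@dataclass(frozen=True)
class StudyPlotSpec:
    plot_id: str
    group_id: str
    cultivar: str
    target_ty: float
    target_wc: float


def default_layout() -> list[StudyPlotSpec]:
    """Twelve plots in four groups of three (plot ``r-g`` sits in group g);
    replicate r = 1, 2, 3 carries low, mid, high white-clover coverage."""
    specs = []
    for g in range(1, 5):
        for r in range(1, 4):
            specs.append(
                StudyPlotSpec(
                    plot_id=f"plot {r}-{g}",
                    group_id=f"group {g}",
                    cultivar=_CULTIVARS[(r + g) % 3],
                    target_ty=_TY_LEVELS[r - 1],
                    target_wc=_WC_LEVELS[r - 1],
                )
            )
    return specs


def _synthetic_score(achieved_pct: float, rng: np.random.Generator) -> float:
    """Emulated breeder score: coverage plus visual error, in 5-point steps."""
    noisy = achieved_pct + rng.normal(0.0, 6.0)
    return float(np.clip(5 * round(noisy / 5), 0, 100))


def generate_study(
    layout: Sequence[StudyPlotSpec] | None = None,
    width: int = 640,
    height: int = 960,
    seed: int = 0,
    withered_fraction: float = 0.0,
    paint_withered: bool = True,
) -> list[PlotRecord]:
    """Generate the full synthetic study: 12 plots in 4 groups of 3.

    Plot size defaults to a desk-scale 640x960; pass the study-scale
    2000x3000 for full-size plots.  Each plot also receives an emulated
    breeder score per category.  Deterministic for a fixed seed.
    """
    layout = list(layout) if layout is not None else default_layout()
    ids = [s.plot_id for s in layout]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate plot ids in layout")
    root = np.random.SeedSequence(seed)
    records = []
    for spec, child in zip(layout, root.spawn(len(layout))):
        plot_seed = int(child.generate_state(1)[0] % (2**31))
        params = SwardParams(
            width=width,
            height=height,
            target_coverage={"TY": spec.target_ty, "WC": spec.target_wc},
            withered_fraction=withered_fraction,
            paint_withered=paint_withered,
            seed=plot_seed,
        )
        rec = generate_plot(params, spec.plot_id, spec.group_id, spec.cultivar)
        score_rng = np.random.default_rng(plot_seed + 1)
        scored = {}
        for cat in ("TY", "WC", "Bg"):
            pct = 100.0 * rec.maps[cat].mean()
            scored[cat] = _synthetic_score(pct, score_rng)
        rec.scored = scored
        records.append(rec)
    return records


def study_manifest(records: Sequence[PlotRecord]) -> pd.DataFrame:
    """Dataset manifest in the study's shape: one row per trainable dataset,
    12 single-plot rows plus one row per group (16 in the canonical layout)."""
    rows = [
        {
            "dataset": f"plot {r.plot_id.split()[-1]}" if r.plot_id.startswith("plot") else r.plot_id,
            "plots": r.plot_id,
            "n_training": TRAIN_PATCHES_PER_PLOT,
        }
        for r in records
    ]
    groups: dict[str, list[str]] = {}
    for r in records:
        if r.group_id:
            groups.setdefault(r.group_id, []).append(r.plot_id)
    for gid, plots in groups.items():
        rows.append(
            {
                "dataset": gid,
                "plots": ",".join(plots),
                "n_training": TRAIN_PATCHES_PER_PLOT * len(plots),
            }
        )
    return pd.DataFrame(rows)
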