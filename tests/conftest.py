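"""Shared fixtures: synthetic plots and studies used across the suite."""

import numpy as np
import pytest

import swardcover as sc


@pytest.fixture(scope="session")
def small_plot() -> sc.PlotRecord:
    """One 512x512 synthetic plot with mid-range coverage."""
    params = sc.SwardParams(
        width=512, height=512, target_coverage={"TY": 0.35, "WC": 0.20}, seed=5
    )
    return sc.generate_plot(params, "small", group_id="g", cultivar="Cultivar A")


@pytest.fixture(scope="session")
def study() -> list[sc.PlotRecord]:
    """The 12-plot synthetic study at its desk-scale default size."""
    return sc.generate_study(seed=42)


@pytest.fixture(scope="session")
def study_by_id(study) -> dict[str, sc.PlotRecord]:
    return {r.plot_id: r for r in study}


def make_separable_dataset(
    n_per_class: int, seed: int, category: str = "WC"
) -> sc.PatchDataset:
    """Solid-colour patches mapped to classes 0 / 50 / 100: linearly separable.

    Green, white and brown textures stand in for no-coverage, half-coverage
    and full-coverage patches of the category.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    colors = {0: (60, 120, 50), 50: (235, 235, 235), 100: (130, 90, 55)}
    images, rows = [], []
    for value, rgb in colors.items():
        for _ in range(n_per_class):
            patch = np.full((64, 64, 3), rgb, dtype=np.float64)
            patch += rng.normal(0, 6, patch.shape)
            images.append(np.clip(patch, 0, 255).astype(np.uint8))
            rows.append(
                {
                    "plot_id": "synthetic",
                    "x0": 0,
                    "y0": 0,
                    f"rp_{category}": value / 100,
                    f"class_{category}": value,
                }
            )
    return sc.PatchDataset(
        np.stack(images), pd.DataFrame(rows), (category,), ("synthetic",)
    )
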