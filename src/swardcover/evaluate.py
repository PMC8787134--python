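"""Model evaluation: tiling prediction, MBE/MAE, cross-evaluation, correlations.

One *one-model-to-one-plot prediction* tiles a plot into non-overlapping
64x64 pieces, predicts each piece's coverage class value and compares it with
the observed class value measured on the category map (same binning as the
training labels).  Per plot the mean bias error and mean absolute error are

    MBE = (1/n) * sum_j (P_j - O_j)        MAE = (1/n) * sum_j |P_j - O_j|

over the n pieces, with P_j the predicted and O_j the observed class value.
Across plots, a model is summarized by the mean of its MBEs (MMBE) and MAEs
(MMAE) over the N evaluation plots, excluding every plot used to train it.

Averaging the predicted class values of all pieces of a plot gives the
model's *estimated coverage* of the plot, which is correlated against the
breeder-scored and the map-measured coverage (Pearson r), again leaving the
model's training plots out.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import PlotRecord, measured_coverage
from .patches import PATCH_SIDE, tile_evaluation_patches, extract_patch
from .train import ModelSpec, predict_class_value


def mbe(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Mean bias error: positive when the model over-estimates."""
    p, o = np.asarray(predicted, float), np.asarray(observed, float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if p.size == 0:
        raise ValueError("empty prediction vectors")
    return float(np.mean(p - o))


def mae(predicted: Sequence[float], observed: Sequence[float]) -> float:
    """Mean absolute error: magnitude of the per-piece prediction error."""
    p, o = np.asarray(predicted, float), np.asarray(observed, float)
    if p.shape != o.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {o.shape}")
    if p.size == 0:
        raise ValueError("empty prediction vectors")
    return float(np.mean(np.abs(p - o)))


@dataclass
class EvalCell:
    """One one-model-to-one-plot prediction."""

    model_name: str
    plot_id: str
    n: int
    mbe: float
    mae: float
    used_in_training: bool


@dataclass
class ModelSummary:
    """MMBE/MMAE of a model over its N non-training evaluation plots."""

    model_name: str
    N: int
    mmbe: float
    mmae: float


@dataclass
class CoverageTriple:
    """Scored / measured / estimated coverage of one plot for one category."""

    plot_id: str
    category: str
    measured: float
    scored: float | None = None
    estimated: float | None = None


@dataclass
class OracleModel:
    """Reference "model" that looks up each piece's true class value.

    Its prediction error against the observed class values is zero by
    construction, so it isolates the error contributed by tiling, binning and
    averaging alone: its estimated plot coverage can deviate from the measured
    coverage only by the class-bin half-width (2.5 points) over the tiled
    extent.  Used as the upper-bound reference in evaluation tests.
    """

    category: str
    name: str = ""
    training_plots: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            self.name = f"{self.category}-oracle"


AnyModel = ModelSpec | OracleModel


def predict_plot(
    spec: AnyModel, record: PlotRecord, side: int = PATCH_SIDE
) -> tuple[np.ndarray, np.ndarray]:
    """(predicted, observed) class-value vectors over the plot's full tiling."""
    pieces = tile_evaluation_patches(record, side)
    observed = np.array([p.class_value[spec.category] for p in pieces], float)
    if isinstance(spec, OracleModel):
        return observed.copy(), observed
    patches = np.stack([extract_patch(record.image, p.window) for p in pieces])
    predicted = predict_class_value(spec, patches).astype(float)
    return predicted, observed


def evaluate_model_on_plot(
    spec: AnyModel, record: PlotRecord, side: int = PATCH_SIDE
) -> EvalCell:
    predicted, observed = predict_plot(spec, record, side)
    return EvalCell(
        model_name=spec.name,
        plot_id=record.plot_id,
        n=len(predicted),
        mbe=mbe(predicted, observed),
        mae=mae(predicted, observed),
        used_in_training=record.plot_id in spec.training_plots,
    )


def estimate_plot_coverage(
    spec: AnyModel, record: PlotRecord, side: int = PATCH_SIDE
) -> float:
    """Estimated coverage percent: mean predicted class value over the full
    non-overlapping tiling (validation strip included)."""
    predicted, _ = predict_plot(spec, record, side)
    return float(predicted.mean())


def cross_evaluate(
    models: Sequence[AnyModel],
    records: Sequence[PlotRecord],
    side: int = PATCH_SIDE,
) -> tuple[list[EvalCell], list[ModelSummary]]:
    """Every model x plot cell plus per-model MMBE/MMAE summaries.

    Cells for plots in a model's training set are computed and flagged but
    excluded from that model's summary.  A model whose training set covers
    every record has no evaluation plots (N = 0) and is an error.
    """
    if not models:
        raise ValueError("no models given")
    if len(records) < 2:
        raise ValueError("cross-evaluation needs at least two plots")
    cells: list[EvalCell] = []
    summaries: list[ModelSummary] = []
    for spec in models:
        model_cells = [evaluate_model_on_plot(spec, rec, side) for rec in records]
        cells.extend(model_cells)
        kept = [c for c in model_cells if not c.used_in_training]
        if not kept:
            raise ValueError(
                f"model {spec.name!r} was trained on every given plot (N = 0)"
            )
        summaries.append(
            ModelSummary(
                model_name=spec.name,
                N=len(kept),
                mmbe=float(np.mean([c.mbe for c in kept])),
                mmae=float(np.mean([c.mae for c in kept])),
            )
        )
    return cells, summaries


def build_coverage_triples(
    spec: AnyModel, records: Sequence[PlotRecord], side: int = PATCH_SIDE
) -> list[CoverageTriple]:
    """Scored/measured/estimated coverage of every plot for the model's category."""
    cat = spec.category
    return [
        CoverageTriple(
            plot_id=rec.plot_id,
            category=cat,
            measured=measured_coverage(rec, cat),
            scored=rec.scored.get(cat),
            estimated=estimate_plot_coverage(spec, rec, side),
        )
        for rec in records
    ]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if len(x) < 3:
        raise ValueError(f"need at least 3 plots for a correlation, got {len(x)}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined: zero variance in one variable")
    return float(stats.pearsonr(x, y).statistic)


def correlate_triples(
    triples: Sequence[CoverageTriple],
    model: ModelSpec | None = None,
) -> dict[str, float]:
    """Pearson r of the three coverage pairings over the retained plots.

    Keys: ``scored_measured``, ``measured_estimated``, ``scored_estimated``.
    When a model is given, its training plots are excluded from every pairing
    (including scored vs. measured, which therefore differs between models).
    Pairings whose variables are absent are left out of the result.
    """
    excluded = set(model.training_plots) if model is not None else set()
    kept = [t for t in triples if t.plot_id not in excluded]
    if len(kept) < 3:
        raise ValueError(
            f"only {len(kept)} plots left after excluding training plots; need >= 3"
        )
    out: dict[str, float] = {}
    scored = np.array([np.nan if t.scored is None else t.scored for t in kept])
    meas = np.array([t.measured for t in kept], float)
    est = np.array([np.nan if t.estimated is None else t.estimated for t in kept])
    if not np.isnan(scored).any():
        out["scored_measured"] = _pearson(scored, meas)
    if not np.isnan(est).any():
        out["measured_estimated"] = _pearson(meas, est)
    if not (np.isnan(scored).any() or np.isnan(est).any()):
        out["scored_estimated"] = _pearson(scored, est)
    return out


# ---------------------------------------------------------------------------
# Tabular export / import
# ---------------------------------------------------------------------------

def cells_to_frame(cells: Sequence[EvalCell], category_by_model: Mapping[str, str] | None = None) -> pd.DataFrame:
    rows = []
    for c in cells:
        cat = category_by_model.get(c.model_name, "") if category_by_model else c.model_name.split("-")[0]
        rows.append(
            {
                "model": c.model_name,
                "plot": c.plot_id,
                "category": cat,
                "n": c.n,
                "MBE": c.mbe,
                "MAE": c.mae,
                "used_in_training": c.used_in_training,
            }
        )
    return pd.DataFrame(rows)


def frame_to_cells(df: pd.DataFrame) -> list[EvalCell]:
    return [
        EvalCell(
            model_name=str(r["model"]),
            plot_id=str(r["plot"]),
            n=int(r["n"]),
            mbe=float(r["MBE"]),
            mae=float(r["MAE"]),
            used_in_training=bool(r["used_in_training"]),
        )
        for _, r in df.iterrows()
    ]


def summaries_to_frame(summaries: Sequence[ModelSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"model": s.model_name, "N": s.N, "MMBE": s.mmbe, "MMAE": s.mmae}
            for s in summaries
        ]
    )
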