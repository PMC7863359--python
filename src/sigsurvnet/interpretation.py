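"""Smoothgrad relevance of signaling pathways and density summaries.

For each patient, the relevance of pathway p is the smoothgrad estimate of
the gradient of the predicted survival time with respect to the pathway-
layer activation p: the gradient is averaged over ``n_noise_samples``
replicates in which i.i.d. Gaussian noise is added to the pathway
activations.  The noise standard deviation follows the input-range rule

    noise_scale = (max(input) - min(input)) * 0.1

applied to the pathway-activation matrix over the whole dataset.  Pooled
per-pathway score distributions are summarized by Gaussian kernel density
estimation (Scott's rule) and pathways are ranked by mean absolute
relevance; pathways whose scores straddle zero with large spread are
flagged separately, since a density plot would show them as wide,
zero-centred humps rather than consistently signed relevance.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .model import DeepSigSurvNet
from .pathway_data import OmicsDataset

logger = logging.getLogger(__name__)


@dataclass
class RelevanceMatrix:
    """Per-sample, per-pathway smoothgrad relevance scores (days per unit
    activation)."""

    scores: pd.DataFrame  # samples x pathways
    n_noise_samples: int
    noise_scale: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.scores.to_numpy()).all():
            raise ValueError("relevance scores must be finite")

    @property
    def pathway_index(self) -> tuple[str, ...]:
        return tuple(self.scores.columns)


@dataclass
class PathwayDensity:
    """KDE of one pathway's pooled relevance scores."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float
    point_mass: bool = False
    point_mass_at: float = float("nan")


@dataclass
class DensitySummary:
    """Per-pathway densities plus location/spread statistics."""

    densities: dict[str, PathwayDensity]
    stats: pd.DataFrame = field(default_factory=pd.DataFrame)
    # stats columns: mean, sd, mean_abs (index = pathway names)


def noise_scale(input_matrix) -> float:
    """Smoothgrad noise standard deviation: (max - min) * 0.1 over all
    entries.  A constant matrix yields 0 with a warning (degenerate noise)."""
    values = np.asarray(input_matrix, dtype=float)
    if values.size == 0 or not np.isfinite(values).all():
        raise ValueError("input matrix must be non-empty and finite")
    span = float(values.max() - values.min())
    if span == 0.0:
        warnings.warn("constant input: smoothgrad noise scale is 0", stacklevel=2)
    return span * 0.1


def smoothgrad_relevance(model: DeepSigSurvNet, dataset: OmicsDataset,
                         n_noise_samples: int = 50, seed: int = 0,
                         scale: float | None = None) -> RelevanceMatrix:
    """Smoothgrad relevance of every pathway for every sample.

    ``scale`` overrides the input-range noise standard deviation (useful for
    the zero-noise limit, where one replicate reproduces the plain
    gradient).  Seeded and reproducible.
    """
    if n_noise_samples < 1:
        raise ValueError("n_noise_samples must be >= 1")
    if not hasattr(model, "training_log_"):
        raise ValueError("model must be fitted before attribution")
    X = dataset.features(model.include_vital_status)
    activations = model.pathway_activations(X)
    clin = model.clinical_block(X)
    sd = noise_scale(activations) if scale is None else float(scale)

    rng = np.random.default_rng(seed)
    total = np.zeros_like(activations)
    for _ in range(n_noise_samples):
        noisy = activations + rng.normal(0.0, sd, size=activations.shape) if sd > 0 \
            else activations
        total += model.gradient_wrt_pathways(noisy, clin)
    scores = total / n_noise_samples

    names = (model.mask.pathway_index if hasattr(model.mask, "pathway_index")
             else [f"P{j + 1}" for j in range(scores.shape[1])])
    return RelevanceMatrix(
        scores=pd.DataFrame(scores, index=dataset.expression.index, columns=list(names)),
        n_noise_samples=n_noise_samples,
        noise_scale=sd,
    )


def density_summary(relevance: RelevanceMatrix, grid_points: int = 512) -> DensitySummary:
    """Gaussian-KDE density of each pathway's pooled scores, with Scott's
    bandwidth, on a grid spanning [min - 3*bw, max + 3*bw].

    Zero-variance columns are flagged as point masses (and logged) rather
    than smoothed.
    """
    values = relevance.scores
    if len(values) < 2:
        raise ValueError("need at least 2 samples for density estimation")
    densities: dict[str, PathwayDensity] = {}
    rows = []
    for name in values.columns:
        col = values[name].to_numpy(dtype=float)
        mean, sd = float(col.mean()), float(col.std(ddof=1))
        rows.append({"pathway": name, "mean": mean, "sd": sd,
                     "mean_abs": float(np.abs(col).mean())})
        if sd == 0.0:
            logger.info("pathway %s has zero-variance relevance: point mass at %g",
                        name, col[0])
            densities[name] = PathwayDensity(
                grid=np.array([col[0]]), density=np.array([np.inf]),
                bandwidth=0.0, point_mass=True, point_mass_at=float(col[0]))
            continue
        kde = gaussian_kde(col, bw_method="scott")
        bw = float(kde.factor * sd)
        grid = np.linspace(col.min() - 3 * bw, col.max() + 3 * bw, grid_points)
        densities[name] = PathwayDensity(grid=grid, density=kde(grid), bandwidth=bw)
    stats = pd.DataFrame(rows).set_index("pathway")
    return DensitySummary(densities=densities, stats=stats)


def rank_pathways(summary: DensitySummary,
                  high_variance_fraction: float = 0.25) -> pd.DataFrame:
    """Pathways ordered by descending mean absolute relevance (ties by name).

    ``high_variance_zero_mean`` flags pathways with |mean| below
    ``high_variance_fraction`` of their standard deviation — scores that
    straddle zero with large spread, whose sign is therefore inconsistent
    across patients.
    """
    stats = summary.stats.copy()
    stats.index.name = "pathway"
    stats["high_variance_zero_mean"] = (
        stats["mean"].abs() < high_variance_fraction * stats["sd"]
    )
    # stable sort: alphabetical first, then by score, so ties break by name
    ranked = stats.sort_index(kind="mergesort").sort_values(
        "mean_abs", ascending=False, kind="mergesort")
    ranked = ranked.reset_index()
    ranked.insert(0, "rank", np.arange(1, len(ranked) + 1))
    return ranked


def write_relevance(relevance: RelevanceMatrix, path) -> None:
    relevance.scores.to_csv(path, sep="\t", float_format="%.10g")


def summary_to_json(summary: DensitySummary) -> dict:
    """JSON-serializable form of a density summary."""
    out = {"stats": summary.stats.reset_index().to_dict(orient="records"),
           "densities": {}}
    for name, d in summary.densities.items():
        out["densities"][name] = {
            "bandwidth": d.bandwidth,
            "point_mass": d.point_mass,
            "point_mass_at": None if np.isnan(d.point_mass_at) else d.point_mass_at,
            "grid": [float(v) for v in d.grid] if not d.point_mass else [float(d.grid[0])],
            "density": [float(v) for v in d.density] if not d.point_mass else None,
        }
    return out


def plot_densities(summary: DensitySummary, path,
                   pathways: Sequence[str] | None = None) -> None:
    """Overlaid per-pathway relevance densities, written as an image file.

    Requires matplotlib (optional dependency).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = list(pathways) if pathways is not None else list(summary.densities)
    fig, ax = plt.subplots(figsize=(9, 6))
    for name in names:
        d = summary.densities[name]
        if d.point_mass:
            ax.axvline(d.point_mass_at, linestyle="--", alpha=0.6, label=f"{name} (point mass)")
        else:
            ax.plot(d.grid, d.density, alpha=0.7, label=name)
    ax.set_xlabel("relevance score (days per unit pathway activation)")
    ax.set_ylabel("density")
    if len(names) <= 12:
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
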