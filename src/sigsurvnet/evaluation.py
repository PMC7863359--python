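"""Concordance-index evaluation, data splits, the random-forest baseline and
the repeated-subsampling experiment protocols.

The concordance index (c-index) is the probability that, of two patients
with different true survival times, the one predicted to survive longer
actually does.  With C concordant, D discordant and T prediction-tied pairs,

    c-index = (C + T/2) / (C + D + T).

Pairs whose *true* times are equal carry no ordering information and are
excluded by default (``tied_truth="exclude"``); ``tied_truth="count"``
instead counts them into T, the alternative reading of "equal survival
times".  Censoring plays no role in pair eligibility here: vital status
enters the model as a covariate, not the metric.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pathway_data import ConnectionMask, OmicsDataset

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CIndexResult:
    """Concordant/discordant/tied pair counts and the concordance value."""

    concordant: int
    discordant: int
    tied: int

    @property
    def n_pairs(self) -> int:
        return self.concordant + self.discordant + self.tied

    @property
    def value(self) -> float:
        return (self.concordant + 0.5 * self.tied) / self.n_pairs

    def __float__(self) -> float:
        return self.value


def concordance_index(true_times: Sequence[float], predicted: Sequence[float],
                      tied_truth: str = "exclude") -> CIndexResult:
    """C-index of ``predicted`` against ``true_times`` over all sample pairs.

    Raises ``ValueError`` if fewer than 2 samples, non-finite values, or no
    evaluable pair exists (all true times equal under the default reading).
    """
    t = np.asarray(true_times, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if t.shape != p.shape or t.ndim != 1:
        raise ValueError("true and predicted must be 1-D of equal length")
    if len(t) < 2:
        raise ValueError("need at least 2 samples")
    if not (np.isfinite(t).all() and np.isfinite(p).all()):
        raise ValueError("non-finite survival times or predictions")
    if tied_truth not in ("exclude", "count"):
        raise ValueError("tied_truth must be 'exclude' or 'count'")

    dt = np.sign(t[:, None] - t[None, :])
    dp = np.sign(p[:, None] - p[None, :])
    upper = np.triu(np.ones_like(dt, dtype=bool), k=1)

    distinct = upper & (dt != 0)
    concordant = int(np.count_nonzero(distinct & (dp == dt)))
    discordant = int(np.count_nonzero(distinct & (dp == -dt)))
    tied = int(np.count_nonzero(distinct & (dp == 0)))
    if tied_truth == "count":
        tied += int(np.count_nonzero(upper & (dt == 0)))
    if concordant + discordant + tied == 0:
        raise ValueError("no evaluable pairs: all true survival times are equal")
    return CIndexResult(concordant=concordant, discordant=discordant, tied=tied)


def split_samples(n: int, train_fraction: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Uniform random partition of ``range(n)`` into train/test index arrays.

    Train size is ``round(n * train_fraction)``; both parts must be
    non-empty.  Reproducible for a fixed seed.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = int(round(n * train_fraction))
    if n_train == 0 or n_train == n:
        raise ValueError(f"train_fraction {train_fraction} leaves an empty partition for n={n}")
    perm = np.random.default_rng(seed).permutation(n)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def tree_baseline(dataset: OmicsDataset, split: tuple[np.ndarray, np.ndarray],
                  n_estimators: int = 40, max_depth: int = 7,
                  include_vital_status: bool = True,
                  seed: int = 0) -> tuple[CIndexResult, CIndexResult]:
    """Random-forest regression of survival days on the same flattened
    feature block the network sees (expression + copy number + clinical).

    Returns (train, test) c-index results.
    """
    from sklearn.ensemble import RandomForestRegressor

    train_idx, test_idx = split
    X = dataset.features(include_vital_status)
    y = dataset.survival_days.to_numpy(dtype=float)
    if np.ptp(y[train_idx]) == 0:
        raise ValueError("degenerate training targets: all survival times equal")
    forest = RandomForestRegressor(n_estimators=n_estimators, max_depth=max_depth,
                                   random_state=seed)
    forest.fit(X[train_idx], y[train_idx])
    return (
        concordance_index(y[train_idx], forest.predict(X[train_idx])),
        concordance_index(y[test_idx], forest.predict(X[test_idx])),
    )


@dataclass
class ExperimentReport:
    """Per-repetition c-index records of a repeated-subsampling experiment.

    ``records`` has one row per (cell, repetition, method) with the seed
    used, the train c-index at the checkpointed epoch and the held-out
    c-index; ``means()`` re-aggregates them, so printed means are always the
    arithmetic mean of the stored rows.
    """

    design: str
    settings: dict = field(default_factory=dict)
    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    def means(self) -> pd.DataFrame:
        return (self.records
                .groupby(["cell", "method"], sort=True)[["train_cindex", "test_cindex"]]
                .mean()
                .reset_index())

    def to_files(self, records_path, summary_path) -> None:
        import json
        from pathlib import Path
        self.records.to_csv(records_path, sep="\t", index=False)
        summary = {
            "design": self.design,
            "settings": self.settings,
            "means": self.means().to_dict(orient="records"),
        }
        Path(summary_path).write_text(json.dumps(summary, indent=2))


def _cell_seeds(master_seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(master_seed)
    return [int(s) for s in rng.integers(0, 2 ** 31 - 1, size=n)]


def _run_survnet_cell(dataset, mask, split, epochs, seed, model_kwargs):
    from .model import DeepSigSurvNet, train as train_model

    kwargs = dict(model_kwargs or {})
    kwargs.setdefault("dense_units", 32)
    est = DeepSigSurvNet(mask=mask, epochs=epochs, random_state=seed, **kwargs)
    train_model(est, dataset, split)
    log = est.training_log_
    at_best = log.loc[log["epoch"] == est.best_epoch_].iloc[0]
    return float(at_best["train_cindex"]), float(est.best_test_cindex_)


def ratio_sweep_experiment(dataset: OmicsDataset, mask: ConnectionMask,
                           ratios: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9),
                           reps: int = 10, epochs: int = 25,
                           methods: Sequence[str] = ("survnet", "random_forest"),
                           seed: int = 0, model_kwargs: dict | None = None,
                           rf_kwargs: dict | None = None) -> ExperimentReport:
    """Repeated random subsampling at several training fractions.

    For each ratio x repetition a fresh seeded split is drawn, every method
    is trained on it and its train/held-out c-index recorded.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    cells = [(r, k) for r in ratios for k in range(reps)]
    seeds = _cell_seeds(seed, len(cells))
    rows = []
    for (ratio, rep), cell_seed in zip(cells, seeds):
        split = split_samples(dataset.n_samples, ratio, cell_seed)
        for method in methods:
            if method == "survnet":
                tr, te = _run_survnet_cell(dataset, mask, split, epochs, cell_seed, model_kwargs)
            elif method == "random_forest":
                res_tr, res_te = tree_baseline(dataset, split, seed=cell_seed,
                                               **(rf_kwargs or {}))
                tr, te = res_tr.value, res_te.value
            else:
                raise ValueError(f"unknown method {method!r}")
            rows.append({"cell": ratio, "rep": rep, "seed": cell_seed, "method": method,
                         "train_cindex": tr, "test_cindex": te})
        logger.info("ratio %.2f rep %d done", ratio, rep)
    return ExperimentReport(
        design="ratio_sweep",
        settings={"ratios": list(ratios), "reps": reps, "epochs": epochs,
                  "seed": seed, "methods": list(methods)},
        records=pd.DataFrame(rows),
    )


def restrict_to_pathways(dataset: OmicsDataset, mask: ConnectionMask,
                         pathway_indices: Sequence[int]) -> tuple[OmicsDataset, ConnectionMask]:
    """Restrict dataset and mask to the pathways at ``pathway_indices`` and
    the genes belonging to at least one of them."""
    cols = list(pathway_indices)
    sub = mask.matrix[:, cols]
    keep_rows = np.flatnonzero(sub.sum(axis=1) > 0)
    if keep_rows.size == 0:
        raise ValueError("pathway subset retains no genes")
    genes = [mask.gene_index[g] for g in keep_rows]
    sub_mask = ConnectionMask(
        matrix=sub[keep_rows],
        gene_index=tuple(genes),
        pathway_index=tuple(mask.pathway_index[p] for p in cols),
    )
    sub_dataset = OmicsDataset(
        expression=dataset.expression[genes],
        copy_number=dataset.copy_number[genes],
        clinical=dataset.clinical,
        survival_days=dataset.survival_days,
        exclusions=dict(dataset.exclusions),
    )
    return sub_dataset, sub_mask


def pathway_subset_experiment(dataset: OmicsDataset, mask: ConnectionMask,
                              subset_sizes: Sequence[int] = (10, 20, 30, 40),
                              reps: int = 10, epochs: int = 25,
                              train_fraction: float = 0.8,
                              methods: Sequence[str] = ("survnet",),
                              seed: int = 0,
                              model_kwargs: dict | None = None,
                              rf_kwargs: dict | None = None) -> ExperimentReport:
    """Repeated training on randomly chosen pathway subsets.

    Per repetition, ``size`` pathways are sampled uniformly, the mask is
    rebuilt on their member genes, the model retrained on a fresh 80/20
    split, and c-index recorded.  A subset retaining no genes is skipped and
    logged.
    """
    if any(s > mask.n_pathways for s in subset_sizes):
        raise ValueError("subset size exceeds number of pathways")
    cells = [(s, k) for s in subset_sizes for k in range(reps)]
    seeds = _cell_seeds(seed, len(cells))
    rows = []
    for (size, rep), cell_seed in zip(cells, seeds):
        rng = np.random.default_rng(cell_seed)
        chosen = np.sort(rng.choice(mask.n_pathways, size=size, replace=False))
        try:
            sub_data, sub_mask = restrict_to_pathways(dataset, mask, chosen)
        except ValueError:
            logger.warning("subset size %d rep %d retains no genes; skipped", size, rep)
            continue
        split = split_samples(sub_data.n_samples, train_fraction, cell_seed)
        for method in methods:
            if method == "survnet":
                tr, te = _run_survnet_cell(sub_data, sub_mask, split, epochs,
                                           cell_seed, model_kwargs)
            elif method == "random_forest":
                res_tr, res_te = tree_baseline(sub_data, split, seed=cell_seed,
                                               **(rf_kwargs or {}))
                tr, te = res_tr.value, res_te.value
            else:
                raise ValueError(f"unknown method {method!r}")
            rows.append({"cell": size, "rep": rep, "seed": cell_seed, "method": method,
                         "train_cindex": tr, "test_cindex": te})
        logger.info("subset size %d rep %d done", size, rep)
    return ExperimentReport(
        design="pathway_subset",
        settings={"subset_sizes": list(subset_sizes), "reps": reps, "epochs": epochs,
                  "train_fraction": train_fraction, "seed": seed,
                  "methods": list(methods)},
        records=pd.DataFrame(rows),
    )
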