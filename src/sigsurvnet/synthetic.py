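"""Synthetic multi-omics survival data with known pathway-level ground truth.

A linear-Gaussian generative model, chosen for analytical transparency:

* each sample draws one latent activity per pathway, i.i.d. standard normal;
* a gene's expression is the loading-weighted sum of the activities of the
  pathway(s) it belongs to plus Gaussian noise, shifted to be non-negative
  (log-scale-like values);
* copy number is an integer in [-2, 2]; with probability ``cnv_coupling`` a
  gene's calls track its pathway activity, otherwise they are pure noise;
* uncensored survival (days) is a baseline plus the effect-weighted sum of
  the *causal* pathway activities, small fixed age/stage effects, and
  Gaussian noise, clipped to [1, 3000];
* a ``censor_fraction`` of samples is censored uniformly below their event
  time (uninformative censoring); vital status records event vs censored.

Outputs are written in exactly the TSV/GMT dialects that
:mod:`sigsurvnet.pathway_data` reads, alongside a JSON manifest with the
spec and the latent truth, so recovery of the causal pathways can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ._names import SIGNALING_PATHWAYS_46
from .pathway_data import PathwayCollection

#: fixed clinical coefficients (days per unit), deliberately small relative
#: to the default pathway effects so relevance recovery is attributable to
#: the pathways
AGE_COEF_DAYS_PER_YEAR = -5.0
STAGE_COEF_DAYS_PER_STAGE = -100.0

SURVIVAL_MIN_DAYS = 1
SURVIVAL_MAX_DAYS = 3000


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generator; defaults emulate a cohort of the scale
    the method targets (hundreds of samples, ~1800 genes in 46 pathways)."""

    n_samples: int = 400
    n_pathways: int = 46
    genes_per_pathway: int = 43
    overlap_fraction: float = 0.1
    causal_pathways: tuple[int, ...] = (2, 11, 21, 26, 35)
    effect_sizes: tuple[float, ...] = (300.0, -300.0, 300.0, -300.0, 300.0)
    noise_sd_expression: float = 1.0
    noise_sd_survival: float = 200.0
    cnv_coupling: float = 0.3
    censor_fraction: float = 0.2
    baseline_days: float = 1500.0
    seed: int = 0
    zero_genes: tuple[str, ...] = ()
    n_over_cap: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_pathways", "genes_per_pathway"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.censor_fraction < 1.0:
            raise ValueError("censor_fraction must be in [0, 1)")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if not 0.0 <= self.cnv_coupling <= 1.0:
            raise ValueError("cnv_coupling must be in [0, 1]")
        if len(self.causal_pathways) != len(self.effect_sizes):
            raise ValueError("causal_pathways and effect_sizes must align")
        if any(not 0 <= p < self.n_pathways for p in self.causal_pathways):
            raise ValueError("causal pathway index out of range")
        if len(set(self.causal_pathways)) != len(self.causal_pathways):
            raise ValueError("duplicate causal pathway indices")
        if self.noise_sd_expression < 0 or self.noise_sd_survival < 0:
            raise ValueError("noise standard deviations must be non-negative")
        if self.n_over_cap < 0 or self.n_over_cap > self.n_samples:
            raise ValueError("n_over_cap must be in [0, n_samples]")


@dataclass
class SyntheticTruth:
    """Latent ground truth emitted next to the observable files."""

    pathway_activity: pd.DataFrame  # samples x pathways
    causal_pathways: tuple[int, ...]
    effect_sizes: dict[int, float]
    uncensored_survival: pd.Series  # days, before censoring/cap injection


@dataclass
class SyntheticDataset:
    """In-memory generator output plus the paths written (if any)."""

    expression: pd.DataFrame
    copy_number: pd.DataFrame
    clinical: pd.DataFrame
    pathways: PathwayCollection
    truth: SyntheticTruth
    paths: dict[str, Path] = field(default_factory=dict)


def _pathway_names(n: int) -> tuple[str, ...]:
    if n == len(SIGNALING_PATHWAYS_46):
        return SIGNALING_PATHWAYS_46
    return tuple(f"PW{i + 1:02d}" for i in range(n))


def _memberships(spec: SyntheticSpec) -> tuple[list[str], list[list[int]], PathwayCollection]:
    """Gene list, per-gene pathway memberships, and the pathway collection.

    Adjacent pathways share ``round(overlap_fraction * genes_per_pathway)``
    genes, so every gene belongs to one or two pathways.
    """
    n_shared = int(round(spec.overlap_fraction * spec.genes_per_pathway))
    names = _pathway_names(spec.n_pathways)
    genes: list[str] = []
    gene_pathways: list[list[int]] = []
    per_pathway: list[list[str]] = [[] for _ in range(spec.n_pathways)]
    for p in range(spec.n_pathways):
        n_fresh = spec.genes_per_pathway - (n_shared if p > 0 else 0)
        if p > 0 and n_shared > 0:
            for g in per_pathway[p - 1][-n_shared:]:
                per_pathway[p].append(g)
                gene_pathways[genes.index(g)].append(p)
        for j in range(n_fresh):
            g = f"G{p:02d}_{j:03d}"
            genes.append(g)
            gene_pathways.append([p])
            per_pathway[p].append(g)
    collection = PathwayCollection(
        names=names,
        genes=tuple(frozenset(members) for members in per_pathway),
    )
    return genes, gene_pathways, collection


def generate(spec: SyntheticSpec, out_dir: str | Path | None = None) -> SyntheticDataset:
    """Draw one dataset under ``spec``; write files if ``out_dir`` is given.

    Deterministic: the same spec (including seed) yields byte-identical
    files.
    """
    rng = np.random.default_rng(spec.seed)
    genes, gene_pathways, collection = _memberships(spec)
    n, n_genes = spec.n_samples, len(genes)
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    activity = rng.standard_normal((n, spec.n_pathways))

    loadings = [rng.uniform(0.5, 1.5, size=len(ps)) for ps in gene_pathways]
    expr = np.empty((n, n_genes))
    for g, (ps, lo) in enumerate(zip(gene_pathways, loadings)):
        expr[:, g] = activity[:, ps] @ lo
    expr += rng.normal(0.0, spec.noise_sd_expression, size=expr.shape)
    expr -= expr.min()  # shift to non-negative, log-scale-like values

    coupled = rng.random(n_genes) < spec.cnv_coupling
    cnv = np.empty((n, n_genes))
    for g, ps in enumerate(gene_pathways):
        if coupled[g]:
            raw = activity[:, ps[0]] + rng.normal(0.0, 0.5, size=n)
        else:
            raw = rng.normal(0.0, 0.8, size=n)
        cnv[:, g] = np.clip(np.round(raw), -2, 2)

    for g in spec.zero_genes:
        if g in genes:
            expr[:, genes.index(g)] = 0.0

    age = np.clip(np.round(rng.normal(60.0, 10.0, size=n)), 30, 90)
    gender = rng.choice(["female", "male"], size=n)
    stage = rng.choice([1, 2, 3, 4], size=n, p=[0.25, 0.35, 0.25, 0.15])

    effect = np.zeros(spec.n_pathways)
    for p, e in zip(spec.causal_pathways, spec.effect_sizes):
        effect[p] = e
    uncensored = (
        spec.baseline_days
        + activity @ effect
        + AGE_COEF_DAYS_PER_YEAR * (age - 60.0)
        + STAGE_COEF_DAYS_PER_STAGE * (stage - 2.0)
        + rng.normal(0.0, spec.noise_sd_survival, size=n)
    )
    uncensored = np.clip(np.round(uncensored), SURVIVAL_MIN_DAYS, SURVIVAL_MAX_DAYS).astype(int)

    n_censored = int(np.floor(spec.censor_fraction * n))
    censored_idx = rng.choice(n, size=n_censored, replace=False)
    vital = np.ones(n, dtype=int)
    survival_days = uncensored.copy()
    for i in censored_idx:
        vital[i] = 0
        # uniform strictly below the event time (upper bound exclusive)
        survival_days[i] = rng.integers(
            SURVIVAL_MIN_DAYS, max(int(uncensored[i]), SURVIVAL_MIN_DAYS + 1))

    if spec.n_over_cap:
        event_idx = np.flatnonzero(vital == 1)
        over = rng.choice(event_idx, size=spec.n_over_cap, replace=False)
        extra = rng.integers(1, 601, size=spec.n_over_cap)
        survival_days[over] = SURVIVAL_MAX_DAYS + extra
        uncensored[over] = survival_days[over]

    expression = pd.DataFrame(expr, index=sample_ids, columns=genes)
    copy_number = pd.DataFrame(cnv.astype(int), index=sample_ids, columns=genes)
    roman = {1: "Stage I", 2: "Stage II", 3: "Stage III", 4: "Stage IV"}
    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": age.astype(int),
            "gender": gender,
            "stage": [roman[s] for s in stage],
            "vital_status": np.where(vital == 1, "deceased", "living"),
            "survival_days": survival_days,
        }
    )
    truth = SyntheticTruth(
        pathway_activity=pd.DataFrame(activity, index=sample_ids, columns=collection.names),
        causal_pathways=tuple(spec.causal_pathways),
        effect_sizes={p: float(e) for p, e in zip(spec.causal_pathways, spec.effect_sizes)},
        uncensored_survival=pd.Series(uncensored, index=sample_ids, name="uncensored_days"),
    )
    dataset = SyntheticDataset(
        expression=expression, copy_number=copy_number, clinical=clinical,
        pathways=collection, truth=truth,
    )
    if out_dir is not None:
        dataset.paths = write_dataset(dataset, spec, Path(out_dir))
    return dataset


def write_dataset(dataset: SyntheticDataset, spec: SyntheticSpec,
                  out_dir: Path) -> dict[str, Path]:
    """Emit the loader-compatible TSV/GMT files plus a truth manifest."""
    from .pathway_data import write_matrix

    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out_dir / "expression.tsv",
        "copy_number": out_dir / "copy_number.tsv",
        "clinical": out_dir / "clinical.tsv",
        "pathways": out_dir / "pathways.gmt",
        "manifest": out_dir / "manifest.json",
    }
    write_matrix(dataset.expression, paths["expression"])
    write_matrix(dataset.copy_number.astype(float), paths["copy_number"])
    dataset.clinical.to_csv(paths["clinical"], sep="\t", index=False)
    with paths["pathways"].open("w") as fh:
        for name, members in dataset.pathways:
            fh.write("\t".join([name, "synthetic membership"] + sorted(members)) + "\n")
    manifest = {
        "spec": asdict(spec),
        "truth": {
            "causal_pathways": list(dataset.truth.causal_pathways),
            "effect_sizes": {str(k): v for k, v in dataset.truth.effect_sizes.items()},
            "uncensored_survival": dataset.truth.uncensored_survival.to_dict(),
            "pathway_activity": {
                name: [round(float(v), 6) for v in dataset.truth.pathway_activity[name]]
                for name in dataset.truth.pathway_activity.columns
            },
        },
    }
    paths["manifest"].write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return paths


def truth_ranking(truth: SyntheticTruth) -> list[int]:
    """Pathway indices ordered by decreasing absolute effect size.

    Non-causal pathways (effect 0) come last; ties break by index, so with
    no causal pathways the identity order is returned.
    """
    n = truth.pathway_activity.shape[1]
    effects = np.zeros(n)
    for p, e in truth.effect_sizes.items():
        effects[p] = e
    return sorted(range(n), key=lambda p: (-abs(effects[p]), p))
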