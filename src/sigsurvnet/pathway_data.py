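"""Loading and alignment of pathway gene sets, omics matrices and clinical tables.

The loaders speak the two plain-text dialects common in cancer genomics:

* GMT gene-set files — one pathway per line: ``name<TAB>description<TAB>gene...``
* UCSC-Xena-style TSV matrices — first column holds gene identifiers, the
  remaining columns are samples; loaded transposed to samples x genes.

``assemble_dataset`` intersects the three sources, applies the study filters
(survival capped at 3000 days; genes with identically-zero expression on the
training partition removed) and builds the binary gene x pathway connection
mask that constrains the network's sparse pathway layer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: default clinical column names; override via the ``column_map`` argument
DEFAULT_CLINICAL_COLUMNS: dict[str, str] = {
    "sample_id": "sample_id",
    "age": "age",
    "gender": "gender",
    "stage": "stage",
    "vital_status": "vital_status",
    "survival_days": "survival_days",
}

#: tumour-stage strings mapped to ordinal codes; sub-stages (a/b/c) collapse
#: to the parent stage
STAGE_ORDINALS: dict[str, int] = {"i": 1, "ii": 2, "iii": 3, "iv": 4}

SURVIVAL_CAP_DAYS = 3000


class PathwayFileError(ValueError):
    """Malformed gene-set file."""


class MatrixFormatError(ValueError):
    """Malformed omics matrix file."""


class ClinicalFormatError(ValueError):
    """Clinical table missing required columns."""


class AssemblyError(ValueError):
    """Dataset alignment produced an empty sample or gene set."""


@dataclass(frozen=True)
class PathwayCollection:
    """Ordered, named gene sets.

    The order of ``names`` is the canonical pathway order used everywhere
    downstream (connection-mask columns, the 1-D convolution axis, relevance
    matrices).
    """

    names: tuple[str, ...]
    genes: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.genes):
            raise ValueError("names and genes must have equal length")
        if len(set(self.names)) != len(self.names):
            raise PathwayFileError("duplicate pathway names")
        for name, members in zip(self.names, self.genes):
            if not name:
                raise PathwayFileError("empty pathway name")
            if not members:
                raise PathwayFileError(f"pathway {name!r} has no member genes")

    def __len__(self) -> int:
        return len(self.names)

    def __iter__(self):
        return iter(zip(self.names, self.genes))

    @property
    def gene_union(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.genes:
            out |= members
        return frozenset(out)

    def subset(self, indices: Sequence[int]) -> "PathwayCollection":
        """Restriction to the pathways at ``indices`` (order preserved)."""
        return PathwayCollection(
            names=tuple(self.names[i] for i in indices),
            genes=tuple(self.genes[i] for i in indices),
        )


@dataclass(frozen=True)
class ConnectionMask:
    """Binary gene x pathway membership indicator.

    ``matrix[g, p] == 1`` iff gene ``gene_index[g]`` belongs to pathway
    ``pathway_index[p]``.  Rows follow the model's input gene order, columns
    the canonical pathway order.
    """

    matrix: np.ndarray
    gene_index: tuple[str, ...]
    pathway_index: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape != (len(self.gene_index), len(self.pathway_index)):
            raise ValueError("mask shape does not match its indices")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("mask entries must be 0/1")
        empty = np.flatnonzero(m.sum(axis=0) == 0)
        if empty.size:
            bad = [self.pathway_index[i] for i in empty]
            raise AssemblyError(f"pathways with no retained genes: {bad}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_index)

    @property
    def n_pathways(self) -> int:
        return len(self.pathway_index)


@dataclass
class OmicsDataset:
    """Aligned expression, copy number, clinical covariates and survival.

    ``expression`` and ``copy_number`` are samples x genes DataFrames with
    identical index/columns; ``clinical`` shares the sample index and carries
    ``age``, ``gender_code``, ``stage_ordinal``, ``stage_unknown`` and
    ``vital_status``; ``survival_days`` is an integer Series on the same
    index.
    """

    expression: pd.DataFrame
    copy_number: pd.DataFrame
    clinical: pd.DataFrame
    survival_days: pd.Series
    exclusions: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.expression.index
        for other in (self.copy_number.index, self.clinical.index, self.survival_days.index):
            if not idx.equals(other):
                raise AssemblyError("sample order differs across dataset components")
        if not self.expression.columns.equals(self.copy_number.columns):
            raise AssemblyError("gene order differs between expression and copy number")
        if (self.survival_days > SURVIVAL_CAP_DAYS).any():
            raise AssemblyError(f"survival times exceed {SURVIVAL_CAP_DAYS} days")

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.expression.index)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.expression.columns)

    @property
    def n_samples(self) -> int:
        return len(self.expression)

    @property
    def n_genes(self) -> int:
        return self.expression.shape[1]

    def clinical_features(self, include_vital_status: bool = True) -> np.ndarray:
        """Clinical covariate block: age, gender code, ordinal stage, vital status."""
        cols = ["age", "gender_code", "stage_ordinal"]
        if include_vital_status:
            cols.append("vital_status")
        return self.clinical[cols].to_numpy(dtype=float)

    def features(self, include_vital_status: bool = True) -> np.ndarray:
        """Model input: ``[expression | copy_number | clinical]`` per sample."""
        return np.hstack(
            [
                self.expression.to_numpy(dtype=float),
                self.copy_number.to_numpy(dtype=float),
                self.clinical_features(include_vital_status),
            ]
        )

    def subset_samples(self, idx: Sequence[int]) -> "OmicsDataset":
        idx = list(idx)
        return OmicsDataset(
            expression=self.expression.iloc[idx],
            copy_number=self.copy_number.iloc[idx],
            clinical=self.clinical.iloc[idx],
            survival_days=self.survival_days.iloc[idx],
            exclusions=dict(self.exclusions),
        )


def load_pathways(path: str | Path) -> PathwayCollection:
    """Parse a GMT gene-set file into an ordered :class:`PathwayCollection`.

    Duplicate genes within one pathway are collapsed; gene symbols are
    whitespace-trimmed.  Duplicate pathway names, empty member lists and an
    empty file raise :class:`PathwayFileError`.
    """
    path = Path(path)
    names: list[str] = []
    genes: list[frozenset[str]] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise PathwayFileError(
                    f"{path.name}:{lineno}: expected >=3 tab-separated fields, got {len(fields)}"
                )
            name = fields[0].strip()
            members = frozenset(g.strip() for g in fields[2:] if g.strip())
            if name in names:
                raise PathwayFileError(f"{path.name}:{lineno}: duplicate pathway name {name!r}")
            if not members:
                raise PathwayFileError(f"{path.name}:{lineno}: pathway {name!r} has no genes")
            names.append(name)
            genes.append(members)
    if not names:
        raise PathwayFileError(f"{path.name}: no pathways found")
    logger.info("loaded %d pathways (%d distinct genes) from %s",
                len(names), len(frozenset().union(*genes)), path)
    return PathwayCollection(names=tuple(names), genes=tuple(genes))


def default_pathway_file() -> Path:
    """Path to the packaged 46-pathway gene-set fixture (synthetic memberships)."""
    return Path(__file__).parent / "data" / "pathways_46.gmt"


def load_matrix(path: str | Path, value_kind: str = "continuous") -> pd.DataFrame:
    """Load a Xena-dialect TSV matrix as a samples x genes DataFrame.

    The file stores genes as rows and samples as columns (header
    ``sample<TAB>id1<TAB>...``); the result is transposed so that samples are
    rows.  ``value_kind="integer"`` additionally rejects non-integral values
    (GISTIC-thresholded copy-number calls are integers in [-2, 2]).
    """
    if value_kind not in ("continuous", "integer"):
        raise ValueError(f"unknown value_kind {value_kind!r}")
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    dup = raw.index[raw.index.duplicated()]
    if len(dup):
        raise MatrixFormatError(f"{path.name}: duplicate gene rows: {sorted(set(dup))}")
    try:
        values = raw.astype(float)
    except ValueError:
        # localize the offending cell for the error message
        for gene, row in raw.iterrows():
            for sample, cell in row.items():
                if pd.notna(cell):
                    try:
                        float(cell)
                    except ValueError:
                        raise MatrixFormatError(
                            f"{path.name}: non-numeric cell at gene {gene!r}, sample {sample!r}: {cell!r}"
                        ) from None
        raise
    if value_kind == "integer":
        body = values.to_numpy()
        finite = np.isfinite(body)
        if not np.array_equal(body[finite], np.round(body[finite])):
            bad = np.argwhere(finite & (body != np.round(body)))[0]
            raise MatrixFormatError(
                f"{path.name}: non-integral value at gene {values.index[bad[0]]!r}, "
                f"sample {values.columns[bad[1]]!r}"
            )
    out = values.T
    out.index.name = "sample"
    logger.info("loaded %d samples x %d genes from %s", out.shape[0], out.shape[1], path)
    return out


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a samples x genes DataFrame in the Xena dialect (genes as rows).

    Inverse of :func:`load_matrix`: a round trip reproduces values to full
    precision.
    """
    out = matrix.T
    out.index.name = "sample"
    out.to_csv(path, sep="\t", float_format="%.17g")


def load_clinical(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Load a clinical TSV into the canonical covariate table.

    Returns a DataFrame indexed by sample id with columns ``age``,
    ``gender_code`` (0/1 by sorted label order), ``stage_ordinal`` (1-4;
    unknown stages get the median ordinal of the parsable rows),
    ``stage_unknown`` (bool) and ``vital_status`` (1 = deceased/event,
    0 = living/censored), plus ``survival_days``.  Rows missing survival time
    are dropped (count logged).
    """
    cols = dict(DEFAULT_CLINICAL_COLUMNS)
    if column_map:
        cols.update(column_map)
    path = Path(path)
    raw = pd.read_csv(path, sep="\t", dtype=str)
    missing = [v for v in cols.values() if v not in raw.columns]
    if missing:
        raise ClinicalFormatError(f"{path.name}: missing required columns {missing}")

    df = raw.rename(columns={v: k for k, v in cols.items()})
    n_before = len(df)
    survival = pd.to_numeric(df["survival_days"], errors="coerce")
    keep = survival.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d clinical rows with missing survival time", n_dropped)
    df = df.loc[keep].copy()
    df["survival_days"] = survival.loc[keep].astype(int)
    df["age"] = pd.to_numeric(df["age"], errors="coerce")

    genders = sorted(df["gender"].fillna("").str.strip().str.lower().unique())
    gender_codes = {g: i for i, g in enumerate(genders)}
    df["gender_code"] = df["gender"].fillna("").str.strip().str.lower().map(gender_codes)

    ordinals = df["stage"].map(parse_stage)
    df["stage_unknown"] = ordinals.isna()
    known = ordinals.dropna()
    fill = float(known.median()) if len(known) else 2.0
    df["stage_ordinal"] = ordinals.fillna(fill).astype(float)
    n_unknown = int(df["stage_unknown"].sum())
    if n_unknown:
        logger.info("%d rows with unparsable stage imputed to ordinal %.1f", n_unknown, fill)

    df["vital_status"] = df["vital_status"].map(parse_vital_status)
    out = df.set_index("sample_id")[
        ["age", "gender_code", "stage_ordinal", "stage_unknown", "vital_status", "survival_days"]
    ]
    out.attrs["n_dropped_missing_survival"] = n_dropped
    out.attrs["n_stage_unknown"] = n_unknown
    logger.info("loaded %d/%d clinical records from %s", len(out), n_before, path)
    return out


def parse_stage(value: object) -> float:
    """Map a stage string to its ordinal (``"Stage IIb"`` -> 2); NaN if unparsable."""
    if not isinstance(value, str):
        return float("nan")
    token = value.strip().lower()
    if token.startswith("stage"):
        token = token[len("stage"):].strip()
    token = token.rstrip("abc").strip()
    return float(STAGE_ORDINALS.get(token, float("nan")))


def parse_vital_status(value: object) -> int:
    """Map vital-status labels to 1 (event observed) / 0 (censored)."""
    token = str(value).strip().lower()
    if token in ("1", "deceased", "dead", "event", "true"):
        return 1
    return 0


def build_connection_mask(genes: Sequence[str], pathways: PathwayCollection) -> ConnectionMask:
    """Binary membership mask over ``genes`` (rows) and ``pathways`` (columns)."""
    matrix = np.zeros((len(genes), len(pathways)), dtype=np.uint8)
    for p, members in enumerate(pathways.genes):
        for g, gene in enumerate(genes):
            if gene in members:
                matrix[g, p] = 1
    return ConnectionMask(matrix=matrix, gene_index=tuple(genes), pathway_index=tuple(pathways.names))


def assemble_dataset(
    expression: pd.DataFrame,
    copy_number: pd.DataFrame,
    clinical: pd.DataFrame,
    pathways: PathwayCollection,
    training_samples: Sequence[str] | None = None,
) -> tuple[OmicsDataset, ConnectionMask]:
    """Align the three sources into one dataset and build the connection mask.

    Samples: the intersection of expression, copy-number and clinical sample
    ids (expression order preserved), minus samples with any missing value
    and minus samples with survival above 3000 days (3000 itself retained).

    Genes: expression ∩ copy-number ∩ pathway-union genes, minus genes whose
    expression is identically zero across the training partition
    (``training_samples``; all retained samples if omitted).  The filter uses
    training samples only so test-set values cannot influence the input space.

    Every exclusion is counted in ``OmicsDataset.exclusions`` and logged.
    """
    exclusions: dict[str, int] = {}

    samples = [s for s in expression.index if s in set(copy_number.index) & set(clinical.index)]
    if not samples:
        raise AssemblyError("no samples shared by expression, copy number and clinical data")

    surv = clinical.loc[samples, "survival_days"]
    over_cap = surv > SURVIVAL_CAP_DAYS
    exclusions["samples_survival_gt_3000"] = int(over_cap.sum())
    samples = [s for s in samples if not over_cap[s]]

    genes = [g for g in expression.columns
             if g in set(copy_number.columns) & pathways.gene_union]
    if not genes:
        raise AssemblyError("no genes shared by expression, copy number and the pathway union")
    exclusions["genes_outside_pathways_or_unshared"] = expression.shape[1] - len(genes)

    expr = expression.loc[samples, genes]
    cnv = copy_number.loc[samples, genes]
    clin = clinical.loc[samples]

    incomplete = expr.isna().any(axis=1) | cnv.isna().any(axis=1) | clin["age"].isna()
    exclusions["samples_missing_values"] = int(incomplete.sum())
    if incomplete.any():
        keep = ~incomplete
        expr, cnv, clin = expr.loc[keep], cnv.loc[keep], clin.loc[keep]
        samples = list(expr.index)
    if not samples:
        raise AssemblyError("all samples excluded by survival/missingness filters")

    if training_samples is None:
        training = list(samples)
    else:
        training = [s for s in training_samples if s in set(samples)]
        if not training:
            raise AssemblyError("training partition is empty after sample filtering")
    zero_expr = (expr.loc[training] == 0).all(axis=0)
    exclusions["genes_zero_expression_in_training"] = int(zero_expr.sum())
    genes = [g for g in genes if not zero_expr[g]]
    if not genes:
        raise AssemblyError("all genes excluded by the zero-expression filter")
    expr, cnv = expr[genes], cnv[genes]

    dropped_pathway_genes = len(pathways.gene_union - set(genes))
    exclusions["pathway_genes_absent_from_data"] = dropped_pathway_genes
    mask = build_connection_mask(genes, pathways)

    dataset = OmicsDataset(
        expression=expr,
        copy_number=cnv,
        clinical=clin,
        survival_days=clin["survival_days"].astype(int),
        exclusions=exclusions,
    )
    logger.info(
        "assembled dataset: %d samples x %d genes, %d pathways; exclusions=%s",
        dataset.n_samples, dataset.n_genes, mask.n_pathways, exclusions,
    )
    return dataset, mask
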