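"""The pathway-masked survival network, as a scikit-learn style regressor.

Architecture (in order):

1. per-gene state layer: each gene's (expression, copy number) pair is mapped
   through its own 2->1 affine map with ReLU — weights are not shared across
   genes;
2. masked gene->pathway affine layer + ReLU: a gene's state feeds a pathway
   only if the gene belongs to it (binary connection mask as a hard
   structural constraint), yielding one activation per pathway;
3. the pathway vector, treated as a 1-channel sequence in canonical pathway
   order, passes through a stack of 1-D inception blocks (parallel
   convolutions of several kernel sizes plus a max-pool branch, concatenated
   on channels, dropout after each block);
4. a 1x1 dimension-reduction convolution compresses the concatenated branch
   channels, and the flattened result is concatenated with the clinical
   covariates (standardized age, gender code, ordinal stage, vital status)
   and, by default, with the raw pathway vector itself (a skip path, so the
   head can weight individual pathways without recovering position-specific
   weights from position-shared convolution filters);
5. one dense ReLU layer with L2 weight decay and dropout;
6. a single linear output unit predicting survival time (days, internally
   scaled).

Training minimizes mean squared error on the scaled survival time with
Adadelta (batch size 32 by default); after every epoch the concordance index
is computed on the train and held-out partitions and the parameters with the
best held-out c-index are checkpointed and restored at the end.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

from . import _nn
from .evaluation import concordance_index
from .pathway_data import ConnectionMask, OmicsDataset

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    """Hyperparameters of the survival network.

    ``survival_scale`` divides survival days before the MSE loss so targets
    are O(1); predictions are scaled back.  ``inception_modules=0`` skips the
    convolution stack (the pathway vector feeds the head directly) and
    ``dense_units=0`` skips the hidden dense layer — together they yield a
    purely linear head, useful for closed-form checks.
    """

    dropout_rate: float = 0.3
    l2_weight: float = 1e-4
    epochs: int = 30
    batch_size: int = 32
    inception_modules: int = 2
    branch_kernel_sizes: tuple[int, ...] = (1, 3, 5)
    filters_per_branch: int = 8
    pool_width: int = 3
    reduce_channels: int = 2
    pathway_skip: bool = True
    dense_units: int = 32
    survival_scale: float = 1000.0
    optimizer_name: str = "Adadelta"
    learning_rate: float = 1.0
    include_vital_status: bool = True
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.l2_weight < 0:
            raise ValueError("l2_weight must be non-negative")
        if self.survival_scale <= 0:
            raise ValueError("survival_scale must be positive")
        if any(k < 1 or k % 2 == 0 for k in self.branch_kernel_sizes):
            raise ValueError("branch kernel sizes must be odd and >= 1")
        if self.optimizer_name.lower() != "adadelta":
            raise ValueError("only the Adadelta optimizer is supported")
        for name in ("epochs", "batch_size", "inception_modules",
                     "filters_per_branch", "reduce_channels", "dense_units"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def estimator_kwargs(self) -> dict:
        kw = asdict(self)
        kw["random_state"] = kw.pop("seed")
        kw.pop("optimizer_name")
        return kw


class DeepSigSurvNet(BaseEstimator, RegressorMixin):
    """Pathway-masked deep survival-time regressor.

    Parameters
    ----------
    mask : ConnectionMask or binary array of shape (n_genes, n_pathways)
        Gene->pathway membership; masked-out connections are structurally
        zero throughout training.
    Other parameters mirror :class:`ModelConfig`.

    The feature matrix ``X`` passed to :meth:`fit`/:meth:`predict` is the
    horizontal concatenation ``[expression | copy_number | clinical]`` with
    ``n_genes`` columns for each omics block (see
    :meth:`OmicsDataset.features`); ``y`` is survival time in days.

    Fitted attributes (trailing underscore): ``training_log_`` with per-epoch
    loss and train/test c-index, ``best_epoch_``, ``best_test_cindex_``,
    ``n_features_in_``.
    """

    def __init__(self, mask=None, dropout_rate=0.3, l2_weight=1e-4, epochs=30,
                 batch_size=32, inception_modules=2, branch_kernel_sizes=(1, 3, 5),
                 filters_per_branch=8, pool_width=3, reduce_channels=2,
                 pathway_skip=True, dense_units=32, survival_scale=1000.0,
                 learning_rate=1.0, include_vital_status=True,
                 standardize=True, random_state=0):
        self.mask = mask
        self.dropout_rate = dropout_rate
        self.l2_weight = l2_weight
        self.epochs = epochs
        self.batch_size = batch_size
        self.inception_modules = inception_modules
        self.branch_kernel_sizes = branch_kernel_sizes
        self.filters_per_branch = filters_per_branch
        self.pool_width = pool_width
        self.reduce_channels = reduce_channels
        self.pathway_skip = pathway_skip
        self.dense_units = dense_units
        self.survival_scale = survival_scale
        self.learning_rate = learning_rate
        self.include_vital_status = include_vital_status
        self.standardize = standardize
        self.random_state = random_state

    # ------------------------------------------------------------------ setup

    def _mask_matrix(self) -> np.ndarray:
        if self.mask is None:
            raise ValueError("a connection mask is required")
        m = self.mask.matrix if isinstance(self.mask, ConnectionMask) else np.asarray(self.mask)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D (genes x pathways)")
        if (m.sum(axis=0) == 0).any():
            raise ValueError("mask has a pathway column with no member genes")
        return m.astype(float)

    def _split_columns(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        g = self.n_genes_
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, expected {self.n_features_in_} "
                f"(2 x {g} genes + {self.n_clinical_} clinical)"
            )
        return X[:, :g], X[:, g:2 * g], X[:, 2 * g:]

    def _build(self, rng: np.random.Generator) -> None:
        m = self._mask_matrix()
        n_genes, n_pathways = m.shape
        self.gene_state_ = _nn.GeneState(n_genes, rng)
        self.pathway_layer_ = _nn.MaskedDense(m, rng)
        self.blocks_ = []
        channels = 1
        for _ in range(self.inception_modules):
            block = _nn.InceptionBlock(channels, tuple(self.branch_kernel_sizes),
                                       self.filters_per_branch, self.dropout_rate,
                                       self.pool_width, rng)
            self.blocks_.append(block)
            channels = block.out_channels
        # 1x1 dimension-reduction convolution, in the inception spirit: keeps
        # the head small relative to the concatenated branch channels
        if self.blocks_ and self.reduce_channels > 0:
            self.reduce_ = _nn.Conv1D(channels, self.reduce_channels, 1, rng, relu=True)
            channels = self.reduce_channels
        else:
            self.reduce_ = None
        self._flat_dim = n_pathways * channels
        # skip path: the raw pathway vector joins the head input so position-
        # specific (pathway-specific) weights need not be recovered from the
        # position-shared convolution filters; redundant without conv blocks
        self._use_skip = bool(self.pathway_skip) and bool(self.blocks_)
        head_in = self._flat_dim + self.n_clinical_ + (n_pathways if self._use_skip else 0)
        if self.dense_units > 0:
            self.dense_ = _nn.Dense(head_in, self.dense_units, rng, relu=True)
            self.head_dropout_ = _nn.Dropout(self.dropout_rate)
            out_in = self.dense_units
        else:
            self.dense_ = None
            self.head_dropout_ = None
            out_in = head_in
        self.out_ = _nn.Dense(out_in, 1, rng, relu=False)
        layers = [self.gene_state_, self.pathway_layer_]
        for block in self.blocks_:
            layers.extend(block.sublayers)
        if self.reduce_ is not None:
            layers.append(self.reduce_)
        if self.dense_ is not None:
            layers.extend([self.dense_, self.head_dropout_])
        layers.append(self.out_)
        self._flat_layers = layers

    # ---------------------------------------------------------------- forward

    def _standardize_blocks(self, expr, cnv, clin, fitting: bool):
        if not self.standardize:
            return expr, cnv, clin
        if fitting:
            self._expr_mean = expr.mean(axis=0)
            sd = expr.std(axis=0)
            self._expr_sd = np.where(sd > 1e-12, sd, 1.0)
            self._age_mean = clin[:, 0].mean()
            age_sd = clin[:, 0].std()
            self._age_sd = age_sd if age_sd > 1e-12 else 1.0
        expr = (expr - self._expr_mean) / self._expr_sd
        clin = clin.copy()
        clin[:, 0] = (clin[:, 0] - self._age_mean) / self._age_sd
        return expr, cnv, clin

    def _forward_front(self, expr, cnv):
        state = self.gene_state_.forward_pair(expr, cnv)
        return self.pathway_layer_.forward(state)

    def _forward_back(self, pathways, clin, train=False, rng=None):
        h = pathways[:, :, None]
        for block in self.blocks_:
            h = block.forward(h, train, rng)
        if self.reduce_ is not None:
            h = self.reduce_.forward(h)
        self._h_shape = h.shape
        flat = h.reshape(h.shape[0], -1)
        z = np.hstack([flat, clin, pathways]) if self._use_skip else np.hstack([flat, clin])
        if self.dense_ is not None:
            z = self.dense_.forward(z)
            z = self.head_dropout_.forward(z, train, rng)
        return self.out_.forward(z)[:, 0]

    def _backward_back(self, dy):
        dz = self.out_.backward(dy[:, None])
        if self.dense_ is not None:
            dz = self.dense_.backward(self.head_dropout_.backward(dz))
        dflat = dz[:, :self._flat_dim]
        dh = dflat.reshape(self._h_shape)
        if self.reduce_ is not None:
            dh = self.reduce_.backward(dh)
        for block in reversed(self.blocks_):
            dh = block.backward(dh)
        dpath = dh[:, :, 0]
        if self._use_skip:
            dpath = dpath + dz[:, self._flat_dim + self.n_clinical_:]
        return dpath

    def _backward_front(self, dpathways):
        dstate = self.pathway_layer_.backward(dpathways)
        self.gene_state_.backward(dstate)

    # -------------------------------------------------------------------- fit

    def fit(self, X, y, eval_set: tuple | None = None):
        """Train on ``(X, y)``; ``eval_set=(X_test, y_test)`` enables per-epoch
        held-out c-index logging and best-checkpoint restoration."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or len(X) != len(y):
            raise ValueError("X must be 2-D with one row per element of y")
        if len(y) < 2:
            raise ValueError("need at least 2 training samples")
        m = self._mask_matrix()
        self.n_genes_ = m.shape[0]
        self.n_pathways_ = m.shape[1]
        self.n_features_in_ = X.shape[1]
        self.n_clinical_ = X.shape[1] - 2 * self.n_genes_
        if self.n_clinical_ < 0:
            raise ValueError("X has fewer columns than two omics blocks require")

        rng = np.random.default_rng(self.random_state)
        self._build(rng)
        self._optimizer = _nn.Adadelta(self._flat_layers, lr=self.learning_rate)

        expr, cnv, clin = self._split_columns(X)
        expr, cnv, clin = self._standardize_blocks(expr, cnv, clin, fitting=True)
        targets = y / self.survival_scale
        # start the output bias at the mean scaled survival so short runs
        # spend their steps on the signal, not the offset
        self.out_.params["bias"][0] = targets.mean()

        log_rows: list[dict] = []
        best = (-np.inf, None, 0)  # (test c-index, snapshot, epoch)
        n = len(y)
        for epoch in range(1, self.epochs + 1):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start:start + self.batch_size]
                p = self._forward_front(expr[idx], cnv[idx])
                pred = self._forward_back(p, clin[idx], train=True, rng=rng)
                resid = pred - targets[idx]
                loss = float(np.mean(resid ** 2))
                if not np.isfinite(loss):
                    raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
                losses.append(loss)
                dpath = self._backward_back(2.0 * resid / len(idx))
                self._backward_front(dpath)
                self._optimizer_step()
            train_ci = self._safe_cindex(y, self._raw_predict(expr, cnv, clin))
            row = {"epoch": epoch, "loss": float(np.mean(losses)),
                   "train_cindex": train_ci, "test_cindex": np.nan}
            if eval_set is not None:
                X_te, y_te = eval_set
                test_ci = self._safe_cindex(np.asarray(y_te, float),
                                            self._predict_internal(np.asarray(X_te, float)))
                row["test_cindex"] = test_ci
                if test_ci > best[0]:
                    best = (test_ci, _nn.snapshot_params(self._flat_layers), epoch)
            log_rows.append(row)

        if eval_set is not None and best[1] is not None:
            _nn.restore_params(self._flat_layers, best[1])
            self.best_epoch_ = best[2]
            self.best_test_cindex_ = best[0]
        else:
            self.best_epoch_ = self.epochs
            self.best_test_cindex_ = np.nan
        self.training_log_ = pd.DataFrame(
            log_rows, columns=["epoch", "loss", "train_cindex", "test_cindex"]
        )
        return self

    def _optimizer_step(self) -> None:
        self._optimizer.step(self.l2_weight)

    @staticmethod
    def _safe_cindex(y_true, y_pred) -> float:
        try:
            return concordance_index(y_true, y_pred).value
        except ValueError:
            return np.nan

    # ---------------------------------------------------------------- predict

    def _raw_predict(self, expr, cnv, clin) -> np.ndarray:
        p = self._forward_front(expr, cnv)
        return self._forward_back(p, clin, train=False) * self.survival_scale

    def _predict_internal(self, X: np.ndarray) -> np.ndarray:
        expr, cnv, clin = self._split_columns(X)
        expr, cnv, clin = self._standardize_blocks(expr, cnv, clin, fitting=False)
        return self._raw_predict(expr, cnv, clin)

    def predict(self, X) -> np.ndarray:
        """Predicted survival time in days (dropout inactive, deterministic)."""
        check_is_fitted(self, "training_log_")
        return self._predict_internal(np.asarray(X, dtype=float))

    # ------------------------------------------------- attribution interface

    def pathway_activations(self, X) -> np.ndarray:
        """Post-ReLU activations of the masked pathway layer, one column per
        pathway in canonical order."""
        check_is_fitted(self, "training_log_")
        X = np.asarray(X, dtype=float)
        expr, cnv, _ = self._split_columns(X)
        expr, cnv, _clin = self._standardize_blocks(
            expr, cnv, np.zeros((len(X), self.n_clinical_)), fitting=False)
        return self._forward_front(expr, cnv)

    def clinical_block(self, X) -> np.ndarray:
        """Standardized clinical covariates as fed to the head."""
        check_is_fitted(self, "training_log_")
        X = np.asarray(X, dtype=float)
        expr, cnv, clin = self._split_columns(X)
        _, _, clin = self._standardize_blocks(expr, cnv, clin, fitting=False)
        return clin

    def gradient_wrt_pathways(self, pathway_values, clin) -> np.ndarray:
        """Gradient of predicted survival (days) with respect to the pathway
        activations, evaluated at ``pathway_values``; one row per sample."""
        check_is_fitted(self, "training_log_")
        self._forward_back(np.asarray(pathway_values, float),
                           np.asarray(clin, float), train=False)
        ones = np.ones(len(pathway_values))
        return self._backward_back(ones) * self.survival_scale

    # ------------------------------------------------------------ persistence

    def save(self, directory: str | Path) -> None:
        """Serialize architecture config, mask and parameter tensors."""
        check_is_fitted(self, "training_log_")
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        params = self.get_params()
        mask = params.pop("mask")
        meta = {
            "params": {k: (list(v) if isinstance(v, tuple) else v) for k, v in params.items()},
            "n_clinical": int(self.n_clinical_),
            "best_epoch": int(self.best_epoch_),
            "best_test_cindex": None if np.isnan(self.best_test_cindex_)
            else float(self.best_test_cindex_),
        }
        if isinstance(mask, ConnectionMask):
            meta["gene_index"] = list(mask.gene_index)
            meta["pathway_index"] = list(mask.pathway_index)
            mask_matrix = mask.matrix
        else:
            mask_matrix = np.asarray(mask)
        (directory / "config.json").write_text(json.dumps(meta, indent=2))
        tensors = {"mask": mask_matrix}
        for i, layer in enumerate(self._flat_layers):
            for name, value in layer.params.items():
                tensors[f"layer{i:03d}.{name}"] = value
        if self.standardize:
            tensors["expr_mean"] = self._expr_mean
            tensors["expr_sd"] = self._expr_sd
            tensors["age_stats"] = np.array([self._age_mean, self._age_sd])
        np.savez(directory / "weights.npz", **tensors)
        self.training_log_.to_csv(directory / "training_log.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, directory: str | Path) -> "DeepSigSurvNet":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        tensors = np.load(directory / "weights.npz")
        kwargs = dict(meta["params"])
        kwargs["branch_kernel_sizes"] = tuple(kwargs["branch_kernel_sizes"])
        mask_matrix = tensors["mask"]
        if "gene_index" in meta:
            kwargs["mask"] = ConnectionMask(
                matrix=mask_matrix.astype(np.uint8),
                gene_index=tuple(meta["gene_index"]),
                pathway_index=tuple(meta["pathway_index"]),
            )
        else:
            kwargs["mask"] = mask_matrix
        est = cls(**kwargs)
        est.n_genes_, est.n_pathways_ = mask_matrix.shape
        est.n_clinical_ = meta["n_clinical"]
        est.n_features_in_ = 2 * est.n_genes_ + est.n_clinical_
        est._build(np.random.default_rng(est.random_state))
        for i, layer in enumerate(est._flat_layers):
            for name in layer.params:
                layer.params[name] = tensors[f"layer{i:03d}.{name}"]
        if est.standardize:
            est._expr_mean = tensors["expr_mean"]
            est._expr_sd = tensors["expr_sd"]
            est._age_mean, est._age_sd = tensors["age_stats"]
        est.training_log_ = pd.read_csv(directory / "training_log.tsv", sep="\t")
        est.best_epoch_ = meta["best_epoch"]
        est.best_test_cindex_ = (np.nan if meta["best_test_cindex"] is None
                                 else meta["best_test_cindex"])
        return est


# ----------------------------------------------------------- thin module API

def build_model(config: ModelConfig, mask: ConnectionMask,
                n_clinical: int = 4) -> DeepSigSurvNet:
    """Untrained estimator for the given hyperparameters and connection mask."""
    est = DeepSigSurvNet(mask=mask, **config.estimator_kwargs())
    est.n_clinical_expected_ = n_clinical
    return est


def train(model: DeepSigSurvNet, dataset: OmicsDataset,
          split: tuple[np.ndarray, np.ndarray]) -> DeepSigSurvNet:
    """Fit ``model`` on the train partition of ``dataset``; per-epoch c-index
    is evaluated on the test partition and the best checkpoint restored."""
    train_idx, test_idx = split
    if set(train_idx) & set(test_idx):
        raise ValueError("train and test indices overlap")
    X = dataset.features(model.include_vital_status)
    y = dataset.survival_days.to_numpy(dtype=float)
    return model.fit(X[train_idx], y[train_idx], eval_set=(X[test_idx], y[test_idx]))


def predict(model: DeepSigSurvNet, dataset: OmicsDataset) -> pd.Series:
    """Per-sample predicted survival in days, indexed by sample id."""
    if isinstance(model.mask, ConnectionMask) and dataset.gene_ids != model.mask.gene_index:
        raise ValueError("dataset gene order does not match the model's mask")
    values = model.predict(dataset.features(model.include_vital_status))
    return pd.Series(values, index=dataset.expression.index, name="predicted_days")
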