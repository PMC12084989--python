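"""Deep ordinal neural network (DONN) and binary-DNN health-score models.

The DONN models the cumulative logits of an ordered outcome with a shared
neural score and per-threshold intercepts::

    log Pr(Y > j | x) / Pr(Y <= j | x) = alpha_j + f(x)' beta,

where ``f`` is a small ReLU network (two hidden layers by default) mapped
to a q-dimensional representation W = f(X), ``beta`` is shared across all
J - 1 thresholds and ``alpha_j`` are free intercepts. An individual's
health score on an axis is the intercept-free linear predictor
``f(x)' beta``: larger means worse on that axis under the "Y > j"
parameterization.

Training minimises the sum over thresholds of binary cross-entropies of
the exceedance indicators I(Y > j), with Adam (learning rate 0.001, batch
size 100, up to 150 epochs) and early stopping on a held-out validation
split. The four binary-DNN variants collapse (or subset) the ordinal
outcome to a binary one and fit the identical architecture with J = 2.

The API follows the Model/Results convention: construct a model from
data, call :meth:`DeepOrdinalModel.fit`, and use the returned
:class:`DeepOrdinalResults` for prediction, scoring and summary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _nn

__all__ = [
    "NetworkSpec",
    "TrainConfig",
    "DeepOrdinalModel",
    "DeepOrdinalResults",
    "encode_levels",
    "donn_loss",
    "fit_donn",
    "fit_binary_dnn",
    "collapse_labels",
    "COLLAPSE_MODES",
]

#: binary collapse variants of a 4-level outcome: retain only the extreme
#: groups, or threshold the ordinal scale at j = 0, 1, 2.
COLLAPSE_MODES = ("zero_vs_three", "zero_vs_rest", "low_vs_high", "rest_vs_three")


@dataclass(frozen=True)
class NetworkSpec:
    """Architecture of the feature map f.

    ``n_hidden_layers = 0`` makes f the identity, so the model degenerates
    to an ordinary cumulative-logit linear model (useful for equivalence
    checks against logistic-regression oracles).
    """

    n_hidden_layers: int = 2
    hidden_widths: tuple[int, ...] = (32, 16)
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.n_hidden_layers < 0:
            raise ValueError("n_hidden_layers must be >= 0")
        if len(self.hidden_widths) != self.n_hidden_layers:
            raise ValueError(
                f"hidden_widths must have length n_hidden_layers="
                f"{self.n_hidden_layers}, got {len(self.hidden_widths)}"
            )
        if self.activation != "relu":
            raise ValueError("only relu activation is supported")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings shared by the DONN and binary-DNN fits."""

    learning_rate: float = 0.001
    batch_size: int = 100
    max_epochs: int = 150
    early_stopping_patience: int = 10
    validation_fraction: float = 0.1
    seed: int = 0
    optimizer: str = "adam"
    monitor: str = "val"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.monitor not in ("val", "train"):
            raise ValueError("monitor must be 'val' or 'train'")
        if not 0 < self.validation_fraction < 1:
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is supported")


def encode_levels(y: np.ndarray, n_categories: int) -> np.ndarray:
    """Exceedance encoding of ordinal labels: entry (i, j) = I(y_i > j).

    For J = 4 a label of 2 encodes to (1, 1, 0).
    """
    y = np.asarray(y)
    if y.ndim != 1:
        raise ValueError("y must be a 1-d label vector")
    bad = np.flatnonzero((y < 0) | (y > n_categories - 1) | (y != np.floor(y)))
    if bad.size:
        raise ValueError(
            f"label out of range {{0,...,{n_categories - 1}}} at row "
            f"{bad[0]}: {y[bad[0]]!r}"
        )
    return (y[:, None] > np.arange(n_categories - 1)[None, :]).astype(float)


def donn_loss(scores: np.ndarray, alpha: np.ndarray, y: np.ndarray) -> float:
    """Cumulative-logit cross-entropy summed over samples and thresholds.

    With z_ij = s_i + alpha_j the per-element term is the stable form
    softplus(z) - z * I(y_i > j); the total is non-negative and equals
    (J - 1) * ln 2 per sample when every z is zero.
    """
    scores = np.asarray(scores, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if not (np.all(np.isfinite(scores)) and np.all(np.isfinite(alpha))):
        raise ValueError("donn_loss requires finite scores and intercepts")
    targets = encode_levels(y, alpha.shape[0] + 1)
    z = scores[:, None] + alpha[None, :]
    return float(np.sum(_nn.softplus(z) - z * targets))


def collapse_labels(y: np.ndarray, mode: str, n_categories: int = 4):
    """Collapse an ordinal outcome to binary per the named variant.

    Returns ``(y_binary, keep_mask)``: ``zero_vs_three`` keeps only the
    extreme categories (rows with intermediate labels are dropped) and
    relabels them 0/1; the other modes keep all rows and threshold at
    j = 0, 1 or 2 respectively (I(y > j)).
    """
    y = np.asarray(y)
    J = n_categories
    if mode == "zero_vs_three":
        keep = (y == 0) | (y == J - 1)
        return (y[keep] == J - 1).astype(np.int64), keep
    thresholds = {
        "zero_vs_rest": 0,
        "low_vs_high": max(J // 2 - 1, 0),
        "rest_vs_three": J - 2,
    }
    if mode not in thresholds:
        raise ValueError(
            f"unknown collapse mode {mode!r}; expected one of {COLLAPSE_MODES}"
        )
    keep = np.ones(y.shape[0], dtype=bool)
    return (y > thresholds[mode]).astype(np.int64), keep


class DeepOrdinalModel:
    """Cumulative-logit neural model for an ordered outcome.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Ordinal labels in {0, ..., J - 1}.
    exog : array-like, shape (n, p)
        Covariate matrix.
    n_categories : int, optional
        J; inferred as ``max(endog) + 1`` when omitted.
    network : NetworkSpec, optional
        Architecture of the feature map (two ReLU hidden layers of widths
        32 and 16 by default).
    standardize : bool
        z-score the covariates with training-set statistics inside fit
        (stored and reapplied when scoring new data).
    """

    def __init__(
        self,
        endog,
        exog,
        n_categories: int | None = None,
        network: NetworkSpec | None = None,
        standardize: bool = True,
    ) -> None:
        self.endog = np.asarray(endog, dtype=np.int64)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("exog must be 2-d with one row per label")
        if not np.all(np.isfinite(self.exog)):
            raise ValueError("exog contains non-finite values")
        self.n_categories = (
            int(self.endog.max()) + 1 if n_categories is None else int(n_categories)
        )
        if self.n_categories < 2:
            raise ValueError("need at least two outcome categories")
        encode_levels(self.endog, self.n_categories)  # label-range check
        self.network = network or NetworkSpec()
        self.standardize = standardize

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        label_col: str,
        feature_cols: list[str],
        **kwargs,
    ) -> "DeepOrdinalModel":
        return cls(df[label_col].to_numpy(), df[feature_cols].to_numpy(float), **kwargs)

    # -- fitting -----------------------------------------------------------

    def fit(self, config: TrainConfig | None = None) -> "DeepOrdinalResults":
        """Minimise the cumulative-logit cross-entropy with minibatch Adam.

        A ``validation_fraction`` random split is held out; training stops
        when the monitored loss (validation by default; training when
        ``monitor='train'``, useful for convergence studies on convex
        cases) has not improved for ``early_stopping_patience`` epochs,
        and the best-epoch parameters are restored. Deterministic for a
        fixed seed.
        """
        cfg = config or TrainConfig()
        X, y, J = self.exog, self.endog, self.n_categories
        n = X.shape[0]
        if n < cfg.batch_size:
            raise ValueError(
                f"n={n} is smaller than batch_size={cfg.batch_size}"
            )
        rng = np.random.default_rng(cfg.seed)

        if self.standardize:
            mean = X.mean(axis=0)
            sd = X.std(axis=0)
            sd[sd == 0] = 1.0
        else:
            mean = np.zeros(X.shape[1])
            sd = np.ones(X.shape[1])
        Xz = (X - mean) / sd

        perm = rng.permutation(n)
        n_val = max(1, int(round(cfg.validation_fraction * n)))
        val_idx, train_idx = perm[:n_val], perm[n_val:]
        present = np.unique(y[train_idx])
        if present.size < J:
            missing = sorted(set(range(J)) - set(present.tolist()))
            raise ValueError(
                f"categories {missing} absent from the training split; "
                "the exceedance targets would be degenerate"
            )
        Xtr, ytr = Xz[train_idx], y[train_idx]
        Xva, yva = Xz[val_idx], y[val_idx]
        Ttr = encode_levels(ytr, J)
        Tva = encode_levels(yva, J)

        # start alpha at the empirical cumulative log-odds
        frac = Ttr.mean(axis=0)
        alpha0 = np.log(np.clip(frac, 1e-3, 1 - 1e-3)) - np.log(
            1 - np.clip(frac, 1e-3, 1 - 1e-3)
        )
        params = _nn.init_params(
            X.shape[1], self.network.hidden_widths, J - 1, rng, alpha0=alpha0
        )
        opt = _nn.Adam(params, lr=cfg.learning_rate)

        def eval_loss(Xs, Ts):
            z = _nn.forward_scores(Xs, params)[:, None] + params[-1][None, :]
            return float(np.sum(_nn.softplus(z) - z * Ts)) / Xs.shape[0]

        n_train = Xtr.shape[0]
        best_val = np.inf
        best_params = [p.copy() for p in params]
        best_epoch = 0
        log_rows = []
        since_best = 0
        for epoch in range(1, cfg.max_epochs + 1):
            order = rng.permutation(n_train)
            for start in range(0, n_train, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                loss, grads = _nn.loss_and_grads(Xtr[idx], Ttr[idx], params)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite training loss at epoch {epoch}"
                    )
                opt.step(params, grads)
            tr_loss = eval_loss(Xtr, Ttr)
            va_loss = eval_loss(Xva, Tva)
            log_rows.append((epoch, tr_loss, va_loss))
            monitored = va_loss if cfg.monitor == "val" else tr_loss
            if monitored < best_val - 1e-9:
                best_val = monitored
                best_params = [p.copy() for p in params]
                best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= cfg.early_stopping_patience:
                    break

        train_log = pd.DataFrame(
            log_rows, columns=["epoch", "train_loss", "val_loss"]
        )
        return DeepOrdinalResults(
            model=self,
            params=best_params,
            scaler_mean=mean,
            scaler_sd=sd,
            config=cfg,
            train_log=train_log,
            best_epoch=best_epoch,
            train_idx=train_idx,
            val_idx=val_idx,
        )


@dataclass
class DeepOrdinalResults:
    """Fitted DONN / binary-DNN: parameters, diagnostics and predictions."""

    model: DeepOrdinalModel
    params: list[np.ndarray]
    scaler_mean: np.ndarray
    scaler_sd: np.ndarray
    config: TrainConfig
    train_log: pd.DataFrame
    best_epoch: int
    collapse_mode: str | None = None
    train_idx: np.ndarray | None = None
    val_idx: np.ndarray | None = None

    @property
    def alpha(self) -> np.ndarray:
        """Threshold intercepts alpha_j, j = 0..J-2."""
        return self.params[-1]

    @property
    def beta(self) -> np.ndarray:
        """Shared coefficients of the last hidden representation."""
        return self.params[-2]

    @property
    def n_categories(self) -> int:
        return self.alpha.shape[0] + 1

    @property
    def alpha_ordered(self) -> bool:
        """Whether the fitted intercepts respect the ordinal ordering
        (non-increasing in j), i.e. predicted exceedance curves never
        cross. Not enforced during training; reported as a diagnostic."""
        return bool(np.all(np.diff(self.alpha) <= 0))

    def _check_width(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.model.exog.shape[1]:
            raise ValueError(
                f"expected {self.model.exog.shape[1]} columns, got {X.shape[1]}"
            )
        return (X - self.scaler_mean) / self.scaler_sd

    def health_score(self, X) -> np.ndarray:
        """Intercept-free linear predictor f(x)' beta, one value per row.

        Invariant to how rows are batched: scoring row-by-row equals
        scoring in one call.
        """
        return _nn.forward_scores(self._check_width(X), self.params)

    def predict_cumulative(self, X) -> np.ndarray:
        """Exceedance probabilities Pr(Y > j | x), shape (n, J - 1)."""
        s = self.health_score(X)
        return _nn.sigmoid(s[:, None] + self.alpha[None, :])

    def predict_proba(self, X) -> np.ndarray:
        """Per-category probabilities, shape (n, J)."""
        S = self.predict_cumulative(X)
        J = self.n_categories
        out = np.empty((S.shape[0], J))
        out[:, 0] = 1.0 - S[:, 0]
        if J > 2:
            out[:, 1:-1] = S[:, :-1] - S[:, 1:]
        out[:, -1] = S[:, -1]
        return out

    def loss(self, X, y) -> float:
        """Summed cumulative-logit cross-entropy of (X, y) at the fit."""
        return donn_loss(self.health_score(X), self.alpha, y)

    def summary(self) -> str:
        net = self.model.network
        lines = [
            "Deep ordinal neural network results",
            "=" * 44,
            f"n obs:             {self.model.endog.shape[0]}",
            f"categories (J):    {self.n_categories}",
            f"input width (p):   {self.model.exog.shape[1]}",
            f"hidden widths:     {list(net.hidden_widths) or '[] (linear)'}",
            f"collapse mode:     {self.collapse_mode or '-'}",
            f"best epoch:        {self.best_epoch} / {len(self.train_log)}",
            f"final train loss:  {self.train_log['train_loss'].iloc[-1]:.4f}",
            f"final val loss:    {self.train_log['val_loss'].iloc[-1]:.4f}",
            f"alpha (Y>j):       {np.array2string(self.alpha, precision=3)}",
            f"alpha ordered:     {self.alpha_ordered}",
        ]
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path, name: str = "model") -> Path:
        """Write ``<name>.json`` (architecture + config + scaler) and
        ``<name>.weights.npz`` (parameter arrays) into ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "n_categories": self.n_categories,
            "p": int(self.model.exog.shape[1]),
            "network": {
                "n_hidden_layers": self.model.network.n_hidden_layers,
                "hidden_widths": list(self.model.network.hidden_widths),
                "activation": self.model.network.activation,
            },
            "config": self.config.__dict__,
            "collapse_mode": self.collapse_mode,
            "best_epoch": self.best_epoch,
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_sd": self.scaler_sd.tolist(),
        }
        (directory / f"{name}.json").write_text(json.dumps(meta, indent=2))
        np.savez(
            directory / f"{name}.weights.npz",
            **{f"param_{k}": p for k, p in enumerate(self.params)},
        )
        return directory / f"{name}.json"

    @classmethod
    def load(cls, directory: str | Path, name: str = "model") -> "DeepOrdinalResults":
        directory = Path(directory)
        meta = json.loads((directory / f"{name}.json").read_text())
        with np.load(directory / f"{name}.weights.npz") as npz:
            params = [npz[f"param_{k}"] for k in range(len(npz.files))]
        net = NetworkSpec(
            n_hidden_layers=meta["network"]["n_hidden_layers"],
            hidden_widths=tuple(meta["network"]["hidden_widths"]),
            activation=meta["network"]["activation"],
        )
        cfg = TrainConfig(**meta["config"])
        # reconstruct a shell model carrying the shapes needed for scoring
        shell = DeepOrdinalModel.__new__(DeepOrdinalModel)
        shell.endog = np.zeros(0, dtype=np.int64)
        shell.exog = np.zeros((0, meta["p"]))
        shell.n_categories = meta["n_categories"]
        shell.network = net
        shell.standardize = True
        return cls(
            model=shell,
            params=params,
            scaler_mean=np.asarray(meta["scaler_mean"]),
            scaler_sd=np.asarray(meta["scaler_sd"]),
            config=cfg,
            train_log=pd.DataFrame(columns=["epoch", "train_loss", "val_loss"]),
            best_epoch=meta["best_epoch"],
            collapse_mode=meta["collapse_mode"],
        )


def fit_donn(
    X,
    y,
    n_categories: int | None = None,
    network: NetworkSpec | None = None,
    config: TrainConfig | None = None,
) -> DeepOrdinalResults:
    """Fit the full deep ordinal neural network on an ordinal outcome."""
    return DeepOrdinalModel(y, X, n_categories=n_categories, network=network).fit(
        config
    )


def fit_binary_dnn(
    X,
    y,
    mode: str,
    n_categories: int = 4,
    network: NetworkSpec | None = None,
    config: TrainConfig | None = None,
) -> DeepOrdinalResults:
    """Fit a binary-DNN health-score model after collapsing the outcome.

    Uses the identical architecture, optimiser and hyperparameters as the
    DONN fit, with J = 2.
    """
    X = np.asarray(X, dtype=float)
    y_bin, keep = collapse_labels(y, mode, n_categories)
    if np.unique(y_bin).size < 2:
        raise ValueError(f"collapse mode {mode!r} left a single class")
    res = DeepOrdinalModel(y_bin, X[keep], n_categories=2, network=network).fit(
        config
    )
    res.collapse_mode = mode
    return res
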