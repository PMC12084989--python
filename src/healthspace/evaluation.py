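"""Model comparison: six health-space models, four measures, bootstrap.

The comparison fits, on one training cohort, the deep ordinal network
(DONN), the four binary-DNN variants (0 vs 3 on the extreme groups only;
0 vs 1+2+3, 0+1 vs 2+3, 0+1+2 vs 3 on collapsed labels) and the
proportional-odds baseline — one fit per axis each — then scores any
number of cohorts and reports, per model and dataset, the average Health
Space Index and the three clustering indices. External cohorts are scored
with the normalisation frozen at training time, never refitted.

The bootstrap routine quantifies stability: resample the training cohort
with replacement, refit the named model on each replicate, recompute the
average HSI (on the replicate itself by default, or out-of-bag), and
report the bootstrap mean with a percentile 95% interval.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cluster import metrics_report
from .cohort import SyntheticCohort
from .hsi import pairwise_hsi
from .ordinal import NetworkSpec, TrainConfig, fit_binary_dnn, fit_donn
from .pom import fit_pom
from .space import HealthSpace

__all__ = [
    "MODEL_NAMES",
    "EvaluationReport",
    "BootstrapResult",
    "fit_health_space_model",
    "evaluate_models",
    "bootstrap_hsi",
]

MODEL_NAMES = (
    "DONN",
    "BinaryDNN_0v3",
    "BinaryDNN_0v123",
    "BinaryDNN_01v23",
    "BinaryDNN_012v3",
    "POM",
)

_COLLAPSE_FOR = {
    "BinaryDNN_0v3": "zero_vs_three",
    "BinaryDNN_0v123": "zero_vs_rest",
    "BinaryDNN_01v23": "low_vs_high",
    "BinaryDNN_012v3": "rest_vs_three",
}


def _fit_axis(name, X, y, n_categories, network, config, axis_offset):
    """Fit one axis of the named model; nets get a per-axis seed."""
    if name == "POM":
        return fit_pom(X, y, n_categories)
    cfg = dataclasses.replace(config, seed=config.seed + axis_offset)
    if name == "DONN":
        return fit_donn(X, y, n_categories, network=network, config=cfg)
    mode = _COLLAPSE_FOR.get(name)
    if mode is None:
        raise ValueError(f"unknown model {name!r}; expected one of {MODEL_NAMES}")
    return fit_binary_dnn(
        X, y, mode, n_categories=n_categories, network=network, config=cfg
    )


def fit_health_space_model(
    name: str,
    cohort: SyntheticCohort,
    network: NetworkSpec | None = None,
    config: TrainConfig | None = None,
    normalizer: str = "minmax",
):
    """Fit the named model on both axes and freeze the health space.

    Returns ``(health_space, train_scores)``.
    """
    network = network or NetworkSpec()
    config = config or TrainConfig()
    J = cohort.spec.n_categories
    try:
        res_oxi = _fit_axis(name, cohort.X_oxi, cohort.y, J, network, config, 0)
        res_meta = _fit_axis(name, cohort.X_meta, cohort.y, J, network, config, 1)
    except Exception as exc:
        raise RuntimeError(f"fitting model {name!r} failed: {exc}") from exc
    hs = HealthSpace(res_oxi, res_meta, normalizer=normalizer)
    train_scores = hs.fit_normalization(cohort.X_oxi, cohort.X_meta, cohort.y)
    return hs, train_scores


@dataclass
class EvaluationReport:
    """Per-(model, dataset) table of the four comparison measures."""

    table: pd.DataFrame
    spaces: dict = field(default_factory=dict)
    scores: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(self.table.to_dict(orient="records"), indent=2)
        )

    def best_model(self, dataset: str = "train", measure: str = "avg_hsi") -> str:
        sub = self.table[self.table["dataset"] == dataset]
        higher_better = measure != "davies_bouldin"
        idx = sub[measure].idxmax() if higher_better else sub[measure].idxmin()
        return str(sub.loc[idx, "model"])


def evaluate_models(
    train: SyntheticCohort,
    eval_sets: dict[str, SyntheticCohort] | None = None,
    model_names=MODEL_NAMES,
    network: NetworkSpec | None = None,
    config: TrainConfig | None = None,
    normalizer: str = "minmax",
    hsi_level: float = 0.95,
    hsi_method: str = "grid",
    hsi_resolution: int = 512,
    keep_spaces: bool = True,
) -> EvaluationReport:
    """Fit every named model once and measure every cohort.

    Each model is fitted (both axes) on ``train`` only; cohorts in
    ``eval_sets`` are scored with the frozen training normalisation. The
    report holds one row per (model, dataset) with the average HSI,
    silhouette, Davies-Bouldin and Calinski-Harabasz measures.
    """
    if np.unique(train.y).size < train.spec.n_categories:
        raise ValueError("training cohort must contain every outcome category")
    eval_sets = eval_sets or {}
    rows = []
    spaces: dict = {}
    all_scores: dict = {}
    for name in model_names:
        hs, train_scores = fit_health_space_model(
            name, train, network=network, config=config, normalizer=normalizer
        )
        if keep_spaces:
            spaces[name] = hs
        datasets = {"train": train_scores}
        for ds_name, cohort in eval_sets.items():
            datasets[ds_name] = hs.transform(cohort.X_oxi, cohort.X_meta, cohort.y)
        for ds_name, scores in datasets.items():
            hsi = pairwise_hsi(
                scores.points,
                scores.labels,
                level=hsi_level,
                method=hsi_method,
                resolution=hsi_resolution,
            )
            rep = metrics_report(scores.points, scores.labels)
            rows.append(
                {
                    "model": name,
                    "dataset": ds_name,
                    "avg_hsi": hsi.average,
                    "silhouette": rep.silhouette,
                    "davies_bouldin": rep.davies_bouldin,
                    "calinski_harabasz": rep.calinski_harabasz,
                    "n": scores.n,
                }
            )
            if keep_spaces:
                all_scores[(name, ds_name)] = scores
    return EvaluationReport(
        table=pd.DataFrame(rows), spaces=spaces, scores=all_scores
    )


@dataclass
class BootstrapResult:
    """Bootstrap distribution of one model's average HSI."""

    model_name: str
    B: int
    point_estimate: float
    boot_mean: float
    ci_low: float
    ci_high: float
    replicates: np.ndarray

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "B": self.B,
            "point_estimate": self.point_estimate,
            "boot_mean": self.boot_mean,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "replicates": self.replicates.tolist(),
        }


def _required_categories(name: str, J: int) -> set[int]:
    mode = _COLLAPSE_FOR.get(name)
    if mode == "zero_vs_three":
        return {0, J - 1}
    return set(range(J))


def bootstrap_hsi(
    cohort: SyntheticCohort,
    model_name: str = "DONN",
    B: int = 200,
    seed: int = 0,
    network: NetworkSpec | None = None,
    config: TrainConfig | None = None,
    normalizer: str = "minmax",
    refit: bool = True,
    out_of_bag: bool = False,
    hsi_level: float = 0.95,
    hsi_method: str = "grid",
    hsi_resolution: int = 512,
    max_redraws: int = 10,
) -> BootstrapResult:
    """Percentile bootstrap of the average HSI for one model.

    Each replicate resamples the cohort rows with replacement; with
    ``refit=True`` (default) the model is refitted on the replicate —
    capturing variability of the whole training pipeline — otherwise the
    full-data fit is kept and only the scored sample varies. The average
    HSI of each replicate is evaluated on the replicate itself by
    default, or on the out-of-bag rows with ``out_of_bag=True``.
    Replicates missing a category the model needs are redrawn (at most
    ``max_redraws`` times each).
    """
    if B < 2:
        raise ValueError("B must be at least 2")
    network = network or NetworkSpec()
    config = config or TrainConfig()
    rng = np.random.default_rng(seed)
    n = cohort.n
    J = cohort.spec.n_categories
    needed = _required_categories(model_name, J)

    hs_full, full_scores = fit_health_space_model(
        model_name, cohort, network=network, config=config, normalizer=normalizer
    )
    hsi_kwargs = dict(
        level=hsi_level, method=hsi_method, resolution=hsi_resolution
    )
    point = pairwise_hsi(full_scores.points, full_scores.labels, **hsi_kwargs).average

    reps = np.empty(B)
    for b in range(B):
        for attempt in range(max_redraws + 1):
            idx = rng.integers(0, n, size=n)
            if needed <= set(np.unique(cohort.y[idx]).tolist()):
                break
        else:
            raise RuntimeError(
                f"replicate {b} missing required categories after "
                f"{max_redraws} redraws"
            )
        boot = SyntheticCohort(
            X_oxi=cohort.X_oxi[idx],
            X_meta=cohort.X_meta[idx],
            y=cohort.y[idx],
            spec=cohort.spec,
        )
        rep_cfg = dataclasses.replace(config, seed=int(rng.integers(2**31)))
        if refit:
            hs_b, scores_b = fit_health_space_model(
                model_name, boot, network=network, config=rep_cfg,
                normalizer=normalizer,
            )
        else:
            hs_b = hs_full
            scores_b = hs_full.transform(boot.X_oxi, boot.X_meta, boot.y)
        if out_of_bag:
            oob = np.setdiff1d(np.arange(n), idx)
            scores_b = hs_b.transform(
                cohort.X_oxi[oob], cohort.X_meta[oob], cohort.y[oob]
            )
        reps[b] = pairwise_hsi(scores_b.points, scores_b.labels, **hsi_kwargs).average

    lo, hi = np.percentile(reps, [2.5, 97.5])
    return BootstrapResult(
        model_name=model_name,
        B=B,
        point_estimate=float(point),
        boot_mean=float(reps.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        replicates=reps,
    )
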