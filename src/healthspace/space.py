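"""Two-axis health space: per-individual (oxidation, metabolism) scores.

One fitted model per axis produces the raw scores ``(W_oxi' b_oxi,
W_meta' b_meta)``; these are oriented so that larger means worse (the
axis is flipped, and the flip recorded, when the fitted score correlates
negatively with the ordinal labels) and then mapped into [0, 1] — by
training-set min-max with clamping for new data (default), or by a
sigmoid squashing. Normalisation constants are frozen at training time so
external cohorts are scored on the same scale as the training cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from ._nn import sigmoid

__all__ = [
    "HealthSpaceScores",
    "HealthSpace",
    "compute_health_space",
    "plot_health_space",
]

logger = logging.getLogger(__name__)


@dataclass
class HealthSpaceScores:
    """Per-individual 2-D health-space coordinates.

    ``raw_*`` are the (orientation-corrected) linear predictors; ``norm_*``
    the [0, 1]-normalized scores. ``normalization`` records the constants
    used so any cohort can be mapped onto the training scale;
    ``n_clamped`` counts out-of-range points clamped into [0, 1].
    """

    raw_oxi: np.ndarray
    raw_meta: np.ndarray
    norm_oxi: np.ndarray
    norm_meta: np.ndarray
    labels: np.ndarray
    normalization: dict = field(default_factory=dict)
    n_clamped: int = 0

    @property
    def n(self) -> int:
        return self.raw_oxi.shape[0]

    @property
    def points(self) -> np.ndarray:
        """The n x 2 matrix of normalized (oxidation, metabolism) scores."""
        return np.column_stack([self.norm_oxi, self.norm_meta])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": np.arange(self.n),
                "raw_oxi": self.raw_oxi,
                "raw_meta": self.raw_meta,
                "norm_oxi": self.norm_oxi,
                "norm_meta": self.norm_meta,
                "label": self.labels,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class HealthSpace:
    """Builds and freezes a two-axis health space from two fitted models.

    Parameters
    ----------
    results_oxi, results_meta
        Fitted results objects exposing ``health_score(X)`` (DONN,
        binary-DNN or proportional-odds fits).
    normalizer : {"minmax", "sigmoid"}
        How raw scores are mapped into [0, 1]. ``minmax`` rescales by the
        training-set range (training min/max map to exactly 0/1; new data
        are clamped). ``sigmoid`` applies a logistic squashing centred at
        the mean fitted threshold of each axis model.
    """

    def __init__(self, results_oxi, results_meta, normalizer: str = "minmax"):
        if normalizer not in ("minmax", "sigmoid"):
            raise ValueError(f"unknown normalizer {normalizer!r}")
        self.results_oxi = results_oxi
        self.results_meta = results_meta
        self.normalizer = normalizer
        self._constants: dict | None = None

    @property
    def is_frozen(self) -> bool:
        return self._constants is not None

    def _raw(self, X_oxi, X_meta) -> tuple[np.ndarray, np.ndarray]:
        r_oxi = np.asarray(self.results_oxi.health_score(X_oxi), dtype=float)
        r_meta = np.asarray(self.results_meta.health_score(X_meta), dtype=float)
        if r_oxi.shape[0] != r_meta.shape[0]:
            raise ValueError(
                f"row-count mismatch between axes: {r_oxi.shape[0]} vs "
                f"{r_meta.shape[0]}"
            )
        return r_oxi, r_meta

    def fit_normalization(self, X_oxi, X_meta, labels) -> HealthSpaceScores:
        """Orient and normalise on the training cohort; freeze constants."""
        labels = np.asarray(labels)
        r_oxi, r_meta = self._raw(X_oxi, X_meta)
        consts: dict = {"normalizer": self.normalizer}
        for axis, raw in (("oxi", r_oxi), ("meta", r_meta)):
            rho = spearmanr(raw, labels).statistic if labels.size > 1 else 1.0
            flip = bool(np.isfinite(rho) and rho < 0)
            consts[f"flip_{axis}"] = flip
            oriented = -raw if flip else raw
            if self.normalizer == "minmax":
                lo, hi = float(oriented.min()), float(oriented.max())
                if hi <= lo:
                    hi = lo + 1.0  # degenerate constant axis
                consts[f"min_{axis}"], consts[f"max_{axis}"] = lo, hi
            else:
                results = self.results_oxi if axis == "oxi" else self.results_meta
                shift = float(np.mean(getattr(results, "alpha", np.zeros(1))))
                consts[f"shift_{axis}"] = shift
        self._constants = consts
        return self.transform(X_oxi, X_meta, labels)

    def transform(self, X_oxi, X_meta, labels=None) -> HealthSpaceScores:
        """Score a cohort with the frozen constants (clamping new data)."""
        if self._constants is None:
            raise RuntimeError(
                "normalization not fitted; call fit_normalization first"
            )
        c = self._constants
        r_oxi, r_meta = self._raw(X_oxi, X_meta)
        n = r_oxi.shape[0]
        labels = (
            np.full(n, -1, dtype=np.int64)
            if labels is None
            else np.asarray(labels, dtype=np.int64)
        )
        if labels.shape[0] != n:
            raise ValueError("labels length does not match score rows")
        norm = {}
        raw = {}
        n_clamped = 0
        for axis, r in (("oxi", r_oxi), ("meta", r_meta)):
            oriented = -r if c[f"flip_{axis}"] else r
            raw[axis] = oriented
            if self.normalizer == "minmax":
                lo, hi = c[f"min_{axis}"], c[f"max_{axis}"]
                v = (oriented - lo) / (hi - lo)
                n_clamped += int(np.sum((v < 0) | (v > 1)))
                norm[axis] = np.clip(v, 0.0, 1.0)
            else:
                norm[axis] = sigmoid(oriented + c[f"shift_{axis}"])
        if n_clamped:
            logger.info("clamped %d out-of-range normalized scores", n_clamped)
        return HealthSpaceScores(
            raw_oxi=raw["oxi"],
            raw_meta=raw["meta"],
            norm_oxi=norm["oxi"],
            norm_meta=norm["meta"],
            labels=labels,
            normalization=dict(c),
            n_clamped=n_clamped,
        )


def compute_health_space(
    results_oxi,
    results_meta,
    X_oxi,
    X_meta,
    labels,
    normalizer: str = "minmax",
) -> HealthSpaceScores:
    """One-shot health space on a training cohort (fit + score).

    For scoring external cohorts on a frozen scale, build a
    :class:`HealthSpace`, call ``fit_normalization`` on the training
    cohort and ``transform`` on each external one.
    """
    hs = HealthSpace(results_oxi, results_meta, normalizer=normalizer)
    return hs.fit_normalization(X_oxi, X_meta, labels)


_GROUP_COLORS = ("#2c7fb8", "#7fcdbb", "#fdae61", "#d7191c")


def plot_health_space(scores: HealthSpaceScores, path, title: str | None = None):
    """Scatter the health space: x = oxidation, y = metabolism score.

    One colour per ordinal group with a legend; axes fixed to [0, 1] for
    min-max-normalized scores. Returns the matplotlib figure (also saved
    to ``path`` when given).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    groups = np.unique(scores.labels)
    for k, g in enumerate(groups):
        mask = scores.labels == g
        ax.scatter(
            scores.norm_oxi[mask],
            scores.norm_meta[mask],
            s=8,
            alpha=0.6,
            color=_GROUP_COLORS[k % len(_GROUP_COLORS)],
            label=f"group {g}",
        )
    ax.set_xlabel("oxidation score")
    ax.set_ylabel("metabolism score")
    if scores.normalization.get("normalizer", "minmax") == "minmax":
        ax.set_xlim(-0.02, 1.02)
        ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="best", frameon=False)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
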