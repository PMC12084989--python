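"""Synthetic cohort generation for health-space modelling.

Cohorts mimic the structure the two-axis health-space models assume: an
"oxidation" covariate block (age, sex, smoking, white-blood-cell and ALT
analogues; 5 columns by default) and a "metabolism" block (age, sex, BMI,
triglyceride, HDL and glucose analogues; 6 columns), sharing their first
two columns, with a 4-level ordered outcome drawn from a cumulative-logit
latent process with optional nonlinear effects.

Because the generating parameters are known, every downstream stage
(ordinal fits, health-space scores, separation indices) can be tested for
parameter and score recovery.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "true_cumulative_probs",
    "write_cohort",
    "read_cohort_csv",
]

#: default true coefficients: moderate, mixed-sign effects giving four
#: reasonably balanced outcome groups when alpha_true is at its default.
_DEFAULT_BETA_OXI = (0.6, 0.4, 0.5, 0.45, 0.35)
_DEFAULT_BETA_META = (0.3, 0.2, 0.55, 0.4, -0.45, 0.5)
_DEFAULT_ALPHA = (2.0, 0.0, -2.0)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


@dataclass(frozen=True)
class CohortSpec:
    """Generating parameters of a synthetic cohort.

    The ordinal outcome follows ``Pr(Y > j | x) = sigma((alpha_j + g(x)) /
    noise_scale)`` where ``g`` is linear in the true coefficients plus the
    chosen nonlinearity. ``alpha_true`` must be strictly decreasing so the
    cumulative probabilities are valid.

    Parameters
    ----------
    n_samples : int
        Cohort size.
    n_categories : int
        Number of ordered outcome levels J (default 4).
    seed : int
        Seed for all random draws; cohorts are bit-identical for a fixed
        spec.
    alpha_true : tuple of float, length J - 1
        Threshold intercepts of the "Y > j" cumulative logits, strictly
        decreasing in j.
    beta_oxi_true, beta_meta_true : tuple of float
        True linear coefficients of the oxidation (width 5 by default) and
        metabolism (width 6) covariate blocks.
    nonlinearity : {"none", "quadratic", "interaction"}
        Optional nonlinear term added to g: ``c * x1**2`` (quadratic in the
        shared age analogue) or ``c * x1 * x2`` (age-by-sex interaction).
    nonlin_coef : float
        Coefficient c of the nonlinear term.
    noise_scale : float
        Scale of the latent logistic noise; 1.0 is the canonical
        cumulative-logit model, larger values produce noisier labels.
    n_shared : int
        Leading columns shared (identical draws) between the two blocks.
    """

    n_samples: int
    n_categories: int = 4
    seed: int = 0
    alpha_true: tuple[float, ...] = _DEFAULT_ALPHA
    beta_oxi_true: tuple[float, ...] = _DEFAULT_BETA_OXI
    beta_meta_true: tuple[float, ...] = _DEFAULT_BETA_META
    nonlinearity: str = "none"
    nonlin_coef: float = 1.0
    noise_scale: float = 1.0
    n_shared: int = 2

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be a positive integer")
        if self.n_categories < 2:
            raise ValueError(
                f"n_categories must be >= 2, got {self.n_categories}"
            )
        alpha = np.asarray(self.alpha_true, dtype=float)
        if alpha.shape != (self.n_categories - 1,):
            raise ValueError(
                f"alpha_true must have length J - 1 = {self.n_categories - 1}, "
                f"got {alpha.shape[0]}"
            )
        if not np.all(np.diff(alpha) < 0):
            raise ValueError(
                "alpha_true must be strictly decreasing in j "
                "(the 'Y > j' thresholds)"
            )
        if self.nonlinearity not in ("none", "quadratic", "interaction"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")
        if self.noise_scale <= 0:
            raise ValueError("noise_scale must be positive")
        if not (0 <= self.n_shared <= min(self.p_oxi, self.p_meta)):
            raise ValueError("n_shared exceeds a covariate block width")

    @property
    def p_oxi(self) -> int:
        return len(self.beta_oxi_true)

    @property
    def p_meta(self) -> int:
        return len(self.beta_meta_true)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        for key in ("alpha_true", "beta_oxi_true", "beta_meta_true"):
            d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticCohort:
    """A generated cohort: two covariate blocks and the ordinal outcome."""

    X_oxi: np.ndarray
    X_meta: np.ndarray
    y: np.ndarray
    spec: CohortSpec

    @property
    def n(self) -> int:
        return self.y.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = {
            f"oxi_{k + 1}": self.X_oxi[:, k] for k in range(self.X_oxi.shape[1])
        }
        cols.update(
            {f"meta_{k + 1}": self.X_meta[:, k] for k in range(self.X_meta.shape[1])}
        )
        cols["label"] = self.y
        return pd.DataFrame(cols)


def _draw_covariates(
    spec: CohortSpec, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw the two blocks: continuous columns standard normal, the shared
    sex analogue (column 1) and the oxidation block's smoking analogue
    (column 2) Bernoulli(0.5)."""
    n = spec.n_samples
    shared = np.empty((n, spec.n_shared))
    for k in range(spec.n_shared):
        if k == 1:
            shared[:, k] = rng.binomial(1, 0.5, size=n)
        else:
            shared[:, k] = rng.standard_normal(n)

    def block(p: int, binary_cols: set[int]) -> np.ndarray:
        X = np.empty((n, p))
        X[:, : spec.n_shared] = shared
        for k in range(spec.n_shared, p):
            if k in binary_cols:
                X[:, k] = rng.binomial(1, 0.5, size=n)
            else:
                X[:, k] = rng.standard_normal(n)
        return X

    X_oxi = block(spec.p_oxi, binary_cols={2})  # smoking-status analogue
    X_meta = block(spec.p_meta, binary_cols=set())
    return X_oxi, X_meta


def _latent_predictor(
    spec: CohortSpec, X_oxi: np.ndarray, X_meta: np.ndarray
) -> np.ndarray:
    """g(x): linear part over both blocks plus the optional nonlinearity."""
    g = X_oxi @ np.asarray(spec.beta_oxi_true) + X_meta @ np.asarray(
        spec.beta_meta_true
    )
    if spec.nonlinearity == "quadratic":
        g = g + spec.nonlin_coef * X_oxi[:, 0] ** 2
    elif spec.nonlinearity == "interaction":
        g = g + spec.nonlin_coef * X_oxi[:, 0] * X_oxi[:, 1]
    return g


def true_cumulative_probs(
    spec: CohortSpec, X_oxi: np.ndarray, X_meta: np.ndarray
) -> np.ndarray:
    """Exact exceedance probabilities Pr(Y > j | x) of the generating process.

    Returns an ``n x (J - 1)`` matrix whose rows are non-increasing across
    j (guaranteed by the strictly decreasing thresholds). Serves as the
    oracle for recovery tests.
    """
    X_oxi = np.asarray(X_oxi, dtype=float)
    X_meta = np.asarray(X_meta, dtype=float)
    if X_oxi.ndim != 2 or X_oxi.shape[1] != spec.p_oxi:
        raise ValueError(
            f"X_oxi must have {spec.p_oxi} columns, got shape {X_oxi.shape}"
        )
    if X_meta.ndim != 2 or X_meta.shape[1] != spec.p_meta:
        raise ValueError(
            f"X_meta must have {spec.p_meta} columns, got shape {X_meta.shape}"
        )
    g = _latent_predictor(spec, X_oxi, X_meta)
    alpha = np.asarray(spec.alpha_true)
    return _sigmoid((alpha[None, :] + g[:, None]) / spec.noise_scale)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a cohort from the cumulative-logit process of ``spec``.

    Labels are drawn by inverse-CDF sampling of the J per-row category
    probabilities with a single uniform draw per row, so output is
    bit-identical for a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    X_oxi, X_meta = _draw_covariates(spec, rng)
    exceed = true_cumulative_probs(spec, X_oxi, X_meta)
    # category probabilities: P(Y=0)=1-S_0, P(Y=j)=S_{j-1}-S_j, P(Y=J-1)=S_{J-2}
    J = spec.n_categories
    probs = np.empty((spec.n_samples, J))
    probs[:, 0] = 1.0 - exceed[:, 0]
    if J > 2:
        probs[:, 1:-1] = exceed[:, :-1] - exceed[:, 1:]
    probs[:, -1] = exceed[:, -1]
    u = rng.uniform(size=spec.n_samples)
    cdf = np.cumsum(probs, axis=1)
    y = (u[:, None] > cdf).sum(axis=1).astype(np.int64)
    np.clip(y, 0, J - 1, out=y)  # guards float round-off at the last edge
    return SyntheticCohort(X_oxi=X_oxi, X_meta=X_meta, y=y, spec=spec)


def write_cohort(cohort: SyntheticCohort, csv_path: str | Path) -> Path:
    """Write the cohort as CSV plus a JSON sidecar holding the full spec."""
    csv_path = Path(csv_path)
    cohort.to_frame().to_csv(csv_path, index=False)
    sidecar = csv_path.with_suffix(".spec.json")
    sidecar.write_text(json.dumps(cohort.spec.to_dict(), indent=2))
    return csv_path


def read_cohort_csv(csv_path: str | Path) -> SyntheticCohort:
    """Read a cohort written by :func:`write_cohort` (spec sidecar required)."""
    csv_path = Path(csv_path)
    spec = CohortSpec.from_dict(
        json.loads(csv_path.with_suffix(".spec.json").read_text())
    )
    df = pd.read_csv(csv_path)
    X_oxi = df[[f"oxi_{k + 1}" for k in range(spec.p_oxi)]].to_numpy(float)
    X_meta = df[[f"meta_{k + 1}" for k in range(spec.p_meta)]].to_numpy(float)
    y = df["label"].to_numpy(np.int64)
    return SyntheticCohort(X_oxi=X_oxi, X_meta=X_meta, y=y, spec=spec)
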