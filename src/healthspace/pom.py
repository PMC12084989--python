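"""Proportional-odds (cumulative-logit) baseline health-score model.

The classical ordinal regression with a linear predictor and shared
slopes across thresholds::

    log Pr(Y > j | x) / Pr(Y <= j | x) = alpha_j + x' beta.

Maximum likelihood is delegated to :class:`statsmodels.miscmodels.
ordinal_model.OrderedModel` (logit link), whose increasing-threshold
parameterization ``Pr(Y <= j) = sigma(theta_j - x'beta)`` maps onto the
convention used throughout this package via ``alpha_j = -theta_j``; the
monotone-threshold constraint is handled there through cumulative
differences of positive increments. The axis health score is ``x' beta``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.miscmodels.ordinal_model import OrderedModel

from ._nn import sigmoid

__all__ = ["ProportionalOddsModel", "ProportionalOddsResults", "fit_pom"]


class ProportionalOddsModel:
    """Cumulative-logit ordinal regression with shared slopes."""

    def __init__(self, endog, exog, n_categories: int | None = None) -> None:
        self.endog = np.asarray(endog, dtype=np.int64)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("exog must be 2-d with one row per label")
        self.n_categories = (
            int(self.endog.max()) + 1 if n_categories is None else int(n_categories)
        )
        present = np.unique(self.endog)
        if present.size < self.n_categories:
            missing = sorted(set(range(self.n_categories)) - set(present.tolist()))
            raise ValueError(f"categories {missing} absent from the data")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_col: str, feature_cols, **kw):
        return cls(df[label_col].to_numpy(), df[feature_cols].to_numpy(float), **kw)

    def fit(self, method: str = "bfgs", maxiter: int = 500) -> "ProportionalOddsResults":
        sm_model = OrderedModel(self.endog, self.exog, distr="logit")
        res = sm_model.fit(method=method, maxiter=maxiter, disp=False)
        grad_norm = float(np.linalg.norm(sm_model.score(res.params)))
        converged = bool(res.mle_retvals.get("converged", True))
        if not converged and grad_norm > 1e-2 * max(1, self.endog.shape[0]):
            raise RuntimeError(
                "proportional-odds fit did not converge "
                f"(gradient norm {grad_norm:.3g}); the data may be separable"
            )
        p = self.exog.shape[1]
        thresholds = sm_model.transform_threshold_params(res.params)[1:-1]
        return ProportionalOddsResults(
            model=self,
            beta=np.asarray(res.params[:p], dtype=float),
            alpha=-np.asarray(thresholds, dtype=float),
            llf=float(res.llf),
            n_iter=int(res.mle_retvals.get("iterations", -1)),
            gradient_norm=grad_norm,
            bse=np.asarray(res.bse[:p], dtype=float),
        )


@dataclass
class ProportionalOddsResults:
    """MLE of the proportional-odds model in 'Y > j' orientation."""

    model: ProportionalOddsModel
    beta: np.ndarray
    alpha: np.ndarray  # strictly decreasing in j
    llf: float
    n_iter: int
    gradient_norm: float
    bse: np.ndarray

    @property
    def n_categories(self) -> int:
        return self.alpha.shape[0] + 1

    def _check(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.beta.shape[0]:
            raise ValueError(
                f"expected {self.beta.shape[0]} columns, got {X.shape[1]}"
            )
        return X

    def health_score(self, X) -> np.ndarray:
        """Linear predictor x' beta (no intercepts)."""
        return self._check(X) @ self.beta

    def predict_cumulative(self, X) -> np.ndarray:
        """Pr(Y > j | x) = sigma(alpha_j + x'beta), shape (n, J - 1)."""
        s = self.health_score(X)
        return sigmoid(s[:, None] + self.alpha[None, :])

    def predict_proba(self, X) -> np.ndarray:
        S = self.predict_cumulative(X)
        J = self.n_categories
        out = np.empty((S.shape[0], J))
        out[:, 0] = 1.0 - S[:, 0]
        if J > 2:
            out[:, 1:-1] = S[:, :-1] - S[:, 1:]
        out[:, -1] = S[:, -1]
        return out

    def log_likelihood(self, X=None, y=None) -> float:
        """Ordered-logit log likelihood; at the MLE on the training data
        this equals ``llf``."""
        if X is None:
            return self.llf
        P = self.predict_proba(X)
        y = np.asarray(y, dtype=np.int64)
        return float(np.sum(np.log(np.clip(P[np.arange(y.size), y], 1e-300, None))))

    def summary(self) -> str:
        lines = [
            "Proportional odds model results",
            "=" * 40,
            f"n obs:           {self.model.endog.shape[0]}",
            f"categories (J):  {self.n_categories}",
            f"log-likelihood:  {self.llf:.3f}",
            f"iterations:      {self.n_iter}",
        ]
        for k, (b, se) in enumerate(zip(self.beta, self.bse)):
            lines.append(f"beta[{k}]:  {b:+.4f}  (se {se:.4f})")
        lines.append(f"alpha:  {np.array2string(self.alpha, precision=4)}")
        return "\n".join(lines)


def fit_pom(X, y, n_categories: int | None = None) -> ProportionalOddsResults:
    """Maximum-likelihood proportional-odds fit (functional wrapper)."""
    return ProportionalOddsModel(y, X, n_categories=n_categories).fit()
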