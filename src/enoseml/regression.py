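"""Gaussian-kernel ridge regression.

Given N training observations X_n with targets A(X_n), the prediction at a
query x is

    A*(x) = k(x)^T (K + lambda I)^{-1} A,

where K_{nm} = k(X_n, X_m), k(x)_n = k(X_n, x), I is the N x N identity
and the kernel is Gaussian, k(u, v) = exp(-|u - v|^2 / (2 sigma^2)).
The dual weights (K + lambda I)^{-1} A are obtained by a Cholesky solve
(with a generic symmetric solve as fallback), never by explicit inversion,
and are checked against a relative-residual tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.linalg import cho_factor, cho_solve, solve
from scipy.spatial.distance import cdist

_RESIDUAL_RTOL = 1e-8


def gaussian_kernel(x: np.ndarray, y: np.ndarray, sigma: float) -> float:
    """k(x, y) = exp(-|x - y|^2 / (2 sigma^2)); lies in (0, 1]."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    return float(np.exp(-np.sum((x - y) ** 2) / (2.0 * sigma**2)))


def kernel_matrix(X: np.ndarray, Y: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian kernel matrix between the rows of X and the rows of Y."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    sq = cdist(np.atleast_2d(X), np.atleast_2d(Y), metric="sqeuclidean")
    return np.exp(-sq / (2.0 * sigma**2))


def _solve_regularized(K: np.ndarray, lam: float, A: np.ndarray) -> np.ndarray:
    """Solve (K + lam I) w = A; raises LinAlgError for (near-)singular systems."""
    M = K + lam * np.eye(len(K))
    try:
        w = cho_solve(cho_factor(M, lower=True), A)
    except np.linalg.LinAlgError:
        try:
            w = solve(M, A, assume_a="sym")
        except np.linalg.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                "K + lambda*I is singular; use lambda > 0"
            ) from exc
    residual = np.linalg.norm(M @ w - A)
    if residual > _RESIDUAL_RTOL * max(np.linalg.norm(A), 1e-30):
        raise np.linalg.LinAlgError(
            f"ill-conditioned kernel system (relative residual "
            f"{residual / max(np.linalg.norm(A), 1e-30):.2e}); use lambda > 0"
        )
    return w


@dataclass
class KernelRidge:
    """Kernel ridge regression model (fit returns a results object).

    Parameters
    ----------
    X : array_like, N x d
        Training features (normalized upstream; this class does not scale).
    A : array_like, length N
        Training targets (alcohol content, vol %).
    lam : float
        Ridge strength, >= 0 (0 only when K is numerically invertible).
    sigma : float
        Gaussian kernel width, > 0.
    column_labels, normalization_sds : optional metadata carried through
        to serialization so a saved model can be applied to raw features.
    """

    X: np.ndarray
    A: np.ndarray
    lam: float
    sigma: float
    column_labels: list[str] | None = None
    normalization_sds: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.A = np.asarray(self.A, dtype=float).ravel()
        if len(self.X) != len(self.A):
            raise ValueError("X and A must have the same number of rows")
        if len(self.A) < 1:
            raise ValueError("need at least one training observation")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def fit(self) -> "KernelRidgeResults":
        K = kernel_matrix(self.X, self.X, self.sigma)
        dual_weights = _solve_regularized(K, self.lam, self.A)
        return KernelRidgeResults(model=self, K=K, dual_weights=dual_weights)


@dataclass
class KernelRidgeResults:
    """Fitted KRR: dual weights, in-sample fit and prediction."""

    model: KernelRidge
    K: np.ndarray
    dual_weights: np.ndarray
    _fitted: np.ndarray | None = field(default=None, repr=False)

    @property
    def fittedvalues(self) -> np.ndarray:
        if self._fitted is None:
            self._fitted = self.K @ self.dual_weights
        return self._fitted

    @property
    def resid(self) -> np.ndarray:
        return self.model.A - self.fittedvalues

    def predict(self, X_query: np.ndarray) -> np.ndarray:
        """A*(x) = sum_n k(X_n, x) w_n for each query row."""
        Xq = np.atleast_2d(np.asarray(X_query, dtype=float))
        if Xq.shape[1] != self.model.X.shape[1]:
            raise ValueError(
                f"query dimension {Xq.shape[1]} != training "
                f"dimension {self.model.X.shape[1]}"
            )
        k = kernel_matrix(Xq, self.model.X, self.model.sigma)
        return k @ self.dual_weights

    def mse(self) -> float:
        return float(np.mean(self.resid**2))

    def summary(self) -> str:
        m = self.model
        lines = [
            "Kernel Ridge Regression Results",
            "=" * 46,
            f"{'No. observations:':<28}{len(m.A):>18d}",
            f"{'Feature dimension:':<28}{m.X.shape[1]:>18d}",
            f"{'Ridge strength lambda:':<28}{m.lam:>18.6g}",
            f"{'Kernel width sigma:':<28}{m.sigma:>18.6g}",
            f"{'Training MSE (vol %)^2:':<28}{self.mse():>18.6g}",
            f"{'Dual weight norm:':<28}{np.linalg.norm(self.dual_weights):>18.6g}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def save(self, path: str | Path) -> None:
        m = self.model
        payload = {
            "lambda": float(m.lam),
            "sigma": float(m.sigma),
            "X_train": m.X.tolist(),
            "A": m.A.tolist(),
            "dual_weights": self.dual_weights.tolist(),
            "column_labels": list(m.column_labels) if m.column_labels else None,
            "normalization_sds": (
                np.asarray(m.normalization_sds, dtype=float).tolist()
                if m.normalization_sds is not None
                else None
            ),
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_results(path: str | Path) -> KernelRidgeResults:
    payload = yaml.safe_load(Path(path).read_text())
    model = KernelRidge(
        X=np.array(payload["X_train"], dtype=float),
        A=np.array(payload["A"], dtype=float),
        lam=payload["lambda"],
        sigma=payload["sigma"],
        column_labels=payload.get("column_labels"),
        normalization_sds=(
            np.array(payload["normalization_sds"], dtype=float)
            if payload.get("normalization_sds") is not None
            else None
        ),
    )
    return KernelRidgeResults(
        model=model,
        K=kernel_matrix(model.X, model.X, model.sigma),
        dual_weights=np.array(payload["dual_weights"], dtype=float),
    )


def fit_krr(
    X: np.ndarray, A: np.ndarray, lam: float, sigma: float
) -> KernelRidgeResults:
    """Convenience wrapper: build and fit a :class:`KernelRidge`."""
    return KernelRidge(X=X, A=A, lam=lam, sigma=sigma).fit()


def predict(results: KernelRidgeResults, X_query: np.ndarray) -> np.ndarray:
    """Functional alias for :meth:`KernelRidgeResults.predict`."""
    return results.predict(X_query)
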