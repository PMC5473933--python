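"""Cross-validated hyperparameter tuning and exhaustive subset search.

The prediction error of one candidate model is the S-fold cross-validation
error: the dataset is randomly split into S folds; for fold s the model is
fitted on the other S-1 folds and the mean-square deviation between actual
and predicted targets is computed on fold s,

    Delta^(s)(lam, sigma) = (1/N_te) sum_{l in D_s} [A(X_l) - A*(X_l)]^2,

and Delta(lam, sigma) is the average over the S folds.  The hyperparameters
(lam*, sigma*) minimize Delta over a grid, and the model's prediction error
is Delta = Delta(lam*, sigma*).

Feature subsets are labelled by a bitmask integer: binary digit i (from the
least significant end) is 1 iff parameter i is used, so e.g. 13 = 1101
selects parameters {1, 3, 4}.  The exhaustive search scores all 2^d - 1
non-empty subsets of the d candidate columns and ranks them by Delta.

Fold grouping: ``"sample"`` (default) keeps the three cycles of one liquid
in one fold, preventing leakage between near-duplicate rows; ``"row"``
splits rows independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .regression import KernelRidge, _solve_regularized
from .signals import FeatureMatrix, normalize_features

GridPoint = tuple[float, float]


def default_grid() -> list[GridPoint]:
    """9 x 9 log-spaced (lambda, sigma) grid, lambda-major.

    lambda spans 1e-6 .. 1e2 (interpolation to heavy shrinkage), sigma
    spans 1e-2 .. 1e2 — brackets the pairwise-distance scale of
    unit-variance features.
    """
    lams = np.logspace(-6, 2, 9)
    sigmas = np.logspace(-2, 2, 9)
    return [(float(l), float(s)) for l in lams for s in sigmas]


def reduced_grid() -> list[GridPoint]:
    """5 x 5 grid spanning the same ranges; for large subset searches."""
    lams = np.logspace(-6, 2, 5)
    sigmas = np.logspace(-1, 1, 5)
    return [(float(l), float(s)) for l in lams for s in sigmas]


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldAssignment:
    """Partition of N rows into S folds (labels 1..S)."""

    S: int
    assignment: np.ndarray
    seed: int
    grouping: str = "row"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "assignment", np.asarray(self.assignment, dtype=int)
        )
        labels = np.unique(self.assignment)
        if len(labels) != self.S or labels.min() != 1 or labels.max() != self.S:
            raise ValueError("assignment must use every fold label 1..S")

    @property
    def n_obs(self) -> int:
        return len(self.assignment)

    def test_indices(self, s: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == s)

    def train_indices(self, s: int) -> np.ndarray:
        return np.flatnonzero(self.assignment != s)


def _deal(n_items: int, S: int, rng: np.random.Generator) -> np.ndarray:
    """Random balanced assignment of n_items to S folds (sizes differ <= 1)."""
    labels = np.tile(np.arange(1, S + 1), n_items // S + 1)[:n_items]
    return labels[rng.permutation(n_items)]


def make_folds(
    N: int,
    S: int,
    seed: int = 0,
    grouping: str = "row",
    sample_names: Sequence[str] | None = None,
) -> FoldAssignment:
    """Randomly partition N rows into S folds.

    With ``grouping="row"`` rows are dealt independently; every fold has
    exactly N/S rows when S divides N, otherwise sizes differ by at most
    one.  With ``grouping="sample"`` whole samples (all cycles of one
    liquid, identified via ``sample_names``) are dealt to folds, so the
    near-duplicate cycle rows of one sample never straddle a fold split.
    """
    if S < 2:
        raise ValueError("need at least 2 folds")
    if S > N:
        raise ValueError(f"S={S} exceeds the number of rows N={N}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF01D]))
    if grouping == "row":
        assignment = _deal(N, S, rng)
    elif grouping == "sample":
        if sample_names is None:
            raise ValueError("grouping='sample' requires sample_names")
        sample_names = np.asarray(sample_names, dtype=object)
        if len(sample_names) != N:
            raise ValueError("sample_names length must equal N")
        uniques = list(dict.fromkeys(sample_names))
        if S > len(uniques):
            raise ValueError(
                f"S={S} exceeds the number of distinct samples {len(uniques)}"
            )
        sample_fold = dict(zip(uniques, _deal(len(uniques), S, rng)))
        assignment = np.array([sample_fold[n] for n in sample_names])
    else:
        raise ValueError("grouping must be 'row' or 'sample'")
    return FoldAssignment(S=S, assignment=assignment, seed=int(seed),
                          grouping=grouping)


# ---------------------------------------------------------------------------
# Cross-validation error
# ---------------------------------------------------------------------------

class _CVEngine:
    """Evaluates Delta(lam, sigma) for one feature subset.

    Caches the sigma-independent squared-distance blocks per fold and the
    per-sigma kernel blocks, so a grid sweep repeats only the linear
    solves.
    """

    def __init__(self, sqdist: np.ndarray, A: np.ndarray, folds: FoldAssignment):
        if len(A) != folds.n_obs or sqdist.shape != (len(A), len(A)):
            raise ValueError("sqdist / A / folds sizes disagree")
        self.A = np.asarray(A, dtype=float)
        self.folds = folds
        self._blocks = []
        for s in range(1, folds.S + 1):
            tr = folds.train_indices(s)
            te = folds.test_indices(s)
            if len(tr) == 0:
                raise ValueError(f"fold {s} has an empty training part")
            self._blocks.append(
                (tr, te, sqdist[np.ix_(tr, tr)], sqdist[np.ix_(te, tr)])
            )
        self._kernel_cache: dict[float, list[tuple[np.ndarray, np.ndarray]]] = {}

    def _kernels(self, sigma: float) -> list[tuple[np.ndarray, np.ndarray]]:
        if sigma not in self._kernel_cache:
            g = 1.0 / (2.0 * sigma**2)
            self._kernel_cache[sigma] = [
                (np.exp(-g * dtr), np.exp(-g * dte))
                for _, _, dtr, dte in self._blocks
            ]
        return self._kernel_cache[sigma]

    def delta(self, lam: float, sigma: float) -> float:
        if sigma <= 0:
            raise ValueError("sigma must be positive")
        if lam < 0:
            raise ValueError("lambda must be >= 0")
        kernels = self._kernels(sigma)
        total = 0.0
        for (tr, te, _, _), (K_tr, K_te) in zip(self._blocks, kernels):
            w = _solve_regularized(K_tr, lam, self.A[tr])
            pred = K_te @ w
            total += float(np.mean((self.A[te] - pred) ** 2))
        return total / self.folds.S


def _pairwise_sq(X: np.ndarray) -> np.ndarray:
    diff = X[:, None, :] - X[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def cv_error(
    X: np.ndarray,
    A: np.ndarray,
    folds: FoldAssignment,
    lam: float,
    sigma: float,
) -> float:
    """S-fold cross-validation error Delta(lam, sigma) for one model."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return _CVEngine(_pairwise_sq(X), np.asarray(A, float), folds).delta(lam, sigma)


@dataclass
class CVResult:
    """Delta surface over a hyperparameter grid and its minimizer."""

    grid: list[GridPoint]
    deltas: np.ndarray
    lambda_star: float
    sigma_star: float
    delta_star: float

    def surface(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda": [g[0] for g in self.grid],
                "sigma": [g[1] for g in self.grid],
                "delta": self.deltas,
            }
        )


def optimize_hyperparameters(
    X: np.ndarray | None,
    A: np.ndarray,
    folds: FoldAssignment,
    grid: Sequence[GridPoint],
    sqdist: np.ndarray | None = None,
) -> CVResult:
    """Evaluate Delta on the full grid and return the argmin.

    Ties are broken by grid order (first encountered wins).  Grid points
    whose linear system fails are recorded as NaN; if every point fails a
    RuntimeError is raised.  ``sqdist`` may carry a precomputed pairwise
    squared-distance matrix (it is sigma-independent).
    """
    grid = list(grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")
    if sqdist is None:
        if X is None:
            raise ValueError("either X or sqdist is required")
        sqdist = _pairwise_sq(np.atleast_2d(np.asarray(X, dtype=float)))
    engine = _CVEngine(sqdist, np.asarray(A, dtype=float), folds)
    deltas = np.empty(len(grid))
    best = None
    for i, (lam, sigma) in enumerate(grid):
        try:
            deltas[i] = engine.delta(lam, sigma)
        except np.linalg.LinAlgError:
            deltas[i] = np.nan
            continue
        if best is None or deltas[i] < deltas[best]:
            best = i
    if best is None:
        raise RuntimeError("every grid point failed (singular systems)")
    return CVResult(
        grid=grid,
        deltas=deltas,
        lambda_star=grid[best][0],
        sigma_star=grid[best][1],
        delta_star=float(deltas[best]),
    )


# ---------------------------------------------------------------------------
# Bitmask subset encoding
# ---------------------------------------------------------------------------

def encode_mask(parameters: Iterable[int], d: int = 4) -> int:
    """Encode a parameter subset as its bitmask label (bit i-1 <=> param i)."""
    params = set(parameters)
    if not params:
        raise ValueError("empty parameter subset")
    if any((not isinstance(p, (int, np.integer))) or p < 1 or p > d
           for p in params):
        raise ValueError(f"parameters must be integers in 1..{d}")
    return sum(1 << (p - 1) for p in params)


def decode_mask(mask: int, d: int = 4) -> set[int]:
    """Inverse of :func:`encode_mask`."""
    if not 1 <= mask < 2**d:
        raise ValueError(f"mask must be in [1, {2**d - 1}]")
    return {i + 1 for i in range(d) if mask >> i & 1}


@dataclass(frozen=True)
class CombinationMask:
    """A non-empty feature subset labelled by its bitmask integer."""

    mask: int
    d: int

    def __post_init__(self) -> None:
        if not 1 <= self.mask < 2**self.d:
            raise ValueError(f"mask must be in [1, {2**self.d - 1}]")

    @property
    def bits(self) -> tuple[int, ...]:
        """0-based column indices selected by the mask, ascending."""
        return tuple(i for i in range(self.d) if self.mask >> i & 1)

    @property
    def parameters(self) -> set[int]:
        return decode_mask(self.mask, self.d)

    @property
    def binary(self) -> str:
        return format(self.mask, f"0{self.d}b")

    def __len__(self) -> int:
        return len(self.bits)


def enumerate_combinations(d: int) -> list[CombinationMask]:
    """All 2^d - 1 non-empty masks over d columns, ascending."""
    if d < 1:
        raise ValueError("d must be >= 1")
    return [CombinationMask(m, d) for m in range(1, 2**d)]


# ---------------------------------------------------------------------------
# Exhaustive subset search
# ---------------------------------------------------------------------------

@dataclass
class SearchResult:
    """One subset's cross-validated score within a search."""

    mask: CombinationMask
    cv: CVResult | None
    column_labels: tuple[str, ...]
    rank: int | None = None
    error: str | None = None

    @property
    def delta(self) -> float:
        return self.cv.delta_star if self.cv is not None else np.inf

    @property
    def selected_columns(self) -> tuple[str, ...]:
        return tuple(self.column_labels[i] for i in self.mask.bits)


def search_combinations(
    features: FeatureMatrix,
    folds: FoldAssignment,
    grid: Sequence[GridPoint],
    masks: Sequence[CombinationMask] | None = None,
    columns: Sequence[str] | None = None,
) -> list[SearchResult]:
    """Score every mask over the chosen columns and rank by Delta.

    ``features`` must contain exactly the rows the folds describe (the
    training set) and should be normalized.  Per mask the pairwise
    squared-distance matrix is assembled from per-column blocks (computed
    once), then the (lambda, sigma) grid is minimized independently.
    Ranking is ascending in Delta, ties broken by smaller mask integer;
    per-mask failures are recorded, ranked last, and never fatal.
    """
    labels = tuple(columns) if columns is not None else tuple(features.X.columns)
    d = len(labels)
    if masks is None:
        masks = enumerate_combinations(d)
    for m in masks:
        if m.d != d:
            raise ValueError(f"mask over {m.d} columns but {d} columns searched")
    Xsub = features.X[list(labels)].to_numpy(dtype=float)
    if len(Xsub) != folds.n_obs:
        raise ValueError(
            f"folds describe {folds.n_obs} rows but features have {len(Xsub)}"
        )
    col_sq = [
        (Xsub[:, j, None] - Xsub[None, :, j]) ** 2 for j in range(d)
    ]
    results: list[SearchResult] = []
    for m in masks:
        sqdist = sum(col_sq[j] for j in m.bits)
        try:
            cv = optimize_hyperparameters(None, features.A, folds, grid,
                                          sqdist=sqdist)
            results.append(SearchResult(mask=m, cv=cv, column_labels=labels))
        except Exception as exc:  # recorded, not fatal
            results.append(
                SearchResult(mask=m, cv=None, column_labels=labels,
                             error=str(exc))
            )
    results.sort(key=lambda r: (r.delta, r.mask.mask))
    for rank, r in enumerate(results, start=1):
        r.rank = rank
    return results


def results_table(results: Sequence[SearchResult]) -> pd.DataFrame:
    """Ranked search results as a flat table."""
    return pd.DataFrame(
        {
            "rank": [r.rank for r in results],
            "mask": [r.mask.mask for r in results],
            "binary": [r.mask.binary for r in results],
            "delta": [r.delta for r in results],
            "lambda_star": [r.cv.lambda_star if r.cv else np.nan for r in results],
            "sigma_star": [r.cv.sigma_star if r.cv else np.nan for r in results],
            "columns": ["+".join(r.selected_columns) for r in results],
            "error": [r.error or "" for r in results],
        }
    )


def usage_rates(results: Sequence[SearchResult], top_k: int) -> pd.Series:
    """Percentage of the top-k ranked masks that include each column."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if top_k > len(results):
        raise ValueError(f"top_k={top_k} exceeds {len(results)} results")
    ordered = sorted(results, key=lambda r: r.rank)[:top_k]
    labels = ordered[0].column_labels
    counts = np.zeros(len(labels))
    for r in ordered:
        for j in r.mask.bits:
            counts[j] += 1
    return pd.Series(100.0 * counts / top_k, index=list(labels), name="usage_%")


def usage_rate_table(rates: pd.Series) -> pd.DataFrame:
    """Pivot ``"<channel>:p<i>"``-labelled usage rates to parameter x channel."""
    rows = []
    for label, value in rates.items():
        channel, param = label.rsplit(":", 1)
        rows.append({"channel": channel, "parameter": param, "usage_%": value})
    frame = pd.DataFrame(rows)
    return frame.pivot(index="parameter", columns="channel", values="usage_%")


# ---------------------------------------------------------------------------
# Held-out evaluation
# ---------------------------------------------------------------------------

def _fit_selected(
    features: FeatureMatrix,
    columns: Sequence[str],
    lam: float,
    sigma: float,
):
    known = np.flatnonzero(features.known)
    if len(known) == 0:
        raise ValueError("no known rows to fit on")
    X_train = features.X[list(columns)].to_numpy(dtype=float)[known]
    return KernelRidge(
        X=X_train,
        A=features.A[known],
        lam=lam,
        sigma=sigma,
        column_labels=list(columns),
    ).fit()


def parity_table(
    features: FeatureMatrix,
    columns: Sequence[str],
    lam: float,
    sigma: float,
) -> pd.DataFrame:
    """Predicted vs actual alcohol content for every row.

    The model is fitted on the known rows only (with the normalization
    the matrix already carries), then applied to all rows, so unknown
    rows are genuine out-of-sample predictions.
    """
    fitted = _fit_selected(features, columns, lam, sigma)
    preds = fitted.predict(features.X[list(columns)].to_numpy(dtype=float))
    return pd.DataFrame(
        {
            "sample": features.sample_names,
            "t_a": features.t_a,
            "actual": features.A,
            "predicted": preds,
            "known": features.known,
        }
    )


def evaluate_unknowns(
    features: FeatureMatrix,
    result: SearchResult,
    lam: float | None = None,
    sigma: float | None = None,
) -> pd.DataFrame:
    """Parity records for the held-out unknown rows under one search result."""
    if result.cv is None and (lam is None or sigma is None):
        raise ValueError("result carries no fitted hyperparameters")
    lam = result.cv.lambda_star if lam is None else lam
    sigma = result.cv.sigma_star if sigma is None else sigma
    table = parity_table(features, result.selected_columns, lam, sigma)
    return table[~table["known"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# Model-style wrapper
# ---------------------------------------------------------------------------

class SubsetSearch:
    """Exhaustive feature-subset selection as a fit/results model.

    Parameters
    ----------
    features : FeatureMatrix
        Full observation matrix (known + unknown rows).  If unnormalized,
        it is normalized over the known rows on construction.
    S : int
        Fold count (default 24).
    seed : int
        Fold-assignment seed.
    grouping : {"sample", "row"}
        Whether a sample's cycles stay in one fold (default) or rows are
        dealt independently.
    grid : list of (lambda, sigma)
        Hyperparameter grid; :func:`default_grid` if omitted.
    columns : sequence of str, optional
        Restrict the search to these feature columns (e.g. one channel).
    masks : sequence of CombinationMask, optional
        Restrict to specific subsets; all non-empty ones if omitted.
    """

    def __init__(
        self,
        features: FeatureMatrix,
        S: int = 24,
        seed: int = 0,
        grouping: str = "sample",
        grid: Sequence[GridPoint] | None = None,
        columns: Sequence[str] | None = None,
        masks: Sequence[CombinationMask] | None = None,
    ):
        if features.normalization_sds is None:
            features = normalize_features(features)
        self.features = features
        self.S = S
        self.seed = int(seed)
        self.grouping = grouping
        self.grid = list(grid) if grid is not None else default_grid()
        self.columns = list(columns) if columns is not None else None
        self.masks = list(masks) if masks is not None else None

    def fit(self) -> "SubsetSearchResults":
        known = np.flatnonzero(self.features.known)
        train = self.features.subset_rows(known)
        folds = make_folds(
            train.n_obs,
            self.S,
            seed=self.seed,
            grouping=self.grouping,
            sample_names=train.sample_names,
        )
        results = search_combinations(
            train, folds, self.grid, masks=self.masks, columns=self.columns
        )
        return SubsetSearchResults(model=self, folds=folds, results=results)


@dataclass
class SubsetSearchResults:
    """Ranked subset-search outcome with reporting helpers."""

    model: SubsetSearch
    folds: FoldAssignment
    results: list[SearchResult] = field(repr=False)

    @property
    def best(self) -> SearchResult:
        return self.results[0]

    @property
    def delta_star(self) -> float:
        return self.best.delta

    def table(self) -> pd.DataFrame:
        return results_table(self.results)

    def usage_rates(self, top_k: int) -> pd.DataFrame:
        return usage_rate_table(usage_rates(self.results, top_k))

    def parity(self, result: SearchResult | None = None) -> pd.DataFrame:
        r = result or self.best
        return parity_table(
            self.model.features, r.selected_columns,
            r.cv.lambda_star, r.cv.sigma_star,
        )

    def evaluate_unknowns(self, result: SearchResult | None = None) -> pd.DataFrame:
        return evaluate_unknowns(self.model.features, result or self.best)

    def summary(self) -> str:
        b = self.best
        lines = [
            "Exhaustive Subset Search Results",
            "=" * 56,
            f"{'Masks evaluated:':<32}{len(self.results):>24d}",
            f"{'Folds (S, grouping):':<32}"
            f"{f'{self.folds.S}, {self.folds.grouping}':>24}",
            f"{'Grid points:':<32}{len(self.model.grid):>24d}",
            f"{'Best mask (decimal/binary):':<32}"
            f"{f'{b.mask.mask} / {b.mask.binary}':>24}",
            f"{'Best columns:':<32}{'+'.join(b.selected_columns):>24}",
            f"{'Delta (vol %)^2:':<32}{b.delta:>24.6g}",
            f"{'lambda*, sigma*:':<32}"
            f"{f'{b.cv.lambda_star:g}, {b.cv.sigma_star:g}':>24}",
            "=" * 56,
        ]
        return "\n".join(lines)
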