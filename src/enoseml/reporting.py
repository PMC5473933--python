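"""Correlation, PCA and end-to-end pipeline reporting.

``correlation_summary`` quantifies how each extracted parameter tracks
alcohol content (Spearman rank correlation per feature column);
``pca_scores`` projects the feature matrix onto its leading principal
axes for unsupervised discrimination; ``run_pipeline`` chains
simulate -> extract -> normalize -> fold -> search -> evaluate into a
deterministic, machine-readable report bundle.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import synth
from .signals import FeatureMatrix, extract_features, normalize_features
from .selection import (
    GridPoint,
    SubsetSearch,
    SubsetSearchResults,
    default_grid,
    reduced_grid,
    usage_rate_table,
)


def correlation_summary(features: FeatureMatrix) -> pd.Series:
    """Spearman rank correlation of every feature column with alcohol content.

    Constant columns get NaN (correlation undefined).  Requires at least
    three observations.
    """
    if features.n_obs < 3:
        raise ValueError("need at least 3 rows for a correlation summary")
    out = {}
    for col in features.X.columns:
        x = features.X[col].to_numpy(dtype=float)
        if np.ptp(x) == 0 or np.ptp(features.A) == 0:
            out[col] = np.nan
        else:
            out[col] = float(stats.spearmanr(x, features.A).statistic)
    return pd.Series(out, name="spearman_vs_alcohol")


def pca_scores(
    X: np.ndarray | pd.DataFrame | FeatureMatrix,
    n_components: int = 2,
    scale: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal-component scores of the feature matrix.

    Columns are centered and (by default) scaled to unit standard
    deviation — the same normalization the regression uses — then
    decomposed by SVD.  Axis signs are fixed by making each component's
    largest-magnitude loading positive.

    Returns
    -------
    scores : (N, n_components) array
    explained : (n_components,) explained-variance fractions, nonincreasing
    loadings : (d, n_components) array of component loadings
    """
    if isinstance(X, FeatureMatrix):
        X = X.X
    M = np.asarray(X, dtype=float)
    if M.ndim != 2:
        raise ValueError("X must be 2-D")
    n, d = M.shape
    C = M - M.mean(axis=0)
    if scale:
        sds = C.std(axis=0, ddof=0)
        if np.any(sds == 0):
            bad = list(np.flatnonzero(sds == 0))
            raise ValueError(f"constant column(s) {bad}; cannot scale")
        C = C / sds
    max_rank = min(n, d)
    if not 1 <= n_components <= max_rank:
        raise ValueError(
            f"n_components must be in 1..{max_rank} for a {n}x{d} matrix"
        )
    U, svals, Vt = np.linalg.svd(C, full_matrices=False)
    V = Vt.T[:, :n_components]
    # sign convention: largest-|loading| entry of each axis positive
    for j in range(n_components):
        k = np.argmax(np.abs(V[:, j]))
        if V[k, j] < 0:
            V[:, j] = -V[:, j]
    scores = C @ V
    total_var = np.sum(svals**2)
    explained = (svals[:n_components] ** 2) / total_var
    return scores, explained, V


# ---------------------------------------------------------------------------
# End-to-end pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Configuration of one full simulate-to-report run."""

    seed: int = 0
    S: int = 24
    grouping: str = "sample"
    t_a_list: tuple[float, ...] = (60.0, 80.0, 100.0)
    grid: list[GridPoint] = field(default_factory=reduced_grid)
    top_k: int = 10
    n_pca_components: int = 2
    joint: bool = False
    generator: synth.GeneratorConfig | None = None

    def resolve_generator(self) -> synth.GeneratorConfig:
        return self.generator or synth.default_config(seed=self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        for key in ("seed", "S", "grouping", "top_k", "n_pca_components",
                    "joint"):
            if key in raw:
                setattr(cfg, key, raw[key])
        if "t_a_list" in raw:
            cfg.t_a_list = tuple(float(t) for t in raw["t_a_list"])
        if "grid" in raw:
            g = raw["grid"]
            if isinstance(g, str):
                cfg.grid = {"default": default_grid,
                            "reduced": reduced_grid}[g]()
            else:
                cfg.grid = [(float(l), float(s)) for l, s in g]
        return cfg


@dataclass
class PipelineReport:
    """Everything one pipeline run produced."""

    config: PipelineConfig
    features: FeatureMatrix
    per_channel: dict[str, SubsetSearchResults]
    joint: SubsetSearchResults | None
    best_channel: str
    parity: pd.DataFrame
    unknown_parity: pd.DataFrame
    correlations: pd.Series
    usage: pd.DataFrame
    pca_explained: np.ndarray
    log: list[str]

    @property
    def best(self) -> SubsetSearchResults:
        if self.joint is not None and (
            self.joint.delta_star < self.per_channel[self.best_channel].delta_star
        ):
            return self.joint
        return self.per_channel[self.best_channel]

    def channel_deltas(self) -> pd.Series:
        return pd.Series(
            {ch: res.delta_star for ch, res in self.per_channel.items()},
            name="delta",
        )

    def unknown_mse(self) -> float:
        p = self.unknown_parity
        return float(np.mean((p["actual"] - p["predicted"]) ** 2))

    def summary_dict(self) -> dict:
        best = self.best.best
        return {
            "seed": self.config.seed,
            "folds": {"S": self.config.S, "grouping": self.config.grouping},
            "grid_points": len(self.config.grid),
            "channel_deltas": {
                k: round(v, 10) for k, v in self.channel_deltas().items()
            },
            "best_channel": self.best_channel,
            "best_mask": best.mask.mask,
            "best_mask_binary": best.mask.binary,
            "best_columns": list(best.selected_columns),
            "delta_star": round(best.delta, 10),
            "lambda_star": best.cv.lambda_star,
            "sigma_star": best.cv.sigma_star,
            "unknown_mse": round(self.unknown_mse(), 10),
            "usage_rates": {
                col: {p: round(float(v), 4) for p, v in series.items()}
                for col, series in self.usage.items()
            },
            "correlations": {
                k: (None if pd.isna(v) else round(float(v), 10))
                for k, v in self.correlations.items()
            },
            "pca_explained": [round(float(v), 10) for v in self.pca_explained],
            "log": self.log,
        }

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        from .signals import write_features

        write_features(self.features, out / "features.csv")
        self.best.table().to_csv(out / "search_results.csv", index=False)
        self.parity.to_csv(out / "parity.csv", index=False)
        self.usage.to_csv(out / "usage_rates.csv")
        self.correlations.to_csv(out / "correlations.csv")
        (out / "summary.json").write_text(
            json.dumps(self.summary_dict(), indent=2, sort_keys=True) + "\n"
        )


def run_pipeline(config: PipelineConfig | None = None) -> PipelineReport:
    """Execute the full analysis on a synthetic dataset.

    Stages: simulate the sensor array -> extract the four kinetic
    parameters from the late cycles -> normalize on the known rows ->
    per-channel exhaustive 15-mask searches (plus the joint multi-channel
    search when ``config.joint``) -> evaluate the held-out unknowns with
    the overall best mask -> correlations, usage rates and PCA.  Fully
    deterministic under ``config.seed``.
    """
    config = config or PipelineConfig()
    log: list[str] = []

    def stage(name: str, fn):
        try:
            out = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        log.append(f"{name}: ok")
        return out

    gen = config.resolve_generator()
    signals, metadata = stage("simulate", lambda: synth.simulate_dataset(gen))
    log.append(
        f"simulate: {len(gen.samples)} samples x {len(gen.channels)} channels, "
        f"seed={gen.seed}"
    )
    raw = stage(
        "extract", lambda: extract_features(signals, metadata, config.t_a_list)
    )
    features = stage("normalize", lambda: normalize_features(raw))
    log.append(
        f"folds: S={config.S}, grouping={config.grouping}, seed={config.seed}"
    )
    log.append(f"grid: {len(config.grid)} points")

    per_channel: dict[str, SubsetSearchResults] = {}
    for ch in features.channels:
        per_channel[ch] = stage(
            f"search[{ch}]",
            lambda ch=ch: SubsetSearch(
                features,
                S=config.S,
                seed=config.seed,
                grouping=config.grouping,
                grid=config.grid,
                columns=features.channel_columns(ch),
            ).fit(),
        )
    joint = None
    if config.joint:
        joint = stage(
            "search[joint]",
            lambda: SubsetSearch(
                features,
                S=config.S,
                seed=config.seed,
                grouping=config.grouping,
                grid=config.grid,
            ).fit(),
        )

    best_channel = min(per_channel, key=lambda ch: per_channel[ch].delta_star)
    best_results = joint if (
        joint is not None and joint.delta_star < per_channel[best_channel].delta_star
    ) else per_channel[best_channel]

    parity = stage("parity", best_results.parity)
    unknown_parity = parity[~parity["known"]].reset_index(drop=True)
    correlations = stage("correlations", lambda: correlation_summary(features))

    pooled = [r for res in per_channel.values() for r in res.results]
    pooled.sort(key=lambda r: (r.delta, r.mask.mask))
    top_k = min(config.top_k, len(pooled))
    pooled_ranked = [
        dataclasses.replace(r, rank=i + 1) for i, r in enumerate(pooled)
    ]
    usage = stage(
        "usage_rates",
        lambda: _pooled_usage(pooled_ranked, top_k, features),
    )
    _, explained, _ = stage(
        "pca", lambda: pca_scores(features, config.n_pca_components)
    )

    return PipelineReport(
        config=config,
        features=features,
        per_channel=per_channel,
        joint=joint,
        best_channel=best_channel,
        parity=parity,
        unknown_parity=unknown_parity,
        correlations=correlations,
        usage=usage,
        pca_explained=explained,
        log=log,
    )


def _pooled_usage(results, top_k, features: FeatureMatrix) -> pd.DataFrame:
    """Usage rates over a pooled ranked list of per-channel search results.

    Each result's mask addresses its own channel's four columns; rates are
    reported on the full (parameter x channel) grid with channels that a
    top-k mask never touches at 0%.
    """
    ordered = sorted(results, key=lambda r: r.rank)[:top_k]
    counts: dict[str, int] = {c: 0 for c in features.X.columns}
    for r in ordered:
        for col in r.selected_columns:
            counts[col] += 1
    series = pd.Series(
        {c: 100.0 * n / top_k for c, n in counts.items()}, name="usage_%"
    )
    return usage_rate_table(series)
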