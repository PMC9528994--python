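"""Resampled feature selection.

Protocol: 100 stratified 70% patient subsamples; in each, zero-variance
features are dropped and every remaining feature is marked 1 when its
two-group ANOVA F-test p-value is below 0.01; marks are summed into a
selection frequency.  The top max(ceil(0.10 N), 40) features by frequency
are reserved, then greedily pruned so no kept pair has |Pearson r| > 0.5
(the higher-frequency member survives).
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("fwlomics")


class ResampleInvalidError(ValueError):
    """A subsample contains a single class; the draw must be redrawn."""


@dataclasses.dataclass
class SelectionConfig:
    n_repeats: int = 100
    subsample_fraction: float = 0.70
    p_threshold: float = 0.01
    reserve_fraction: float = 0.10
    reserve_min: int = 40
    correlation_threshold: float = 0.5
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in [
            ("subsample_fraction", self.subsample_fraction),
            ("p_threshold", self.p_threshold),
            ("correlation_threshold", self.correlation_threshold),
        ]:
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")

    def reserve_size(self, n_features: int) -> int:
        k = max(int(np.ceil(self.reserve_fraction * n_features)), self.reserve_min)
        return min(k, n_features)


@dataclasses.dataclass
class SelectionOutcome:
    frequency: pd.Series  # per-feature mark count in 0..n_repeats
    mean_f: pd.Series  # mean F statistic over valid repeats (tie-break)
    reserved: list[str]
    primary: list[str]


def anova_f_screen(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-group one-way ANOVA F with (1, n-2) df and its upper-tail p.

    Equivalent to the squared pooled-variance two-sample t statistic.
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ResampleInvalidError("subsample contains a single class")
    f, p = _f_stats(np.asarray(x, dtype=float).reshape(-1, 1), y)
    return float(f[0]), float(p[0])


def _f_stats(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised two-group ANOVA F over feature columns."""
    y = y.astype(bool)
    n1, n0 = int(y.sum()), int((~y).sum())
    n = n1 + n0
    m1 = X[y].mean(axis=0)
    m0 = X[~y].mean(axis=0)
    gm = X.mean(axis=0)
    ssb = n1 * (m1 - gm) ** 2 + n0 * (m0 - gm) ** 2
    ssw = ((X[y] - m1) ** 2).sum(axis=0) + ((X[~y] - m0) ** 2).sum(axis=0)
    df2 = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ssb / (ssw / df2)
    f = np.where(ssw > 0, f, np.where(ssb > 0, np.inf, 0.0))
    p = stats.f.sf(f, 1, df2)
    p = np.where(np.isinf(f), 0.0, p)
    p = np.where(f == 0.0, 1.0, p)
    return f, p


def _stratified_subsample(y: np.ndarray, frac: float, rng: np.random.Generator) -> np.ndarray:
    idx = []
    for cls in np.unique(y):
        members = np.nonzero(y == cls)[0]
        k = max(int(np.ceil(frac * members.size)), 1)
        idx.append(rng.choice(members, size=k, replace=False))
    return np.sort(np.concatenate(idx))


def undersample_frequency_matrix(
    table: pd.DataFrame, y: np.ndarray, cfg: SelectionConfig
) -> SelectionOutcome:
    """Frequency stage: per-feature count of p < threshold marks over
    n_repeats subsamples (constant-in-subsample features are marked 0)."""
    X = table.to_numpy(dtype=float)
    y = np.asarray(y).astype(int)
    n = len(table)
    if n < 10:
        raise ValueError("need at least 10 patients")
    rng = np.random.default_rng(cfg.seed)
    marks = np.zeros(X.shape[1])
    fsum = np.zeros(X.shape[1])
    fcnt = np.zeros(X.shape[1])
    for _ in range(cfg.n_repeats):
        for attempt in range(11):
            idx = (
                _stratified_subsample(y, cfg.subsample_fraction, rng)
                if cfg.stratified
                else np.sort(rng.choice(n, size=int(np.ceil(cfg.subsample_fraction * n)), replace=False))
            )
            if len(np.unique(y[idx])) > 1:
                break
        else:
            raise ValueError("more than 10 consecutive single-class subsamples")
        Xs = X[idx]
        nonconst = Xs.std(axis=0) > 0
        f, p = _f_stats(Xs[:, nonconst], y[idx])
        hit = np.zeros(X.shape[1], dtype=bool)
        hit[nonconst] = p < cfg.p_threshold
        marks += hit
        fin = np.isfinite(f)
        fsum[np.nonzero(nonconst)[0][fin]] += f[fin]
        fcnt[np.nonzero(nonconst)[0][fin]] += 1
    freq = pd.Series(marks, index=table.columns, dtype=int)
    with np.errstate(invalid="ignore"):
        mean_f = pd.Series(np.where(fcnt > 0, fsum / np.maximum(fcnt, 1), 0.0), index=table.columns)
    return SelectionOutcome(frequency=freq, mean_f=mean_f, reserved=[], primary=[])


def reserve_by_frequency(
    freq: pd.Series, cfg: SelectionConfig, mean_f: pd.Series | None = None
) -> list[str]:
    """Top max(ceil(0.10 N), 40) features by frequency (capped at N).

    Ties broken by mean F statistic, then by feature name.
    """
    n = len(freq)
    if n < 1:
        raise ValueError("no features to reserve")
    k = cfg.reserve_size(n)
    tie = mean_f if mean_f is not None else pd.Series(0.0, index=freq.index)
    order = sorted(
        freq.index, key=lambda c: (-int(freq[c]), -float(tie[c]), str(c))
    )
    return order[:k]


def pearson_redundancy_filter(
    table: pd.DataFrame, reserved: list[str], cfg: SelectionConfig
) -> list[str]:
    """Greedy frequency-ordered scan: keep a feature iff its |Pearson r|
    with every already-kept feature is <= the threshold."""
    if not reserved:
        raise ValueError("reserved list is empty")
    X = table[reserved].to_numpy(dtype=float)
    sd = X.std(axis=0)
    mean = X.mean(axis=0)
    Z = np.where(sd > 0, (X - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    n = X.shape[0]
    kept: list[int] = []
    for j in range(len(reserved)):
        if not kept:
            kept.append(j)
            continue
        r = np.abs(Z[:, kept].T @ Z[:, j]) / n
        if np.all(r <= cfg.correlation_threshold):
            kept.append(j)
    return [reserved[j] for j in kept]


def select_primary_features(
    table: pd.DataFrame, y: np.ndarray, cfg: SelectionConfig | None = None
) -> SelectionOutcome:
    """Full pipeline: frequency stage -> reservation -> redundancy pruning."""
    cfg = cfg or SelectionConfig()
    out = undersample_frequency_matrix(table, y, cfg)
    nonconst = table.columns[table.std(axis=0).to_numpy() > 0]
    freq_nc = out.frequency[nonconst]
    mean_f_nc = out.mean_f[nonconst]
    reserved = reserve_by_frequency(freq_nc, cfg, mean_f_nc)
    primary = pearson_redundancy_filter(table, reserved, cfg)
    logger.info(
        "selection: %d features -> %d nonconstant -> %d reserved -> %d primary",
        table.shape[1], len(nonconst), len(reserved), len(primary),
    )
    return SelectionOutcome(
        frequency=out.frequency, mean_f=out.mean_f, reserved=reserved, primary=primary
    )
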