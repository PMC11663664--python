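"""Descriptive statistics, correlations, PCA biplot data, K-means variety
clustering and three-tier quality grading.

Grading thresholds (g/100 g) follow the three-class scheme used for pea
quality: fat <=5 / 5-9 / >=9, starch >=55 / 45-55 / <=45, protein >=25 /
20-25 / <=20, with shared endpoints resolved half-open in favor of the
better grade. Varieties are clustered on the five standardized chemical
components and the clusters named low-fat, high-starch and high-protein by
their centroid composition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import CHEMICAL_COMPONENTS

VARIETY_CLASSES = ("low_fat", "high_starch", "high_protein")

#: Recommended processing use per variety class.
RECOMMENDED_USE = {
    "low_fat": "Low-Fat Functional Foods",
    "high_starch": (
        "Used in canned goods, dried fruit, and other products, or processed "
        "into pea flour for bread, biscuits, and other products"
    ),
    "high_protein": "Pea protein powder or pea protein meat substitute",
}


def descriptive_stats(comp_table: pd.DataFrame) -> pd.DataFrame:
    """Per-variable min/max, mean, SE, sd, CV and quartiles.

    SE = sd/sqrt(n); CV = sd/mean; quartiles by linear interpolation.
    """
    num = comp_table.select_dtypes("number")
    n = len(num)
    if n < 2:
        raise ValueError("need at least 2 samples")
    sd = num.std(ddof=1)
    mean = num.mean()
    out = pd.DataFrame(
        {
            "min": num.min(),
            "max": num.max(),
            "mean": mean,
            "se": sd / np.sqrt(n),
            "sd": sd,
            "cv": sd / mean,
            "q1": num.quantile(0.25),
            "median": num.quantile(0.5),
            "q3": num.quantile(0.75),
        }
    )
    out.index.name = "variable"
    return out


@dataclass
class CorrelationResult:
    """Pairwise Pearson correlations with two-sided p-values."""

    r: pd.DataFrame
    p: pd.DataFrame
    n: int

    def stars(self) -> pd.DataFrame:
        """Significance markers: '**' p<0.01, '*' p<0.05, '' otherwise."""
        def mark(p: float) -> str:
            if np.isnan(p):
                return ""
            return "**" if p < 0.01 else "*" if p < 0.05 else ""

        return self.p.map(mark)


def correlation_matrix(comp_table: pd.DataFrame) -> CorrelationResult:
    """Pearson r with p from ``t = r sqrt((n-2)/(1-r^2))`` on t(n-2).

    Zero-variance columns yield NaN entries (correlation undefined).
    """
    num = comp_table.select_dtypes("number")
    n = len(num)
    if n < 3:
        raise ValueError("need at least 3 samples")
    x = num.to_numpy(dtype=float)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r[sd == 0, :] = np.nan
    r[:, sd == 0] = np.nan
    np.fill_diagonal(r, np.where(sd == 0, np.nan, 1.0))
    rr = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rr * np.sqrt((n - 2) / (1 - rr**2))
    p = 2 * sps.t.sf(np.abs(t), df=n - 2)
    p[np.isinf(t)] = 0.0
    np.fill_diagonal(p, 0.0)
    p[np.isnan(rr)] = np.nan
    cols = num.columns
    return CorrelationResult(
        r=pd.DataFrame(r, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
        n=n,
    )


@dataclass
class BiplotResult:
    """Standardized-PCA biplot data: sample scores, variable loadings."""

    scores: pd.DataFrame  # samples x PCs
    loadings: pd.DataFrame  # variables x PCs
    explained_variance_ratio: np.ndarray

    def loading_angle(self, var_a: str, var_b: str) -> float:
        """Angle in degrees between two variables' 2-D loading arrows."""
        u = self.loadings.loc[var_a, ["PC1", "PC2"]].to_numpy(dtype=float)
        v = self.loadings.loc[var_b, ["PC1", "PC2"]].to_numpy(dtype=float)
        c = u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
        return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))

    def loading_length(self, var: str) -> float:
        u = self.loadings.loc[var, ["PC1", "PC2"]].to_numpy(dtype=float)
        return float(np.linalg.norm(u))


def pca_biplot(
    comp_table: pd.DataFrame, standardize: bool = True
) -> BiplotResult:
    """Correlation-matrix PCA of a composition/sensory table.

    Variables are standardized to unit variance by default (units are
    heterogeneous: mm, g, %, ordinal scores). Loadings are scaled by the
    singular values so arrow lengths reflect explained variance.
    """
    num = comp_table.select_dtypes("number")
    x = num.to_numpy(dtype=float)
    xc = x - x.mean(axis=0)
    if standardize:
        sd = x.std(axis=0, ddof=1)
        if np.any(sd == 0):
            raise ValueError("zero-variance column cannot be standardized")
        xc = xc / sd
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    ratio = var / var.sum()
    k = s.size
    pcs = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(u * s, index=num.index, columns=pcs)
    loadings = pd.DataFrame(
        vt.T * (s / np.sqrt(max(len(num) - 1, 1))), index=num.columns, columns=pcs
    )
    return BiplotResult(scores, loadings, ratio)


# --------------------------------------------------------------------------
# K-means clustering into variety classes
# --------------------------------------------------------------------------


def _kmeans_once(
    x: np.ndarray, k: int, rng: np.random.Generator, max_iter: int = 300
) -> tuple[np.ndarray, np.ndarray, float]:
    """One Lloyd run with k-means++ initialization.

    Returns (labels, centers, inertia); raises RuntimeError on an empty
    cluster so the caller can restart.
    """
    n = x.shape[0]
    centers = np.empty((k, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    d2 = np.sum((x - centers[0]) ** 2, axis=1)
    for c in range(1, k):
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1 / n)
        centers[c] = x[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, np.sum((x - centers[c]) ** 2, axis=1))
    labels = np.zeros(n, dtype=int)
    for _ in range(max_iter):
        dist = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = dist.argmin(axis=1)
        if np.any(np.bincount(new_labels, minlength=k) == 0):
            raise RuntimeError("empty cluster")
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for c in range(k):
            centers[c] = x[labels == c].mean(axis=0)
    inertia = float(((x - centers[labels]) ** 2).sum())
    return labels, centers, inertia


def kmeans(
    x: np.ndarray, k: int, seed: int = 0, n_init: int = 10
) -> tuple[np.ndarray, np.ndarray, float]:
    """K-means with ``n_init`` seeded restarts; best inertia kept."""
    if k > x.shape[0]:
        raise ValueError("k cannot exceed the number of samples")
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    failures = 0
    for _ in range(n_init):
        try:
            labels, centers, inertia = _kmeans_once(x, k, rng)
        except RuntimeError:
            failures += 1
            continue
        if best is None or inertia < best[2]:
            best = (labels, centers, inertia)
    if best is None:
        raise RuntimeError(f"all {n_init} k-means restarts produced empty clusters")
    return best


def cluster_and_type(
    comp_table: pd.DataFrame, k: int = 3, seed: int = 0, n_init: int = 10
) -> tuple[pd.Series, dict[int, str]]:
    """Cluster varieties on standardized chemical components.

    For ``k=3`` the clusters are named by centroid composition: lowest mean
    crude fat -> ``low_fat``; of the remaining two, higher mean starch ->
    ``high_starch``; the other -> ``high_protein``. Returns per-sample
    cluster labels and the cluster->class mapping (empty unless k=3).
    """
    comps = comp_table[list(CHEMICAL_COMPONENTS)].to_numpy(dtype=float)
    sd = comps.std(axis=0, ddof=1)
    if np.any(sd == 0):
        sd = np.where(sd == 0, 1.0, sd)
    z = (comps - comps.mean(axis=0)) / sd
    labels, _, _ = kmeans(z, k, seed=seed, n_init=n_init)

    mapping: dict[int, str] = {}
    if k == 3:
        fat = comp_table["crude_fat"].groupby(labels).mean()
        low_fat = int(fat.idxmin())
        rest = [c for c in range(3) if c != low_fat]
        starch = comp_table["starch"].groupby(labels).mean()
        high_starch = rest[0] if starch[rest[0]] >= starch[rest[1]] else rest[1]
        high_protein = rest[1] if high_starch == rest[0] else rest[0]
        mapping = {
            low_fat: "low_fat",
            high_starch: "high_starch",
            high_protein: "high_protein",
        }
    return pd.Series(labels, index=comp_table.index, name="cluster"), mapping


# --------------------------------------------------------------------------
# Three-tier grading
# --------------------------------------------------------------------------


def _fat_level(v: float) -> int:
    return 1 if v <= 5 else 2 if v < 9 else 3


def _starch_level(v: float) -> int:
    return 1 if v >= 55 else 2 if v >= 45 else 3


def _protein_level(v: float) -> int:
    return 1 if v >= 25 else 2 if v >= 20 else 3


def grade_samples(
    comp_table: pd.DataFrame, variety_class: pd.Series | None = None
) -> pd.DataFrame:
    """Assign the three-tier fat/starch/protein levels per sample.

    Levels are total and deterministic for any finite nonnegative
    composition; shared boundary values take the better grade (e.g. fat
    exactly 5 is level 1, starch exactly 55 is level 1, protein exactly 25
    is level 1). When a variety class series is given (from
    :func:`cluster_and_type`) the recommended processing use is attached.
    """
    for col in ("crude_fat", "starch", "crude_protein"):
        vals = comp_table[col].to_numpy(dtype=float)
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError(f"{col} must be finite and nonnegative")
    out = pd.DataFrame(index=comp_table.index)
    out["fat_level"] = comp_table["crude_fat"].map(_fat_level)
    out["starch_level"] = comp_table["starch"].map(_starch_level)
    out["protein_level"] = comp_table["crude_protein"].map(_protein_level)
    if variety_class is not None:
        out["variety_class"] = variety_class.reindex(out.index)
        out["recommended_use"] = out["variety_class"].map(RECOMMENDED_USE)
    return out


def grading_summary(grades: pd.DataFrame) -> dict:
    """Counts per level and (when present) per variety class."""
    summary = {
        "fat_level": grades["fat_level"].value_counts().sort_index().to_dict(),
        "starch_level": grades["starch_level"].value_counts().sort_index().to_dict(),
        "protein_level": grades["protein_level"]
        .value_counts()
        .sort_index()
        .to_dict(),
    }
    if "variety_class" in grades:
        summary["variety_class"] = (
            grades["variety_class"].value_counts().sort_index().to_dict()
        )
    return summary
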