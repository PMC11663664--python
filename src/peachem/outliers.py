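"""PCA-score Mahalanobis-distance outlier detection for spectra.

Spectra are column-centered and decomposed by SVD; the Mahalanobis distance
of each sample is computed on the retained principal-component scores,
whose diagonal covariance makes the distance numerically stable. Distances
are scaled to a maximum of 1 and samples at or above half that scale are
flagged, with a cap on how many are actually removed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import SpectraSet


@dataclass
class PCAResult:
    """Column-centered SVD decomposition of a spectra matrix."""

    mean_spectrum: np.ndarray
    loadings: np.ndarray  # (n_wavelengths, k), orthonormal columns
    scores: np.ndarray  # (n_samples, k)
    explained_variance_ratio: np.ndarray  # length k, non-increasing
    sample_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


@dataclass
class OutlierReport:
    """Per-sample Mahalanobis distances and the flagged id set."""

    sample_ids: list[str]
    md: np.ndarray
    md_scaled: np.ndarray
    flagged: list[str]
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "md": self.md,
                "md_scaled": self.md_scaled,
                "flagged": [s in set(self.flagged) for s in self.sample_ids],
            }
        ).set_index("sample_id")


def pca_decompose(spectra: SpectraSet, variance_target: float = 0.95) -> PCAResult:
    """Center (no scaling) and SVD-decompose a spectra set.

    Keeps the smallest number of components reaching ``variance_target``
    cumulative explained variance, capped at ``n_samples - 2`` so the score
    covariance stays invertible.
    """
    x = spectra.absorbance
    n = x.shape[0]
    if n < 3:
        raise ValueError("need at least 3 samples")
    mean = x.mean(axis=0)
    xc = x - mean
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    tol = s.max() * max(xc.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int(np.sum(s > tol))
    if rank < 1:
        raise ValueError("spectra matrix has rank 0 (all spectra identical)")
    var = s**2
    ratio_all = var / var.sum()
    k = int(np.searchsorted(np.cumsum(ratio_all), variance_target) + 1)
    k = min(k, n - 2, rank)
    k = max(k, 1)
    return PCAResult(
        mean_spectrum=mean,
        loadings=vt[:k].T,
        scores=xc @ vt[:k].T,
        explained_variance_ratio=ratio_all[:k],
        sample_ids=list(spectra.sample_ids),
    )


def mahalanobis_outliers(
    pca_result: PCAResult, threshold: float = 0.5
) -> OutlierReport:
    """Mahalanobis distances on PCA scores, scaled to max 1.

    ``MD_i = sqrt((t_i - mean)' S^-1 (t_i - mean))`` with ``S`` the sample
    covariance (n-1) of the scores. Samples with ``md_scaled >= threshold``
    are flagged; the sample attaining the maximum always has scale 1.
    """
    t = np.atleast_2d(pca_result.scores)
    n, k = t.shape
    if k < 1:
        raise ValueError("need at least one score dimension")
    centered = t - t.mean(axis=0)
    cov = centered.T @ centered / (n - 1)
    try:
        solved = np.linalg.solve(cov, centered.T)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError("singular score covariance") from exc
    md = np.sqrt(np.einsum("ij,ji->i", centered, solved))
    md_scaled = md / md.max()
    flagged = [
        sid for sid, ms in zip(pca_result.sample_ids, md_scaled) if ms >= threshold
    ]
    return OutlierReport(
        sample_ids=list(pca_result.sample_ids),
        md=md,
        md_scaled=md_scaled,
        flagged=flagged,
        threshold=threshold,
    )


def remove_outliers(
    spectra: SpectraSet,
    comp_table: pd.DataFrame,
    report: OutlierReport,
    max_removed: int = 10,
) -> tuple[SpectraSet, pd.DataFrame, list[str]]:
    """Drop flagged samples (largest distances first), at most ``max_removed``.

    Spectra and composition stay aligned on the surviving id order.
    """
    if max_removed < 0:
        raise ValueError("max_removed must be >= 0")
    if set(report.sample_ids) != set(spectra.sample_ids):
        raise ValueError("report refers to different sample ids")
    md_by_id = dict(zip(report.sample_ids, report.md))
    ranked = sorted(report.flagged, key=lambda s: -md_by_id[s])
    removed = ranked[:max_removed]
    removed_set = set(removed)
    keep = [s for s in spectra.sample_ids if s not in removed_set]
    return spectra.subset(keep), comp_table.loc[keep], removed
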