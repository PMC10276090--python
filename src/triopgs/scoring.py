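"""Polygenic scoring at multiple p-value thresholds, PGS-PCA aggregation,
and genotype principal components for covariate use.

A raw score at threshold t is the weighted allele count
``score_i = sum_{j: p_j < t} w_j * d_ij`` over harmonized variants, with
missing dosages mean-imputed at twice the panel alt-allele frequency.
Because the choice of a single threshold is arbitrary, scores computed on a
ladder of thresholds are aggregated by taking the first principal component
across thresholds and z-standardizing it (PGS-PCA); the composite captures
the variance shared by the threshold scores without committing to one cutoff.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .sumstats_io import GenotypePanel, HarmonizedWeights

log = logging.getLogger(__name__)

#: conventional PRS threshold ladder, sparse to all-SNP
DEFAULT_THRESHOLDS = (0.001, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0)


@dataclass
class ScoreSet:
    """Per-sample raw scores at each threshold plus the PGS-PCA composite."""

    sample_ids: pd.Index
    thresholds: tuple[float, ...]
    raw_scores: np.ndarray              # samples x thresholds
    n_snps_used: np.ndarray             # per threshold
    pgs_pca: np.ndarray | None = None   # standardized composite
    pc1_loadings: np.ndarray | None = None
    pc1_variance_fraction: float | None = None

    def composite_series(self) -> pd.Series:
        if self.pgs_pca is None:
            raise ValueError("run pgs_pca() before requesting the composite")
        return pd.Series(self.pgs_pca, index=self.sample_ids, name="pgs_pca")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.raw_scores,
            index=self.sample_ids,
            columns=[f"score_p{t:g}" for t in self.thresholds],
        )
        if self.pgs_pca is not None:
            df["pgs_pca"] = self.pgs_pca
        df.index.name = "sample_id"
        return df


@dataclass
class AncestryPCs:
    """Genotype principal components, ordered by decreasing explained variance."""

    sample_ids: pd.Index
    scores: np.ndarray                  # samples x k
    explained_variance_ratio: np.ndarray

    @property
    def k(self) -> int:
        return self.scores.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.scores,
            index=self.sample_ids,
            columns=[f"pc{i + 1}" for i in range(self.k)],
        )
        df.index.name = "sample_id"
        return df


def _imputed_dosages(panel: GenotypePanel, variant_index: np.ndarray) -> np.ndarray:
    """Dosage submatrix with missing entries set to the variant's mean (2*af)."""
    d = panel.dosages[:, variant_index].copy()
    fill = 2.0 * panel.variants["af_alt"].to_numpy()[variant_index]
    nan = np.isnan(d)
    if nan.any():
        d[nan] = np.broadcast_to(fill, d.shape)[nan]
    return d


def compute_raw_scores(
    panel: GenotypePanel,
    hw: HarmonizedWeights,
    thresholds: tuple[float, ...] | list[float] = DEFAULT_THRESHOLDS,
) -> ScoreSet:
    """Weighted allele-count scores at each p-value threshold (strict ``p < t``)."""
    if len(hw) == 0:
        raise ValueError("no harmonized variants to score")
    thresholds = tuple(float(t) for t in thresholds)
    if list(thresholds) != sorted(thresholds) or not all(0 < t <= 1 for t in thresholds):
        raise ValueError("thresholds must be ascending and in (0, 1]")
    d = _imputed_dosages(panel, hw.variant_index)
    raw = np.empty((panel.n_samples, len(thresholds)))
    n_used = np.empty(len(thresholds), dtype=int)
    for j, t in enumerate(thresholds):
        mask = hw.pvalue < t
        n_used[j] = int(mask.sum())
        if n_used[j] == 0:
            log.warning("threshold %g: no variants pass; score column is zero", t)
            raw[:, j] = 0.0
        else:
            raw[:, j] = d[:, mask] @ hw.weight[mask]
    return ScoreSet(
        sample_ids=panel.sample_index(),
        thresholds=thresholds,
        raw_scores=raw,
        n_snps_used=n_used,
    )


def pgs_pca(scores: ScoreSet) -> ScoreSet:
    """Aggregate threshold scores into a standardized PGS-PCA composite.

    Threshold columns are z-standardized, the first principal component is
    extracted, its sign is fixed so the loading sum is positive (the
    composite points the same way as the threshold scores), and the PC1
    scores are z-standardized. Constant columns carry no information and are
    excluded (loading 0); a single usable column is returned standardized.
    """
    raw = scores.raw_scores
    if raw.shape[0] < 2:
        raise ValueError("PGS-PCA needs at least 2 samples")
    sd = raw.std(axis=0)
    usable = sd > 0
    if not usable.any():
        raise ValueError("all threshold score columns are constant; nothing to aggregate")
    z = (raw[:, usable] - raw[:, usable].mean(axis=0)) / sd[usable]

    loadings = np.zeros(raw.shape[1])
    if z.shape[1] == 1:
        pc1 = z[:, 0]
        loadings[usable] = 1.0
        varfrac = 1.0
    else:
        pca = PCA(n_components=1)
        pc1 = pca.fit_transform(z)[:, 0]
        load = pca.components_[0]
        if load.sum() < 0:
            load, pc1 = -load, -pc1
        loadings[usable] = load
        varfrac = float(pca.explained_variance_ratio_[0])
    pc1 = (pc1 - pc1.mean()) / pc1.std()

    scores.pgs_pca = pc1
    scores.pc1_loadings = loadings
    scores.pc1_variance_fraction = varfrac
    return scores


def compute_ancestry_pcs(panel: GenotypePanel, k: int = 5) -> AncestryPCs:
    """Principal components of the centered, variance-standardized dosage matrix.

    Monomorphic variants are excluded; missing dosages are mean-imputed. Each
    PC's sign is fixed by making its largest-magnitude variant loading
    positive, so results are reproducible across runs. If k exceeds the
    available rank, fewer components are returned with a warning.
    """
    if k == 0:
        return AncestryPCs(panel.sample_index(), np.empty((panel.n_samples, 0)),
                           np.empty(0))
    poly = np.flatnonzero(panel.variants["maf"].to_numpy() > 0)
    if poly.size == 0:
        raise ValueError("no polymorphic variants; cannot compute PCs")
    d = _imputed_dosages(panel, poly)
    sd = d.std(axis=0)
    keep = sd > 0
    d = (d[:, keep] - d[:, keep].mean(axis=0)) / sd[keep]
    max_k = min(panel.n_samples - 1, d.shape[1])
    if k > max_k:
        log.warning("requested %d PCs but rank allows only %d", k, max_k)
        k = max_k
    pca = PCA(n_components=k, svd_solver="full" if min(d.shape) < 500 else "randomized",
              random_state=0)
    pcs = pca.fit_transform(d)
    for j in range(k):
        lead = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, lead] < 0:
            pcs[:, j] = -pcs[:, j]
    return AncestryPCs(panel.sample_index(), pcs, pca.explained_variance_ratio_[:k])
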