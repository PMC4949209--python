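"""Population structure of the panel: kinship, PCA, cluster assignment
and linkage-disequilibrium decay per sub-population.

The Bayesian admixture clustering used to justify structure covariates in
association models is replaced here by PCA plus k-means with K=3 — the
panel's known composition (cultivars, landraces, wild) — which recovers
the same three clusters on structured data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .panel import GenotypePanel

log = logging.getLogger(__name__)


class DegenerateInputError(ValueError):
    pass


def _imputed_centered(panel: GenotypePanel):
    """Mean-impute missing dosages and centre by twice the allele frequency."""
    X = panel.dosage.copy()
    p = panel.allele_freq()
    poly = np.nanstd(X, axis=0) > 0
    mu = 2.0 * p
    idx = np.where(np.isnan(X))
    X[idx] = mu[idx[1]]
    return X - mu, p, poly


@dataclass
class KinshipMatrix:
    values: np.ndarray
    genotype_ids: list
    method: str = "vanraden1"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genotype_ids,
                            columns=self.genotype_ids)


def compute_kinship(panel: GenotypePanel) -> KinshipMatrix:
    """VanRaden method-1 realized relationship matrix.

    Dosages are centred by 2p and the cross-product scaled by
    2*sum(p(1-p)); missing calls are mean-imputed for this computation
    only.
    """
    if panel.n_genotypes < 2:
        raise DegenerateInputError("kinship needs at least 2 genotypes")
    W, p, poly = _imputed_centered(panel)
    if poly.sum() == 0:
        raise DegenerateInputError("no polymorphic markers for kinship")
    W = W[:, poly]
    p = p[poly]
    denom = 2.0 * np.sum(p * (1.0 - p))
    K = W @ W.T / denom
    return KinshipMatrix((K + K.T) / 2.0, list(panel.genotype_ids))


@dataclass
class PCAResult:
    scores: np.ndarray
    explained_variance_ratio: np.ndarray
    genotype_ids: list

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PC{i+1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.genotype_ids, columns=cols)


def compute_pca(panel: GenotypePanel, n_components: int = 10) -> PCAResult:
    """PCA of the centred (mean-imputed) dosage matrix."""
    n_components = min(n_components, panel.n_genotypes, max(panel.n_markers, 1))
    W, _, poly = _imputed_centered(panel)
    if poly.sum() == 0 or np.allclose(W, 0):
        log.warning("constant dosage matrix: PCA scores are all zero")
        return PCAResult(
            np.zeros((panel.n_genotypes, n_components)),
            np.zeros(n_components),
            list(panel.genotype_ids),
        )
    pca = PCA(n_components=n_components, svd_solver="full", random_state=0)
    scores = pca.fit_transform(W)
    return PCAResult(scores, pca.explained_variance_ratio_,
                     list(panel.genotype_ids))


def assign_subpops(panel: GenotypePanel, k: int = 3, seed: int = 0) -> np.ndarray:
    """Cluster genotypes into k groups on the first two PCs (k-means)."""
    pcs = compute_pca(panel, n_components=2).scores
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(pcs)


def ld_r2(panel: GenotypePanel, chromosome: str, scope: str = "all",
          max_pairs: int | None = None) -> pd.DataFrame:
    """Pairwise LD on one chromosome: squared Pearson correlation of
    dosage vectors over pairwise-complete calls.

    ``scope`` is ``"all"`` or a sub-population label. Pairs involving a
    marker monomorphic within scope are skipped. Returns a DataFrame with
    columns marker_a, marker_b, distance_cM, r2.
    """
    mm = panel.marker_map
    on_chr = mm.index[mm["chromosome"] == chromosome].to_numpy()
    if len(on_chr) < 2:
        raise DegenerateInputError(
            f"need >=2 markers on {chromosome}, found {len(on_chr)}"
        )
    rows = np.arange(panel.n_genotypes)
    if scope != "all":
        rows = rows[np.asarray(panel.subpops) == scope]
    X = panel.dosage[np.ix_(rows, on_chr)]
    pos = mm["cM"].to_numpy()[on_chr]
    ids = mm["marker"].to_numpy()[on_chr]

    # masked pairwise-complete correlation via count/sum matmuls
    M = (~np.isnan(X)).astype(float)
    Z = np.where(np.isnan(X), 0.0, X)
    n = M.T @ M
    sx = Z.T @ M
    sxy = Z.T @ Z
    sxx = (Z * Z).T @ M
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = sx / n
        cov = sxy / n - mean * mean.T
        var_a = sxx / n - mean**2
        var_b = var_a.T
        r2 = cov**2 / (var_a * var_b)
    skipped = 0
    recs = []
    m = len(on_chr)
    iu, ju = np.triu_indices(m, k=1)
    for a, b in zip(iu, ju):
        v = r2[a, b]
        if not np.isfinite(v):
            skipped += 1
            continue
        recs.append((ids[a], ids[b], abs(pos[a] - pos[b]), min(v, 1.0)))
    if skipped:
        log.info("%d marker pairs skipped (monomorphic in scope)", skipped)
    df = pd.DataFrame(recs, columns=["marker_a", "marker_b", "distance_cM", "r2"])
    if max_pairs is not None and len(df) > max_pairs:
        df = df.sample(max_pairs, random_state=0).reset_index(drop=True)
    return df


@dataclass
class LDDecayCurve:
    bins_cM: np.ndarray        # bin centres
    mean_r2: np.ndarray        # smoothed bin means
    threshold: float
    decay_distance_cM: float | None  # None when the curve never crosses

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"bin_cM": self.bins_cM, "mean_r2": self.mean_r2})


def ld_decay(records: pd.DataFrame, threshold: float = 0.1,
             bin_width: float = 1.0, smooth: int = 3) -> LDDecayCurve:
    """Bin r2 by cM distance (1 cM default), smooth by a running mean of
    width 3, and report the first bin centre where the smoothed mean
    falls below ``threshold`` (``None`` if never crossed)."""
    if len(records) == 0:
        raise DegenerateInputError("no LD records")
    d = records["distance_cM"].to_numpy()
    r2 = records["r2"].to_numpy()
    edges = np.arange(0.0, d.max() + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([0.0, bin_width])
    idx = np.clip(np.digitize(d, edges) - 1, 0, len(edges) - 2)
    sums = np.bincount(idx, weights=r2, minlength=len(edges) - 1)
    cnts = np.bincount(idx, minlength=len(edges) - 1)
    keep = cnts > 0
    centres = (edges[:-1] + edges[1:])[keep] / 2.0
    means = sums[keep] / cnts[keep]
    if smooth > 1 and len(means) >= 2:
        half = smooth // 2
        sm = np.empty_like(means)
        for i in range(len(means)):  # edge windows truncate, no zero padding
            lo, hi = max(0, i - half), min(len(means), i + half + 1)
            sm[i] = means[lo:hi].mean()
        means = sm
    below = np.where(means < threshold)[0]
    dist = float(centres[below[0]]) if len(below) else None
    return LDDecayCurve(centres, means, threshold, dist)


def ld_decay_by_subpop(panel: GenotypePanel, chromosome: str,
                       threshold: float = 0.1) -> dict:
    """Convenience: decay curve per sub-population on one chromosome."""
    out = {}
    for sp in sorted(set(panel.subpops)):
        recs = ld_r2(panel, chromosome, scope=sp)
        out[sp] = ld_decay(recs, threshold=threshold)
    return out
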