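"""Rogers-distance relatedness of allele-defined genotype groups.

For two individuals, each locus contributes the Euclidean distance
between their allele-frequency vectors: with dosage coding, the per-locus
frequency of the counted allele is dosage/2, so the locus distance is
sqrt(0.5 * sum_a (p_a - q_a)^2) = |d1 - d2| / 2. The Rogers distance is
the mean locus distance over loci where both calls are present. Groups
of genotypes (by default the homozygous allele classes at a QTL peak)
are compared both locally — markers within +-5 cM of the peak — and
globally over all markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .panel import GenotypePanel

log = logging.getLogger(__name__)


class UndefinedDistanceError(ValueError):
    """No locus with both calls non-missing."""


def rogers_distance(g1, g2) -> float:
    """Rogers distance between two dosage vectors in [0, 1]."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    if g1.shape != g2.shape:
        raise ValueError("dosage vectors differ in length")
    ok = ~(np.isnan(g1) | np.isnan(g2))
    if not ok.any():
        raise UndefinedDistanceError("no shared non-missing loci")
    return float(np.mean(np.abs(g1[ok] - g2[ok])) / 2.0)


def distance_matrix(dosage: np.ndarray, ids) -> pd.DataFrame:
    """Pairwise Rogers distances; symmetric, zero diagonal.

    Vectorised over pairs using pairwise-complete loci.
    """
    X = np.asarray(dosage, dtype=float)
    M = (~np.isnan(X)).astype(float)
    Z = np.where(np.isnan(X), 0.0, X)
    n_pairs = M @ M.T
    if (n_pairs == 0).any():
        raise UndefinedDistanceError("a pair shares no non-missing loci")
    # sum |d1 - d2| over complete loci; do it blockwise to stay O(n^2 m)
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        diff = np.abs(Z[i][None, :] - Z) * (M[i][None, :] * M)
        D[i] = diff.sum(axis=1) / n_pairs[i] / 2.0
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=list(ids), columns=list(ids))


def local_window(marker_map: pd.DataFrame, marker: str,
                 half_width_cM: float = 5.0) -> list:
    """Markers on the peak's chromosome within +-half_width cM, inclusive."""
    mm = marker_map.set_index("marker")
    if marker not in mm.index:
        raise KeyError(f"marker {marker!r} not on map")
    chrom, pos = mm.loc[marker, "chromosome"], mm.loc[marker, "cM"]
    sel = marker_map[(marker_map["chromosome"] == chrom)
                     & ((marker_map["cM"] - pos).abs() <= half_width_cM)]
    return sel["marker"].tolist()


@dataclass
class HaplotypeComparison:
    marker: str
    window: tuple               # (chromosome, lo_cM, hi_cM)
    groups: pd.Series           # selected genotype id -> group label
    local_distances: pd.DataFrame
    global_distances: pd.DataFrame
    summary: pd.DataFrame       # scope, group_a, group_b, mean_distance, mean_similarity
    flags: list


def _group_summary(D: pd.DataFrame, groups: pd.Series, scope: str) -> list:
    labels = sorted(groups.unique())
    rows = []
    for i, ga in enumerate(labels):
        for gb in labels[i:]:
            ia = groups.index[groups == ga]
            ib = groups.index[groups == gb]
            block = D.loc[ia, ib].to_numpy()
            if ga == gb:
                iu = np.triu_indices(len(ia), k=1)
                vals = block[iu]
            else:
                vals = block.ravel()
            if len(vals) == 0:
                continue
            mean_d = float(np.mean(vals))
            rows.append((scope, ga, gb, mean_d, 1.0 - mean_d))
    return rows


def compare_groups(panel: GenotypePanel, marker: str, groups=None,
                   half_width_cM: float = 5.0, n_select: int = 30,
                   seed: int = 0) -> HaplotypeComparison:
    """Local (+-5 cM window) vs global Rogers-distance comparison of
    genotype groups.

    ``groups`` maps genotype id -> label; by default the homozygous
    allele classes at the peak marker (dosage 0 vs 2). ``n_select``
    genotypes are sampled, stratified evenly across groups; a group
    smaller than its quota contributes all its members (flagged).
    """
    flags = []
    if groups is None:
        dose = np.round(panel.marker_dosage(marker))
        groups = {}
        for gid, d in zip(panel.genotype_ids, dose):
            if d == 0:
                groups[gid] = "hom_ref"
            elif d == 2:
                groups[gid] = "hom_alt"
    groups = pd.Series(groups)
    if groups.empty:
        raise ValueError("no genotypes in any group")
    rng = np.random.default_rng(seed)
    labels = sorted(groups.unique())
    quota = max(1, n_select // len(labels))
    chosen = []
    for lab in labels:
        ids = sorted(groups.index[groups == lab])
        if len(ids) <= quota:
            if len(ids) < quota:
                flags.append(f"group {lab}: {len(ids)} < quota {quota}, taking all")
            chosen += ids
        else:
            chosen += sorted(rng.choice(ids, size=quota, replace=False))
    sel = groups.loc[chosen]

    window_markers = local_window(panel.marker_map, marker, half_width_cM)
    mm = panel.marker_map.set_index("marker")
    chrom = mm.loc[marker, "chromosome"]
    w_pos = [mm.loc[m, "cM"] for m in window_markers]
    sub = panel.subset_genotypes(chosen)
    local = distance_matrix(
        sub.subset_markers(window_markers).dosage, chosen
    )
    glob = distance_matrix(sub.dosage, chosen)
    summary = pd.DataFrame(
        _group_summary(local, sel, "local") + _group_summary(glob, sel, "global"),
        columns=["scope", "group_a", "group_b", "mean_distance",
                 "mean_similarity"],
    )
    return HaplotypeComparison(
        marker, (chrom, float(min(w_pos)), float(max(w_pos))), sel,
        local, glob, summary, flags,
    )
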