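"""Allele-class quantification at a QTL peak marker.

Genotype-level trait means (averaged over replicates, treatments and
both years) are grouped into major-homozygote, heterozygote and
minor-homozygote classes; the relative performance (RP) of the locus is
the percent excess of the best class mean over the worst:

    RP = 100 * (max class mean - min class mean) / min class mean

computed over whichever of the three classes are present. The
heterozygote class participates: a locus whose heterozygotes outperform
both homozygotes (an apparent heterotic effect) gets its RP from the
het mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import GenotypePanel
from .phenostats import genotype_means

log = logging.getLogger(__name__)

CLASS_LABELS = ("major", "het", "minor")


@dataclass
class AlleleClassSummary:
    marker: str
    trait: str
    major_allele: str
    minor_allele: str
    class_n: dict       # label -> genotype count (non-missing calls)
    class_freq: dict    # label -> fraction of non-missing calls
    class_means: dict   # label -> genotype-level trait mean (absent class: NaN)
    genotype_classes: pd.Series = field(repr=False, default=None)


def _classify(panel: GenotypePanel, marker: str):
    """Map each genotype to major/het/minor at the marker (NaN -> missing).

    Major is the more frequent homozygote class by genotype count over
    non-missing calls; frequency ties break toward the alphabetically
    first allele label (dosage-0 class when labels are unknown).
    """
    dose = np.round(panel.marker_dosage(marker))
    alleles = panel.alleles.get(marker, ("0", "2"))
    n0 = int(np.sum(dose == 0))
    n2 = int(np.sum(dose == 2))
    # allele copies: dosage counts the second allele
    copies_second = 2 * n2 + int(np.sum(dose == 1))
    copies_first = 2 * n0 + int(np.sum(dose == 1))
    if copies_first > copies_second:
        major_dose, major_allele, minor_allele = 0.0, alleles[0], alleles[1]
    elif copies_second > copies_first:
        major_dose, major_allele, minor_allele = 2.0, alleles[1], alleles[0]
    else:  # tie: alphabetically first allele is called major
        first = min(alleles)
        major_dose = 0.0 if first == alleles[0] else 2.0
        major_allele, minor_allele = first, max(alleles)
    labels = pd.Series(index=panel.genotype_ids, dtype=object)
    labels[:] = "missing"
    labels[dose == major_dose] = "major"
    labels[dose == 1.0] = "het"
    labels[dose == (2.0 - major_dose)] = "minor"
    return labels, major_allele, minor_allele


def allele_class_means(panel: GenotypePanel, pheno: pd.DataFrame,
                       marker: str, trait: str) -> AlleleClassSummary:
    """Per-class genotype counts, frequencies and trait means.

    Trait means average each genotype over replicates, treatments and
    years before grouping; genotypes with missing calls are excluded.
    """
    labels, major, minor = _classify(panel, marker)
    gmeans = genotype_means(pheno, trait)
    n = {lab: int((labels == lab).sum()) for lab in CLASS_LABELS}
    total = sum(n.values())
    if total == 0:
        raise ValueError(f"marker {marker!r} has no non-missing calls")
    freq = {lab: n[lab] / total for lab in CLASS_LABELS}
    means = {}
    for lab in CLASS_LABELS:
        ids = labels.index[labels == lab]
        vals = gmeans.reindex(ids).dropna()
        means[lab] = float(vals.mean()) if len(vals) else np.nan
    return AlleleClassSummary(marker, trait, major, minor, n, freq, means, labels)


def relative_performance(summary) -> float:
    """RP % from an :class:`AlleleClassSummary` or a mapping/sequence of
    class means. Undefined (ValueError) when fewer than two classes are
    present or the smallest class mean is not positive."""
    if isinstance(summary, AlleleClassSummary):
        means = summary.class_means
    elif isinstance(summary, dict):
        means = summary
    else:
        means = dict(zip(CLASS_LABELS, summary))
    vals = [v for v in means.values() if np.isfinite(v)]
    if len(vals) < 2:
        raise ValueError("RP needs at least two allele classes with means")
    lo, hi = min(vals), max(vals)
    if lo <= 0:
        raise ValueError("RP undefined: smallest class mean is not positive")
    return 100.0 * (hi - lo) / lo


def pinplot_data(panel: GenotypePanel, pheno: pd.DataFrame,
                 marker: str, trait: str) -> pd.DataFrame:
    """Plot-ready table: genotypes sorted ascending by their two-year
    average trait value, tagged with their allele class at the marker.
    Ties keep genotype-id order (stable)."""
    labels, _, _ = _classify(panel, marker)
    gmeans = genotype_means(pheno, trait)
    df = pd.DataFrame({
        "genotype": gmeans.index,
        "value": gmeans.to_numpy(),
        "allele_class": labels.reindex(gmeans.index).fillna("missing").to_numpy(),
    })
    df = df.sort_values(["value", "genotype"], kind="mergesort")
    return df.reset_index(drop=True)


def sample_extreme_groups(summary: AlleleClassSummary, n_per_class: int = 10,
                          seed: int = 0) -> dict:
    """Reproducible random sample of genotypes per homozygous class
    (heterozygotes excluded). Classes smaller than ``n_per_class`` are
    returned whole with a flag."""
    rng = np.random.default_rng(seed)
    labels = summary.genotype_classes
    out = {}
    for lab in ("major", "minor"):
        ids = sorted(labels.index[labels == lab])
        if len(ids) <= n_per_class:
            if len(ids) < n_per_class:
                log.warning("class %s has %d < %d genotypes; taking all",
                            lab, len(ids), n_per_class)
            out[lab] = {"genotypes": list(ids), "complete_class": True}
        else:
            pick = sorted(rng.choice(ids, size=n_per_class, replace=False))
            out[lab] = {"genotypes": [str(g) for g in pick],
                        "complete_class": False}
    return out


def quantification_table(panel: GenotypePanel, pheno: pd.DataFrame,
                         qtl_records, trait: str) -> pd.DataFrame:
    """QTL summary table: one row per QTL with position, interval, LOD,
    variance explained, allele labels, class means and RP %."""
    rows = []
    for rec in qtl_records:
        s = allele_class_means(panel, pheno, rec.peak_marker, trait)
        try:
            rp = relative_performance(s)
        except ValueError:
            rp = np.nan
        rows.append({
            "trait": trait, "QTL": rec.qtl_name, "marker": rec.peak_marker,
            "effect": rec.effect_type, "chromosome": rec.chromosome,
            "pos_cM": rec.position_cM,
            "flanking": f"{rec.interval_cM[0]:.2f}-{rec.interval_cM[1]:.2f}",
            "LOD": rec.lod, "var_pct": rec.var_explained,
            "major_minor": f"{s.major_allele}/{s.minor_allele}",
            "major_mean": s.class_means["major"],
            "het_mean": s.class_means["het"],
            "minor_mean": s.class_means["minor"],
            "RP_pct": rp,
        })
    return pd.DataFrame(rows)
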