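"""Core data containers: genotype panel with genetic map, phenotype table.

The dosage matrix codes each biallelic SNP as the count of the
alphabetically-second allele (0, 1, 2) with ``NaN`` for missing calls.
Map positions are genetic (centimorgan) on the seven barley chromosomes
1H..7H.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CHROMOSOMES = tuple(f"{i}H" for i in range(1, 8))
SUBPOPS = ("cultivar", "landrace", "wild")
TRAITS = ("Rdw", "Rl", "Sdw", "Til", "RS")
TREATMENTS = ("control", "drought")


class PanelError(ValueError):
    """Malformed genotype panel or map."""


@dataclass
class GenotypePanel:
    """Diploid dosage matrix plus genetic map and sub-population labels.

    Parameters
    ----------
    genotype_ids : list of str
        Unique accession identifiers, one per matrix row.
    subpops : list of str
        Sub-population label per genotype (``cultivar``, ``landrace``,
        ``wild`` or ``unknown``).
    dosage : ndarray, shape (n_genotypes, n_markers)
        Minor/major dosage coding in {0, 1, 2}; missing calls are NaN.
    marker_map : DataFrame with columns ``marker``, ``chromosome``, ``cM``
        Sorted by (chromosome, cM); one row per dosage column.
    alleles : dict, optional
        marker -> (first, second) allele labels, e.g. ``("A", "G")``.
    """

    genotype_ids: list
    subpops: list
    dosage: np.ndarray
    marker_map: pd.DataFrame
    alleles: dict = field(default_factory=dict)

    def __post_init__(self):
        self.genotype_ids = list(self.genotype_ids)
        self.subpops = list(self.subpops)
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise PanelError("dosage must be a 2-D matrix")
        n_g, n_m = self.dosage.shape
        if len(self.genotype_ids) != n_g:
            raise PanelError(
                f"{len(self.genotype_ids)} genotype ids for {n_g} dosage rows"
            )
        if len(self.subpops) != n_g:
            raise PanelError("subpop labels do not match genotype count")
        if len(set(self.genotype_ids)) != n_g:
            dup = pd.Index(self.genotype_ids)
            dup = dup[dup.duplicated()][0]
            raise PanelError(f"duplicate genotype id {dup!r}")
        mm = self.marker_map.reset_index(drop=True)
        if list(mm.columns[:3]) != ["marker", "chromosome", "cM"]:
            mm = mm.rename(
                columns=dict(zip(mm.columns[:3], ["marker", "chromosome", "cM"]))
            )
        if len(mm) != n_m:
            raise PanelError(f"map has {len(mm)} markers for {n_m} dosage columns")
        if mm["marker"].duplicated().any():
            dup = mm.loc[mm["marker"].duplicated(), "marker"].iloc[0]
            raise PanelError(f"duplicate marker id {dup!r}")
        if (mm["cM"] < 0).any():
            raise PanelError("negative cM position in map")
        # canonical order: chromosome then position then id (stable tie-break)
        order = np.lexsort(
            (mm["marker"].to_numpy(), mm["cM"].to_numpy(),
             mm["chromosome"].astype(str).to_numpy())
        )
        if not np.array_equal(order, np.arange(n_m)):
            mm = mm.iloc[order].reset_index(drop=True)
            self.dosage = self.dosage[:, order]
        self.marker_map = mm
        bad = ~(np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0)))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise PanelError(
                f"dosage entry {self.dosage[i, j]!r} at genotype "
                f"{self.genotype_ids[i]!r}, marker {mm['marker'][j]!r} "
                "not in {0, 1, 2, NaN}"
            )

    # -- basic queries ----------------------------------------------------
    @property
    def n_genotypes(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    @property
    def marker_ids(self) -> list:
        return self.marker_map["marker"].tolist()

    def marker_index(self, marker: str) -> int:
        idx = self.marker_map.index[self.marker_map["marker"] == marker]
        if len(idx) == 0:
            raise KeyError(f"marker {marker!r} not in panel")
        return int(idx[0])

    def marker_dosage(self, marker: str) -> np.ndarray:
        return self.dosage[:, self.marker_index(marker)]

    def subset_markers(self, markers) -> "GenotypePanel":
        idx = [self.marker_index(m) for m in markers]
        return GenotypePanel(
            self.genotype_ids,
            self.subpops,
            self.dosage[:, idx],
            self.marker_map.iloc[idx].reset_index(drop=True),
            {m: self.alleles[m] for m in markers if m in self.alleles},
        )

    def subset_genotypes(self, ids) -> "GenotypePanel":
        pos = {g: i for i, g in enumerate(self.genotype_ids)}
        idx = [pos[g] for g in ids]
        return GenotypePanel(
            [self.genotype_ids[i] for i in idx],
            [self.subpops[i] for i in idx],
            self.dosage[idx],
            self.marker_map,
            self.alleles,
        )

    def allele_freq(self) -> np.ndarray:
        """Frequency of the dosage-counted allele per marker (non-missing calls)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=0)


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Check a long-format phenotype table and normalise column dtypes.

    Required columns: genotype, treatment, year, replicate, trait, value.
    """
    required = ["genotype", "treatment", "year", "replicate", "trait", "value"]
    missing = [c for c in required if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns {missing}")
    out = pheno[required].copy()
    out["value"] = out["value"].astype(float)
    out["year"] = out["year"].astype(int)
    out["replicate"] = out["replicate"].astype(int)
    return out
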