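"""Synthetic barley diversity panels and split-plot phenotypes.

The generator emulates the statistical structure a structured-panel GWAS
assumes: three sub-populations (modern cultivars, landraces, wild
accessions) with divergent allele frequencies, sub-population-dependent
linkage-disequilibrium decay along a seven-chromosome genetic map, low
residual heterozygosity as expected for a selfing species, and a
two-treatment (control/drought) x two-year x replicated split-plot
phenotype with genotype, GxT, GxY and GxTxY variance components plus
planted QTL carrying main and QTL-by-treatment effects.

LD is produced by a founder-haplotype mosaic: each sub-population has a
small pool of founder haplotypes drawn from Balding-Nichols diverged
allele frequencies, and every accession's (doubled) gamete switches
founders along the chromosome with probability ``1 - exp(-rate * d_cM)``.
A smaller rate means fewer switches and therefore slower r2 decay; wild
barley is given the smallest rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import CHROMOSOMES, GenotypePanel, TRAITS, TREATMENTS


class ConfigError(ValueError):
    """Invalid simulation configuration."""


def _default_subpop_sizes():
    return {"cultivar": 59, "landrace": 72, "wild": 48}


def _default_ld_decay():
    # founder-switch intensity per cM; wild < landrace < cultivar
    return {"wild": 0.04, "landrace": 0.08, "cultivar": 0.15}


@dataclass
class PanelConfig:
    """Parameters of the synthetic genotype panel.

    ``ld_decay_cm`` is the per-cM founder-exchange intensity per
    sub-population; the invariant wild < landrace < cultivar encodes the
    slower LD decay observed in wild material.
    """

    n_genotypes: int = 179
    subpop_sizes: dict | None = None
    n_chromosomes: int = 7
    map_length_cm: float = 150.0
    n_markers: int = 5892
    ld_decay_cm: dict = field(default_factory=_default_ld_decay)
    n_founders: int = 8
    fst: float = 0.15
    het_rate: float = 0.03
    missing_rate: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.subpop_sizes is None:
            # scale the 59/72/48 cultivar/landrace/wild composition
            ref = _default_subpop_sizes()
            total = sum(ref.values())
            sizes = {sp: int(round(n * self.n_genotypes / total))
                     for sp, n in ref.items()}
            sizes["landrace"] += self.n_genotypes - sum(sizes.values())
            self.subpop_sizes = sizes
        if sum(self.subpop_sizes.values()) != self.n_genotypes:
            raise ConfigError(
                f"subpop sizes {self.subpop_sizes} do not sum to "
                f"n_genotypes={self.n_genotypes}"
            )
        if self.n_chromosomes < 1 or self.n_chromosomes > 7:
            raise ConfigError("n_chromosomes must be in 1..7")
        if self.n_markers < 0:
            raise ConfigError("n_markers must be non-negative")
        ld = self.ld_decay_cm
        if set(ld) >= {"wild", "landrace", "cultivar"} and not (
            ld["wild"] <= ld["landrace"] <= ld["cultivar"]
        ):
            raise ConfigError(
                "ld_decay_cm must be ordered wild <= landrace <= cultivar"
            )
        for frac, name in ((self.het_rate, "het_rate"),
                           (self.missing_rate, "missing_rate")):
            if not 0 <= frac <= 1:
                raise ConfigError(f"{name} must be in [0, 1]")

    @property
    def chromosomes(self):
        return CHROMOSOMES[: self.n_chromosomes]


@dataclass
class PlantedQTL:
    """A causal marker planted into the phenotype simulation.

    ``main_effect`` is added per copy of the dosage-counted allele in both
    treatments; ``gxt_effect`` is the additional per-copy effect under
    drought only. ``minor_allele_subpop`` records which sub-population is
    meant to carry the minor allele; it is used by
    :func:`choose_qtl_markers` when selecting candidate markers and kept
    as metadata here.
    """

    marker_id: str
    trait: str
    main_effect: float = 0.0
    gxt_effect: float = 0.0
    minor_allele_subpop: str = "wild"

    def __post_init__(self):
        if self.trait not in TRAITS:
            raise ConfigError(f"unknown trait {self.trait!r}")
        if not (np.isfinite(self.main_effect) and np.isfinite(self.gxt_effect)):
            raise ConfigError("QTL effects must be finite")


def _default_baselines():
    # per trait: {(treatment, year): mean}; Rdw anchored to the observed
    # population means (control/drought 9.7/5.1 g in 2014, 6.2/3.3 g in 2015)
    b = {
        "Rdw": {("control", 2014): 9.7, ("drought", 2014): 5.1,
                ("control", 2015): 6.2, ("drought", 2015): 3.3},
        "Rl": {("control", 2014): 47.0, ("drought", 2014): 45.0,
               ("control", 2015): 46.0, ("drought", 2015): 44.0},
        "Sdw": {("control", 2014): 22.0, ("drought", 2014): 13.0,
                ("control", 2015): 18.0, ("drought", 2015): 11.0},
        "Til": {("control", 2014): 14.0, ("drought", 2014): 9.0,
                ("control", 2015): 12.0, ("drought", 2015): 8.0},
    }
    # RS is constructed record-wise as Rdw/Sdw; its implied baseline is the
    # ratio of the component baselines.
    b["RS"] = {k: b["Rdw"][k] / b["Sdw"][k] for k in b["Rdw"]}
    return b


def _default_varcomps():
    # loosely calibrated so that broad-sense heritability lands near the
    # reported coefficients (Rdw 0.62, Rl 0.48, Sdw 0.54, Til 0.90)
    return {
        "Rdw": dict(V_G=2.0, V_GxT=0.8, V_GxY=0.8, V_GxTxY=0.3, V_rep=0.1, V_E=4.0),
        "Rl": dict(V_G=5.0, V_GxT=3.0, V_GxY=4.0, V_GxTxY=1.0, V_rep=0.5, V_E=25.0),
        "Sdw": dict(V_G=8.0, V_GxT=5.0, V_GxY=5.0, V_GxTxY=1.5, V_rep=0.5, V_E=20.0),
        "Til": dict(V_G=9.0, V_GxT=0.5, V_GxY=0.5, V_GxTxY=0.3, V_rep=0.1, V_E=4.0),
        # RS components are implied by the Rdw/Sdw ratio and not sampled
        "RS": dict(V_G=0.0, V_GxT=0.0, V_GxY=0.0, V_GxTxY=0.0, V_rep=0.0, V_E=0.0),
    }


@dataclass
class PhenoDesign:
    """Split-plot phenotype design: treatments x years x replicates."""

    treatments: tuple = TREATMENTS
    years: tuple = (2014, 2015)
    replicates: int = 4
    trait_baselines: dict = field(default_factory=_default_baselines)
    variance_components: dict = field(default_factory=_default_varcomps)
    traits: tuple = TRAITS
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 2:
            raise ConfigError("need at least 2 replicates")
        for trait, vc in self.variance_components.items():
            for name, v in vc.items():
                if v < 0:
                    raise ConfigError(f"{trait} {name} is negative")


def simulate_panel(config: PanelConfig) -> GenotypePanel:
    """Generate a structured genotype panel with LD along the map.

    Returns a :class:`GenotypePanel` whose markers are sorted by
    (chromosome, cM). Same seed, same config => bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    chroms = config.chromosomes
    n_chr = len(chroms)
    # markers per chromosome, as even as possible
    per_chr = np.full(n_chr, config.n_markers // n_chr, dtype=int)
    per_chr[: config.n_markers % n_chr] += 1

    rows_map = []
    for c, chrom in enumerate(chroms):
        pos = np.sort(rng.uniform(0.0, config.map_length_cm, per_chr[c]))
        for j, p in enumerate(pos):
            rows_map.append((f"{chrom}_snp{j:04d}", chrom, round(float(p), 2)))
    mmap = pd.DataFrame(rows_map, columns=["marker", "chromosome", "cM"])
    n_m = len(mmap)

    # ancestral and sub-population allele frequencies (Balding-Nichols)
    p_anc = rng.uniform(0.1, 0.9, n_m)
    c = config.fst
    subpop_names = list(config.subpop_sizes)
    freqs = {}
    for sp in subpop_names:
        if c > 0:
            a = p_anc * (1 - c) / c
            b = (1 - p_anc) * (1 - c) / c
            freqs[sp] = rng.beta(a, b)
        else:
            freqs[sp] = p_anc.copy()

    genotype_ids, subpops, blocks = [], [], []
    for sp in subpop_names:
        n_ind = config.subpop_sizes[sp]
        rate = config.ld_decay_cm.get(sp, 0.1)
        founders = (rng.random((config.n_founders, n_m)) < freqs[sp]).astype(float)
        hap = np.empty((n_ind, n_m))
        col = 0
        for ci, chrom in enumerate(chroms):
            m_c = per_chr[ci]
            if m_c == 0:
                continue
            pos = mmap.loc[mmap["chromosome"] == chrom, "cM"].to_numpy()
            gaps = np.diff(pos)
            state = rng.integers(0, config.n_founders, n_ind)
            hap[:, col] = founders[state, col]
            for j in range(1, m_c):
                p_switch = 1.0 - np.exp(-rate * gaps[j - 1])
                switch = rng.random(n_ind) < p_switch
                if switch.any():
                    state = np.where(
                        switch, rng.integers(0, config.n_founders, n_ind), state
                    )
                hap[:, col + j] = founders[state, col + j]
            col += m_c
        dose = 2.0 * hap  # selfing: doubled gametes, fully homozygous
        blocks.append(dose)
        genotype_ids += [f"{sp[:4]}_{i:03d}" for i in range(n_ind)]
        subpops += [sp] * n_ind

    dosage = (
        np.vstack(blocks) if blocks else np.empty((config.n_genotypes, 0))
    )
    if n_m:
        # residual heterozygosity, then missing calls, both MCAR
        het = rng.random(dosage.shape) < config.het_rate
        dosage[het] = 1.0
        miss = rng.random(dosage.shape) < config.missing_rate
        dosage[miss] = np.nan
    return GenotypePanel(genotype_ids, subpops, dosage, mmap)


def choose_qtl_markers(
    panel: GenotypePanel,
    n: int,
    minor_allele_subpop: str = "wild",
    min_maf: float = 0.08,
    max_maf: float = 0.35,
    min_gap_cm: float = 30.0,
    target_contrast: float = 0.35,
    seed: int = 0,
) -> list:
    """Pick well-separated candidate QTL markers whose minor allele is
    enriched in one sub-population.

    Markers are ranked by how close their minor-allele frequency contrast
    (target sub-population minus the rest) is to ``target_contrast`` and
    taken greedily subject to a minimum map distance between picks. A
    moderate contrast keeps the biology — carriers are mostly wild
    accessions — without making the locus collinear with the
    population-structure axes, which no structure-corrected scan could
    separate from ancestry.
    """
    sp = np.asarray(panel.subpops)
    in_grp = sp == minor_allele_subpop
    if in_grp.sum() == 0:
        raise ConfigError(f"no genotypes in subpop {minor_allele_subpop!r}")
    with np.errstate(invalid="ignore"):
        f_all = panel.allele_freq()
        f_grp = np.nanmean(panel.dosage[in_grp], axis=0) / 2.0
        f_out = np.nanmean(panel.dosage[~in_grp], axis=0) / 2.0
    # orient to the panel-wide minor allele
    minor_f = np.where(f_all <= 0.5, f_all, 1 - f_all)
    minor_grp = np.where(f_all <= 0.5, f_grp, 1 - f_grp)
    minor_out = np.where(f_all <= 0.5, f_out, 1 - f_out)
    contrast = minor_grp - minor_out
    ok = (minor_f > min_maf) & (minor_f < max_maf) & (contrast > 0.15)
    score = np.where(ok, -np.abs(contrast - target_contrast), -np.inf)
    order = np.argsort(-score)
    rng = np.random.default_rng(seed)
    picked = []
    mm = panel.marker_map
    for j in order:
        if not np.isfinite(score[j]) or len(picked) >= n:
            break
        chrom, cm = mm["chromosome"][j], mm["cM"][j]
        close = any(
            mm["chromosome"][k] == chrom and abs(mm["cM"][k] - cm) < min_gap_cm
            for k in picked
        )
        if not close:
            picked.append(j)
    if len(picked) < n:
        raise ConfigError(f"only {len(picked)} of {n} QTL markers placeable")
    rng.shuffle(picked)
    return [mm["marker"][j] for j in picked]


def simulate_phenotypes(
    panel: GenotypePanel, qtls, design: PhenoDesign
) -> pd.DataFrame:
    """Simulate the split-plot phenotype table.

    One record per genotype x treatment x year x replicate x trait. Trait
    value = baseline(treatment, year) + sum of planted-QTL dosage effects
    (plus the QTL-by-treatment effect under drought) + random genotype,
    GxT, GxY, GxTxY, replicate-within-treatment-and-year and residual
    effects at the configured variances. The root-to-shoot ratio RS is
    computed record-wise as Rdw/Sdw of the same experimental unit; planted
    QTL declared on RS act through the numerator Rdw.
    """
    rng = np.random.default_rng(design.seed)
    for q in qtls:
        panel.marker_index(q.marker_id)  # raises KeyError if absent

    n_g = panel.n_genotypes
    treatments = list(design.treatments)
    years = list(design.years)
    reps = list(range(1, design.replicates + 1))
    n_t, n_y, n_r = len(treatments), len(years), len(reps)

    # dosage per QTL, missing treated as the marker mean (keeps records complete)
    qtl_dose = {}
    for q in qtls:
        d = panel.marker_dosage(q.marker_id).copy()
        if np.isnan(d).any():
            d[np.isnan(d)] = np.nanmean(d)
        qtl_dose[q.marker_id] = d

    base_traits = [t for t in design.traits if t != "RS"]
    values = {}  # trait -> array (n_g, n_t, n_y, n_r)
    for trait in base_traits:
        vc = design.variance_components[trait]
        g = rng.normal(0, np.sqrt(vc["V_G"]), n_g)
        gt = rng.normal(0, np.sqrt(vc["V_GxT"]), (n_g, n_t))
        gy = rng.normal(0, np.sqrt(vc["V_GxY"]), (n_g, n_y))
        gty = rng.normal(0, np.sqrt(vc["V_GxTxY"]), (n_g, n_t, n_y))
        rep_eff = rng.normal(0, np.sqrt(vc["V_rep"]), (n_t, n_y, n_r))
        eps = rng.normal(0, np.sqrt(vc["V_E"]), (n_g, n_t, n_y, n_r))
        arr = np.empty((n_g, n_t, n_y, n_r))
        for ti, trt in enumerate(treatments):
            for yi, yr in enumerate(years):
                mu = design.trait_baselines[trait][(trt, yr)]
                cell = mu + g + gt[:, ti] + gy[:, yi] + gty[:, ti, yi]
                for q in qtls:
                    target = "Rdw" if q.trait == "RS" else q.trait
                    if target != trait:
                        continue
                    eff = q.main_effect + (q.gxt_effect if trt == "drought" else 0.0)
                    cell = cell + eff * qtl_dose[q.marker_id]
                arr[:, ti, yi, :] = cell[:, None] + rep_eff[ti, yi][None, :]
        arr += eps
        values[trait] = arr

    records = []
    gids = panel.genotype_ids
    want_rs = "RS" in design.traits or "RS" in {q.trait for q in qtls}
    for ti, trt in enumerate(treatments):
        for yi, yr in enumerate(years):
            for ri, rep in enumerate(reps):
                for trait in base_traits:
                    col = values[trait][:, ti, yi, ri]
                    records.extend(
                        (gids[i], trt, yr, rep, trait, col[i]) for i in range(n_g)
                    )
                if want_rs and "Rdw" in values and "Sdw" in values:
                    rdw = values["Rdw"][:, ti, yi, ri]
                    # denominator floored at 0.5 g: a shoot cannot weigh
                    # nothing, and the ratio must not change sign
                    sdw = np.maximum(values["Sdw"][:, ti, yi, ri], 0.5)
                    rs = rdw / sdw
                    records.extend(
                        (gids[i], trt, yr, rep, "RS", rs[i]) for i in range(n_g)
                    )
    return pd.DataFrame(
        records,
        columns=["genotype", "treatment", "year", "replicate", "trait", "value"],
    )


def default_qtl_set(panel: GenotypePanel, seed: int = 0) -> list:
    """Four planted QTL mirroring the study design: three with main
    effects (Rdw, Til, Sdw) and one drought-responsive crossover QTL on
    Rdw — the allele costs under control what it gains under drought, so
    only the QTL-by-treatment contrast carries signal."""
    markers = choose_qtl_markers(panel, 4, seed=seed)
    return [
        PlantedQTL(markers[0], "Rdw", main_effect=1.8),
        PlantedQTL(markers[1], "Til", main_effect=2.5),
        PlantedQTL(markers[2], "Sdw", main_effect=3.5),
        PlantedQTL(markers[3], "Rdw", main_effect=-1.25, gxt_effect=2.5),
    ]
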