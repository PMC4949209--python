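"""End-to-end orchestration: simulate -> qc -> structure -> anova ->
gwas -> quantify -> haplo, driven by a flat YAML config.

Every stage writes deterministically named outputs into the output
directory and the run manifest records inputs (with SHA-256 hashes),
seeds and per-stage products, so a rerun with the same config is
bit-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from . import qc as rqc
from .haplotype import compare_groups
from .panel import TRAITS
from .phenostats import (estimate_variance_components, fit_anova, heritability,
                         summarize_traits)
from .quantify import quantification_table
from .scan import (MLMSpec, cross_validate, merge_to_qtl, multilocus_scan,
                   permutation_threshold, variance_explained)
from .simulate import (PanelConfig, PhenoDesign, default_qtl_set,
                       simulate_panel, simulate_phenotypes)
from .structure import compute_kinship, compute_pca, ld_decay, ld_r2

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str = "rootqtl_run"
    simulate: bool = True
    genotypes: str | None = None
    map: str | None = None
    phenotypes: str | None = None
    # simulation scale
    n_genotypes: int = 179
    n_markers: int = 5892
    subpop_sizes: dict | None = None
    # QC
    maf_min: float = 0.05
    call_rate_min: float = 0.95
    # scan
    traits: tuple = ("Rdw", "Til", "Sdw")
    n_perm: int = 1000
    alpha: float = 0.05
    lod_floor: float = 4.0
    flank_cM: float = 5.0
    cv_runs: int = 0
    leave_frac: float = 0.2
    n_pcs: int = 3
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.leave_frac < 1:
            raise ValueError("leave_frac must be in [0, 1)")
        for tr in self.traits:
            if tr not in TRAITS:
                raise ValueError(f"unknown trait {tr!r}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "traits" in raw:
            raw["traits"] = tuple(raw["traits"])
        return cls(**raw)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in asdict(config).items()},
                "stages": [], "inputs": {}}
    t0 = time.time()

    def stage(name):
        log.info("stage %s", name)
        manifest["stages"].append({"name": name, "outputs": []})
        return manifest["stages"][-1]

    def emit(st, path):
        st["outputs"].append(str(path))

    # 1. simulate or load -------------------------------------------------
    st = stage("simulate" if config.simulate else "load")
    try:
        if config.simulate:
            pcfg_kw = dict(n_genotypes=config.n_genotypes,
                           n_markers=config.n_markers, seed=config.seed)
            if config.subpop_sizes:
                pcfg_kw["subpop_sizes"] = dict(config.subpop_sizes)
            pcfg = PanelConfig(**pcfg_kw)
            panel = simulate_panel(pcfg)
            qtls = default_qtl_set(panel, seed=config.seed + 1)
            design = PhenoDesign(seed=config.seed + 2)
            pheno = simulate_phenotypes(panel, qtls, design)
            gpath, mpath = out / "genotypes.tsv", out / "map.tsv"
            ppath = out / "phenotypes.csv"
            rio.write_genotypes(panel, gpath, mpath)
            rio.write_phenotypes(pheno, ppath)
            manifest["planted_qtl"] = [
                {"marker": q.marker_id, "trait": q.trait,
                 "main_effect": q.main_effect, "gxt_effect": q.gxt_effect}
                for q in qtls
            ]
            for p in (gpath, mpath, ppath):
                emit(st, p)
        else:
            for name, p in (("genotypes", config.genotypes),
                            ("map", config.map),
                            ("phenotypes", config.phenotypes)):
                if p is None or not Path(p).exists():
                    raise FileNotFoundError(f"{name} file not found: {p}")
                manifest["inputs"][name] = {"path": p, "sha256": _sha256(p)}
            panel = rio.read_genotypes(config.genotypes, config.map)
            pheno = rio.read_phenotypes(config.phenotypes)
    except Exception as e:  # noqa: BLE001
        raise StageError(st["name"], e) from e

    # 2. qc ----------------------------------------------------------------
    st = stage("qc")
    try:
        panel, report = rqc.filter_markers(panel, config.maf_min,
                                           config.call_rate_min)
        qpath = out / "qc_report.json"
        qpath.write_text(report.to_json(indent=2))
        emit(st, qpath)
        manifest["qc"] = json.loads(report.to_json())
    except Exception as e:  # noqa: BLE001
        raise StageError("qc", e) from e

    # 3. structure -----------------------------------------------------------
    st = stage("structure")
    try:
        kin = compute_kinship(panel)
        kin.to_frame().to_csv(out / "kinship.tsv", sep="\t")
        emit(st, out / "kinship.tsv")
        pca = compute_pca(panel, n_components=min(10, panel.n_genotypes))
        pca.to_frame().to_csv(out / "pca_scores.csv")
        emit(st, out / "pca_scores.csv")
        ld_rows = []
        for chrom in panel.marker_map["chromosome"].unique():
            recs = ld_r2(panel, chrom, scope="all")
            curve = ld_decay(recs)
            for b, r in zip(curve.bins_cM, curve.mean_r2):
                ld_rows.append((chrom, "all", b, r))
        pd.DataFrame(ld_rows, columns=["chromosome", "scope", "bin_cM",
                                       "mean_r2"]).to_csv(
            out / "ld_decay.csv", index=False)
        emit(st, out / "ld_decay.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("structure", e) from e

    # 4. anova / heritability -------------------------------------------------
    st = stage("anova")
    try:
        rows = []
        for trait in config.traits:
            res = fit_anova(pheno, trait)
            for _, r in res.table.iterrows():
                rows.append((trait, r["term"], r["SS"], r["df"], r["F"], r["p"]))
            vc = estimate_variance_components(pheno, trait)
            h2 = heritability(vc)
            rows.append((trait, "H2", h2.H2, np.nan, np.nan, np.nan))
        pd.DataFrame(rows, columns=["trait", "term", "value", "df", "F",
                                    "p"]).to_csv(out / "anova.csv", index=False)
        emit(st, out / "anova.csv")
        summarize_traits(pheno).to_csv(out / "trait_summary.csv", index=False)
        emit(st, out / "trait_summary.csv")
    except Exception as e:  # noqa: BLE001
        raise StageError("anova", e) from e

    # 5-7. gwas, quantify, haplo per trait ---------------------------------
    spec = MLMSpec(n_pcs=config.n_pcs)
    qtl_tables = []
    for ti, trait in enumerate(config.traits):
        st = stage(f"gwas:{trait}")
        try:
            thr = permutation_threshold(
                pheno, panel, trait, n_perm=config.n_perm, alpha=config.alpha,
                seed=config.seed + 100 + ti, spec=spec,
                lod_floor=config.lod_floor)
            res = multilocus_scan(pheno, panel, trait, spec, thr)
            res.first_scan.to_csv(out / f"scan_{trait}.csv", index=False)
            emit(st, out / f"scan_{trait}.csv")
            records = merge_to_qtl(res, panel.marker_map, config.flank_cM)
            for rec in records:
                rec.var_explained = variance_explained(
                    pheno, panel, trait, rec.peak_marker,
                    [m for m in res.selected if m != rec.peak_marker])
            if config.cv_runs > 0 and res.selected:
                cv = cross_validate(pheno, panel, trait, spec, thr,
                                    candidates=res.selected,
                                    leave_frac=config.leave_frac,
                                    n_runs=config.cv_runs,
                                    seed=config.seed + 200 + ti)
                cv.table.to_csv(out / f"cv_{trait}.csv", index=False)
                emit(st, out / f"cv_{trait}.csv")
            manifest.setdefault("thresholds", {})[trait] = {
                "permutation": thr.threshold, "effective": thr.effective}
        except Exception as e:  # noqa: BLE001
            raise StageError(f"gwas:{trait}", e) from e

        st = stage(f"quantify:{trait}")
        try:
            qt = quantification_table(panel, pheno, records, trait)
            qt.to_csv(out / f"qtl_{trait}.csv", index=False)
            emit(st, out / f"qtl_{trait}.csv")
            qtl_tables.append(qt)
        except Exception as e:  # noqa: BLE001
            raise StageError(f"quantify:{trait}", e) from e

        st = stage(f"haplo:{trait}")
        try:
            if records:
                peak = max(records, key=lambda r: r.lod)
                comp = compare_groups(panel, peak.peak_marker,
                                      half_width_cM=config.flank_cM,
                                      seed=config.seed + 300 + ti)
                comp.summary.to_csv(out / f"haplo_{trait}.csv", index=False)
                comp.local_distances.to_csv(
                    out / f"haplo_{trait}_local.tsv", sep="\t")
                comp.global_distances.to_csv(
                    out / f"haplo_{trait}_global.tsv", sep="\t")
                for p in (f"haplo_{trait}.csv", f"haplo_{trait}_local.tsv",
                          f"haplo_{trait}_global.tsv"):
                    emit(st, out / p)
        except Exception as e:  # noqa: BLE001
            raise StageError(f"haplo:{trait}", e) from e

    if qtl_tables:
        pd.concat(qtl_tables).to_csv(out / "qtl_table.csv", index=False)

    manifest["wall_seconds"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
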