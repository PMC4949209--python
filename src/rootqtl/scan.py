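"""Iterative multi-locus mixed-model association scan.

Model per marker (single-marker step):

    Y_ij = mu + PCs + T + M_i + MxT + cofactors + L_j(M_i) + eps_ij

with the marker genotype class M a fixed factor, treatment T fixed, the
line L random nested within marker class, and the first principal
components of the dosage matrix as structure covariates. Year is treated
as replication and never enters the model. With lines as the containing
stratum, the F-tests for M and MxT with containment denominator degrees
of freedom reduce exactly (balanced case) to F-tests on line-level
aggregates: the marker main effect is tested on genotype means pooled
over treatments, and the marker-by-treatment interaction on genotype
drought-minus-control differences. That reduction is what makes
1000-permutation genome-wide thresholds affordable.

Significance combines a permutation genome-wide threshold (95th
percentile of the per-permutation maximum LOD) with a fixed LOD floor of
4, i.e. p <= 1e-4. The multi-locus procedure forward-selects the most
informative SNP above threshold as a cofactor, rescans, and stops when
nothing passes; QTL intervals merge significant first-iteration SNPs
within 5 cM of each peak.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import GenotypePanel
from .structure import compute_kinship, compute_pca

log = logging.getLogger(__name__)


def lod_from_p(p) -> float:
    """LOD score as -log10 of the marker test p-value."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p must lie in (0, 1]")
    out = -np.log10(p)
    return float(out) if out.ndim == 0 else out


@dataclass
class MLMSpec:
    """Configuration of the single-marker model."""

    n_pcs: int = 3
    use_kinship: bool = False  # whiten the line means by the realized kinship
    min_class_size: int = 1    # marker classes below this are merged into missing


def _orth(A: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-revealing)."""
    if A.size == 0:
        return np.zeros((A.shape[0], 0))
    U, s, _ = np.linalg.svd(A, full_matrices=False)
    if len(s) == 0 or s[0] == 0:
        return np.zeros((A.shape[0], 0))
    # absolute floor sqrt(n): design columns (indicators, intercept) have
    # norm >= 1, so a residual this small is cancellation, not signal
    tol = max(A.shape) * np.finfo(float).eps * max(s[0], np.sqrt(A.shape[0]))
    return U[:, s > tol]


def _class_indicators(dose: np.ndarray):
    """Indicator columns for observed dosage classes (0/1/2); NaN rows zero."""
    classes = np.unique(dose[~np.isnan(dose)])
    Z = np.zeros((len(dose), len(classes)))
    for k, c in enumerate(classes):
        Z[dose == c, k] = 1.0
    return Z, classes


class MarkerScanEngine:
    """Precomputed line-level design for fast repeated scans of one trait."""

    def __init__(self, panel: GenotypePanel, pheno: pd.DataFrame, trait: str,
                 spec: MLMSpec | None = None, cofactors=()):
        self.spec = spec or MLMSpec()
        self.trait = trait
        df = pheno[pheno["trait"] == trait]
        if df.empty:
            raise ValueError(f"no phenotype records for trait {trait!r}")
        cell = df.groupby(["genotype", "treatment"])["value"].mean().unstack()
        cell = cell.reindex(panel.genotype_ids)
        keep = cell.notna().any(axis=1).to_numpy()
        self.genotype_ids = [g for g, k in zip(panel.genotype_ids, keep) if k]
        self._rows = np.where(keep)[0]
        sub = cell.iloc[self._rows]
        self.m = sub.mean(axis=1).to_numpy()  # line means across treatments
        if {"control", "drought"} <= set(sub.columns):
            self.d = (sub["drought"] - sub["control"]).to_numpy()
        else:
            self.d = np.full(len(sub), np.nan)
        self.panel = panel
        self.dosage = panel.dosage[self._rows]

        cols = [np.ones((len(self.m), 1))]
        if self.spec.n_pcs > 0 and panel.n_markers > 0:
            sub_panel = panel.subset_genotypes(self.genotype_ids)
            pcs = compute_pca(sub_panel, n_components=self.spec.n_pcs).scores
            cols.append(pcs)
        for cof in cofactors:
            dose = self.dosage[:, panel.marker_index(cof)].copy()
            if np.isnan(dose).any():
                dose[np.isnan(dose)] = np.round(np.nanmean(dose))
            Z, _ = _class_indicators(dose)
            cols.append(Z)
        self.C = np.hstack(cols)
        self.cofactors = list(cofactors)

        if self.spec.use_kinship:
            self._whiten_by_kinship()

        self.mask_m = np.isfinite(self.m)
        self.mask_d = np.isfinite(self.d)
        self._cache = {}

    # -- kinship whitening (mean model only) ---------------------------
    def _whiten_by_kinship(self):
        """GLS whitening of the line means with Var = s2g*K + s2e*I.

        The variance ratio is profiled on the null (no-marker) model by a
        coarse grid over log-delta. Marker calls are modal-imputed during
        whitened scans so every row stays usable. The difference model is
        left unwhitened: polygenic main effects cancel in the contrast.
        """
        sub_panel = self.panel.subset_genotypes(self.genotype_ids)
        K = compute_kinship(sub_panel).values
        w, U = np.linalg.eigh(K)
        w = np.maximum(w, 0.0)
        y = U.T @ np.nan_to_num(self.m, nan=float(np.nanmean(self.m)))
        X = U.T @ self.C
        best, best_ll = 1.0, -np.inf
        for logd in np.linspace(-4, 4, 33):
            delta = 10.0 ** logd
            v = w + delta
            Xw = X / np.sqrt(v)[:, None]
            yw = y / np.sqrt(v)
            beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
            r = yw - Xw @ beta
            n = len(yw)
            s2 = (r @ r) / n
            ll = -0.5 * (n * np.log(s2) + np.sum(np.log(v)))
            if ll > best_ll:
                best_ll, best = ll, delta
        v = w + best
        T = U / np.sqrt(v)[None, :]
        self._whitener = T.T  # y* = T' y
        self.m = self._whitener @ np.nan_to_num(self.m, nan=float(np.nanmean(self.m)))
        self.C = self._whitener @ self.C
    # -------------------------------------------------------------------

    def _marker_dose(self, j: int) -> np.ndarray:
        dose = self.dosage[:, j].copy()
        dose = np.round(dose)
        if self.spec.use_kinship and np.isnan(dose).any():
            dose[np.isnan(dose)] = np.round(np.nanmean(dose))
        return dose

    def _prep_marker(self, j: int):
        """Projection pieces for marker j's mean-model test (cached)."""
        if j in self._cache:
            return self._cache[j]
        dose = self._marker_dose(j)
        mask = self.mask_m & ~np.isnan(dose)
        Z, classes = _class_indicators(dose[mask])
        if self.spec.use_kinship:
            Z = self._whitener @ Z
        out = None
        if len(classes) >= 2:
            Qc = _orth(self.C[mask])
            Zr = Z - Qc @ (Qc.T @ Z)
            Qz = _orth(Zr)
            df2 = int(mask.sum()) - Qc.shape[1] - Qz.shape[1]
            if Qz.shape[1] > 0 and df2 > 0:
                out = (mask, Qc, Qz, df2)
        self._cache[j] = out
        return out

    def _test_on(self, y, C, Z):
        """F-test of class block Z given covariates C on response y."""
        Qc = _orth(C)
        yr = y - Qc @ (Qc.T @ y)
        Zr = Z - Qc @ (Qc.T @ Z)
        Qz = _orth(Zr)
        k = Qz.shape[1]
        df2 = len(y) - Qc.shape[1] - k
        if k == 0 or df2 <= 0:
            return np.nan, np.nan, k, df2
        ssm = float(np.sum((Qz.T @ y) ** 2))
        sse0 = float(yr @ yr)
        sse1 = max(sse0 - ssm, 0.0)
        if sse1 <= 0:
            return np.inf, np.finfo(float).tiny, k, df2
        F = (ssm / k) / (sse1 / df2)
        p = float(stats.f.sf(F, k, df2))
        return F, max(p, np.finfo(float).tiny), k, df2

    def test_marker(self, j: int) -> dict:
        dose = self._marker_dose(j)
        mm = self.panel.marker_map
        rec = {
            "marker": mm["marker"][j], "chromosome": mm["chromosome"][j],
            "cM": mm["cM"][j], "p_M": 1.0, "p_MxT": 1.0, "reason": "",
        }
        mask = self.mask_m & ~np.isnan(dose)
        classes = np.unique(dose[mask][~np.isnan(dose[mask])])
        if len(classes) < 2:
            rec["reason"] = "monomorphic"
            return rec
        Z, _ = _class_indicators(dose[mask])
        if self.spec.use_kinship:
            Z = self._whitener @ Z  # GLS transform applies to the design too
        _, p_m, _, _ = self._test_on(self.m[mask], self.C[mask], Z)
        if np.isfinite(p_m):
            rec["p_M"] = p_m
        else:
            rec["reason"] = "degenerate"
        mask_d = self.mask_d & ~np.isnan(dose)
        if mask_d.sum() >= 3 and len(np.unique(dose[mask_d])) >= 2:
            Zd, _ = _class_indicators(dose[mask_d])
            Cd = self._C_unwhitened()[mask_d]
            _, p_mt, _, _ = self._test_on(self.d[mask_d], Cd, Zd)
            if np.isfinite(p_mt):
                rec["p_MxT"] = p_mt
        return rec

    def _C_unwhitened(self):
        # diff-model covariates are never whitened; rebuild if needed
        if not self.spec.use_kinship:
            return self.C
        if not hasattr(self, "_C_raw"):
            cols = [np.ones((len(self.d), 1))]
            if self.spec.n_pcs > 0 and self.panel.n_markers > 0:
                sub_panel = self.panel.subset_genotypes(self.genotype_ids)
                cols.append(compute_pca(sub_panel, self.spec.n_pcs).scores)
            for cof in self.cofactors:
                dose = self.dosage[:, self.panel.marker_index(cof)].copy()
                if np.isnan(dose).any():
                    dose[np.isnan(dose)] = np.round(np.nanmean(dose))
                Z, _ = _class_indicators(dose)
                cols.append(Z)
            self._C_raw = np.hstack(cols)
        return self._C_raw

    def scan(self, exclude=()) -> pd.DataFrame:
        """Scan every marker; returns per-marker p_M, p_MxT, LOD columns."""
        excl = set(exclude)
        recs = []
        for j in range(self.panel.n_markers):
            if self.panel.marker_map["marker"][j] in excl:
                continue
            recs.append(self.test_marker(j))
        df = pd.DataFrame(recs)
        if len(df):
            df["LOD_M"] = -np.log10(df["p_M"])
            df["LOD_MxT"] = -np.log10(df["p_MxT"])
        return df

    def permutation_max_lods(self, n_perm: int, rng) -> np.ndarray:
        """Genome-wide maximum LOD of the marker main-effect test for each
        of ``n_perm`` whole-line permutations of the phenotypes."""
        n = len(self.m)
        perms = np.stack([rng.permutation(n) for _ in range(n_perm)])
        Y = self.m[perms].T  # (n, n_perm); NaN-free after engine masking
        Y = np.where(np.isfinite(Y), Y, np.nanmean(self.m))
        max_lod = np.zeros(n_perm)
        for j in range(self.panel.n_markers):
            prep = self._prep_marker(j)
            if prep is None:
                continue
            mask, Qc, Qz, df2 = prep
            Yj = Y[mask]
            ss_tot = np.sum(Yj * Yj, axis=0)
            ss_cov = np.sum((Qc.T @ Yj) ** 2, axis=0)
            ssm = np.sum((Qz.T @ Yj) ** 2, axis=0)
            sse1 = np.maximum(ss_tot - ss_cov - ssm, np.finfo(float).tiny)
            k = Qz.shape[1]
            F = (ssm / k) / (sse1 / df2)
            p = np.maximum(stats.f.sf(F, k, df2), np.finfo(float).tiny)
            np.maximum(max_lod, -np.log10(p), out=max_lod)
        return max_lod


def fit_marker_model(pheno: pd.DataFrame, panel: GenotypePanel, marker: str,
                     cofactors=(), spec: MLMSpec | None = None,
                     trait: str | None = None) -> dict:
    """Fit the single-marker model for one marker and return its statistics.

    ``trait`` defaults to the only trait present in ``pheno``. Returns a
    dict with p_M, p_MxT, LOD_M, LOD_MxT, per-class line-mean effects and
    class counts; monomorphic markers come back with reason
    ``"monomorphic"`` and p = 1.
    """
    if trait is None:
        traits = pheno["trait"].unique()
        if len(traits) != 1:
            raise ValueError("trait must be named when pheno holds several")
        trait = traits[0]
    eng = MarkerScanEngine(panel, pheno, trait, spec, cofactors)
    j = panel.marker_index(marker)
    rec = eng.test_marker(j)
    rec["LOD_M"] = -np.log10(rec["p_M"])
    rec["LOD_MxT"] = -np.log10(rec["p_MxT"])
    dose = np.round(eng.dosage[:, j])
    means, ns = {}, {}
    for c in (0.0, 1.0, 2.0):
        sel = (dose == c) & eng.mask_m
        ns[int(c)] = int(sel.sum())
        means[int(c)] = float(np.mean(eng.m[sel])) if sel.any() else np.nan
    rec["class_means"] = means
    rec["class_n"] = ns
    return rec


@dataclass
class PermutationThreshold:
    threshold: float       # (1 - alpha) quantile of permuted max LOD
    lod_floor: float       # fixed p <= 1e-4 floor
    alpha: float
    n_perm: int
    max_lods: np.ndarray = field(repr=False, default=None)

    @property
    def effective(self) -> float:
        return max(self.threshold, self.lod_floor)


def permutation_threshold(pheno: pd.DataFrame, panel: GenotypePanel, trait: str,
                          n_perm: int = 1000, alpha: float = 0.05,
                          seed: int = 0, spec: MLMSpec | None = None,
                          lod_floor: float = 4.0) -> PermutationThreshold:
    """Genome-wide LOD threshold from whole-line permutations.

    All records of a line move together (the permutation happens on the
    line-level aggregates), preserving the treatment/year/replicate
    structure. The significance rule downstream is
    ``LOD >= max(threshold, lod_floor)``.
    """
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    eng = MarkerScanEngine(panel, pheno, trait, spec)
    rng = np.random.default_rng(seed)
    max_lods = eng.permutation_max_lods(n_perm, rng)
    thr = float(np.quantile(max_lods, 1.0 - alpha))
    return PermutationThreshold(thr, lod_floor, alpha, n_perm, max_lods)


def _effective_threshold(threshold, lod_floor=4.0) -> float:
    if isinstance(threshold, PermutationThreshold):
        return threshold.effective
    return max(float(threshold), lod_floor)


@dataclass
class MultilocusResult:
    trait: str
    selected: list
    first_scan: pd.DataFrame
    iterations: list
    threshold: float


def _pairwise_r2(panel: GenotypePanel, a: int, b: int) -> float:
    x, y = panel.dosage[:, a], panel.dosage[:, b]
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
        return 0.0
    return float(np.corrcoef(x[ok], y[ok])[0, 1] ** 2)


def multilocus_scan(pheno: pd.DataFrame, panel: GenotypePanel, trait: str,
                    spec: MLMSpec | None = None, threshold=4.0,
                    max_iter: int = 20, lod_floor: float = 4.0,
                    collinearity_r2: float = 0.99) -> MultilocusResult:
    """Forward cofactor selection: repeatedly scan, take the most
    informative SNP above threshold as a fixed cofactor, rescan.

    Ties on LOD break toward the smaller map position, then the
    lexicographically smaller marker id. Markers with r2 > 0.99 to a
    selected cofactor leave the candidate pool. An empty selection is a
    valid result.
    """
    thr = _effective_threshold(threshold, lod_floor)
    selected, iterations = [], []
    excluded = set()
    first_scan = None
    for it in range(max_iter):
        eng = MarkerScanEngine(panel, pheno, trait, spec, cofactors=selected)
        sc = eng.scan(exclude=set(selected) | excluded)
        if first_scan is None:
            first_scan = sc
        iterations.append(sc)
        if sc.empty:
            break
        best_lod = np.maximum(sc["LOD_M"], sc["LOD_MxT"])
        sc = sc.assign(best_lod=best_lod)
        passing = sc[sc["best_lod"] >= thr]
        if passing.empty:
            break
        passing = passing.sort_values(
            ["best_lod", "cM", "marker"], ascending=[False, True, True]
        )
        pick = passing.iloc[0]["marker"]
        selected.append(pick)
        jp = panel.marker_index(pick)
        for j in range(panel.n_markers):
            mid = panel.marker_map["marker"][j]
            if mid in excluded or mid in selected:
                continue
            if _pairwise_r2(panel, jp, j) > collinearity_r2:
                excluded.add(mid)
    return MultilocusResult(trait, selected, first_scan, iterations, thr)


@dataclass
class QTLRecord:
    trait: str
    qtl_name: str
    peak_marker: str
    effect_type: str          # "M", "MxT" or "M/MxT"
    chromosome: str
    position_cM: float
    interval_cM: tuple        # (lo, hi), contains the peak
    lod: float
    members: list             # significant first-iteration SNPs merged in
    var_explained: float | None = None


def merge_to_qtl(result: MultilocusResult, marker_map: pd.DataFrame,
                 flank_cM: float = 5.0) -> list:
    """Combine significant first-iteration SNPs near each selected peak
    into joint QTL intervals.

    The interval is [min cM, max cM] over the peak and the significant
    first-iteration SNPs within ``flank_cM`` of it (collapsing to the
    peak position for a lone peak). The effect type comes from which of
    the peak's tests passed the threshold at selection.
    """
    if not result.selected:
        return []
    fs = result.first_scan.set_index("marker")
    thr = result.threshold
    sig = fs[(fs["LOD_M"] >= thr) | (fs["LOD_MxT"] >= thr)]
    records = []
    taken = set()
    name_count = {}
    for i, peak in enumerate(result.selected):
        it_scan = result.iterations[i].set_index("marker")
        row = it_scan.loc[peak]
        m_pass = row["LOD_M"] >= thr
        t_pass = row["LOD_MxT"] >= thr
        effect = "M/MxT" if (m_pass and t_pass) else ("MxT" if t_pass else "M")
        chrom, pos = row["chromosome"], float(row["cM"])
        near = sig[(sig["chromosome"] == chrom)
                   & ((sig["cM"] - pos).abs() <= flank_cM)]
        members = [m for m in near.index if m not in taken]
        if peak not in members:
            members.append(peak)
        taken.update(members)
        cms = [pos] + [float(fs.loc[m, "cM"]) for m in members if m != peak]
        lod = float(max(row["LOD_M"], row["LOD_MxT"]))
        base = f"Q{result.trait}.{chrom}"
        k = name_count.get(base, 0)
        name_count[base] = k + 1
        name = base if k == 0 else f"{base}.{chr(ord('a') + k)}"
        records.append(QTLRecord(
            trait=result.trait, qtl_name=name, peak_marker=peak,
            effect_type=effect, chromosome=chrom, position_cM=pos,
            interval_cM=(min(cms), max(cms)), lod=lod, members=members,
        ))
    # rename chromosomes with several QTL using .a/.b suffixes
    for base, cnt in name_count.items():
        if cnt > 1:
            idx = 0
            for rec in records:
                if rec.qtl_name.startswith(base) and (rec.qtl_name == base
                                                      or rec.qtl_name[len(base):].startswith(".")):
                    rec.qtl_name = f"{base}.{chr(ord('a') + idx)}"
                    idx += 1
    return records


@dataclass
class CVResult:
    trait: str
    table: pd.DataFrame  # marker, detection_rate, mean_p, passed
    n_runs: int
    leave_frac: float


def cross_validate(pheno: pd.DataFrame, panel: GenotypePanel, trait: str,
                   spec: MLMSpec | None = None, threshold=4.0,
                   candidates=None, leave_frac: float = 0.2,
                   n_runs: int = 20, seed: int = 0,
                   match_cM: float = 5.0, p_pass: float = 1e-4) -> CVResult:
    """Leave-20%-out cross validation of the multi-locus selection.

    Each run drops ``leave_frac`` of the trait's phenotype records at
    random and reruns the full multi-locus scan. A candidate counts as
    detected when a selected marker lies within ``match_cM`` of it on the
    same chromosome. The arithmetic mean of the candidate's per-run
    first-iteration p-values is reported as its validated p, and the pass
    flag applies the p <= 1e-4 rule to that mean.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be positive")
    thr = _effective_threshold(threshold)
    if candidates is None:
        candidates = multilocus_scan(pheno, panel, trait, spec, thr).selected
    rng = np.random.default_rng(seed)
    mm = panel.marker_map.set_index("marker")
    trait_idx = pheno.index[pheno["trait"] == trait].to_numpy()
    other = pheno.loc[pheno["trait"] != trait]
    hits = {c: 0 for c in candidates}
    pvals = {c: [] for c in candidates}
    for _ in range(n_runs):
        if leave_frac > 0:
            n_drop = int(round(leave_frac * len(trait_idx)))
            drop = rng.choice(trait_idx, size=n_drop, replace=False)
            reduced = pd.concat([pheno.loc[np.setdiff1d(trait_idx, drop)], other])
        else:
            reduced = pheno
        res = multilocus_scan(reduced, panel, trait, spec, thr)
        fs = res.first_scan.set_index("marker")
        for c in candidates:
            c_chrom, c_cm = mm.loc[c, "chromosome"], mm.loc[c, "cM"]
            found = any(
                mm.loc[s, "chromosome"] == c_chrom
                and abs(mm.loc[s, "cM"] - c_cm) <= match_cM
                for s in res.selected
            )
            hits[c] += int(found)
            if c in fs.index:
                pvals[c].append(float(min(fs.loc[c, "p_M"], fs.loc[c, "p_MxT"])))
    rows = []
    for c in candidates:
        rate = hits[c] / n_runs
        mean_p = float(np.mean(pvals[c])) if pvals[c] else np.nan
        rows.append((c, rate, mean_p, bool(mean_p <= p_pass)))
    table = pd.DataFrame(rows, columns=["marker", "detection_rate",
                                        "mean_p", "passed"])
    return CVResult(trait, table, n_runs, leave_frac)


def variance_explained(pheno: pd.DataFrame, panel: GenotypePanel, trait: str,
                       marker: str, cofactors=()) -> float:
    """Percent of line-mean variance explained by the marker: the partial
    R2 (SSE_without - SSE_with) / SS_total of the genotype-mean model."""
    df = pheno[pheno["trait"] == trait]
    means = df.groupby("genotype")["value"].mean().reindex(panel.genotype_ids)
    y = means.to_numpy()
    dose = np.round(panel.marker_dosage(marker))
    mask = np.isfinite(y) & ~np.isnan(dose)
    if mask.sum() < 3:
        raise ValueError("too few genotypes with marker call and phenotype")
    y = y[mask]
    cols = [np.ones((mask.sum(), 1))]
    for cof in cofactors:
        cd = np.round(panel.marker_dosage(cof))[mask]
        if np.isnan(cd).any():
            cd[np.isnan(cd)] = np.round(np.nanmean(cd))
        Z, _ = _class_indicators(cd)
        cols.append(Z)
    C = np.hstack(cols)
    Z, classes = _class_indicators(dose[mask])
    if len(classes) < 2:
        raise ValueError(f"marker {marker!r} monomorphic in phenotyped subset")
    Qc = _orth(C)
    yr = y - Qc @ (Qc.T @ y)
    sse0 = float(yr @ yr)
    Qz = _orth(Z - Qc @ (Qc.T @ Z))
    sse1 = sse0 - float(np.sum((Qz.T @ y) ** 2))
    ss_total = float(np.sum((y - y.mean()) ** 2))
    if ss_total <= 0:
        raise ValueError("constant line means: variance explained undefined")
    return 100.0 * (sse0 - sse1) / ss_total
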