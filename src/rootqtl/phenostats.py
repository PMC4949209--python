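"""Split-plot phenotype statistics: ANOVA, variance components,
broad-sense heritability, trait summaries and correlations.

The analysis of variance fits, by sequential (Type-I) projection in the
model's term order, the crossed model

    Y = mu + T + R(T) + G + GxT + GxY + GxTxY + error

with treatment T, replication R nested in treatment, genotype G and year
Y entering only through its interactions with G (a year main effect can
be switched on). Variance components for heritability come from the
classical expected-mean-squares (ANOVA) estimators treating G and its
interactions as random; on balanced data with interior solutions these
coincide with REML. Broad-sense heritability is

    H2 = V_G / (V_G + V_GxT/t + V_GxY/y + V_E/(t*y*r))

with t treatments, y years and r the average replication count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .panel import TRAITS


class SingularDesignError(ValueError):
    pass


class InestimableError(ValueError):
    pass


def _indicators(*label_cols) -> np.ndarray:
    """Indicator matrix of the interaction of one or more label vectors."""
    combo = pd.MultiIndex.from_arrays([np.asarray(c) for c in label_cols])
    codes, _ = pd.factorize(combo)
    k = codes.max() + 1
    Z = np.zeros((len(codes), k))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def _sequential_ss(y: np.ndarray, blocks) -> tuple:
    """Sequential (Type-I) sums of squares by block orthogonalisation.

    ``blocks`` is a list of (name, indicator-matrix); the grand mean is
    projected out first. Returns (rows, residual_ss, residual_df).
    """
    n = len(y)
    Q = np.ones((n, 1)) / np.sqrt(n)
    rows = []
    for name, B in blocks:
        R = B - Q @ (Q.T @ B)
        U, s, _ = np.linalg.svd(R, full_matrices=False)
        tol = max(R.shape) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
        rank = int((s > max(tol, 1e-9)).sum())
        Qb = U[:, :rank]
        ss = float(np.sum((Qb.T @ y) ** 2))
        rows.append((name, ss, rank))
        if rank:
            Q = np.hstack([Q, Qb])
    total_ss = float(np.sum((y - y.mean()) ** 2))
    model_ss = sum(r[1] for r in rows)
    model_df = sum(r[2] for r in rows)
    resid_ss = max(total_ss - model_ss, 0.0)
    resid_df = n - 1 - model_df
    return rows, resid_ss, resid_df


@dataclass
class AnovaResult:
    trait: str
    table: pd.DataFrame  # term, SS, df, MS, F, p
    residual_ss: float
    residual_df: int

    @property
    def residual_ms(self) -> float:
        return self.residual_ss / self.residual_df if self.residual_df else np.nan

    def p_value(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "p"])


def fit_anova(pheno: pd.DataFrame, trait: str,
              include_year: bool = False) -> AnovaResult:
    """Sequential-SS ANOVA of the split-plot model for one trait.

    F-tests are against the residual mean square. Terms that add no
    estimable degrees of freedom beyond the nesting raise
    :class:`SingularDesignError`.
    """
    df = pheno[pheno["trait"] == trait]
    if df.empty:
        raise ValueError(f"no records for trait {trait!r}")
    for col in ("treatment", "genotype"):
        if df[col].nunique() < 2:
            raise SingularDesignError(f"factor {col!r} has <2 levels")
    y = df["value"].to_numpy(float)
    t, g, yr, rep = (df[c].to_numpy() for c in
                     ("treatment", "genotype", "year", "replicate"))
    blocks = [("T", _indicators(t)), ("R(T)", _indicators(t, rep))]
    if include_year:
        blocks.append(("Y", _indicators(yr)))
    blocks += [
        ("G", _indicators(g)),
        ("GxT", _indicators(g, t)),
        ("GxY", _indicators(g, yr)),
        ("GxTxY", _indicators(g, t, yr)),
    ]
    rows, resid_ss, resid_df = _sequential_ss(y, blocks)
    aliased = [name for name, _, rank in rows[2:] if rank == 0]
    if aliased:
        raise SingularDesignError(f"aliased terms: {aliased}")
    if resid_df <= 0:
        resid_ms = np.nan
    else:
        resid_ms = resid_ss / resid_df
    out = []
    for name, ss, dfr in rows:
        ms = ss / dfr if dfr else np.nan
        if resid_df > 0 and dfr > 0 and resid_ms > 0:
            F = ms / resid_ms
            p = float(stats.f.sf(F, dfr, resid_df))
        else:
            F, p = np.nan, np.nan
        out.append((name, ss, dfr, ms, F, p))
    table = pd.DataFrame(out, columns=["term", "SS", "df", "MS", "F", "p"])
    return AnovaResult(trait, table, resid_ss, resid_df)


@dataclass
class VarianceComponents:
    trait: str
    V_G: float
    V_GxT: float
    V_GxY: float
    V_E: float
    t: int
    y: int
    r: float
    V_GxTxY: float = 0.0
    truncated: tuple = ()

    def __post_init__(self):
        if min(self.t, self.y) < 1 or self.r <= 0:
            raise ValueError("invalid design constants")


def estimate_variance_components(pheno: pd.DataFrame, trait: str) -> VarianceComponents:
    """ANOVA (expected-mean-squares) estimates of V_G, V_GxT, V_GxY, V_E.

    Genotype and its interactions are treated as random; the environment
    cells (treatment x year x replicate) are swept out first so replicate
    effects do not inflate the residual. Negative solutions are truncated
    to zero and flagged. ``r`` is the arithmetic mean replicate count over
    genotype x treatment x year cells.
    """
    df = pheno[pheno["trait"] == trait]
    if df.empty:
        raise ValueError(f"no records for trait {trait!r}")
    cells = df.groupby(["genotype", "treatment", "year"])["value"].count()
    if (cells <= 1).all():
        raise InestimableError("no replicated genotype x treatment x year cells")
    r = float(cells.mean())
    t = int(df["treatment"].nunique())
    ny = int(df["year"].nunique())
    g = int(df["genotype"].nunique())

    y = df["value"].to_numpy(float)
    trt, gen, yr, rep = (df[c].to_numpy() for c in
                         ("treatment", "genotype", "year", "replicate"))
    blocks = [
        ("env", _indicators(trt, yr, rep)),
        ("G", _indicators(gen)),
        ("GxT", _indicators(gen, trt)),
        ("GxY", _indicators(gen, yr)),
        ("GxTxY", _indicators(gen, trt, yr)),
    ]
    rows, resid_ss, resid_df = _sequential_ss(y, blocks)
    if resid_df <= 0:
        raise InestimableError("residual degrees of freedom exhausted")
    ms = {name: (ss / dfr if dfr else 0.0) for name, ss, dfr in rows}
    ms_e = resid_ss / resid_df
    v_gty = (ms.get("GxTxY", ms_e) - ms_e) / r
    v_gy = (ms["GxY"] - ms.get("GxTxY", ms_e)) / (r * t)
    v_gt = (ms["GxT"] - ms.get("GxTxY", ms_e)) / (r * ny)
    v_g = (ms["G"] - ms["GxT"] - ms["GxY"] + ms.get("GxTxY", ms_e)) / (r * t * ny)
    raw = {"V_G": v_g, "V_GxT": v_gt, "V_GxY": v_gy, "V_GxTxY": v_gty}
    truncated = tuple(k for k, v in raw.items() if v < 0)
    clipped = {k: max(v, 0.0) for k, v in raw.items()}
    return VarianceComponents(
        trait=trait, V_E=ms_e, t=t, y=ny, r=r, truncated=truncated, **clipped
    )


@dataclass
class HeritabilityResult:
    trait: str
    H2: float
    components: VarianceComponents
    truncated: bool = False


def heritability(vc: VarianceComponents) -> HeritabilityResult:
    """Broad-sense heritability on an entry-mean basis."""
    denom = vc.V_G + vc.V_GxT / vc.t + vc.V_GxY / vc.y + vc.V_E / (vc.t * vc.y * vc.r)
    if denom <= 0:
        raise InestimableError("all variance components are zero")
    h2 = vc.V_G / denom
    truncated = not (0.0 <= h2 <= 1.0)
    return HeritabilityResult(vc.trait, float(np.clip(h2, 0.0, 1.0)), vc, truncated)


def genotype_means(pheno: pd.DataFrame, trait: str,
                   condition: str | None = None) -> pd.Series:
    """Genotype-level trait means, averaged over years and replicates
    (and treatments unless ``condition`` restricts to one)."""
    df = pheno[pheno["trait"] == trait]
    if condition is not None:
        df = df[df["treatment"] == condition]
    return df.groupby("genotype")["value"].mean()


def trait_correlations(pheno: pd.DataFrame, condition: str,
                       traits=TRAITS) -> pd.DataFrame:
    """Pearson correlations of genotype-level trait means within one
    treatment condition. Constant traits yield missing entries."""
    cols = {}
    for tr in traits:
        m = genotype_means(pheno, tr, condition)
        if len(m):
            cols[tr] = m
    wide = pd.DataFrame(cols).dropna()
    if len(wide) < 3:
        raise ValueError("need >=3 genotypes with complete trait means")
    return wide.corr(method="pearson")


def summarize_traits(pheno: pd.DataFrame) -> pd.DataFrame:
    """Mean, sd and n per trait x treatment x year."""
    g = pheno.groupby(["trait", "treatment", "year"])["value"]
    out = g.agg(mean="mean", sd="std", n="count").reset_index()
    return out
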