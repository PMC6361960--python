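"""Phenotype preparation, additive association, and signal selection.

Quantitative traits follow the biobank lipid/liver-enzyme conventions:
LDL cholesterol is computed with the Friedewald formula (masked above
TG 400 mg/dL), every trait except total cholesterol is natural-log
transformed, and medication flags blank the affected trait groups.
Association is ordinary least squares of the transformed trait on allele
dosage with age, sex and recruitment-area covariates (additive model).
Post-imputation filtering removes info < 0.4 or MAF < 1%; top signals are
genome-wide-significant common leads plus nonsynonymous candidates inside
qualifying loci; novelty is judged against a known-association catalog
within a 1 Mb window centred on the hit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .core import MISSING, AnnotationTable, GenotypeMatrix, ThresholdConfig

logger = logging.getLogger(__name__)

__all__ = [
    "friedewald_ldl",
    "prepare_traits",
    "AssocResult",
    "additive_assoc",
    "assoc_scan",
    "post_impute_filter",
    "select_signals",
    "annotate_novelty",
    "merge_replication",
    "LOG_TRAITS",
]

#: Traits that are natural-log transformed before analysis (TCHL is not).
LOG_TRAITS = ("HDLc", "LDLc", "TG", "AST", "ALT")
LIPID_TRAITS = ("LDLc", "HDLc", "TG")
LIVER_TRAITS = ("AST", "ALT")


def friedewald_ldl(tc, hdl, tg, tg_mask_mgdl: float = 400.0):
    """Friedewald LDL cholesterol: tc - hdl - tg/5 (mg/dL).

    Returns NaN when any input is missing or TG exceeds ``tg_mask_mgdl``
    (strict inequality: TG = 400 still computes).  Accepts scalars or
    arrays; negative concentrations are an error.
    """
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    for name, arr in (("tc", tc), ("hdl", hdl), ("tg", tg)):
        if np.any(arr[~np.isnan(arr)] < 0):
            raise ValueError(f"negative {name} concentration")
    ldl = tc - hdl - tg / 5.0
    ldl = np.where(np.isnan(tc) | np.isnan(hdl) | np.isnan(tg) | (tg > tg_mask_mgdl),
                   np.nan, ldl)
    return float(ldl) if ldl.ndim == 0 else ldl


def prepare_traits(pheno: pd.DataFrame, cfg: ThresholdConfig | None = None) -> pd.DataFrame:
    """Produce the analysis-ready trait table.

    Recomputes LDLc by Friedewald (TG-masked), blanks lipid traits for
    lipid-medicated samples and liver traits for liver-medicated samples,
    then ln-transforms every trait except TCHL.  Non-positive values that
    would reach a log are set missing (with a logged count).
    """
    cfg = cfg or ThresholdConfig()
    out = pheno.copy()
    if {"TCHL", "HDLc", "TG"}.issubset(out.columns):
        out["LDLc"] = friedewald_ldl(out["TCHL"], out["HDLc"], out["TG"],
                                     tg_mask_mgdl=cfg.tg_mask_mgdl)
    if "lipid_medication" in out.columns:
        mask = out["lipid_medication"].astype(bool)
        for t in LIPID_TRAITS:
            if t in out.columns:
                out.loc[mask, t] = np.nan
    if "liver_medication" in out.columns:
        mask = out["liver_medication"].astype(bool)
        for t in LIVER_TRAITS:
            if t in out.columns:
                out.loc[mask, t] = np.nan
    n_nonpos = 0
    for t in LOG_TRAITS:
        if t not in out.columns:
            continue
        vals = out[t].to_numpy(dtype=float)
        bad = ~np.isnan(vals) & (vals <= 0)
        n_nonpos += int(bad.sum())
        vals = np.where(bad, np.nan, vals)
        out[t] = np.log(vals)
    if n_nonpos:
        logger.warning("prepare_traits: %d non-positive values set missing before log transform",
                       n_nonpos)
    return out


def _covariate_design(covariates: pd.DataFrame) -> pd.DataFrame:
    """Intercept + age + sex (0/1) + one-hot area (first level is reference)."""
    cols = {"const": np.ones(len(covariates))}
    if "age" in covariates.columns:
        cols["age"] = covariates["age"].to_numpy(dtype=float)
    if "sex" in covariates.columns:
        cols["sex"] = covariates["sex"].to_numpy(dtype=float)
    design = pd.DataFrame(cols, index=covariates.index)
    if "area" in covariates.columns:
        dummies = pd.get_dummies(covariates["area"].astype(str), prefix="area",
                                 drop_first=True, dtype=float)
        design = pd.concat([design, dummies], axis=1)
    return design


def _check_collinear(X: pd.DataFrame) -> None:
    mat = X.to_numpy(dtype=float)
    rank = 0
    for j in range(mat.shape[1]):
        new_rank = np.linalg.matrix_rank(mat[:, : j + 1])
        if new_rank == rank:
            raise ValueError(f"collinear design: column {X.columns[j]!r} adds no rank")
        rank = new_rank


@dataclass
class AssocResult:
    """Per-variant additive-model summary statistic."""

    beta: float
    se: float
    p: float
    eaf: float
    n: int

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)


def additive_assoc(dosages: np.ndarray, y: np.ndarray,
                   covariates: pd.DataFrame | None = None) -> AssocResult:
    """OLS of a transformed trait on allele dosage plus covariates.

    Complete-case analysis; the dosage coefficient's two-sided p-value comes
    from the t distribution with residual degrees of freedom.
    """
    dosages = np.asarray(dosages, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        covariates = pd.DataFrame(index=pd.RangeIndex(len(y)))
    design = _covariate_design(covariates.reset_index(drop=True))
    design.insert(1, "dosage", dosages)
    ok = ~np.isnan(y) & ~design.isna().any(axis=1).to_numpy() & (dosages != MISSING)
    Xc = design.loc[ok]
    yc = y[ok]
    if ok.sum() < design.shape[1] + 1:
        raise ValueError(f"too few complete cases ({int(ok.sum())}) for {design.shape[1]} predictors")
    _check_collinear(Xc)
    fit = sm.OLS(yc, Xc).fit()
    d = Xc["dosage"].to_numpy()
    return AssocResult(
        beta=float(fit.params["dosage"]),
        se=float(fit.bse["dosage"]),
        p=float(fit.pvalues["dosage"]),
        eaf=float(d.mean() / 2.0),
        n=int(ok.sum()),
    )


def assoc_scan(geno: GenotypeMatrix, y: np.ndarray,
               covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Vectorised additive association across all variants of a matrix.

    Equivalent to per-variant OLS with the same covariates (by the
    Frisch–Waugh–Lovell projection); missing dosages are mean-imputed per
    variant and samples with missing phenotype or covariates are dropped.
    Returns a frame with id, chrom, pos, ea, eaf, beta, se, p, n.
    """
    y = np.asarray(y, dtype=float)
    if covariates is None:
        covariates = pd.DataFrame(index=pd.RangeIndex(len(y)))
    C = _covariate_design(covariates.reset_index(drop=True)).to_numpy(dtype=float)
    ok = ~np.isnan(y) & ~np.isnan(C).any(axis=1)
    Cc = C[ok]
    yc = y[ok]
    X = geno.calls[ok, :].astype(float)
    X[X == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    eaf = col_mean / 2.0

    Q, _ = np.linalg.qr(Cc)
    y_res = yc - Q @ (Q.T @ yc)
    X_res = X - Q @ (Q.T @ X)
    sxx = (X_res ** 2).sum(axis=0)
    sxy = X_res.T @ y_res
    syy = float(y_res @ y_res)
    dof = len(yc) - Cc.shape[1] - 1
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(sxx > 0, sxy / np.where(sxx > 0, sxx, 1.0), np.nan)
        rss = syy - beta * beta * sxx
        sigma2 = rss / dof
        se = np.sqrt(sigma2 / np.where(sxx > 0, sxx, np.nan))
        t = beta / se
    p = 2.0 * sps.t.sf(np.abs(t), dof)
    return pd.DataFrame({
        "id": [v.id for v in geno.variants],
        "chrom": [v.chrom for v in geno.variants],
        "pos": [v.pos for v in geno.variants],
        "ea": [v.alleleB for v in geno.variants],
        "eaf": eaf, "beta": beta, "se": se, "p": p,
        "n": len(yc),
    })


def post_impute_filter(stats: pd.DataFrame, cfg: ThresholdConfig | None = None) -> pd.DataFrame:
    """Drop variants with info < 0.4 (when info is present) or MAF < 1%.

    Both thresholds match the post-imputation exclusion rule; boundary
    values (info = 0.4, MAF = 0.01) are kept.
    """
    cfg = cfg or ThresholdConfig()
    maf = np.minimum(stats["eaf"].to_numpy(dtype=float),
                     1.0 - stats["eaf"].to_numpy(dtype=float))
    keep = maf >= cfg.maf_min
    if "info" in stats.columns:
        info = stats["info"].to_numpy(dtype=float)
        keep &= np.isnan(info) | (info >= cfg.info_keep_min)
    return stats.loc[keep].reset_index(drop=True)


def _consequences(stats: pd.DataFrame, annot: AnnotationTable | None) -> np.ndarray:
    if "consequence" in stats.columns:
        return stats["consequence"].to_numpy(dtype=object)
    if annot is None:
        return np.full(len(stats), "other", dtype=object)
    from .core import variant_key
    out = np.empty(len(stats), dtype=object)
    for i, r in enumerate(stats.itertuples()):
        rec = None
        if {"alleleA", "alleleB"}.issubset(stats.columns):
            rec = annot.get(variant_key(str(r.chrom), int(r.pos), str(r.alleleA), str(r.alleleB)))
        else:
            rec = annot.get(variant_key(str(r.chrom), int(r.pos), "A", "C"))
        out[i] = rec.consequence if rec is not None else "other"
    return out


def select_signals(stats: pd.DataFrame, annot: AnnotationTable | None = None,
                   cfg: ThresholdConfig | None = None) -> dict:
    """Top-signal selection over (filtered) summary statistics.

    Leads: P <= 5e-8 with MAF >= 1%.  Nonsynonymous candidates: P < 1e-4
    and MAF > 0, lying inside a qualifying locus — a window of half-width
    500 kb (half the 1 Mb novelty window) around any variant with
    P <= 5e-7 that is accompanied by at least one *distinct* supporting
    variant with P <= 1e-4 inside the window.  Insensitive to input row
    order; results are per trait when a ``trait`` column is present.
    """
    cfg = cfg or ThresholdConfig()
    stats = stats.copy()
    if "trait" not in stats.columns:
        stats["trait"] = "trait"
    sort_cols = ["trait", "chrom", "pos", "id"]
    stats = stats.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    maf = np.minimum(stats["eaf"].to_numpy(dtype=float),
                     1.0 - stats["eaf"].to_numpy(dtype=float))
    stats["_maf"] = maf
    cons = _consequences(stats, annot)
    stats["_consequence"] = cons
    half = cfg.novelty_window_bp // 2

    leads = stats[(stats["p"] <= cfg.lead_p) & (stats["_maf"] >= cfg.maf_min)]
    candidate_rows = []
    for trait, grp in stats.groupby("trait", sort=True):
        for chrom, sub in grp.groupby("chrom", sort=True):
            pos = sub["pos"].to_numpy(dtype=np.int64)
            p = sub["p"].to_numpy(dtype=float)
            locus_leads = np.flatnonzero(p <= cfg.locus_lead_p)
            qualifying = []
            for li in locus_leads:
                in_win = np.abs(pos - pos[li]) <= half
                support = in_win & (p <= cfg.support_p)
                support[li] = False
                if support.any():
                    qualifying.append(li)
            if not qualifying:
                continue
            is_cand = (sub["_consequence"].to_numpy() == "nonsynonymous") \
                & (p < cfg.support_p) & (sub["_maf"].to_numpy() > 0)
            for i in np.flatnonzero(is_cand):
                if any(abs(pos[i] - pos[li]) <= half for li in qualifying):
                    candidate_rows.append(sub.index[i])
    candidates = stats.loc[sorted(set(candidate_rows))]
    drop = ["_maf", "_consequence"]
    return {
        "leads": leads.drop(columns=drop).reset_index(drop=True),
        "nonsyn_candidates": candidates.drop(columns=drop).reset_index(drop=True),
    }


def annotate_novelty(hits: pd.DataFrame, catalog: pd.DataFrame,
                     cfg: ThresholdConfig | None = None) -> pd.DataFrame:
    """Flag each hit as novel unless a same-trait known signal lies within
    the 1 Mb window centred on it (different-trait entries are ignored)."""
    cfg = cfg or ThresholdConfig()
    half = cfg.novelty_window_bp // 2
    out = hits.copy()
    novel = np.ones(len(out), dtype=bool)
    for i, r in enumerate(out.itertuples()):
        same = catalog[(catalog["trait"] == r.trait) & (catalog["chrom"].astype(str) == str(r.chrom))]
        if len(same) and (np.abs(same["pos"].to_numpy(dtype=np.int64) - int(r.pos)) <= half).any():
            novel[i] = False
    out["novel"] = novel
    return out


def merge_replication(discovery: pd.DataFrame, replication: pd.DataFrame,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Join discovery hits with replication statistics on (id, trait).

    A hit replicates when the replication P is < ``alpha`` and the effect
    direction agrees.
    """
    rep = replication.rename(columns={"beta": "beta_rep", "se": "se_rep", "p": "p_rep"})
    cols = [c for c in ("id", "trait", "beta_rep", "se_rep", "p_rep") if c in rep.columns]
    merged = discovery.merge(rep[cols], on=[c for c in ("id", "trait") if c in discovery.columns],
                             how="left")
    merged["replicated"] = (
        (merged["p_rep"] < alpha)
        & (np.sign(merged["beta_rep"]) == np.sign(merged["beta"]))
    ).fillna(False)
    return merged
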