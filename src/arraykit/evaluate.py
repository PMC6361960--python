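"""Array evaluation: imputation, info scores, coverage, concordance.

Imputation is a minimal Li–Stephens haplotype-copying HMM: each phased
target haplotype is modelled as a mosaic of reference haplotypes, switching
with probability ``1 - exp(-rho_per_bp * distance)`` between adjacent sites
and copying the reference allele with miscopy probability ``eps``.
Forward–backward posteriors over the copied haplotype give an
alternate-allele posterior at every reference site; the two haploid
processes of a diploid target are independent given phase, and their
convolution yields the genotype posterior triple.

Imputation quality is summarised by the IMPUTE-class info score — the ratio
of observed dosage variance to its binomial expectation — and genomic
coverage is the fraction of reference variants (MAF >= 1%) captured either
by direct genotyping or at info >= 0.8 through imputation, overall, by MAF
stratum, and in 5 Mb windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    AnnotationTable,
    ArrayManifest,
    GenotypeMatrix,
    HaplotypePanel,
    PosteriorMatrix,
    ThresholdConfig,
    VariantRecord,
)

__all__ = [
    "ls_impute",
    "info_score",
    "info_scores",
    "CoverageReport",
    "genomic_coverage",
    "ConcordanceReport",
    "concordance",
    "shared_content",
    "count_nonsyn",
]


def _haploid_posteriors(ref_H: np.ndarray, positions: np.ndarray,
                        typed_cols: np.ndarray, obs: np.ndarray,
                        rho_per_bp: float, eps: float) -> np.ndarray:
    """Allele posteriors for a batch of target haplotypes.

    ref_H: (K, L) reference alleles; obs: (B, T) observed target alleles at
    ``typed_cols``.  Returns (B, L) posterior P(copied allele = 1),
    marginalising the copying path by forward–backward over all L sites
    (per-site transitions compose exactly to the typed-to-typed ones).
    """
    K, L = ref_H.shape
    B, T = obs.shape
    r = 1.0 - np.exp(-rho_per_bp * np.diff(positions).astype(float))
    is_typed = np.full(L, -1, dtype=np.int64)
    is_typed[typed_cols] = np.arange(T)

    Hf = ref_H.astype(np.float64)

    def emission(site: int) -> np.ndarray | None:
        t = is_typed[site]
        if t < 0:
            return None
        o = obs[:, t]  # (B,)
        match = Hf[:, site][None, :] == o[:, None]  # (B, K)
        return np.where(match, 1.0 - eps, eps)

    alphas = np.empty((L, B, K))
    a = np.full((B, K), 1.0 / K)
    e = emission(0)
    if e is not None:
        a = a * e
    a /= a.sum(axis=1, keepdims=True)
    alphas[0] = a
    for i in range(1, L):
        a = (1.0 - r[i - 1]) * a + r[i - 1] * a.sum(axis=1, keepdims=True) / K
        e = emission(i)
        if e is not None:
            a = a * e
        a /= a.sum(axis=1, keepdims=True)
        alphas[i] = a

    out = np.empty((B, L))
    b = np.full((B, K), 1.0)
    g = alphas[L - 1] * b
    g /= g.sum(axis=1, keepdims=True)
    out[:, L - 1] = g @ Hf[:, L - 1]
    for i in range(L - 2, -1, -1):
        e = emission(i + 1)
        m = b if e is None else b * e
        b = (1.0 - r[i]) * m + r[i] * m.sum(axis=1, keepdims=True) / K
        b /= b.sum(axis=1, keepdims=True)
        g = alphas[i] * b
        g /= g.sum(axis=1, keepdims=True)
        out[:, i] = g @ Hf[:, i]
    return out


def ls_impute(
    ref: HaplotypePanel,
    typed: HaplotypePanel,
    rho_per_bp: float = 1e-6,
    eps: float = 1e-3,
    chunk: int = 8,
) -> PosteriorMatrix:
    """Impute all reference variants for phased target haplotypes.

    ``typed`` carries the targets' phased haplotypes at the genotyped
    (manifest) variants, which must be a subset of the reference variants.
    Unphased targets are out of scope: pass a HaplotypePanel, not hard
    calls.  Returns genotype posterior triples at every reference variant.
    """
    if isinstance(typed, GenotypeMatrix):
        raise TypeError("ls_impute requires phased target haplotypes (HaplotypePanel), "
                        "not hard calls; unphased targets are unsupported")
    if rho_per_bp <= 0:
        raise ValueError(f"rho_per_bp must be positive, got {rho_per_bp}")
    if not (0.0 < eps < 0.5):
        raise ValueError(f"eps must be in (0, 0.5), got {eps}")
    if ref.n_haplotypes < 2:
        raise ValueError("reference panel needs at least 2 haplotypes")
    ref_idx = ref.variant_index()
    missing = [v.id for v in typed.variants if v.key not in ref_idx]
    if missing:
        raise ValueError(f"typed variants not in reference panel: {missing[:3]}")
    typed_cols = np.array([ref_idx[v.key] for v in typed.variants], dtype=np.int64)
    order = np.argsort(typed_cols)
    typed_cols = typed_cols[order]

    obs_all = typed.haplotypes[:, order]  # (2*n_samples, T)
    n_hap = obs_all.shape[0]
    allele_post = np.empty((n_hap, ref.n_variants))
    for start in range(0, n_hap, chunk):
        sl = slice(start, min(start + chunk, n_hap))
        allele_post[sl] = _haploid_posteriors(
            ref.haplotypes, ref.positions, typed_cols, obs_all[sl],
            rho_per_bp, eps,
        )

    a1 = allele_post[0::2, :]
    a2 = allele_post[1::2, :]
    probs = np.empty((typed.n_samples, ref.n_variants, 3))
    probs[:, :, 0] = (1.0 - a1) * (1.0 - a2)
    probs[:, :, 2] = a1 * a2
    probs[:, :, 1] = 1.0 - probs[:, :, 0] - probs[:, :, 2]
    np.clip(probs, 0.0, 1.0, out=probs)
    probs /= probs.sum(axis=2, keepdims=True)
    return PosteriorMatrix(variants=list(ref.variants), sample_ids=list(typed.sample_ids),
                           probs=probs)


def info_scores(post: PosteriorMatrix) -> np.ndarray:
    """IMPUTE-style info score per variant.

    With per-sample dosage moments e_i = p1 + 2 p2 and f_i = p1 + 4 p2 and
    estimated frequency theta = sum(e) / 2N:
    info = 1 - sum(f - e^2) / (2N theta (1 - theta)), and 1 by convention
    when theta is 0 or 1.  Values are unclamped (can be negative).
    """
    p = post.probs
    e = p[:, :, 1] + 2.0 * p[:, :, 2]
    f = p[:, :, 1] + 4.0 * p[:, :, 2]
    n = p.shape[0]
    theta = e.sum(axis=0) / (2.0 * n)
    num = (f - e * e).sum(axis=0)
    out = np.ones(p.shape[1])
    inner = (theta > 0) & (theta < 1)
    out[inner] = 1.0 - num[inner] / (2.0 * n * theta[inner] * (1.0 - theta[inner]))
    return out


def info_score(post: PosteriorMatrix, variant: int | VariantRecord) -> float:
    """Info score for a single variant (by column index or record)."""
    if isinstance(variant, VariantRecord):
        j = post.variants.index(variant)
    else:
        j = int(variant)
    if post.probs.shape[0] < 1:
        raise ValueError("info_score needs at least one sample")
    return float(info_scores(post)[j])


@dataclass
class CoverageReport:
    """Imputation-based genomic coverage, overall / by stratum / by 5 Mb window."""

    overall: float
    by_stratum: dict
    by_window: pd.DataFrame  # chrom, window_start, n_variants, coverage
    n_reference: int
    n_covered: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"stratum": "total", "coverage": self.overall, "n": self.n_reference}]
        for name, (frac, n) in self.by_stratum.items():
            rows.append({"stratum": name, "coverage": frac, "n": n})
        return pd.DataFrame(rows)


def genomic_coverage(
    infos: np.ndarray,
    variants: list,
    mafs: np.ndarray,
    manifest: ArrayManifest,
    cfg: ThresholdConfig | None = None,
) -> CoverageReport:
    """Fraction of reference variants captured directly or by imputation.

    The denominator is reference variants with MAF >= ``maf_min``; a variant
    counts as covered when it is on the manifest (typed; info taken as 1) or
    its info score is >= ``info_coverage_min``.  Strata: common (MAF >= 5%)
    and low-frequency (1–5%).  Windows are half-open 5 Mb bins from
    position 1 per chromosome.
    """
    cfg = cfg or ThresholdConfig()
    infos = np.asarray(infos, dtype=float)
    mafs = np.asarray(mafs, dtype=float)
    if not (len(variants) == infos.size == mafs.size):
        raise ValueError("infos, variants and mafs must align")
    denom = mafs >= cfg.maf_min
    if not denom.any():
        raise ValueError("genomic_coverage: empty denominator (no reference variants at MAF >= maf_min)")
    typed = np.array([v.key in manifest for v in variants])
    eff_info = np.where(typed, 1.0, infos)
    covered = typed | (eff_info >= cfg.info_coverage_min)

    overall = covered[denom].mean()
    common = denom & (mafs >= 0.05)
    low = denom & (mafs < 0.05)
    by_stratum = {
        "common": (float(covered[common].mean()) if common.any() else float("nan"), int(common.sum())),
        "low_frequency": (float(covered[low].mean()) if low.any() else float("nan"), int(low.sum())),
    }

    w = cfg.coverage_window_bp
    rows = []
    keys = [(v.chrom, (v.pos - 1) // w) for v in variants]
    df = pd.DataFrame({"key": keys, "covered": covered, "denom": denom})
    for (chrom, widx), grp in df[df["denom"]].groupby("key", sort=True):
        rows.append({"chrom": chrom, "window_start": widx * w + 1,
                     "n_variants": len(grp), "coverage": float(grp["covered"].mean())})
    return CoverageReport(
        overall=float(overall),
        by_stratum=by_stratum,
        by_window=pd.DataFrame(rows, columns=["chrom", "window_start", "n_variants", "coverage"]),
        n_reference=int(denom.sum()),
        n_covered=int(covered[denom].sum()),
    )


@dataclass
class ConcordanceReport:
    """Genotype concordance between two platforms over shared content."""

    n_compared: int
    n_concordant: int
    per_variant: pd.DataFrame  # id, chrom, pos, n_compared, n_concordant, rate

    @property
    def rate(self) -> float:
        return self.n_concordant / self.n_compared


def concordance(
    genoA: GenotypeMatrix,
    genoB: GenotypeMatrix,
    het_only: bool = False,
    sample_map: dict | None = None,
) -> ConcordanceReport:
    """Fraction of identical calls over shared (variant, sample) pairs.

    ``sample_map`` maps A-side sample ids to B-side ids (defaults to shared
    ids — use it for blind duplicates).  Pairs with a missing call on either
    side are excluded from both counts; ``het_only`` keeps only pairs whose
    B-side (reference) call is heterozygous.
    """
    if sample_map is None:
        shared = set(genoB.sample_ids)
        sample_map = {s: s for s in genoA.sample_ids if s in shared}
    if not sample_map:
        raise ValueError("concordance: no mapped samples")
    ia = [genoA.sample_ids.index(a) for a in sample_map]
    ib = [genoB.sample_ids.index(b) for b in sample_map.values()]
    idxB = genoB.variant_index()
    rows = []
    total_cmp = 0
    total_conc = 0
    for i, v in enumerate(genoA.variants):
        if v.key not in idxB:
            continue
        j = idxB[v.key]
        a = genoA.calls[ia, i]
        b = genoB.calls[ib, j]
        ok = (a != MISSING) & (b != MISSING)
        if het_only:
            ok &= b == 1
        n_cmp = int(ok.sum())
        n_conc = int((a[ok] == b[ok]).sum())
        total_cmp += n_cmp
        total_conc += n_conc
        rows.append({"id": v.id, "chrom": v.chrom, "pos": v.pos,
                     "n_compared": n_cmp, "n_concordant": n_conc,
                     "rate": n_conc / n_cmp if n_cmp else float("nan")})
    if total_cmp == 0:
        raise ValueError("concordance: zero comparable pairs")
    return ConcordanceReport(n_compared=total_cmp, n_concordant=total_conc,
                             per_variant=pd.DataFrame(rows))


def shared_content(manifestA: ArrayManifest, manifestB: ArrayManifest) -> tuple[int, list]:
    """Markers present on both arrays: identical (chrom, pos, unordered alleles)."""
    keysB = manifestB.keys()
    matches = [(manifestA.get(k).variant, manifestB.get(k).variant)
               for k in sorted(manifestA.keys() & keysB, key=lambda k: (k[0], k[1]))]
    return len(matches), matches


def count_nonsyn(
    manifest: ArrayManifest,
    annot: AnnotationTable,
    pop: str,
    rule: str = "any_predictor",
) -> dict:
    """Count nonsynonymous manifest content, total and population-observed damaging.

    The second count additionally requires ``pop`` MAF > 0 and the damaging
    rule: ``any_predictor`` (>= 1 damaging flag) or ``more_than_one``
    (>= 2 flags).
    """
    if rule not in ("any_predictor", "more_than_one"):
        raise ValueError(f"unknown rule {rule!r}")
    if pop not in annot.populations():
        raise ValueError(f"unknown population {pop!r}; known: {sorted(annot.populations())}")
    need = 1 if rule == "any_predictor" else 2
    n_nonsyn = 0
    n_damaging = 0
    for e in manifest:
        rec = annot.get(e.variant.key)
        if rec is None or rec.consequence != "nonsynonymous":
            continue
        n_nonsyn += 1
        if rec.pop_maf.get(pop, 0.0) > 0.0 and rec.n_damaging >= need:
            n_damaging += 1
    return {"nonsyn": n_nonsyn, "nonsyn_pop_observed_damaging": n_damaging}
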