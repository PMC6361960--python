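"""Variant-level QC and the validation filters that gate array content.

Candidates reach the array only if they genotype reliably: the screen
compares screening-platform calls against truth-platform calls (dosage r^2
and a cross-platform Fst acting as a batch-effect detector), and standard
variant QC removes low call rate, Hardy–Weinberg failures and rare content
(by MAF, or by MAC on exome-style content).  Strand-ambiguous A/T and C/G
variants are excluded unless an explicit exception applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .core import (
    MISSING,
    AnnotationRecord,
    GenotypeMatrix,
    ThresholdConfig,
    VariantRecord,
)

__all__ = [
    "hwe_exact_test",
    "qc_filter",
    "QCReport",
    "dosage_r2",
    "platform_fst",
    "fst_nei",
    "validate_variants",
    "ValidationReport",
    "ambiguity_policy",
]

# Above this many diploids the exact-integer path gives way to log-gamma
# arithmetic; 32 keeps integer weights small and the exhaustive regime exact.
_EXACT_N_MAX = 32


def hwe_exact_test(nAA: int, nAa: int, naa: int) -> float:
    """Exact conditional Hardy–Weinberg test.

    Returns the probability, under the exact conditional distribution of the
    heterozygote count given the allele totals, of all configurations no more
    probable than the observed one (plain exact test; no mid-p correction).
    """
    for c in (nAA, nAa, naa):
        if c < 0:
            raise ValueError(f"genotype counts must be non-negative, got ({nAA}, {nAa}, {naa})")
    n = nAA + nAa + naa
    if n == 0:
        raise ValueError("total genotype count must be positive")
    n_minor = min(2 * nAA + nAa, 2 * naa + nAa)
    if n_minor == 0:
        return 1.0  # monomorphic: single attainable configuration
    ks = np.arange(n_minor % 2, n_minor + 1, 2)

    if n <= _EXACT_N_MAX:
        weights = []
        for k in ks:
            hom_minor = (n_minor - k) // 2
            hom_major = n - k - hom_minor
            w = (math.factorial(n) // (math.factorial(hom_minor) * math.factorial(int(k))
                                       * math.factorial(hom_major))) * (1 << int(k))
            weights.append(w)
        total = sum(weights)
        w_obs = weights[list(ks).index(nAa)]
        p_num = sum(w for w in weights if w <= w_obs)
        return p_num / total

    hom_minor = (n_minor - ks) // 2
    hom_major = n - ks - hom_minor
    logw = (gammaln(n + 1) - gammaln(hom_minor + 1) - gammaln(ks + 1)
            - gammaln(hom_major + 1) + ks * math.log(2.0))
    log_total = logsumexp(logw)
    logw_obs = logw[np.searchsorted(ks, nAa)]
    keep = logw <= logw_obs + 1e-9
    return float(np.exp(logsumexp(logw[keep]) - log_total))


@dataclass
class QCReport:
    """Per-variant QC metrics and pass/fail with reasons."""

    table: pd.DataFrame  # columns: id, chrom, pos, call_rate, hwe_p, maf, mac, pass, fail_reasons

    @property
    def n_kept(self) -> int:
        return int(self.table["pass"].sum())

    @property
    def n_removed(self) -> int:
        return len(self.table) - self.n_kept

    def kept_indices(self) -> np.ndarray:
        return np.flatnonzero(self.table["pass"].to_numpy())


def qc_filter(geno: GenotypeMatrix, cfg: ThresholdConfig | None = None,
              use_mac: bool = False) -> QCReport:
    """Variant QC: call rate, exact HWE, and MAF (or MAC for exome content).

    A variant is removed iff ``call_rate < callrate_min``, ``hwe_p <
    hwe_p_min``, or the frequency rule fails (``mac < mac_min`` when
    ``use_mac``, else ``maf < maf_min``); every violated rule is listed.
    """
    cfg = cfg or ThresholdConfig()
    if geno.n_variants == 0 or geno.n_samples == 0:
        raise ValueError("qc_filter: empty genotype matrix")
    call_rate = geno.call_rate()
    maf = geno.maf()
    mac = geno.mac()
    rows = []
    for j, v in enumerate(geno.variants):
        n0, n1, n2 = geno.genotype_counts(j)
        hwe_p = hwe_exact_test(n0, n1, n2) if (n0 + n1 + n2) > 0 else 1.0
        reasons = []
        if call_rate[j] < cfg.callrate_min:
            reasons.append("call_rate")
        if hwe_p < cfg.hwe_p_min:
            reasons.append("hwe")
        if use_mac:
            if mac[j] < cfg.mac_min:
                reasons.append("mac")
        else:
            maf_j = 0.0 if np.isnan(maf[j]) else maf[j]
            if maf_j < cfg.maf_min:
                reasons.append("maf")
        rows.append({
            "id": v.id, "chrom": v.chrom, "pos": v.pos,
            "call_rate": call_rate[j], "hwe_p": hwe_p,
            "maf": maf[j], "mac": int(mac[j]),
            "pass": not reasons, "fail_reasons": ";".join(reasons),
        })
    return QCReport(table=pd.DataFrame(rows))


def dosage_r2(dosages: np.ndarray, truth: np.ndarray) -> float:
    """Squared Pearson correlation between dosages in [0, 2] and true calls.

    Pairs with missing truth (sentinel or NaN) are excluded.  Sign-blind:
    a perfectly anti-correlated pair scores 1.0.
    """
    dosages = np.asarray(dosages, dtype=float)
    truth_arr = np.asarray(truth, dtype=float)
    if dosages.shape != truth_arr.shape:
        raise ValueError("dosage and truth vectors must have equal length")
    ok = ~np.isnan(dosages) & ~np.isnan(truth_arr) & (truth_arr != MISSING)
    d, t = dosages[ok], truth_arr[ok]
    if d.size < 2:
        raise ValueError("need at least 2 non-missing pairs")
    if np.ptp(d) == 0 or np.ptp(t) == 0:
        raise ValueError("undefined correlation: constant vector")
    r = np.corrcoef(d, t)[0, 1]
    return float(r * r)


def fst_nei(pA: np.ndarray, pB: np.ndarray) -> np.ndarray:
    """Nei-style Fst from two allele frequencies: (HT - HS) / HT, 0 when HT = 0."""
    pA = np.asarray(pA, dtype=float)
    pB = np.asarray(pB, dtype=float)
    hs = 0.5 * (2 * pA * (1 - pA) + 2 * pB * (1 - pB))
    pbar = 0.5 * (pA + pB)
    ht = 2 * pbar * (1 - pbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(ht > 0, (ht - hs) / np.where(ht > 0, ht, 1.0), 0.0)
    return fst


def _fst_weir_cockerham(pA, pB, nA, nB):
    """Weir–Cockerham theta for two populations from frequencies and sizes."""
    pA, pB = np.asarray(pA, float), np.asarray(pB, float)
    nA, nB = np.asarray(nA, float), np.asarray(nB, float)
    r = 2.0
    n_bar = (nA + nB) / r
    nc = (nA + nB - (nA ** 2 + nB ** 2) / (nA + nB)) / (r - 1)
    p_bar = (nA * pA + nB * pB) / (nA + nB)
    s2 = (nA * (pA - p_bar) ** 2 + nB * (pB - p_bar) ** 2) / ((r - 1) * n_bar)
    a = (n_bar / nc) * (s2 - (p_bar * (1 - p_bar) - (r - 1) / r * s2) / (n_bar - 1))
    total = a + (p_bar * (1 - p_bar) - (r - 1) / r * s2)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(total != 0, a / np.where(total != 0, total, 1.0), 0.0)


def platform_fst(genoA: GenotypeMatrix, genoB: GenotypeMatrix,
                 estimator: str = "nei") -> pd.DataFrame:
    """Per-variant Fst between two call sets treated as two populations.

    Variants are matched on (chrom, pos, unordered allele pair); frequencies
    use non-missing denominators on each side.  Symmetric in its arguments.
    """
    idxB = genoB.variant_index()
    shared = [(i, idxB[v.key]) for i, v in enumerate(genoA.variants) if v.key in idxB]
    if not shared:
        raise ValueError("platform_fst: no shared variants between the two call sets")
    ia = [s[0] for s in shared]
    ib = [s[1] for s in shared]
    pA = genoA.frequencies()[ia]
    pB = genoB.frequencies()[ib]
    if estimator == "nei":
        fst = fst_nei(pA, pB)
    elif estimator == "weir-cockerham":
        nA = (genoA.calls[:, ia] != MISSING).sum(axis=0)
        nB = (genoB.calls[:, ib] != MISSING).sum(axis=0)
        fst = _fst_weir_cockerham(pA, pB, nA, nB)
    else:
        raise ValueError(f"unknown Fst estimator {estimator!r}")
    rows = []
    for (i, _), f in zip(shared, fst):
        v = genoA.variants[i]
        rows.append({"id": v.id, "chrom": v.chrom, "pos": v.pos,
                     "alleleA": v.alleleA, "alleleB": v.alleleB, "fst": float(f)})
    return pd.DataFrame(rows)


@dataclass
class ValidationReport:
    """Per-variant dosage r^2 / Fst validation outcome."""

    table: pd.DataFrame  # columns: id, chrom, pos, alleleA, alleleB, dosage_r2, fst, validated

    def validated_keys(self) -> set:
        from .core import variant_key
        t = self.table[self.table["validated"]]
        return {variant_key(r.chrom, r.pos, r.alleleA, r.alleleB) for r in t.itertuples()}


def validate_variants(screen_geno: GenotypeMatrix, truth_geno: GenotypeMatrix,
                      cfg: ThresholdConfig | None = None) -> ValidationReport:
    """Validate screening-platform variants against a truth platform.

    A variant validates iff its dosage r^2 (screen hard calls as dosages vs
    truth calls, same samples) is >= ``dosage_r2_min`` and its
    cross-platform Fst is <= ``fst_max`` — both thresholds inclusive.
    Variants whose r^2 is undefined (constant calls) do not validate.
    """
    cfg = cfg or ThresholdConfig()
    shared_samples = [s for s in screen_geno.sample_ids if s in set(truth_geno.sample_ids)]
    if not shared_samples:
        raise ValueError("validate_variants: screening and truth sample sets are disjoint")
    sa = [screen_geno.sample_ids.index(s) for s in shared_samples]
    sb = [truth_geno.sample_ids.index(s) for s in shared_samples]

    idxB = truth_geno.variant_index()
    fst_df = platform_fst(screen_geno, truth_geno, estimator=cfg.fst_estimator)
    fst_map = {(r.chrom, r.pos, tuple(sorted((r.alleleA, r.alleleB)))): r.fst
               for r in fst_df.itertuples()}
    rows = []
    for i, v in enumerate(screen_geno.variants):
        if v.key not in idxB:
            continue
        j = idxB[v.key]
        s_calls = screen_geno.calls[sa, i].astype(float)
        t_calls = truth_geno.calls[sb, j].astype(float)
        ok = (s_calls != MISSING) & (t_calls != MISSING)
        try:
            r2 = dosage_r2(s_calls[ok], t_calls[ok])
        except ValueError:
            r2 = np.nan
        fst = fst_map[v.key]
        validated = bool(r2 >= cfg.dosage_r2_min) and bool(fst <= cfg.fst_max) \
            if not np.isnan(r2) else False
        rows.append({"id": v.id, "chrom": v.chrom, "pos": v.pos,
                     "alleleA": v.alleleA, "alleleB": v.alleleB,
                     "dosage_r2": r2, "fst": fst, "validated": validated})
    return ValidationReport(table=pd.DataFrame(rows))


def ambiguity_policy(
    variant: VariantRecord,
    candidate_categories: set[str],
    annot: AnnotationRecord | None = None,
    indispensable_tag: bool = False,
    cfg: ThresholdConfig | None = None,
    design_pop: str = "KOR",
) -> bool:
    """Decide whether a (possibly strand-ambiguous) variant may go on the array.

    Non-ambiguous allele pairs always pass.  A/T and C/G variants pass only
    as indispensable tags, as nonsynonymous variants with design-population
    MAF >= 0.1%, or as members of an interest list.
    """
    if not variant.is_ambiguous:
        return True
    cfg = cfg or ThresholdConfig()
    if indispensable_tag:
        return True
    if any(c.startswith("interest:") for c in candidate_categories):
        return True
    if annot is not None and annot.consequence == "nonsynonymous":
        maf = annot.pop_maf.get(design_pop)
        if maf is not None and maf >= cfg.func_maf_common:
            return True
    return False
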