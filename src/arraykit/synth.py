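"""Synthetic panels, platform genotypes, annotations and phenotypes.

The generators emulate the statistical structure the pipeline assumes, so
every downstream stage is testable without external data:

* ``simulate_panel`` — a phased haplotype panel with block LD, built as
  founder mosaics: founder haplotypes carry exact allele counts drawn from a
  requested MAF spectrum, and each output haplotype copies from a random
  founder, switching founders along the chromosome with a per-bp
  probability.  Low switch rates give long shared blocks and strong local
  r^2; LD decays with distance, which is all tag selection, imputation and
  coverage estimation need.
* ``diverge_populations`` — a one-parameter Balding–Nichols drift of the
  per-variant frequencies, used to manufacture platform/population frequency
  shifts for the Fst screen.
* ``simulate_genotyping`` — hard calls from haplotype-pair sums with
  independent symmetric genotyping error and missingness, including blind
  duplicate samples that share a truth but draw errors independently.
* ``simulate_phenotypes`` — additive quantitative traits: a sum of planted
  per-allele effects, covariate terms and Gaussian noise, matching the
  additive association model used for analysis.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    AnnotationRecord,
    AnnotationTable,
    GenotypeMatrix,
    HaplotypePanel,
    VariantRecord,
)

__all__ = [
    "SimConfig",
    "simulate_panel",
    "diverge_populations",
    "simulate_genotyping",
    "simulate_phenotypes",
    "simulate_annotations",
    "make_covariates",
]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the founder-mosaic panel generator.

    ``maf_spectrum`` is ``("uniform", lo, hi)`` or ``("beta", a, b)`` (the
    beta is rescaled onto (0, 0.5]); founder frequencies are drawn from it
    and alternate alleles are minor by construction.  ``switch_rate`` is the
    per-bp probability that a mosaic haplotype switches to a fresh random
    founder; its default of 1e-5 gives ~100 kb copying blocks.
    """

    n_founders: int = 100
    n_haplotypes: int = 1000
    n_variants: int = 2000
    region_bp: int = 10_000_000
    switch_rate: float = 1e-5
    maf_spectrum: tuple = ("uniform", 0.01, 0.5)
    chrom: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_founders < 2:
            raise ValueError("n_founders must be >= 2")
        if not (0.0 < self.switch_rate < 1.0):
            raise ValueError("switch_rate must be in (0, 1)")
        if self.n_haplotypes < 2 or self.n_haplotypes % 2:
            raise ValueError("n_haplotypes must be even and >= 2")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if self.n_variants > self.region_bp:
            raise ValueError("n_variants cannot exceed region_bp (positions must be distinct)")


def _draw_spectrum(spec: tuple, n: int, rng: np.random.Generator) -> np.ndarray:
    kind = spec[0]
    if kind == "uniform":
        _, lo, hi = spec
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError("uniform MAF spectrum needs 0 < lo < hi <= 0.5")
        return rng.uniform(lo, hi, size=n)
    if kind == "beta":
        _, a, b = spec
        return 0.5 * rng.beta(a, b, size=n)
    raise ValueError(f"unknown MAF spectrum kind {kind!r}")


def simulate_panel(cfg: SimConfig) -> HaplotypePanel:
    """Generate a phased panel of founder-mosaic haplotypes.

    Founder haplotypes carry exactly ``round(p * n_founders)`` (at least 1)
    copies of the alternate allele at each site, so the realized frequency
    spectrum tracks the requested one; output haplotypes are founder mosaics
    with per-bp switch probability ``cfg.switch_rate``.
    """
    rng = np.random.default_rng(cfg.seed)
    F, H, V = cfg.n_founders, cfg.n_haplotypes, cfg.n_variants

    positions = np.sort(rng.choice(cfg.region_bp, size=V, replace=False)) + 1
    p = _draw_spectrum(cfg.maf_spectrum, V, rng)
    k = np.clip(np.rint(p * F).astype(int), 1, F - 1)

    # Founder matrix with exact per-column carrier counts.  Carriers are a
    # random contiguous arc of a fixed circular founder ordering, so founder
    # haplotypes themselves carry LD (overlapping arcs -> correlated sites);
    # the mosaic then attenuates it with distance via founder switching.
    starts = rng.integers(0, F, size=V)
    founders = (((np.arange(F)[:, None] - starts[None, :]) % F) < k[None, :]).astype(np.int8)

    gaps = np.diff(positions)
    r_gap = 1.0 - np.power(1.0 - cfg.switch_rate, gaps)
    switch = np.empty((H, V), dtype=bool)
    switch[:, 0] = True
    switch[:, 1:] = rng.random((H, V - 1)) < r_gap[None, :]
    draws = rng.integers(0, F, size=(H, V))
    col_idx = np.arange(V)
    last_switch = np.maximum.accumulate(np.where(switch, col_idx[None, :], 0), axis=1)
    founder_path = draws[np.arange(H)[:, None], last_switch]
    haplotypes = founders[founder_path, col_idx[None, :]]

    bases = np.array(list("ACGT"))
    ref_idx = rng.integers(0, 4, size=V)
    alt_idx = (ref_idx + rng.integers(1, 4, size=V)) % 4
    variants = [
        VariantRecord(id=f"var{i:06d}", chrom=cfg.chrom, pos=int(positions[i]),
                      alleleA=str(bases[ref_idx[i]]), alleleB=str(bases[alt_idx[i]]))
        for i in range(V)
    ]
    sample_ids = [f"S{i:05d}" for i in range(H // 2)]
    return HaplotypePanel(variants=variants, sample_ids=sample_ids, haplotypes=haplotypes)


def diverge_populations(panel: HaplotypePanel, F: float, seed: int = 0) -> HaplotypePanel:
    """Drift panel frequencies with a Balding–Nichols model of strength ``F``.

    Per variant, a derived-population frequency is drawn from
    ``Beta(p(1-F)/F, (1-p)(1-F)/F)`` around the source frequency ``p``, and
    haplotypes are resampled site-independently at the drifted frequencies.
    Monomorphic sites stay monomorphic.
    """
    if not (0.0 < F < 1.0):
        raise ValueError(f"drift parameter F must be in (0, 1), got {F}")
    rng = np.random.default_rng(seed)
    p = panel.frequencies()
    scale = (1.0 - F) / F
    poly = (p > 0) & (p < 1)
    drifted = p.copy()
    drifted[poly] = rng.beta(p[poly] * scale, (1.0 - p[poly]) * scale)
    H = panel.n_haplotypes
    haps = (rng.random((H, panel.n_variants)) < drifted[None, :]).astype(np.int8)
    return HaplotypePanel(
        variants=list(panel.variants),
        sample_ids=[f"{s}_pop2" for s in panel.sample_ids],
        haplotypes=haps,
    )


def simulate_genotyping(
    panel: HaplotypePanel,
    sample_ids: Sequence[str] | None = None,
    error_rate: float = 0.0,
    missing_rate: float = 0.0,
    duplicate_of: Mapping[str, str] | None = None,
    seed: int = 0,
) -> GenotypeMatrix:
    """Emulate platform genotyping of panel samples.

    True genotypes are haplotype-pair sums.  Each call is independently set
    missing with ``missing_rate``, otherwise perturbed with ``error_rate`` to
    one of the two wrong genotype states (chosen uniformly — a symmetric
    error model).  ``duplicate_of`` maps an output sample id to the panel
    sample whose truth it re-genotypes (blind duplicates draw their own
    errors and missingness).
    """
    for name, rate in (("error_rate", error_rate), ("missing_rate", missing_rate)):
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"{name} must be in [0, 1), got {rate}")
    duplicate_of = dict(duplicate_of or {})
    panel_idx = {s: i for i, s in enumerate(panel.sample_ids)}
    for dup, src in duplicate_of.items():
        if src not in panel_idx:
            raise ValueError(f"duplicate_of: unknown source sample {src!r}")
    if sample_ids is None:
        sample_ids = list(panel.sample_ids) + sorted(duplicate_of)
    truth_all = panel.haplotypes[0::2, :].astype(np.int8) + panel.haplotypes[1::2, :]

    rows = []
    for s in sample_ids:
        src = duplicate_of.get(s, s)
        if src not in panel_idx:
            raise ValueError(f"sample {s!r} is neither a panel sample nor a declared duplicate")
        rows.append(panel_idx[src])
    truth = truth_all[rows, :]

    rng = np.random.default_rng(seed)
    n_s, n_v = truth.shape
    calls = truth.copy()
    err = rng.random((n_s, n_v)) < error_rate
    # symmetric error: jump to one of the two other genotype states
    shift = rng.integers(1, 3, size=(n_s, n_v))
    calls = np.where(err, (calls + shift) % 3, calls).astype(np.int8)
    miss = rng.random((n_s, n_v)) < missing_rate
    calls[miss] = MISSING
    return GenotypeMatrix(variants=list(panel.variants), sample_ids=list(sample_ids), calls=calls)


def make_covariates(sample_ids: Sequence[str], seed: int = 0, n_areas: int = 3) -> pd.DataFrame:
    """Generate an age/sex/recruitment-area covariate table for a cohort."""
    rng = np.random.default_rng(seed)
    n = len(sample_ids)
    return pd.DataFrame({
        "sample_id": list(sample_ids),
        "age": rng.integers(40, 80, size=n),
        "sex": rng.integers(0, 2, size=n),
        "area": [f"area{j}" for j in rng.integers(0, n_areas, size=n)],
    })


def simulate_phenotypes(
    geno: GenotypeMatrix,
    effects: Mapping[tuple, float],
    covariates: pd.DataFrame | None = None,
    covariate_effects: Mapping[str, float] | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    trait: str = "trait",
) -> pd.DataFrame:
    """Additive quantitative trait: sum of planted effects + covariates + noise.

    ``effects`` maps variant identity keys to per-allele effects; missing
    genotypes contribute their variant's mean dosage.  ``covariate_effects``
    maps numeric covariate columns to coefficients (unlisted columns
    contribute nothing).
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be >= 0, got {noise_sd}")
    vidx = geno.variant_index()
    y = np.zeros(geno.n_samples)
    freqs = geno.frequencies()
    for key, beta in effects.items():
        if key not in vidx:
            raise ValueError(f"effect variant {key} not present in genotype matrix")
        j = vidx[key]
        col = geno.calls[:, j].astype(float)
        mean_dosage = 2.0 * freqs[j]
        col[geno.calls[:, j] == MISSING] = mean_dosage
        y += beta * col
    if covariates is not None and covariate_effects:
        cov = covariates.set_index("sample_id").loc[list(geno.sample_ids)]
        for col_name, coef in covariate_effects.items():
            y += coef * cov[col_name].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    y = y + rng.normal(0.0, noise_sd, size=geno.n_samples)
    return pd.DataFrame({"sample_id": list(geno.sample_ids), trait: y})


def simulate_annotations(
    panel: HaplotypePanel,
    design_pop: str = "KOR",
    other_pops: Sequence[str] = ("EAS", "EUR"),
    frac_nonsyn: float = 0.2,
    frac_synonymous: float = 0.2,
    p_damaging: float = 0.35,
    p_absent: float = 0.1,
    drift_f: float = 0.1,
    seed: int = 0,
) -> AnnotationTable:
    """Annotate a panel's variants with consequences, damaging flags and MAFs.

    The design population's MAF is the panel's realized MAF; other
    populations get Balding–Nichols-drifted frequencies, zeroed with
    probability ``p_absent`` to emulate population-specific variants.
    Damaging flags are independent Bernoulli draws per predictor and are
    always defined for nonsynonymous records.
    """
    rng = np.random.default_rng(seed)
    maf = panel.maf()
    V = panel.n_variants
    u = rng.random(V)
    consequence = np.where(u < frac_nonsyn, "nonsynonymous",
                           np.where(u < frac_nonsyn + frac_synonymous, "synonymous", "other"))
    records = []
    scale = (1.0 - drift_f) / drift_f
    for i, v in enumerate(panel.variants):
        pop_maf = {design_pop: float(maf[i])}
        for pop in other_pops:
            if rng.random() < p_absent or maf[i] == 0.0:
                pop_maf[pop] = 0.0
            else:
                drifted = rng.beta(maf[i] * scale, (1.0 - maf[i]) * scale)
                pop_maf[pop] = float(min(drifted, 1.0 - drifted))
        is_nonsyn = consequence[i] == "nonsynonymous"
        flags = rng.random(3) < p_damaging if is_nonsyn else np.zeros(3, dtype=bool)
        records.append(AnnotationRecord(
            key=v.key,
            consequence=str(consequence[i]),
            sift_damaging=bool(flags[0]),
            polyphen_hdiv_damaging=bool(flags[1]),
            polyphen_hvar_damaging=bool(flags[2]),
            pop_maf=pop_maf,
        ))
    return AnnotationTable(records)
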