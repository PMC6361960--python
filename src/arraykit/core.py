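"""Domain types shared by every pipeline stage.

The toolkit operates on four substrates: a phased haplotype reference panel
(the LD substrate for tagging, imputation and coverage), hard-call genotype
matrices from genotyping platforms, genotype posterior probabilities produced
by imputation, and per-variant functional annotations.  All of them are thin
wrappers around numpy arrays / pandas frames with the invariants the pipeline
relies on checked at construction time.

Variants are identified across platforms by ``(chrom, pos, unordered allele
pair)``: matching requires literally identical positions and alleles, and the
allele pair is compared order-insensitively but strand flips are *not*
reconciled.  Coordinates are 1-based (VCF convention); genomic windows are
half-open ``[start, start + len)`` in bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "MISSING",
    "VariantRecord",
    "HaplotypePanel",
    "GenotypeMatrix",
    "PosteriorMatrix",
    "AnnotationRecord",
    "AnnotationTable",
    "ManifestEntry",
    "ArrayManifest",
    "ThresholdConfig",
    "variant_key",
]

#: Sentinel for a missing hard call.  Distinct from 0 by construction.
MISSING: int = -1

_CATEGORY_BASE = {"tag", "functional"}


def _is_valid_category(label: str) -> bool:
    return label in _CATEGORY_BASE or label.startswith("interest:")


@dataclass(frozen=True)
class VariantRecord:
    """A single variant: identifier, locus, and the two observed alleles.

    ``alleleA`` is the first (reference-side) allele as read from the source
    file and ``alleleB`` the alternate; allele order is preserved as stored
    but ignored for cross-platform identity.
    """

    id: str
    chrom: str
    pos: int
    alleleA: str
    alleleB: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.alleleA == self.alleleB:
            raise ValueError(f"variant {self.id}: alleles must differ, got {self.alleleA}/{self.alleleB}")
        for a in (self.alleleA, self.alleleB):
            if not a or any(c not in "ACGT" for c in a.upper()):
                raise ValueError(f"variant {self.id}: allele {a!r} is not a SNV/indel allele string")

    @property
    def key(self) -> tuple[str, int, tuple[str, str]]:
        """Identity key: (chrom, pos, unordered allele pair)."""
        return (self.chrom, self.pos, tuple(sorted((self.alleleA, self.alleleB))))

    @property
    def is_ambiguous(self) -> bool:
        """True for A/T or C/G variants (strand-ambiguous allele pairs)."""
        pair = frozenset((self.alleleA.upper(), self.alleleB.upper()))
        return pair == frozenset("AT") or pair == frozenset("CG")


def variant_key(chrom: str, pos: int, alleleA: str, alleleB: str) -> tuple[str, int, tuple[str, str]]:
    """Order-insensitive identity key for a variant."""
    return (chrom, int(pos), tuple(sorted((alleleA, alleleB))))


def _check_variants(variants: Sequence[VariantRecord]) -> None:
    seen = set()
    for v in variants:
        if v.key in seen:
            raise ValueError(f"duplicate variant at {v.chrom}:{v.pos} alleles {v.alleleA}/{v.alleleB}")
        seen.add(v.key)


@dataclass
class HaplotypePanel:
    """Phased haplotypes: rows are 2 x n_samples haplotypes, columns variants.

    Entries are 0/1 alternate-allele indicators with no missing data.  The
    panel is the substrate for LD computation, tag selection, haplotype-copying
    imputation, and coverage evaluation.
    """

    variants: list[VariantRecord]
    sample_ids: list[str]
    haplotypes: np.ndarray

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        if self.haplotypes.ndim != 2:
            raise ValueError("haplotypes must be a 2-D matrix")
        n_hap, n_var = self.haplotypes.shape
        if n_var != len(self.variants):
            raise ValueError(f"haplotype columns ({n_var}) != variant count ({len(self.variants)})")
        if n_hap % 2 != 0:
            raise ValueError("haplotype row count must be even (two per sample)")
        if n_hap != 2 * len(self.sample_ids):
            raise ValueError("haplotype rows must equal 2 x sample count")
        bad = (self.haplotypes != 0) & (self.haplotypes != 1)
        if bad.any():
            raise ValueError("haplotype entries must be 0/1 with no missing data")
        _check_variants(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_haplotypes(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_variants(self) -> int:
        return self.haplotypes.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.array([v.pos for v in self.variants], dtype=np.int64)

    def frequencies(self) -> np.ndarray:
        """Per-variant alternate-allele frequency (column mean)."""
        return self.haplotypes.mean(axis=0)

    def maf(self) -> np.ndarray:
        p = self.frequencies()
        return np.minimum(p, 1.0 - p)

    def variant_index(self) -> dict:
        return {v.key: i for i, v in enumerate(self.variants)}

    def subset_variants(self, indices: Sequence[int]) -> "HaplotypePanel":
        idx = list(indices)
        return HaplotypePanel(
            variants=[self.variants[i] for i in idx],
            sample_ids=list(self.sample_ids),
            haplotypes=self.haplotypes[:, idx].copy(),
        )

    def genotypes(self) -> "GenotypeMatrix":
        """Collapse phased haplotypes to hard diploid calls (no missingness)."""
        calls = self.haplotypes[0::2, :].astype(np.int8) + self.haplotypes[1::2, :].astype(np.int8)
        return GenotypeMatrix(variants=list(self.variants), sample_ids=list(self.sample_ids), calls=calls)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, HaplotypePanel):
            return NotImplemented
        return (
            self.variants == other.variants
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.haplotypes, other.haplotypes)
        )


@dataclass
class GenotypeMatrix:
    """Hard calls over {0, 1, 2, missing}: counts of alleleB per sample x variant."""

    variants: list[VariantRecord]
    sample_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2:
            raise ValueError("calls must be a 2-D matrix")
        n_s, n_v = self.calls.shape
        if n_v != len(self.variants):
            raise ValueError(f"call columns ({n_v}) != variant count ({len(self.variants)})")
        if n_s != len(self.sample_ids):
            raise ValueError(f"call rows ({n_s}) != sample count ({len(self.sample_ids)})")
        ok = np.isin(self.calls, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("calls must be 0, 1, 2 or the missing sentinel")
        _check_variants(self.variants)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return self.calls.shape[1]

    def call_rate(self) -> np.ndarray:
        """Per-variant fraction of non-missing calls."""
        return (self.calls != MISSING).mean(axis=0)

    def frequencies(self) -> np.ndarray:
        """Per-variant alleleB frequency over non-missing calls (nan if all missing)."""
        obs = self.calls != MISSING
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, self.calls, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, alt / (2.0 * n_obs), np.nan)

    def maf(self) -> np.ndarray:
        p = self.frequencies()
        return np.minimum(p, 1.0 - p)

    def mac(self) -> np.ndarray:
        """Per-variant minor allele count among non-missing calls."""
        obs = self.calls != MISSING
        n_obs = obs.sum(axis=0)
        alt = np.where(obs, self.calls, 0).sum(axis=0)
        return np.minimum(alt, 2 * n_obs - alt)

    def genotype_counts(self, j: int) -> tuple[int, int, int]:
        """(n_homA, n_het, n_homB) for variant column j, ignoring missing."""
        col = self.calls[:, j]
        return int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())

    def variant_index(self) -> dict:
        return {v.key: i for i, v in enumerate(self.variants)}

    def subset_variants(self, indices: Sequence[int]) -> "GenotypeMatrix":
        idx = list(indices)
        return GenotypeMatrix(
            variants=[self.variants[i] for i in idx],
            sample_ids=list(self.sample_ids),
            calls=self.calls[:, idx].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.variants == other.variants
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class PosteriorMatrix:
    """Imputation posteriors: per sample x variant, a probability triple (p0, p1, p2)."""

    variants: list[VariantRecord]
    sample_ids: list[str]
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.shape != (len(self.sample_ids), len(self.variants), 3):
            raise ValueError("probs must have shape (n_samples, n_variants, 3)")
        if (self.probs < 0).any():
            raise ValueError("posterior probabilities must be non-negative")
        sums = self.probs.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("posterior triples must sum to 1 within 1e-6")

    def dosages(self) -> np.ndarray:
        """Expected alternate-allele count e_i = p1 + 2 p2, per sample x variant."""
        return self.probs[:, :, 1] + 2.0 * self.probs[:, :, 2]

    def hard_calls(self) -> GenotypeMatrix:
        calls = self.probs.argmax(axis=2).astype(np.int8)
        return GenotypeMatrix(variants=list(self.variants), sample_ids=list(self.sample_ids), calls=calls)


@dataclass(frozen=True)
class AnnotationRecord:
    """Functional annotation for one variant.

    ``consequence`` is one of nonsynonymous / synonymous / other; the three
    damaging flags come from SIFT and PolyPhen-2 (HDIV, HVAR) style
    predictors; ``pop_maf`` maps population labels to minor allele
    frequencies in [0, 0.5].
    """

    key: tuple
    consequence: str
    sift_damaging: bool
    polyphen_hdiv_damaging: bool
    polyphen_hvar_damaging: bool
    pop_maf: Mapping[str, float] = field(default_factory=dict)

    _CONSEQUENCES = ("nonsynonymous", "synonymous", "other")

    def __post_init__(self) -> None:
        if self.consequence not in self._CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}; expected one of {self._CONSEQUENCES}")
        for pop, maf in self.pop_maf.items():
            if not (0.0 <= maf <= 0.5):
                raise ValueError(f"pop_maf[{pop!r}] = {maf} outside [0, 0.5]")

    @property
    def n_damaging(self) -> int:
        return int(self.sift_damaging) + int(self.polyphen_hdiv_damaging) + int(self.polyphen_hvar_damaging)

    @property
    def any_damaging(self) -> bool:
        return self.n_damaging >= 1


class AnnotationTable:
    """Lookup table of :class:`AnnotationRecord` keyed by variant identity."""

    def __init__(self, records: Iterable[AnnotationRecord]):
        self._by_key: dict = {}
        for rec in records:
            if rec.key in self._by_key:
                raise ValueError(f"duplicate annotation for variant key {rec.key}")
            self._by_key[rec.key] = rec

    def __len__(self) -> int:
        return len(self._by_key)

    def __contains__(self, key: tuple) -> bool:
        return key in self._by_key

    def __iter__(self):
        return iter(self._by_key.values())

    def get(self, key: tuple) -> AnnotationRecord | None:
        return self._by_key.get(key)

    def __getitem__(self, key: tuple) -> AnnotationRecord:
        try:
            return self._by_key[key]
        except KeyError:
            raise KeyError(f"no annotation for variant key {key}") from None

    def populations(self) -> set[str]:
        pops: set[str] = set()
        for rec in self._by_key.values():
            pops.update(rec.pop_maf)
        return pops


@dataclass
class ManifestEntry:
    """One designed marker with its content categories and selection provenance."""

    variant: VariantRecord
    categories: set[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.categories:
            raise ValueError(f"manifest entry {self.variant.id} has no categories")
        for c in self.categories:
            if not _is_valid_category(c):
                raise ValueError(
                    f"unknown category {c!r}; allowed: 'tag', 'functional', 'interest:<listname>'"
                )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ManifestEntry):
            return NotImplemented
        return (
            self.variant == other.variant
            and self.categories == other.categories
            and self.provenance == other.provenance
        )


class ArrayManifest:
    """The designed marker set.

    A variant appears at most once; its category set may contain several
    labels (tag / functional / interest lists overlap on real arrays), so the
    total marker count is the number of distinct entries, not the sum of the
    per-category counts.
    """

    def __init__(self, entries: Iterable[ManifestEntry] = ()):
        self._entries: list[ManifestEntry] = []
        self._by_key: dict = {}
        for e in entries:
            self.add(e)

    def add(self, entry: ManifestEntry) -> None:
        k = entry.variant.key
        if k in self._by_key:
            raise ValueError(f"variant {entry.variant.id} already in manifest")
        self._by_key[k] = entry
        self._entries.append(entry)

    def merge(self, variant: VariantRecord, categories: set[str], provenance: str) -> None:
        """Add a variant, or extend the categories of an existing entry."""
        k = variant.key
        if k in self._by_key:
            existing = self._by_key[k]
            existing.categories |= set(categories)
            if provenance and provenance not in existing.provenance:
                existing.provenance = (existing.provenance + "; " + provenance).strip("; ")
        else:
            self.add(ManifestEntry(variant=variant, categories=set(categories), provenance=provenance))

    @property
    def entries(self) -> list[ManifestEntry]:
        return list(self._entries)

    def __len__(self) -> int:
        """Total marker count: distinct entries."""
        return len(self._entries)

    def __contains__(self, key: tuple) -> bool:
        return key in self._by_key

    def __iter__(self):
        return iter(self._entries)

    def get(self, key: tuple) -> ManifestEntry | None:
        return self._by_key.get(key)

    def keys(self) -> set:
        return set(self._by_key)

    def category_counts(self) -> dict[str, int]:
        """Marker count per category (categories overlap; sums exceed len)."""
        counts: dict[str, int] = {}
        for e in self._entries:
            for c in e.categories:
                counts[c] = counts.get(c, 0) + 1
        return counts

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ArrayManifest):
            return NotImplemented
        if self.keys() != other.keys():
            return False
        return all(self._by_key[k] == other._by_key[k] for k in self._by_key)


@dataclass(frozen=True)
class ThresholdConfig:
    """Every numeric threshold the pipeline applies, in one place.

    Defaults are the published design/evaluation criteria: variants validate
    at dosage r^2 >= 0.7 and Fst <= 0.025; QC removes call rate < 95%,
    HWE P < 1e-6, MAF < 1% (or MAC < 2 on exome-style content); functional
    content splits at MAF 0.1%; tagging counts a target covered at r^2 >= 0.8
    within a 250 kb window; post-imputation analysis keeps info >= 0.4 and
    coverage counts info >= 0.8 per 5 Mb window; GWAS uses P <= 5e-8 leads,
    P <= 5e-7 locus leads, P <= 1e-4 supporting signals, a 1 Mb centred
    novelty window, and masks Friedewald LDL at TG > 400 mg/dL.
    """

    dosage_r2_min: float = 0.7
    fst_max: float = 0.025
    callrate_min: float = 0.95
    hwe_p_min: float = 1e-6
    maf_min: float = 0.01
    mac_min: int = 2
    func_maf_common: float = 0.001
    tag_r2: float = 0.8
    tag_window_bp: int = 250_000
    info_keep_min: float = 0.4
    info_coverage_min: float = 0.8
    coverage_window_bp: int = 5_000_000
    lead_p: float = 5e-8
    locus_lead_p: float = 5e-7
    support_p: float = 1e-4
    novelty_window_bp: int = 1_000_000
    tg_mask_mgdl: float = 400.0
    fst_estimator: str = "nei"  # or "weir-cockerham"

    def __post_init__(self) -> None:
        unit = [
            ("dosage_r2_min", self.dosage_r2_min),
            ("fst_max", self.fst_max),
            ("callrate_min", self.callrate_min),
            ("maf_min", self.maf_min),
            ("func_maf_common", self.func_maf_common),
            ("tag_r2", self.tag_r2),
            ("info_keep_min", self.info_keep_min),
            ("info_coverage_min", self.info_coverage_min),
        ]
        for name, val in unit:
            if not (0.0 <= val <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        for name, val in [("hwe_p_min", self.hwe_p_min), ("lead_p", self.lead_p),
                          ("locus_lead_p", self.locus_lead_p), ("support_p", self.support_p)]:
            if not (0.0 < val <= 1.0):
                raise ValueError(f"{name} must be in (0, 1], got {val}")
        for name, val in [("tag_window_bp", self.tag_window_bp),
                          ("coverage_window_bp", self.coverage_window_bp),
                          ("novelty_window_bp", self.novelty_window_bp),
                          ("mac_min", self.mac_min)]:
            if val <= 0:
                raise ValueError(f"{name} must be positive, got {val}")
        if self.tg_mask_mgdl <= 0:
            raise ValueError("tg_mask_mgdl must be positive")
        if self.fst_estimator not in ("nei", "weir-cockerham"):
            raise ValueError("fst_estimator must be 'nei' or 'weir-cockerham'")

    def replace(self, **kwargs) -> "ThresholdConfig":
        return replace(self, **kwargs)

    @classmethod
    def field_names(cls) -> list[str]:
        return [f.name for f in fields(cls)]
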