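"""Array content selection.

Tagging content is chosen by a documented greedy maximum-coverage algorithm
over pairwise haplotype r^2: a target variant counts as covered when it is
itself selected or sits within ``tag_window_bp`` of a selected marker at
r^2 >= ``tag_r2``.  Pairwise r^2 lower-bounds achievable imputation r^2, so
this is the standard design proxy for imputation-aware selection.
Functional content admits nonsynonymous variants by frequency (MAF >= 0.1%)
or, below that, by a damaging prediction from any of SIFT / PolyPhen-2 HDIV
/ PolyPhen-2 HVAR.  Assembly intersects everything with the validation
screen and the strand-ambiguity policy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    AnnotationTable,
    ArrayManifest,
    HaplotypePanel,
    ManifestEntry,
    ThresholdConfig,
    VariantRecord,
)
from .screen import ValidationReport, ambiguity_policy

__all__ = [
    "LDIndex",
    "compute_pairwise_r2",
    "TagSelection",
    "greedy_tag_select",
    "indispensable_tags",
    "select_functional",
    "assemble_manifest",
]


@dataclass
class LDIndex:
    """Windowed pairwise-r^2 neighborhood lists over a panel's variants.

    ``neighbors[i]`` holds ``(j, r2)`` for every polymorphic variant j != i
    within the window; the structure is symmetric.
    """

    variants: list
    window_bp: int
    neighbors: dict = field(default_factory=dict)

    def r2(self, i: int, j: int) -> float | None:
        for k, r in self.neighbors.get(i, ()):
            if k == j:
                return r
        return None


def compute_pairwise_r2(panel: HaplotypePanel, window_bp: int) -> LDIndex:
    """All pairwise r^2 within ``window_bp``, from phased haplotype counts.

    r^2 = (pAB - pA pB)^2 / (pA (1-pA) pB (1-pB)); pairs with a monomorphic
    member are omitted.
    """
    if window_bp <= 0:
        raise ValueError(f"window_bp must be positive, got {window_bp}")
    if panel.n_variants == 0:
        raise ValueError("panel has no variants")
    H = panel.haplotypes.astype(np.float64)
    n = H.shape[0]
    p = H.mean(axis=0)
    sd = np.sqrt(p * (1.0 - p))
    poly = sd > 0
    pos = panel.positions
    Z = np.zeros_like(H)
    Z[:, poly] = (H[:, poly] - p[poly]) / sd[poly]

    neighbors: dict[int, list] = {i: [] for i in range(panel.n_variants)}
    hi = 0
    for i in range(panel.n_variants):
        if hi < i + 1:
            hi = i + 1
        while hi < panel.n_variants and pos[hi] - pos[i] < window_bp:
            hi += 1
        if not poly[i] or hi == i + 1:
            continue
        js = np.arange(i + 1, hi)
        js = js[poly[js]]
        if js.size == 0:
            continue
        r = (Z[:, i] @ Z[:, js]) / n
        r2 = r * r
        for j, val in zip(js, r2):
            neighbors[i].append((int(j), float(val)))
            neighbors[int(j)].append((i, float(val)))
    return LDIndex(variants=list(panel.variants), window_bp=window_bp, neighbors=neighbors)


@dataclass
class TagSelection:
    """Result of greedy tag selection."""

    selected: list  # ordered VariantRecords
    covered: set  # variant keys of covered targets
    coverage_trace: list  # (VariantRecord, newly_covered_count) per step
    n_targets: int = 0

    @property
    def coverage(self) -> float:
        return len(self.covered) / self.n_targets if self.n_targets else float("nan")

    def selected_keys(self) -> set:
        return {v.key for v in self.selected}


def _cover_sets(panel: HaplotypePanel, ld: LDIndex, candidate_idx: list[int],
                target_set: set[int], tag_r2: float) -> dict[int, set[int]]:
    covers: dict[int, set[int]] = {}
    for c in candidate_idx:
        cov = {c} if c in target_set else set()
        for j, r2 in ld.neighbors.get(c, ()):
            if j in target_set and r2 >= tag_r2:
                cov.add(j)
        covers[c] = cov
    return covers


def greedy_tag_select(
    panel: HaplotypePanel,
    candidates: set,
    cfg: ThresholdConfig | None = None,
    budget: int | None = None,
    ld: LDIndex | None = None,
) -> TagSelection:
    """Greedy maximum-coverage tag selection.

    Targets are panel variants with MAF >= ``maf_min``.  At each step the
    candidate covering the most currently-uncovered targets is added; ties
    break to the higher-MAF candidate, then to the smaller genomic position.
    Stops at ``budget`` or when no candidate adds coverage.
    """
    cfg = cfg or ThresholdConfig()
    if not candidates:
        raise ValueError("greedy_tag_select: empty candidate set")
    vidx = panel.variant_index()
    missing = [k for k in candidates if k not in vidx]
    if missing:
        raise ValueError(f"candidates not in panel: {missing[:3]}")
    candidate_idx = sorted(vidx[k] for k in candidates)
    maf = panel.maf()
    pos = panel.positions
    target_set = set(np.flatnonzero(maf >= cfg.maf_min).tolist())
    if ld is None:
        ld = compute_pairwise_r2(panel, cfg.tag_window_bp)
    covers = _cover_sets(panel, ld, candidate_idx, target_set, cfg.tag_r2)

    uncovered = set(target_set)
    remaining = set(candidate_idx)
    selected: list[int] = []
    trace: list[tuple] = []
    while remaining and uncovered and (budget is None or len(selected) < budget):
        best, best_gain = None, 0
        for c in remaining:
            gain = len(covers[c] & uncovered)
            if gain > best_gain:
                best, best_gain = c, gain
            elif gain == best_gain and gain > 0 and best is not None:
                if (maf[c], -pos[c]) > (maf[best], -pos[best]):
                    best = c
        if best is None or best_gain == 0:
            break
        newly = covers[best] & uncovered
        uncovered -= newly
        remaining.discard(best)
        selected.append(best)
        trace.append((panel.variants[best], len(newly)))

    covered_idx = target_set - uncovered
    return TagSelection(
        selected=[panel.variants[i] for i in selected],
        covered={panel.variants[i].key for i in covered_idx},
        coverage_trace=trace,
        n_targets=len(target_set),
    )


def indispensable_tags(
    panel: HaplotypePanel,
    selection: TagSelection,
    candidates: set,
    cfg: ThresholdConfig | None = None,
    ld: LDIndex | None = None,
) -> set:
    """Keys of selected tags whose removal would strand some covered target.

    A tag is indispensable iff it covers a target for which no other
    candidate reaches r^2 >= ``tag_r2`` (and the target is not itself
    another candidate).
    """
    cfg = cfg or ThresholdConfig()
    vidx = panel.variant_index()
    maf = panel.maf()
    if ld is None:
        ld = compute_pairwise_r2(panel, cfg.tag_window_bp)
    candidate_idx = sorted(vidx[k] for k in candidates)
    target_set = set(np.flatnonzero(maf >= cfg.maf_min).tolist())
    covers = _cover_sets(panel, ld, candidate_idx, target_set, cfg.tag_r2)
    n_cover = {}
    for c, cov in covers.items():
        for t in cov:
            n_cover[t] = n_cover.get(t, 0) + 1
    out = set()
    for v in selection.selected:
        c = vidx[v.key]
        if any(n_cover.get(t, 0) == 1 for t in covers.get(c, ())):
            out.add(v.key)
    return out


def select_functional(annot: AnnotationTable, design_pop: str,
                      cfg: ThresholdConfig | None = None) -> dict:
    """Functional-module selection: map of variant key -> admitting clause.

    Clause 1: nonsynonymous with design-population MAF >= 0.1%.
    Clause 2: nonsynonymous with MAF < 0.1% and a damaging prediction from
    SIFT or PolyPhen-2 (HDIV or HVAR).
    """
    cfg = cfg or ThresholdConfig()
    out: dict = {}
    for rec in annot:
        if rec.consequence != "nonsynonymous":
            continue
        if design_pop not in rec.pop_maf:
            raise ValueError(f"design population {design_pop!r} absent from annotation {rec.key}")
        maf = rec.pop_maf[design_pop]
        if maf >= cfg.func_maf_common:
            out[rec.key] = f"functional clause 1: nonsynonymous, MAF {maf:.4g} >= {cfg.func_maf_common}"
        elif rec.any_damaging:
            out[rec.key] = f"functional clause 2: nonsynonymous, MAF {maf:.4g} < {cfg.func_maf_common}, predicted damaging"
    return out


def assemble_manifest(
    tags: TagSelection,
    functional: dict,
    interest_lists: dict,
    validation: ValidationReport | None,
    cfg: ThresholdConfig | None = None,
    variants_by_key: dict | None = None,
    annot: AnnotationTable | None = None,
    design_pop: str = "KOR",
    indispensable: set | None = None,
) -> tuple[ArrayManifest, pd.DataFrame]:
    """Union tag / functional / interest content into one manifest.

    Only validated variants are admitted (when a validation report is
    supplied), and every variant must pass the strand-ambiguity policy given
    its full category set.  Returns the manifest plus a table of rejected
    variants with reasons; a variant carried by several sources yields a
    single entry with the union of category labels.
    """
    cfg = cfg or ThresholdConfig()
    variants_by_key = dict(variants_by_key or {})
    for v in tags.selected:
        variants_by_key.setdefault(v.key, v)
    indispensable = indispensable or set()

    sources: dict[tuple, tuple[set, list]] = {}

    def _note(key, category, prov):
        cats, provs = sources.setdefault(key, (set(), []))
        cats.add(category)
        provs.append(prov)

    for step, v in enumerate(tags.selected):
        _note(v.key, "tag", f"greedy tag (step {step + 1})")
    for key, prov in functional.items():
        _note(key, "functional", prov)
    for name, keys in (interest_lists or {}).items():
        for key in keys:
            _note(key, f"interest:{name}", f"interest list {name}")

    validated = validation.validated_keys() if validation is not None else None
    manifest = ArrayManifest()
    rejected = []
    for key in sorted(sources, key=lambda k: (k[0], k[1])):
        cats, provs = sources[key]
        variant = variants_by_key.get(key)
        if variant is None:
            raise ValueError(f"no VariantRecord known for manifest key {key}")
        if validated is not None and key not in validated:
            rejected.append({"id": variant.id, "chrom": variant.chrom, "pos": variant.pos,
                             "reason": "failed validation"})
            continue
        rec = annot.get(key) if annot is not None else None
        keep = ambiguity_policy(variant, cats, annot=rec,
                                indispensable_tag=key in indispensable,
                                cfg=cfg, design_pop=design_pop)
        if not keep:
            rejected.append({"id": variant.id, "chrom": variant.chrom, "pos": variant.pos,
                             "reason": "ambiguous alleles (A/T or C/G), no exception applies"})
            continue
        manifest.add(ManifestEntry(variant=variant, categories=set(cats),
                                   provenance="; ".join(provs)))
    rej_df = pd.DataFrame(rejected, columns=["id", "chrom", "pos", "reason"])
    return manifest, rej_df
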