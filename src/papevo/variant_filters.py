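"""Somatic variant exclusion-filter cascades and the ultra-deep presence rule.

Four filter sets are implemented, mirroring the study design of a single- and
multi-region renal tumour sequencing analysis:

* ``burden`` — mutation burden / spectrum filters on single-sample calls
  (mappability, normal contamination, depth, alt support, VAF >= 10%,
  population frequency <= 1%);
* ``driver`` — stricter high-confidence filters for driver discovery;
* ``mseq_snv`` / ``mseq_indel`` — the multi-region pipeline's SNV and indel
  filters (base quality, unique mapping, 10x/20x depth floors, dbSNP132
  exclusion, the 5%-in-at-least-one-region rule, indel size/support rules).

Filters are pure conjunctions: the kept set does not depend on rule order;
the order only attributes the *first failing rule* to each removed variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SomaticVariant",
    "FilterResult",
    "FILTER_SETS",
    "apply_filter_set",
    "driver_candidate_screen",
    "validate_presence",
]

TRUNCATING_CLASSES = frozenset(
    {"stopgain", "frameshift deletion", "frameshift insertion",
     "frameshift substitution", "frameshift", "splicing"}
)


class AnnotationMissingError(ValueError):
    """A rule needed an annotation the variant does not carry."""


class UnknownFilterSetError(KeyError):
    pass


@dataclass
class SomaticVariant:
    """One candidate somatic mutation with the annotations the filters use.

    Per-region read counts live in ``region_depths``/``region_alts`` keyed by
    region id; single-sample tumour counts in tumour_depth/tumour_alt.
    Annotations default to None, meaning "not annotated": a rule that needs a
    missing annotation raises, it never silently passes.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str = "SNV"  # SNV | insertion | deletion | substitution
    tumour_depth: int | None = None
    tumour_alt: int | None = None
    normal_depth: int | None = None
    normal_alt: int | None = None
    region_depths: dict = field(default_factory=dict)
    region_alts: dict = field(default_factory=dict)
    mappability: float | None = None
    segdup: bool | None = None
    pop_freq: dict = field(default_factory=dict)  # database name -> frequency
    dbsnp132: bool | None = None
    base_quality: float | None = None
    unique_mapping: bool | None = None
    sift: float | None = None
    polyphen: float | None = None
    effect: str | None = None
    gene: str | None = None
    sample: str | None = None
    blacklisted: bool = False

    @property
    def tumour_vaf(self) -> float:
        self._need("tumour_depth", "tumour_alt")
        return self.tumour_alt / self.tumour_depth if self.tumour_depth else 0.0

    @property
    def max_region_vaf(self) -> float:
        if not self.region_depths:
            raise AnnotationMissingError("per-region read counts are required")
        vafs = [
            self.region_alts[r] / d if d else 0.0
            for r, d in self.region_depths.items()
        ]
        return max(vafs)

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref.replace("-", "")) - len(self.alt.replace("-", "")))

    def _need(self, *names: str) -> None:
        for name in names:
            if getattr(self, name) is None:
                raise AnnotationMissingError(
                    f"variant {self.chrom}:{self.pos} lacks annotation {name!r}"
                )


def _freq(v: SomaticVariant, db: str) -> float:
    if db not in v.pop_freq:
        raise AnnotationMissingError(
            f"variant {v.chrom}:{v.pos} lacks population frequency for {db!r}"
        )
    return v.pop_freq[db]


def _r_segdup(v):
    v._need("segdup", "mappability")
    return v.segdup or v.mappability < 0.5


def _r_normal_evidence(v):
    v._need("normal_alt")
    return v.normal_alt >= 1


def _r_pop_burden(v):
    return any(_freq(v, db) > 0.01 for db in ("EVS", "1000G", "CG69"))


def _r_pop_driver(v):
    return (
        _freq(v, "local") > 0.01
        or _freq(v, "EVS") > 0.01
        or _freq(v, "1000G") > 0.01
        or _freq(v, "CG69") > 0.10
    )


def _r_blacklist(v):
    return v.blacklisted


# (rule_id, predicate) in the printed order; predicate True => excluded
FILTER_SETS: dict = {
    "burden": [
        ("segdup_or_low_mappability", _r_segdup),
        ("normal_evidence", _r_normal_evidence),
        ("normal_depth_lt_10", lambda v: (v._need("normal_depth"), v.normal_depth < 10)[1]),
        ("tumour_depth_lt_8", lambda v: (v._need("tumour_depth"), v.tumour_depth < 8)[1]),
        ("tumour_alt_lt_3", lambda v: (v._need("tumour_alt"), v.tumour_alt < 3)[1]),
        ("tumour_vaf_lt_10pct", lambda v: v.tumour_vaf < 0.10),
        ("population_freq_gt_1pct", _r_pop_burden),
        ("local_panel_blacklist", _r_blacklist),
    ],
    "driver": [
        ("segdup_or_low_mappability", _r_segdup),
        ("population_freq", _r_pop_driver),
        ("tumour_depth_lt_10", lambda v: (v._need("tumour_depth"), v.tumour_depth < 10)[1]),
    ],
    "mseq_snv": [
        ("base_quality_lt_20", lambda v: (v._need("base_quality"), v.base_quality < 20)[1]),
        ("non_unique_mapping", lambda v: (v._need("unique_mapping"), not v.unique_mapping)[1]),
        ("depth_lt_10_normal_or_tumour",
         lambda v: (v._need("normal_depth", "tumour_depth"),
                    v.normal_depth < 10 or v.tumour_depth < 10)[1]),
        ("tumour_alt_lt_2", lambda v: (v._need("tumour_alt"), v.tumour_alt < 2)[1]),
        ("dbsnp132_member", lambda v: (v._need("dbsnp132"), v.dbsnp132)[1]),
        ("max_region_vaf_lt_5pct", lambda v: v.max_region_vaf < 0.05),
    ],
    "mseq_indel": [
        ("length_ge_10_or_complex",
         lambda v: v.variant_class == "substitution" or v.indel_length >= 10),
        ("depth_lt_20_normal_or_tumour",
         lambda v: (v._need("normal_depth", "tumour_depth"),
                    v.normal_depth < 20 or v.tumour_depth < 20)[1]),
        ("tumour_vaf_lt_10pct", lambda v: v.tumour_vaf < 0.10),
        ("tumour_alt_lt_5", lambda v: (v._need("tumour_alt"), v.tumour_alt < 5)[1]),
        ("normal_evidence", _r_normal_evidence),
    ],
}


@dataclass
class FilterResult:
    kept: list
    removed: list  # (variant, first_failing_rule_id)
    filter_set: str
    rule_counts: dict

    def summary(self) -> dict:
        return {
            "filter_set": self.filter_set,
            "n_input": len(self.kept) + len(self.removed),
            "n_kept": len(self.kept),
            "n_removed": len(self.removed),
            "per_rule_removed": dict(self.rule_counts),
        }

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (v.chrom, v.pos, v.ref, v.alt, "PASS", "") for v in self.kept
        ] + [
            (v.chrom, v.pos, v.ref, v.alt, "FAIL", rule) for v, rule in self.removed
        ]
        return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "status", "rule"])


def apply_filter_set(variants: list, filter_set: str) -> FilterResult:
    """Apply one exclusion-filter cascade; see module docstring for the sets.

    A variant is removed if *any* rule fires; the recorded rule is the first
    one in the printed order.  Missing annotations raise
    :class:`AnnotationMissingError`.
    """
    if filter_set not in FILTER_SETS:
        raise UnknownFilterSetError(
            f"unknown filter set {filter_set!r}; choose from {sorted(FILTER_SETS)}"
        )
    rules = FILTER_SETS[filter_set]
    kept, removed = [], []
    counts = {rule_id: 0 for rule_id, _ in rules}
    for v in variants:
        for rule_id, pred in rules:
            if pred(v):
                removed.append((v, rule_id))
                counts[rule_id] += 1
                break
        else:
            kept.append(v)
    return FilterResult(kept=kept, removed=removed, filter_set=filter_set, rule_counts=counts)


def driver_candidate_screen(variants: list, min_vaf: float = 0.05) -> list:
    """Driver-discovery functional screen.

    Keeps variants with tumour VAF >= ``min_vaf`` that are protein-truncating
    or splice-site (always retained), or SNVs that are not predicted benign.
    An SNV is excluded as benign iff SIFT > 0.3 AND PolyPhen2 < 0.7 (both
    programs must call it benign); synonymous SNVs are excluded outright.
    Non-frameshift indels (in-frame) are retained as moderate-effect changes.
    """
    if not (0 < min_vaf <= 1):
        raise ValueError(f"min_vaf must lie in (0, 1], got {min_vaf}")
    kept = []
    for v in variants:
        if v.tumour_vaf < min_vaf:
            continue
        v._need("effect")
        effect = v.effect.lower().replace(" snv", "")
        if effect in TRUNCATING_CLASSES or effect.startswith("frameshift"):
            kept.append(v)
            continue
        if effect == "synonymous":
            continue
        if effect.startswith("non-frameshift"):
            kept.append(v)
            continue
        v._need("sift", "polyphen")
        benign = v.sift > 0.3 and v.polyphen < 0.7
        if not benign:
            kept.append(v)
    return kept


def validate_presence(deep_counts: pd.DataFrame, threshold: float = 0.01) -> pd.DataFrame:
    """Score ultra-deep validation counts into a presence matrix.

    ``deep_counts`` is a long table with mutation_id, region, depth and
    alt_count columns.  A mutation is present in a region iff its VAF reaches
    ``threshold`` (default 1%, the platform error floor) with at least one
    supporting read.  Cells with zero depth are unevaluable (NaN), not absent.
    Returns a mutation x region matrix of {1.0, 0.0, NaN}.
    """
    req = {"mutation_id", "region", "depth", "alt_count"}
    if not req.issubset(deep_counts.columns):
        raise ValueError(f"deep counts table must have columns {sorted(req)}")

    def score(row):
        if row.depth == 0:
            return np.nan
        return float(row.alt_count >= 1 and row.alt_count / row.depth >= threshold)

    flat = deep_counts.assign(present=[score(r) for r in deep_counts.itertuples()])
    return flat.pivot_table(
        index="mutation_id", columns="region", values="present", dropna=False
    )
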