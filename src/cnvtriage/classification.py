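"""Clinical-significance classification of retained, validated CNVs.

A CNV is *disease causing* when it arose de novo in the fetus and/or
overlaps a curated region with an established association to congenital
brain malformation (type-compatible). It is *probably disease causing*
when it lacks both triggers but overlaps a curated candidate region.
Everything else is a variant of unknown significance (VUS). Inheritance
from a healthy parent, or absence of trio data, is recorded as evidence
but never changes the class.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .cascade import CnvCall, CnvType
from .intervals import GenomicInterval, overlaps
from .segregation import InheritanceVerdict, SegregationResult

__all__ = [
    "RegionTier",
    "RequiredType",
    "CuratedRegion",
    "SignificanceClass",
    "EvidenceTag",
    "ClassificationVerdict",
    "CohortSummary",
    "classify",
    "summarize",
]


class RegionTier(str, Enum):
    ESTABLISHED = "ESTABLISHED"
    CANDIDATE = "CANDIDATE"


class RequiredType(str, Enum):
    DEL = "DEL"
    DUP = "DUP"
    ANY = "ANY"

    def compatible_with(self, cnv_type: CnvType) -> bool:
        return self is RequiredType.ANY or self.value == cnv_type.value


@dataclass(frozen=True)
class CuratedRegion:
    """A genomic region with curated disease-association evidence."""

    label: str
    interval: GenomicInterval
    required_type: RequiredType
    tier: RegionTier
    citation: str = ""


class SignificanceClass(str, Enum):
    DISEASE_CAUSING = "DISEASE_CAUSING"
    PROBABLY_DISEASE_CAUSING = "PROBABLY_DISEASE_CAUSING"
    VUS = "VUS"


class EvidenceTag(str, Enum):
    DE_NOVO = "DE_NOVO"
    ESTABLISHED_REGION = "ESTABLISHED_REGION"
    CANDIDATE_REGION = "CANDIDATE_REGION"
    INHERITED_FROM_HEALTHY_PARENT = "INHERITED_FROM_HEALTHY_PARENT"
    NOT_TESTED = "NOT_TESTED"


@dataclass(frozen=True)
class ClassificationVerdict:
    cnv_id: str
    significance: SignificanceClass
    evidence: tuple[EvidenceTag, ...]
    matched_regions: tuple[str, ...] = ()


class UnconfirmedCallError(ValueError):
    """Classification requires a cascade-retained, assay-confirmed call."""


_INHERITED = {
    InheritanceVerdict.MATERNAL,
    InheritanceVerdict.PATERNAL,
    InheritanceVerdict.BIPARENTAL,
}
_UNTESTED = {
    InheritanceVerdict.NOT_TESTED,
    InheritanceVerdict.PATERNAL_EXCLUDED,
    InheritanceVerdict.MATERNAL_EXCLUDED,
}


def classify(
    call: CnvCall,
    seg: SegregationResult | None,
    regions: Iterable[CuratedRegion],
) -> ClassificationVerdict:
    """Assign a significance class from segregation and curated evidence.

    ``seg`` may be None for a CNV with no trio material at all (treated
    as not tested); when present it must be a confirmed result for this
    call. Curated-region overlap requires >= 1 shared base and type
    compatibility. Deterministic and independent of region-list order.
    """
    if seg is not None:
        if seg.cnv_id != call.call_id:
            raise UnconfirmedCallError(
                f"segregation result {seg.cnv_id} does not match {call.call_id}"
            )
        if not seg.confirmed:
            raise UnconfirmedCallError(
                f"call {call.call_id} was not confirmed; cannot classify"
            )

    evidence: set[EvidenceTag] = set()
    matched: list[str] = []
    for region in regions:
        if not region.required_type.compatible_with(call.cnv_type):
            continue
        if not overlaps(call.interval, region.interval):
            continue
        matched.append(region.label)
        if region.tier is RegionTier.ESTABLISHED:
            evidence.add(EvidenceTag.ESTABLISHED_REGION)
        else:
            evidence.add(EvidenceTag.CANDIDATE_REGION)

    verdict = seg.verdict if seg is not None else InheritanceVerdict.NOT_TESTED
    if verdict is InheritanceVerdict.DE_NOVO:
        evidence.add(EvidenceTag.DE_NOVO)
    elif verdict in _INHERITED:
        evidence.add(EvidenceTag.INHERITED_FROM_HEALTHY_PARENT)
    elif verdict in _UNTESTED:
        evidence.add(EvidenceTag.NOT_TESTED)

    if EvidenceTag.DE_NOVO in evidence or EvidenceTag.ESTABLISHED_REGION in evidence:
        significance = SignificanceClass.DISEASE_CAUSING
    elif EvidenceTag.CANDIDATE_REGION in evidence:
        significance = SignificanceClass.PROBABLY_DISEASE_CAUSING
    else:
        significance = SignificanceClass.VUS

    return ClassificationVerdict(
        cnv_id=call.call_id,
        significance=significance,
        evidence=tuple(sorted(evidence, key=lambda t: t.value)),
        matched_regions=tuple(sorted(matched)),
    )


@dataclass
class CohortSummary:
    """Cohort-level tallies over all classified CNVs.

    ``diagnostic_yield_percent`` is the percentage of analyzed fetuses
    (the full roster, not just CNV carriers) with at least one
    disease-causing CNV, rounded to the nearest integer.
    """

    n_fetuses_analyzed: int
    n_cnvs: int
    n_duplications: int
    n_deletions: int
    n_carrier_fetuses: int
    cnvs_per_class: dict[str, int]
    fetuses_per_class: dict[str, int]
    cnvs_per_fetus: dict[str, int]
    diagnostic_yield_percent: int


def summarize(
    verdicts: Sequence[ClassificationVerdict],
    calls: Sequence[CnvCall],
    fetus_roster: Sequence[str],
) -> CohortSummary:
    """Tally classes, dup/del counts and diagnostic yield over a cohort.

    ``fetus_roster`` lists every fetus analyzed (the yield denominator);
    every classified call's fetus must appear in it.
    """
    by_id = {c.call_id: c for c in calls}
    roster = list(dict.fromkeys(fetus_roster))
    roster_set = set(roster)
    for v in verdicts:
        if v.cnv_id not in by_id:
            raise ValueError(f"verdict for unknown call {v.cnv_id}")
        sample = by_id[v.cnv_id].sample_id
        if sample not in roster_set:
            raise ValueError(
                f"verdict references fetus {sample!r} absent from roster"
            )

    classified_calls = [by_id[v.cnv_id] for v in verdicts]
    cnvs_per_class = Counter(v.significance.value for v in verdicts)
    fetus_classes: dict[str, set[str]] = {}
    for v in verdicts:
        fetus_classes.setdefault(v.significance.value, set()).add(
            by_id[v.cnv_id].sample_id
        )
    fetuses_per_class = {k: len(s) for k, s in fetus_classes.items()}
    per_fetus = Counter(c.sample_id for c in classified_calls)

    n_dc_fetuses = fetuses_per_class.get(
        SignificanceClass.DISEASE_CAUSING.value, 0
    )
    yield_pct = round(100 * n_dc_fetuses / len(roster)) if roster else 0

    return CohortSummary(
        n_fetuses_analyzed=len(roster),
        n_cnvs=len(verdicts),
        n_duplications=sum(
            1 for c in classified_calls if c.cnv_type is CnvType.DUP
        ),
        n_deletions=sum(
            1 for c in classified_calls if c.cnv_type is CnvType.DEL
        ),
        n_carrier_fetuses=len(per_fetus),
        cnvs_per_class={k: cnvs_per_class.get(k, 0) for k in
                        [c.value for c in SignificanceClass]},
        fetuses_per_class={k: fetuses_per_class.get(k, 0) for k in
                           [c.value for c in SignificanceClass]},
        cnvs_per_fetus=dict(sorted(per_fetus.items())),
        diagnostic_yield_percent=yield_pct,
    )
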