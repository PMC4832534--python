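"""Trio segregation of validated CNVs from relative copy-ratio assays.

Quantitative PCR (or MLPA, through the same interface) reports a relative
copy ratio per primer locus, normalized so the reference copy number maps
to 1.0. For autosomes the reference is two copies; for male X-chromosome
loci it is one copy, so a hemizygous male duplication (2 copies) and a
female carrier (3 copies) both present as a gain after normalization.

Confirmation precedes segregation: a fetal CNV must reproduce its array
type (loss for a deletion, gain for a duplication) in the ratio data
before any inheritance verdict is assigned.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .cascade import CnvCall, CnvType

__all__ = [
    "Person",
    "Sex",
    "CopyState",
    "InheritanceVerdict",
    "TrioMeasurement",
    "SegregationResult",
    "SegregationConfig",
    "UnconfirmedCnvError",
    "call_state",
    "segregate",
    "analyze_trio",
]


class Person(str, Enum):
    FETUS = "FETUS"
    MOTHER = "MOTHER"
    FATHER = "FATHER"


class Sex(str, Enum):
    MALE = "MALE"
    FEMALE = "FEMALE"


class CopyState(str, Enum):
    LOSS = "LOSS"
    NORMAL = "NORMAL"
    GAIN = "GAIN"
    MISSING = "MISSING"


class InheritanceVerdict(str, Enum):
    DE_NOVO = "DE_NOVO"
    MATERNAL = "MATERNAL"
    PATERNAL = "PATERNAL"
    BIPARENTAL = "BIPARENTAL"
    PATERNAL_EXCLUDED = "PATERNAL_EXCLUDED"
    MATERNAL_EXCLUDED = "MATERNAL_EXCLUDED"
    NOT_TESTED = "NOT_TESTED"


@dataclass(frozen=True)
class TrioMeasurement:
    """One relative copy-ratio measurement (one primer locus, one person)."""

    cnv_id: str
    person: Person
    locus_id: str
    ratio: float

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise ValueError("copy ratio must be >= 0")


@dataclass(frozen=True)
class SegregationResult:
    cnv_id: str
    fetus_state: CopyState
    mother_state: CopyState
    father_state: CopyState
    verdict: InheritanceVerdict
    confirmed: bool


@dataclass
class SegregationConfig:
    """Ratio thresholds and the locus-consistency rule.

    A locus ratio below ``del_max`` is a loss, above ``dup_min`` a gain;
    a person's state is the majority per-locus call, which must be held
    by at least ``min_consistent`` loci and be a strict majority.
    """

    del_max: float = 0.75
    dup_min: float = 1.25
    min_consistent: int = 2


class UnconfirmedCnvError(ValueError):
    """The fetal ratio data do not reproduce the array CNV, or the
    measurements are too inconsistent to call a state."""


def _locus_call(ratio: float, config: SegregationConfig) -> CopyState:
    if ratio < config.del_max:
        return CopyState.LOSS
    if ratio > config.dup_min:
        return CopyState.GAIN
    return CopyState.NORMAL


def call_state(
    ratios: Sequence[float],
    sex: Sex = Sex.FEMALE,
    chrom: str = "1",
    config: SegregationConfig | None = None,
) -> CopyState:
    """Person-level copy state from per-locus relative ratios.

    Ratios are assumed normalized to the person's own reference copy
    number (1.0 = reference). For male X-chromosome loci the reference
    is a single copy; ratios reported against a two-copy scale are
    doubled before thresholding so that a hemizygous duplication
    (ratio 1.0 on the two-copy scale) is called a gain.

    Raises :class:`UnconfirmedCnvError` when no locus was measured, when
    no state reaches ``min_consistent`` agreeing loci, or on a tie.
    """
    config = config or SegregationConfig()
    if len(ratios) == 0:
        raise UnconfirmedCnvError("no loci measured for a present person")
    scale = 2.0 if (sex is Sex.MALE and chrom == "X") else 1.0
    calls = Counter(_locus_call(r * scale, config) for r in ratios)
    (top_state, top_n), = calls.most_common(1)
    runners = [n for s, n in calls.items() if s is not top_state]
    if top_n < config.min_consistent or (runners and max(runners) == top_n):
        raise UnconfirmedCnvError(
            f"inconsistent locus calls: {dict(calls)}"
        )
    return top_state


def segregate(
    fetus_state: CopyState,
    mother_state: CopyState,
    father_state: CopyState,
) -> InheritanceVerdict:
    """Inheritance verdict from confirmed per-person copy states.

    The fetal state must be an aberration (loss or gain); a parent
    "carries" the CNV iff their state matches the fetal aberration.
    A parent with the opposite aberration does not carry the fetal CNV
    and counts as a non-carrier. Total and deterministic over the 4x4
    grid of parental states.
    """
    if fetus_state in (CopyState.NORMAL, CopyState.MISSING):
        raise UnconfirmedCnvError(
            "cannot segregate an unconfirmed fetal CNV "
            f"(fetal state {fetus_state.value})"
        )
    m_carrier = mother_state == fetus_state
    f_carrier = father_state == fetus_state
    m_missing = mother_state is CopyState.MISSING
    f_missing = father_state is CopyState.MISSING

    if m_carrier and f_carrier:
        return InheritanceVerdict.BIPARENTAL
    if m_carrier:
        return InheritanceVerdict.MATERNAL
    if f_carrier:
        return InheritanceVerdict.PATERNAL
    if m_missing and f_missing:
        return InheritanceVerdict.NOT_TESTED
    if m_missing:
        return InheritanceVerdict.PATERNAL_EXCLUDED
    if f_missing:
        return InheritanceVerdict.MATERNAL_EXCLUDED
    return InheritanceVerdict.DE_NOVO


def analyze_trio(
    call: CnvCall,
    measurements: Iterable[TrioMeasurement],
    fetus_sex: Sex = Sex.FEMALE,
    config: SegregationConfig | None = None,
) -> SegregationResult:
    """Confirm a fetal CNV and segregate it against the parents.

    ``measurements`` are the ratio rows for this CNV; a person with no
    rows is treated as not sampled (MISSING). The fetal state must match
    the array call's type (LOSS for DEL, GAIN for DUP) or the result is
    returned unconfirmed with verdict NOT_TESTED.
    """
    config = config or SegregationConfig()
    by_person: dict[Person, list[float]] = {p: [] for p in Person}
    for m in measurements:
        if m.cnv_id != call.call_id:
            raise ValueError(
                f"measurement for {m.cnv_id} passed with call {call.call_id}"
            )
        by_person[m.person].append(m.ratio)

    chrom = call.interval.chrom

    def person_state(person: Person, sex: Sex) -> CopyState:
        ratios = by_person[person]
        if not ratios:
            return CopyState.MISSING
        try:
            return call_state(ratios, sex=sex, chrom=chrom, config=config)
        except UnconfirmedCnvError:
            return CopyState.MISSING if person is not Person.FETUS else CopyState.NORMAL

    fetus = person_state(Person.FETUS, fetus_sex)
    mother = person_state(Person.MOTHER, Sex.FEMALE)
    father = person_state(Person.FATHER, Sex.MALE)

    expected = CopyState.LOSS if call.cnv_type is CnvType.DEL else CopyState.GAIN
    confirmed = fetus == expected
    if not confirmed:
        return SegregationResult(
            cnv_id=call.call_id,
            fetus_state=fetus,
            mother_state=mother,
            father_state=father,
            verdict=InheritanceVerdict.NOT_TESTED,
            confirmed=False,
        )
    verdict = segregate(fetus, mother, father)
    return SegregationResult(
        cnv_id=call.call_id,
        fetus_state=fetus,
        mother_state=mother,
        father_state=father,
        verdict=verdict,
        confirmed=True,
    )
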