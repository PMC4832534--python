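"""Seven-criterion CNV filter cascade with a per-call audit trace.

Putative CNV calls from a SNP-array HMM caller are whittled down by, in
order: (I) call confidence (log Bayes factor), (II) supporting aberrant
marker count, (III) frequency in an in-house healthy control cohort,
(IV) a manual review gate, (V) coding overlap with CNS-relevant genes,
(VI) presence as fully-overlapping reports in a population CNV database,
and (VII) a breakpoint re-evaluation gate that may widen a call into a
neighbouring brain-related gene and re-test criteria V and VI on the new
interval.

Each call carries a :class:`FilterTrace` recording every criterion's
verdict and the intermediate statistics (control frequency, database
report count, overlapped gene symbols), so any exclusion can be audited.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from intervaltree import IntervalTree

from .intervals import GenomicInterval, contains, overlaps, reciprocal_overlap

__all__ = [
    "CnvType",
    "PopCnvType",
    "CnvCall",
    "SampleQc",
    "PopulationCnvRecord",
    "GeneModel",
    "ReviewDecision",
    "Verdict",
    "FilterTrace",
    "FilterConfig",
    "ControlCohort",
    "PopulationDb",
    "GeneSet",
    "qc_sample",
    "screen_samples",
    "filter_quality",
    "filter_markers",
    "control_frequency",
    "filter_gene_content",
    "filter_dgv",
    "run_cascade",
    "CASCADE_ORDER",
    "COMMUTING_CRITERIA",
]


class CnvType(str, Enum):
    DEL = "DEL"
    DUP = "DUP"


class PopCnvType(str, Enum):
    """Type of a population-database record; MIXED matches both call types."""

    DEL = "DEL"
    DUP = "DUP"
    MIXED = "MIXED"

    def compatible_with(self, call_type: CnvType) -> bool:
        return self is PopCnvType.MIXED or self.value == call_type.value


#: Sentinel marker label meaning the call runs into the telomere.
TELOMERE = "Telomer"


@dataclass(frozen=True)
class CnvCall:
    """One array-derived CNV call.

    ``log_bayes_factor`` is the caller's per-call confidence score and
    ``n_markers`` the number of consecutive aberrant array probes
    supporting the call. Marker/flank identifiers are optional metadata
    (``flank_*`` may be the :data:`TELOMERE` sentinel).
    """

    sample_id: str
    interval: GenomicInterval
    cnv_type: CnvType
    log_bayes_factor: float
    n_markers: int
    copy_state: int | None = None
    first_marker_id: str | None = None
    last_marker_id: str | None = None
    flank_before_id: str | None = None
    flank_after_id: str | None = None

    def __post_init__(self) -> None:
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")
        if self.log_bayes_factor < 0:
            raise ValueError("log_bayes_factor must be >= 0")
        if self.copy_state is not None:
            if self.cnv_type is CnvType.DEL and self.copy_state >= 2:
                raise ValueError("DEL requires copy_state < 2")
            if self.cnv_type is CnvType.DUP and self.copy_state <= 2:
                raise ValueError("DUP requires copy_state > 2")

    @property
    def call_id(self) -> str:
        iv = self.interval
        return (
            f"{self.sample_id}:{self.cnv_type.value.lower()}"
            f"_{iv.chrom}_{iv.start}_{iv.end}"
        )


@dataclass(frozen=True)
class SampleQc:
    """Per-sample array quality: fraction of SNP markers called."""

    sample_id: str
    call_rate: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.call_rate <= 1.0:
            raise ValueError("call_rate must be in [0, 1]")


@dataclass(frozen=True)
class PopulationCnvRecord:
    """One report from a population CNV database (DGV-style)."""

    interval: GenomicInterval
    cnv_type: PopCnvType
    report_id: str


@dataclass(frozen=True)
class GeneModel:
    """A gene's coding span plus a CNS-relevance flag (CNS-associated or
    CNS-expressed per curated annotation resources)."""

    symbol: str
    coding_span: GenomicInterval
    cns_flag: bool


@dataclass(frozen=True)
class ReviewDecision:
    """A recorded manual-review outcome for one call.

    ``action`` is ``"exclude"`` (criterion IV: the call does not survive
    visual inspection) or ``"rebreak"`` (criterion VII: breakpoints are
    replaced, typically widening into a flanking brain-related gene).
    """

    sample_id: str
    interval: GenomicInterval
    action: str
    new_interval: GenomicInterval | None = None

    def __post_init__(self) -> None:
        if self.action not in ("exclude", "rebreak"):
            raise ValueError(f"unknown review action: {self.action!r}")
        if self.action == "rebreak" and self.new_interval is None:
            raise ValueError("rebreak decision requires new coordinates")


class Verdict(str, Enum):
    PASS = "pass"
    FAIL = "fail"
    NOT_EVALUATED = "not_evaluated"


CASCADE_ORDER = ("I", "II", "III", "IV", "V", "VI", "VII")
#: Criteria that depend only on the call and static resources; their
#: relative order never changes the retained set.
COMMUTING_CRITERIA = frozenset({"I", "II", "III", "V", "VI"})


@dataclass
class FilterTrace:
    """Audit record for one call's passage through the cascade."""

    call: CnvCall
    verdicts: dict[str, Verdict] = field(
        default_factory=lambda: {c: Verdict.NOT_EVALUATED for c in CASCADE_ORDER}
    )
    control_frequency: float | None = None
    dgv_full_overlap_count: int | None = None
    overlapping_cns_genes: list[str] = field(default_factory=list)
    final: bool = False
    final_interval: GenomicInterval | None = None


@dataclass
class FilterConfig:
    """Thresholds and matching rules for the cascade.

    Boundary semantics follow the exclusion phrasings literally: calls
    with log Bayes factor strictly below ``lbf_min`` are excluded (30.0
    itself is kept); fewer than ``min_markers`` aberrant markers is
    excluded (exactly 3 kept); control frequency strictly above
    ``max_control_freq`` is excluded; ``dgv_max_full_overlaps`` or more
    fully-overlapping database reports is excluded (count 4 kept).
    """

    qc_min_call_rate: float = 0.95
    lbf_min: float = 30.0
    min_markers: int = 3
    max_control_freq: float = 0.01
    control_match_min_reciprocal_overlap: float = 0.5
    control_match_same_type: bool = True
    dgv_max_full_overlaps: int = 5
    dgv_type_matched: bool = True


def qc_sample(qc: SampleQc, threshold: float = 0.95) -> bool:
    """A sample is usable iff at least ``threshold`` of markers were called."""
    return qc.call_rate >= threshold


def screen_samples(
    qc_table: Iterable[SampleQc], threshold: float = 0.95
) -> list[str]:
    """Sample ids passing array QC, in input order."""
    return [q.sample_id for q in qc_table if qc_sample(q, threshold)]


def filter_quality(call: CnvCall, lbf_min: float = 30.0) -> bool:
    """Criterion I: keep iff log Bayes factor >= ``lbf_min``."""
    return call.log_bayes_factor >= lbf_min


def filter_markers(call: CnvCall, min_markers: int = 3) -> bool:
    """Criterion II: keep iff supported by >= ``min_markers`` aberrant markers."""
    return call.n_markers >= min_markers


def _build_tree(items: Iterable[tuple[GenomicInterval, object]]):
    trees: dict[str, IntervalTree] = {}
    for iv, payload in items:
        trees.setdefault(iv.chrom, IntervalTree()).addi(
            iv.start, iv.end + 1, payload
        )
    return trees


class ControlCohort:
    """In-house control cohort: a fixed number of genotyped individuals
    and their CNV calls. Individuals without calls contribute only to the
    denominator."""

    def __init__(self, n_individuals: int, calls: Sequence[CnvCall] = ()):
        if n_individuals < 1:
            raise ValueError("control cohort must contain >= 1 individual")
        self.n_individuals = int(n_individuals)
        self.calls = list(calls)
        self._trees = _build_tree((c.interval, c) for c in self.calls)

    def matching_individuals(
        self, call: CnvCall, config: FilterConfig
    ) -> set[str]:
        """Control individuals carrying >= 1 call matching ``call`` under
        the configured identity rule."""
        hits: set[str] = set()
        tree = self._trees.get(call.interval.chrom)
        if tree is None:
            return hits
        for node in tree.overlap(call.interval.start, call.interval.end + 1):
            ctrl: CnvCall = node.data
            if config.control_match_same_type and ctrl.cnv_type != call.cnv_type:
                continue
            ro = reciprocal_overlap(call.interval, ctrl.interval)
            if ro >= config.control_match_min_reciprocal_overlap:
                hits.add(ctrl.sample_id)
        return hits

    def frequency(self, call: CnvCall, config: FilterConfig) -> float:
        return len(self.matching_individuals(call, config)) / self.n_individuals


def control_frequency(
    call: CnvCall, cohort: ControlCohort, config: FilterConfig | None = None
) -> float:
    """Criterion III statistic: fraction of control individuals carrying a
    matching call (same type, reciprocal overlap above the configured
    minimum, by default). The criterion keeps the call iff the frequency
    is <= the configured maximum (1% by default)."""
    return cohort.frequency(call, config or FilterConfig())


class PopulationDb:
    """Population CNV database (one row per report; duplicates allowed)."""

    def __init__(self, records: Sequence[PopulationCnvRecord] = ()):
        self.records = list(records)
        self._trees = _build_tree((r.interval, r) for r in self.records)

    def count_full_overlaps(
        self, call: CnvCall, type_matched: bool = True
    ) -> int:
        tree = self._trees.get(call.interval.chrom)
        if tree is None:
            return 0
        n = 0
        for node in tree.overlap(call.interval.start, call.interval.end + 1):
            rec: PopulationCnvRecord = node.data
            if type_matched and not rec.cnv_type.compatible_with(call.cnv_type):
                continue
            if contains(rec.interval, call.interval):
                n += 1
        return n


class GeneSet:
    """Gene annotation with CNS-relevance flags, indexed by coding span."""

    def __init__(self, genes: Sequence[GeneModel] = ()):
        self.genes = list(genes)
        self._trees = _build_tree((g.coding_span, g) for g in self.genes)

    def cns_genes_overlapping(self, interval: GenomicInterval) -> list[str]:
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        out = {
            node.data.symbol
            for node in tree.overlap(interval.start, interval.end + 1)
            if node.data.cns_flag and overlaps(interval, node.data.coding_span)
        }
        return sorted(out)


def filter_gene_content(
    call: CnvCall, genes: GeneSet
) -> tuple[bool, list[str]]:
    """Criterion V: keep iff the call overlaps (>= 1 bp) the coding span of
    at least one CNS-flagged gene; returns the overlapped symbols."""
    symbols = genes.cns_genes_overlapping(call.interval)
    return (len(symbols) > 0, symbols)


def filter_dgv(
    call: CnvCall,
    db: PopulationDb,
    max_full_overlaps: int = 5,
    type_matched: bool = True,
) -> tuple[bool, int]:
    """Criterion VI: count database reports fully containing the call;
    keep iff the count is below ``max_full_overlaps``."""
    n = db.count_full_overlaps(call, type_matched=type_matched)
    return (n < max_full_overlaps, n)


class ReviewTable:
    """Manual-review decisions keyed by (sample_id, interval)."""

    def __init__(self, decisions: Sequence[ReviewDecision] = ()):
        self._by_key = {(d.sample_id, d.interval): d for d in decisions}

    def lookup(self, call: CnvCall) -> ReviewDecision | None:
        return self._by_key.get((call.sample_id, call.interval))

    def validate_against(self, calls: Sequence[CnvCall]) -> None:
        known = {(c.sample_id, c.interval) for c in calls}
        for key in self._by_key:
            if key not in known:
                sid, iv = key
                raise ValueError(
                    f"review decision references unknown call {sid} {iv}"
                )

    def __len__(self) -> int:
        return len(self._by_key)


def _evaluate_static(
    criterion: str,
    call: CnvCall,
    interval: GenomicInterval,
    cohort: ControlCohort | None,
    db: PopulationDb,
    genes: GeneSet,
    config: FilterConfig,
    trace: FilterTrace,
) -> bool:
    """Evaluate one of the commuting criteria on ``interval`` (which may be
    a re-broken version of the call's own), updating trace statistics."""
    probe = dataclasses.replace(call, interval=interval)
    if criterion == "I":
        return filter_quality(call, config.lbf_min)
    if criterion == "II":
        return filter_markers(call, config.min_markers)
    if criterion == "III":
        if cohort is None:
            raise ValueError("criterion III requires a control cohort")
        freq = cohort.frequency(probe, config)
        trace.control_frequency = freq
        return freq <= config.max_control_freq
    if criterion == "V":
        keep, symbols = filter_gene_content(probe, genes)
        trace.overlapping_cns_genes = symbols
        return keep
    if criterion == "VI":
        keep, n = filter_dgv(
            probe, db, config.dgv_max_full_overlaps, config.dgv_type_matched
        )
        trace.dgv_full_overlap_count = n
        return keep
    raise ValueError(f"unknown criterion: {criterion}")


def run_cascade(
    calls: Sequence[CnvCall],
    cohort: ControlCohort | None,
    db: PopulationDb,
    genes: GeneSet,
    decisions: ReviewTable | Sequence[ReviewDecision] | None = None,
    config: FilterConfig | None = None,
    order: Sequence[str] = CASCADE_ORDER,
) -> tuple[list[CnvCall], list[FilterTrace]]:
    """Apply the seven filter criteria in ``order`` to every call.

    ``order`` must be a permutation of the seven criteria keeping the
    review gates IV and VII in their cascade positions (4th and last);
    permuting the commuting subset I/II/III/V/VI never changes the
    retained set. Returns the retained calls (with re-broken intervals
    substituted where criterion VII replaced breakpoints) and one
    :class:`FilterTrace` per input call.
    """
    config = config or FilterConfig()
    if not isinstance(decisions, (ReviewTable, type(None))):
        decisions = ReviewTable(decisions)
    review = decisions or ReviewTable()
    review.validate_against(calls)

    order = tuple(order)
    if sorted(order) != sorted(CASCADE_ORDER):
        raise ValueError("order must be a permutation of criteria I-VII")
    if order[3] != "IV" or order[-1] != "VII":
        raise ValueError("review gates IV and VII are fixed in cascade position")

    retained: list[CnvCall] = []
    traces: list[FilterTrace] = []
    for call in calls:
        trace = FilterTrace(call=call)
        decision = review.lookup(call)
        rebroken = (
            decision is not None and decision.action == "rebreak"
        )
        # a breakpoint replacement (criterion VII) governs the annotation
        # criteria: gene content (V) and database presence (VI) are judged
        # on the corrected interval, while the call-level statistics
        # (I, II) and the control-frequency match (III) refer to the
        # interval the caller actually reported
        interval = decision.new_interval if rebroken else call.interval
        alive = True
        for criterion in order:
            if not alive:
                break  # later criteria stay not_evaluated
            if criterion == "IV":
                if decision is not None and decision.action == "exclude":
                    trace.verdicts["IV"] = Verdict.FAIL
                    alive = False
                else:
                    trace.verdicts["IV"] = Verdict.PASS
            elif criterion == "VII":
                trace.verdicts["VII"] = Verdict.PASS
            else:
                eval_interval = (
                    interval if criterion in ("V", "VI") else call.interval
                )
                ok = _evaluate_static(
                    criterion, call, eval_interval, cohort, db, genes,
                    config, trace,
                )
                trace.verdicts[criterion] = Verdict.PASS if ok else Verdict.FAIL
                if not ok:
                    alive = False
        trace.final = alive
        trace.final_interval = interval
        if alive:
            retained.append(
                call if interval == call.interval
                else dataclasses.replace(call, interval=interval)
            )
        traces.append(trace)
    return retained, traces
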