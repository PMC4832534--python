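"""End-to-end orchestration: QC screen -> filter cascade -> trio
confirmation/segregation -> classification -> cohort summary."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .cascade import (
    CnvCall,
    ControlCohort,
    FilterConfig,
    FilterTrace,
    GeneSet,
    PopulationDb,
    ReviewTable,
    Verdict,
    run_cascade,
    screen_samples,
)
from .classification import (
    ClassificationVerdict,
    CohortSummary,
    CuratedRegion,
    classify,
    summarize,
)
from .intervals import write_bed
from .io import (
    format_summary,
    write_calls,
    write_segregation_results,
    write_summary,
    write_traces,
    write_verdicts,
)
from .cascade import SampleQc
from .segregation import (
    SegregationConfig,
    SegregationResult,
    Sex,
    TrioMeasurement,
    analyze_trio,
)

__all__ = ["PipelineRun", "run_pipeline"]


@dataclass
class PipelineRun:
    """Machine-readable record of one pipeline execution."""

    version: str
    filter_config: dict
    segregation_config: dict
    input_digests: dict[str, str]
    stage_counts: dict[str, int]
    output_paths: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _digest(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(
    calls: Sequence[CnvCall],
    cohort: ControlCohort,
    popdb: PopulationDb,
    genes: GeneSet,
    *,
    sample_qc: Sequence[SampleQc] | None = None,
    trios: Sequence[TrioMeasurement] = (),
    regions: Sequence[CuratedRegion] = (),
    decisions: ReviewTable | None = None,
    sexes: Mapping[str, Sex] | None = None,
    filter_config: FilterConfig | None = None,
    seg_config: SegregationConfig | None = None,
    outdir: str | Path | None = None,
    input_paths: Mapping[str, str | Path] | None = None,
) -> tuple[
    list[CnvCall],
    list[FilterTrace],
    list[SegregationResult],
    list[ClassificationVerdict],
    CohortSummary,
    PipelineRun,
]:
    """Run the full prioritization pipeline on in-memory inputs.

    When ``sample_qc`` is given, calls from samples below the QC
    threshold are dropped before the cascade and the usable samples
    define the yield denominator; otherwise every sample with a call is
    assumed usable. Retained CNVs with trio measurements are confirmed
    and segregated; a retained CNV whose ratio data fail to reproduce
    the array call is reported in the segregation table but receives no
    significance verdict. Deterministic for fixed inputs.
    """
    filter_config = filter_config or FilterConfig()
    seg_config = seg_config or SegregationConfig()
    sexes = dict(sexes or {})
    counts: dict[str, int] = {"input_calls": len(calls)}

    if sample_qc is not None:
        usable = screen_samples(sample_qc, filter_config.qc_min_call_rate)
        usable_set = set(usable)
        roster = usable
        screened = [c for c in calls if c.sample_id in usable_set]
        counts["samples_total"] = len(sample_qc)
        counts["samples_usable"] = len(usable)
    else:
        roster = list(dict.fromkeys(c.sample_id for c in calls))
        screened = list(calls)
    counts["calls_after_qc"] = len(screened)

    retained, traces = run_cascade(
        screened, cohort, popdb, genes,
        decisions=decisions, config=filter_config,
    )
    for criterion in ("I", "II", "III", "IV", "V", "VI", "VII"):
        counts[f"fail_{criterion}"] = sum(
            1 for t in traces if t.verdicts[criterion] is Verdict.FAIL
        )
    counts["retained"] = len(retained)

    by_cnv: dict[str, list[TrioMeasurement]] = {}
    for m in trios:
        by_cnv.setdefault(m.cnv_id, []).append(m)
    seg_results: list[SegregationResult] = []
    seg_by_id: dict[str, SegregationResult] = {}
    for call in retained:
        if call.call_id in by_cnv:
            res = analyze_trio(
                call, by_cnv[call.call_id],
                fetus_sex=sexes.get(call.sample_id, Sex.FEMALE),
                config=seg_config,
            )
            seg_results.append(res)
            seg_by_id[call.call_id] = res
    counts["segregated"] = len(seg_results)
    counts["unconfirmed"] = sum(1 for r in seg_results if not r.confirmed)

    verdicts: list[ClassificationVerdict] = []
    classified_calls: list[CnvCall] = []
    for call in retained:
        seg = seg_by_id.get(call.call_id)
        if seg is not None and not seg.confirmed:
            continue  # confirmation precedes classification
        verdicts.append(classify(call, seg, regions))
        classified_calls.append(call)
    counts["classified"] = len(verdicts)

    summary = summarize(verdicts, classified_calls, roster)

    output_paths: dict[str, str] = {}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_traces(traces, outdir / "filter_trace.tsv")
        write_calls(retained, outdir / "retained_calls.tsv")
        write_bed(
            [c.interval for c in retained],
            outdir / "retained.bed",
            names=[c.call_id for c in retained],
        )
        write_segregation_results(seg_results, outdir / "segregation.tsv")
        write_verdicts(verdicts, outdir / "verdicts.tsv")
        write_summary(summary, outdir / "summary.yaml")
        (outdir / "summary.txt").write_text(format_summary(summary) + "\n")
        output_paths = {
            name: str(outdir / name)
            for name in ("filter_trace.tsv", "retained_calls.tsv",
                         "retained.bed", "segregation.tsv", "verdicts.tsv",
                         "summary.yaml", "summary.txt")
        }

    run = PipelineRun(
        version=__version__,
        filter_config=dataclasses.asdict(filter_config),
        segregation_config=dataclasses.asdict(seg_config),
        input_digests={
            k: _digest(v) for k, v in (input_paths or {}).items()
        },
        stage_counts=counts,
        output_paths=output_paths,
    )
    if outdir is not None:
        (Path(outdir) / "run_manifest.json").write_text(run.to_json() + "\n")
    return retained, traces, seg_results, verdicts, summary, run
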