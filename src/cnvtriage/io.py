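"""Tab-separated readers and writers for every pipeline table.

All tables are headered TSV (trio ratios are CSV). Readers validate row
by row and report the offending file and line number on malformed input.
Writers are the exact inverses of the readers (lossless round-trip).
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .cascade import (
    CnvCall,
    CnvType,
    FilterConfig,
    FilterTrace,
    GeneModel,
    PopCnvType,
    PopulationCnvRecord,
    ReviewDecision,
    SampleQc,
)
from .classification import (
    ClassificationVerdict,
    CohortSummary,
    CuratedRegion,
    RegionTier,
    RequiredType,
)
from .intervals import GenomicInterval
from .segregation import (
    Person,
    SegregationConfig,
    SegregationResult,
    TrioMeasurement,
)

__all__ = [
    "TableFormatError",
    "read_calls",
    "write_calls",
    "read_sample_qc",
    "write_sample_qc",
    "read_population_db",
    "write_population_db",
    "read_genes",
    "write_genes",
    "read_trio_measurements",
    "write_trio_measurements",
    "read_curated_regions",
    "write_curated_regions",
    "read_review_decisions",
    "write_traces",
    "write_segregation_results",
    "write_verdicts",
    "write_summary",
    "load_config",
]

CALL_COLUMNS = [
    "sample_id", "chrom", "start", "end", "cnv_type", "copy_state",
    "log_bayes_factor", "n_markers", "first_marker_id", "last_marker_id",
    "flank_before_id", "flank_after_id",
]


class TableFormatError(ValueError):
    """A table failed to parse; the message names the file and line."""


def _read_rows(path: str | Path, required: Sequence[str], sep: str = "\t"):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"missing input table: {path}")
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - rewrap with file context
        raise TableFormatError(f"{path}: cannot parse table: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}"
        )
    # data rows start at line 2 (line 1 is the header)
    return path, df


def _opt(value: str) -> str | None:
    return value if value not in ("", "NA", ".") else None


def read_calls(path: str | Path) -> list[CnvCall]:
    path, df = _read_rows(path, CALL_COLUMNS[:8])
    calls = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            copy_state = _opt(getattr(row, "copy_state", ""))
            calls.append(CnvCall(
                sample_id=row.sample_id,
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                cnv_type=CnvType(row.cnv_type),
                log_bayes_factor=float(row.log_bayes_factor),
                n_markers=int(row.n_markers),
                copy_state=int(copy_state) if copy_state is not None else None,
                first_marker_id=_opt(getattr(row, "first_marker_id", "")),
                last_marker_id=_opt(getattr(row, "last_marker_id", "")),
                flank_before_id=_opt(getattr(row, "flank_before_id", "")),
                flank_after_id=_opt(getattr(row, "flank_after_id", "")),
            ))
        except (ValueError, KeyError) as exc:
            raise TableFormatError(f"{path}, line {i}: {exc}") from exc
    return calls


def write_calls(calls: Iterable[CnvCall], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CALL_COLUMNS)
        for c in calls:
            w.writerow([
                c.sample_id, c.interval.chrom, c.interval.start, c.interval.end,
                c.cnv_type.value,
                "" if c.copy_state is None else c.copy_state,
                f"{c.log_bayes_factor:.2f}", c.n_markers,
                c.first_marker_id or "", c.last_marker_id or "",
                c.flank_before_id or "", c.flank_after_id or "",
            ])


def read_sample_qc(path: str | Path) -> list[SampleQc]:
    path, df = _read_rows(path, ["sample_id", "call_rate"])
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(SampleQc(row.sample_id, float(row.call_rate)))
        except ValueError as exc:
            raise TableFormatError(f"{path}, line {i}: {exc}") from exc
    return out


def write_sample_qc(qc: Iterable[SampleQc], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["sample_id", "call_rate"])
        for q in qc:
            w.writerow([q.sample_id, f"{q.call_rate:.4f}"])


def read_population_db(path: str | Path) -> list[PopulationCnvRecord]:
    path, df = _read_rows(path, ["chrom", "start", "end", "cnv_type", "report_id"])
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(PopulationCnvRecord(
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                cnv_type=PopCnvType(row.cnv_type),
                report_id=row.report_id,
            ))
        except ValueError as exc:
            raise TableFormatError(f"{path}, line {i}: {exc}") from exc
    return out


def write_population_db(
    records: Iterable[PopulationCnvRecord], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["chrom", "start", "end", "cnv_type", "report_id"])
        for r in records:
            w.writerow([r.interval.chrom, r.interval.start, r.interval.end,
                        r.cnv_type.value, r.report_id])


def read_genes(path: str | Path) -> list[GeneModel]:
    path, df = _read_rows(path, ["symbol", "chrom", "start", "end", "cns_flag"])
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(GeneModel(
                symbol=row.symbol,
                coding_span=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                cns_flag=row.cns_flag in ("1", "true", "True", "TRUE"),
            ))
        except ValueError as exc:
            raise TableFormatError(f"{path}, line {i}: {exc}") from exc
    return out


def write_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["symbol", "chrom", "start", "end", "cns_flag"])
        for g in genes:
            w.writerow([g.symbol, g.coding_span.chrom, g.coding_span.start,
                        g.coding_span.end, int(g.cns_flag)])


def read_trio_measurements(path: str | Path) -> list[TrioMeasurement]:
    path, df = _read_rows(path, ["cnv_id", "person", "locus_id", "ratio"], sep=",")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(TrioMeasurement(
                cnv_id=row.cnv_id,
                person=Person(row.person),
                locus_id=row.locus_id,
                ratio=float(row.ratio),
            ))
        except ValueError as exc:
            raise TableFormatError(f"{path}, line {i}: {exc}") from exc
    return out


def write_trio_measurements(
    measurements: Iterable[TrioMeasurement], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["cnv_id", "person", "locus_id", "ratio"])
        for m in measurements:
            w.writerow([m.cnv_id, m.person.value, m.locus_id, f"{m.ratio:.6f}"])


def read_curated_regions(path: str | Path) -> list[CuratedRegion]:
    path, df = _read_rows(
        path, ["label", "chrom", "start", "end", "required_type", "tier"]
    )
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(CuratedRegion(
                label=row.label,
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                required_type=RequiredType(row.required_type),
                tier=RegionTier(row.tier),
                citation=getattr(row, "citation", ""),
            ))
        except ValueError as exc:
            raise TableFormatError(f"{path}, line {i}: {exc}") from exc
    return out


def write_curated_regions(
    regions: Iterable[CuratedRegion], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["label", "chrom", "start", "end", "required_type",
                    "tier", "citation"])
        for r in regions:
            w.writerow([r.label, r.interval.chrom, r.interval.start,
                        r.interval.end, r.required_type.value, r.tier.value,
                        r.citation])


def read_review_decisions(path: str | Path) -> list[ReviewDecision]:
    path, df = _read_rows(
        path, ["sample_id", "chrom", "start", "end", "action"]
    )
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            new_iv = None
            new_start = _opt(getattr(row, "new_start", ""))
            new_end = _opt(getattr(row, "new_end", ""))
            if new_start is not None and new_end is not None:
                new_iv = GenomicInterval(row.chrom, int(new_start), int(new_end))
            out.append(ReviewDecision(
                sample_id=row.sample_id,
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
                action=row.action,
                new_interval=new_iv,
            ))
        except ValueError as exc:
            raise TableFormatError(f"{path}, line {i}: {exc}") from exc
    return out


def write_traces(traces: Iterable[FilterTrace], path: str | Path) -> None:
    """Filter-trace TSV: one row per input call, one column per criterion."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow([
            "call_id", "sample_id", "chrom", "start", "end", "cnv_type",
            "crit_I", "crit_II", "crit_III", "crit_IV", "crit_V", "crit_VI",
            "crit_VII", "control_frequency", "dgv_full_overlap_count",
            "overlapping_cns_genes", "final_start", "final_end", "retained",
        ])
        for t in traces:
            c = t.call
            fi = t.final_interval or c.interval
            w.writerow([
                c.call_id, c.sample_id, c.interval.chrom, c.interval.start,
                c.interval.end, c.cnv_type.value,
                *[t.verdicts[k].value for k in
                  ("I", "II", "III", "IV", "V", "VI", "VII")],
                "" if t.control_frequency is None
                else f"{t.control_frequency:.4f}",
                "" if t.dgv_full_overlap_count is None
                else t.dgv_full_overlap_count,
                ";".join(t.overlapping_cns_genes),
                fi.start, fi.end, int(t.final),
            ])


def write_segregation_results(
    results: Iterable[SegregationResult], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["cnv_id", "fetus_state", "mother_state", "father_state",
                    "verdict", "confirmed"])
        for r in results:
            w.writerow([r.cnv_id, r.fetus_state.value, r.mother_state.value,
                        r.father_state.value, r.verdict.value, int(r.confirmed)])


def read_segregation_results(path: str | Path) -> list[SegregationResult]:
    from .segregation import CopyState, InheritanceVerdict

    path, df = _read_rows(
        path,
        ["cnv_id", "fetus_state", "mother_state", "father_state",
         "verdict", "confirmed"],
    )
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            out.append(SegregationResult(
                cnv_id=row.cnv_id,
                fetus_state=CopyState(row.fetus_state),
                mother_state=CopyState(row.mother_state),
                father_state=CopyState(row.father_state),
                verdict=InheritanceVerdict(row.verdict),
                confirmed=row.confirmed in ("1", "true", "True"),
            ))
        except ValueError as exc:
            raise TableFormatError(f"{path}, line {i}: {exc}") from exc
    return out


def write_verdicts(
    verdicts: Iterable[ClassificationVerdict], path: str | Path
) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["cnv_id", "significance", "evidence", "matched_regions"])
        for v in verdicts:
            w.writerow([v.cnv_id, v.significance.value,
                        ";".join(t.value for t in v.evidence),
                        ";".join(v.matched_regions)])


def write_summary(summary: CohortSummary, path: str | Path) -> None:
    """Cohort summary as a YAML key-value report (machine readable)."""
    payload = {
        "n_fetuses_analyzed": summary.n_fetuses_analyzed,
        "n_cnvs": summary.n_cnvs,
        "n_duplications": summary.n_duplications,
        "n_deletions": summary.n_deletions,
        "n_carrier_fetuses": summary.n_carrier_fetuses,
        "cnvs_per_class": summary.cnvs_per_class,
        "fetuses_per_class": summary.fetuses_per_class,
        "cnvs_per_fetus": summary.cnvs_per_fetus,
        "diagnostic_yield_percent": summary.diagnostic_yield_percent,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def format_summary(summary: CohortSummary) -> str:
    """Human-readable text table for a cohort summary."""
    lines = [
        "Cohort summary",
        "--------------",
        f"fetuses analyzed            {summary.n_fetuses_analyzed}",
        f"CNVs classified             {summary.n_cnvs}"
        f" ({summary.n_duplications} dup / {summary.n_deletions} del)",
        f"carrier fetuses             {summary.n_carrier_fetuses}",
    ]
    for klass, n in summary.cnvs_per_class.items():
        nf = summary.fetuses_per_class.get(klass, 0)
        lines.append(f"{klass.lower():<28}{n} CNVs in {nf} fetuses")
    lines.append(
        f"diagnostic yield            {summary.diagnostic_yield_percent}%"
    )
    return "\n".join(lines)


def load_config(path: str | Path) -> dict:
    """Load a YAML config with optional ``filter``, ``segregation`` and
    ``cohort`` sections into config objects (unknown keys are an error)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    out: dict = {}
    filt = raw.get("filter", {})
    seg = raw.get("segregation", {})
    try:
        out["filter"] = FilterConfig(**filt)
        out["segregation"] = SegregationConfig(**seg)
    except TypeError as exc:
        raise ValueError(f"{path}: invalid config field: {exc}") from exc
    out["cohort"] = raw.get("cohort", {})
    out["simulate"] = raw.get("simulate", {})
    return out
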