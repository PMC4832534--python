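"""Packaged reference cohort: the 18 validated CNVs of a 33-fetus
prenatal molecular-karyotyping study.

The fixture ships as TSVs under ``cnvtriage/data`` with a checksum
manifest: the 18 validated CNV calls across 14 carrier fetuses (with
marker and flanking-SNP labels; ``Telomer`` marks calls running into a
telomere), the published inheritance outcomes, a curated-region evidence
base (established brain-malformation regions plus one candidate region),
an in-house control cohort of 1307 individuals in which exactly two of
the fixture CNVs were each seen once, and a gene table with one
representative CNS-flagged gene per CNV (approximate hg19 coding spans;
the gene table exists so the coding-overlap criterion genuinely
evaluates on the fixture, it is not a complete annotation).

Quality scores and marker counts are not printed per call in the source
table; the fixture assigns values comfortably above the cascade
thresholds, marked by the ``FIXTURE_LBF``/``FIXTURE_N_MARKERS``
constants, so the cascade's verdicts on the fixture are driven by the
real coordinates, cohort and annotation data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .cascade import (
    CnvCall,
    CnvType,
    ControlCohort,
    FilterConfig,
    GeneSet,
    PopulationDb,
    run_cascade,
)
from .classification import (
    ClassificationVerdict,
    CohortSummary,
    CuratedRegion,
    classify,
    summarize,
)
from .intervals import GenomicInterval
from .io import read_calls, read_curated_regions, read_genes
from .segregation import CopyState, InheritanceVerdict, SegregationResult, Sex

__all__ = ["Table1Fixture", "load_table1_fixture", "run_table1_pipeline"]

#: Cohort size of the in-house control collection.
N_CONTROLS = 1307
#: Number of fetuses with analyzable arrays (the yield denominator).
N_ANALYZED = 33

# Placeholder quality attributes for the fixture calls (validated CNVs;
# the source table prints no per-call scores).
FIXTURE_LBF = 100.0
FIXTURE_N_MARKERS = 50

_INHERITANCE_MAP = {
    "Yes": InheritanceVerdict.DE_NOVO,
    "n.t.": InheritanceVerdict.NOT_TESTED,
    "No paternal inheritance": InheritanceVerdict.PATERNAL_EXCLUDED,
    "Maternal": InheritanceVerdict.MATERNAL,
}


@dataclass
class Table1Fixture:
    calls: list[CnvCall]
    sexes: dict[str, Sex]
    printed_sizes_mb: dict[str, float]
    segregation: dict[str, SegregationResult]
    roster: list[str]
    curated_regions: list[CuratedRegion]
    genes: GeneSet
    cohort: ControlCohort
    popdb: PopulationDb


def _data_path(name: str) -> Path:
    return Path(resources.files("cnvtriage").joinpath("data", name))


def verify_manifest() -> None:
    """Check the packaged data files against their sha256 manifest."""
    manifest = json.loads(_data_path("manifest.json").read_text())
    for name, expected in manifest.items():
        digest = hashlib.sha256(_data_path(name).read_bytes()).hexdigest()
        if digest != expected:
            raise RuntimeError(f"packaged fixture file corrupted: {name}")


def _segregation_from_label(
    call: CnvCall, label: str
) -> SegregationResult:
    verdict = _INHERITANCE_MAP[label]
    aberrant = (
        CopyState.LOSS if call.cnv_type is CnvType.DEL else CopyState.GAIN
    )
    mother, father = {
        InheritanceVerdict.DE_NOVO: (CopyState.NORMAL, CopyState.NORMAL),
        InheritanceVerdict.NOT_TESTED: (CopyState.MISSING, CopyState.MISSING),
        InheritanceVerdict.PATERNAL_EXCLUDED: (
            CopyState.MISSING, CopyState.NORMAL),
        InheritanceVerdict.MATERNAL: (aberrant, CopyState.NORMAL),
    }[verdict]
    return SegregationResult(
        cnv_id=call.call_id,
        fetus_state=aberrant,
        mother_state=mother,
        father_state=father,
        verdict=verdict,
        confirmed=True,
    )


def load_table1_fixture(check_manifest: bool = True) -> Table1Fixture:
    """Load the packaged 18-CNV reference cohort."""
    if check_manifest:
        verify_manifest()
    df = pd.read_csv(_data_path("table1_cnvs.tsv"), sep="\t", dtype=str)

    calls: list[CnvCall] = []
    sexes: dict[str, Sex] = {}
    printed: dict[str, float] = {}
    segregation: dict[str, SegregationResult] = {}
    for row in df.itertuples(index=False):
        call = CnvCall(
            sample_id=row.sample_id,
            interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
            cnv_type=CnvType(row.cnv_type),
            log_bayes_factor=FIXTURE_LBF,
            n_markers=FIXTURE_N_MARKERS,
            first_marker_id=row.first_marker_id,
            last_marker_id=row.last_marker_id,
            flank_before_id=row.flank_before_id,
            flank_after_id=row.flank_after_id,
        )
        calls.append(call)
        sexes[row.sample_id] = Sex(row.sex)
        printed[call.call_id] = float(row.printed_size_mb)
        segregation[call.call_id] = _segregation_from_label(
            call, row.inheritance
        )

    roster = [f"fetus_{i}" for i in range(1, N_ANALYZED + 1)]
    regions = read_curated_regions(_data_path("curated_regions.tsv"))
    genes = GeneSet(read_genes(_data_path("table1_genes.tsv")))
    cohort = ControlCohort(
        N_CONTROLS, read_calls(_data_path("table1_controls.tsv"))
    )
    return Table1Fixture(
        calls=calls,
        sexes=sexes,
        printed_sizes_mb=printed,
        segregation=segregation,
        roster=roster,
        curated_regions=regions,
        genes=genes,
        cohort=cohort,
        popdb=PopulationDb([]),
    )


def run_table1_pipeline(
    fixture: Table1Fixture | None = None,
    config: FilterConfig | None = None,
) -> tuple[list[CnvCall], list[ClassificationVerdict], CohortSummary]:
    """Run cascade -> classification -> summary on the packaged cohort."""
    fx = fixture or load_table1_fixture()
    retained, _traces = run_cascade(
        fx.calls, fx.cohort, fx.popdb, fx.genes, config=config
    )
    verdicts = [
        classify(c, fx.segregation[c.call_id], fx.curated_regions)
        for c in retained
    ]
    summary = summarize(verdicts, retained, fx.roster)
    return retained, verdicts, summary
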