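"""Synthetic cohort generator with planted ground truth.

Emulates every input the pipeline consumes — fetal CNV call tables,
per-sample array QC, an in-house control cohort, a population CNV
database, a CNS-flagged gene table, trio copy-ratio measurements and a
curated-region evidence base — on a miniature genome, with a ground-truth
record of the intended fate of every planted call.

Planted calls fall into classes that each violate exactly one cascade
criterion: true CNVs (confident, well-supported, rare, gene-overlapping,
sparse in the population database), low-confidence noise (log Bayes
factor below threshold), under-supported noise (fewer than three
aberrant markers), and common CNVs (present in >1% of controls, or
backed by at least five fully-overlapping database reports). All
randomness flows from the single seed; equal seeds give byte-identical
output bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .cascade import (
    CnvCall,
    CnvType,
    ControlCohort,
    GeneModel,
    PopCnvType,
    PopulationCnvRecord,
    PopulationDb,
    GeneSet,
    SampleQc,
)
from .classification import CuratedRegion, RegionTier, RequiredType
from .intervals import GenomicInterval
from .segregation import Person, Sex, TrioMeasurement
from . import io as tio

__all__ = [
    "SimConfig",
    "GroundTruthRecord",
    "SyntheticBundle",
    "generate",
    "write_bundle",
    "simulate_trio_ratios",
]

CATEGORY_TRUE = "true"
CATEGORY_LOW_LBF = "noise_low_lbf"
CATEGORY_FEW_MARKERS = "noise_few_markers"
CATEGORY_COMMON_CONTROL = "noise_common_control"
CATEGORY_COMMON_DGV = "noise_common_dgv"
CATEGORY_QC_FAILED = "qc_failed_sample"


@dataclass
class SimConfig:
    """Shape of the emulated study.

    Defaults mirror the study design: 35 recruited fetuses of which 2
    fail array QC, and a 1307-individual healthy control cohort. Planted
    common CNVs are carried by 2% of controls (above the 1% exclusion
    threshold); the miniature genome is three 10-Mb autosomes plus X.
    """

    seed: int = 0
    n_fetuses: int = 35
    n_controls: int = 1307
    n_true_cnvs: int = 6
    n_noise_low_lbf: int = 5
    n_noise_few_markers: int = 5
    n_noise_common: int = 4
    dgv_reports_per_common_region: int = 6
    common_control_carrier_rate: float = 0.02
    de_novo_fraction: float = 0.5
    ratio_noise_sd: float = 0.05
    qc_fail_count: int = 2
    genome: tuple[tuple[str, int], ...] = (
        ("1", 10_000_000),
        ("2", 10_000_000),
        ("3", 10_000_000),
        ("X", 10_000_000),
    )

    def __post_init__(self) -> None:
        counts = (
            self.n_fetuses, self.n_controls, self.n_true_cnvs,
            self.n_noise_low_lbf, self.n_noise_few_markers,
            self.n_noise_common, self.qc_fail_count,
        )
        if any(c < 0 for c in counts):
            raise ValueError("all counts must be >= 0")
        if self.n_controls < 1:
            raise ValueError("n_controls must be >= 1")
        if not 0 <= self.de_novo_fraction <= 1:
            raise ValueError("de_novo_fraction must be in [0, 1]")
        if self.ratio_noise_sd < 0:
            raise ValueError("ratio_noise_sd must be >= 0")
        if self.qc_fail_count > self.n_fetuses:
            raise ValueError("qc_fail_count cannot exceed n_fetuses")


@dataclass(frozen=True)
class GroundTruthRecord:
    """Planted truth for one synthetic call."""

    call_id: str
    sample_id: str
    category: str
    expected_fate: str  # "retained", "fail_<criterion>", or "dropped_qc"
    inheritance: str  # "de_novo" / "maternal" / "paternal" / ""
    intended_class: str  # significance class, or "" for non-retained calls


@dataclass
class SyntheticBundle:
    config: SimConfig
    calls: list[CnvCall]
    sample_qc: list[SampleQc]
    fetus_sexes: dict[str, Sex]
    cohort: ControlCohort
    popdb: PopulationDb
    genes: GeneSet
    trios: list[TrioMeasurement]
    curated_regions: list[CuratedRegion]
    truth: list[GroundTruthRecord]


# Slot layout: planted CNVs live in disjoint slots separated by wide
# gaps so no two planted features can interact by accident.
_SLOT_LEN = 400_000
_SLOT_GAP = 200_000
_SLOT_MARGIN = 200_000


def _slots(genome, autosomes_only: bool = True):
    out = []
    for chrom, length in genome:
        if autosomes_only and chrom in ("X", "Y"):
            continue
        pos = _SLOT_MARGIN
        while pos + _SLOT_LEN + _SLOT_GAP <= length:
            out.append((chrom, pos))
            pos += _SLOT_LEN + _SLOT_GAP
    return out


def _aberrant_ratio(cnv_type: CnvType) -> float:
    # one-copy loss -> 0.5, one-copy gain -> 1.5 on the two-copy scale
    return 0.5 if cnv_type is CnvType.DEL else 1.5


def generate(config: SimConfig | None = None, **overrides) -> SyntheticBundle:
    """Generate a full synthetic input bundle with ground truth.

    Deterministic for a fixed config (all randomness from ``config.seed``
    through one generator stream). Raises if the miniature genome cannot
    hold the requested number of planted CNVs in disjoint slots.
    """
    if config is None:
        config = SimConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    rng = np.random.default_rng(config.seed)

    categories = (
        [CATEGORY_TRUE] * config.n_true_cnvs
        + [CATEGORY_LOW_LBF] * config.n_noise_low_lbf
        + [CATEGORY_FEW_MARKERS] * config.n_noise_few_markers
        + [
            CATEGORY_COMMON_CONTROL if i % 2 == 0 else CATEGORY_COMMON_DGV
            for i in range(config.n_noise_common)
        ]
        + [CATEGORY_QC_FAILED] * config.qc_fail_count
    )
    slots = _slots(config.genome)
    # reserve extra slots for background genes not tied to any CNV
    n_background_genes = 10
    if len(slots) < len(categories) + n_background_genes:
        raise ValueError(
            f"genome too small: {len(slots)} slots available for "
            f"{len(categories)} planted CNVs + {n_background_genes} "
            "background genes"
        )
    slot_idx = rng.permutation(len(slots))

    # --- sample-level QC -------------------------------------------------
    fetus_ids = [f"fetus_{i:02d}" for i in range(1, config.n_fetuses + 1)]
    fail_ids = set(
        rng.choice(fetus_ids, size=config.qc_fail_count, replace=False)
    ) if config.qc_fail_count else set()
    sample_qc = [
        SampleQc(
            fid,
            round(float(rng.uniform(0.85, 0.9499)), 4) if fid in fail_ids
            else round(float(rng.uniform(0.955, 0.9995)), 4),
        )
        for fid in fetus_ids
    ]
    passing_ids = [f for f in fetus_ids if f not in fail_ids]
    fetus_sexes = {
        fid: Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
        for fid in fetus_ids
    }

    # --- plant the fetal calls ------------------------------------------
    calls: list[CnvCall] = []
    truth: list[GroundTruthRecord] = []
    genes: list[GeneModel] = []
    controls: list[CnvCall] = []
    popdb: list[PopulationCnvRecord] = []
    trios: list[TrioMeasurement] = []
    curated: list[CuratedRegion] = []
    inheritance_of: dict[str, str] = {}
    report_counter = 0

    control_ids = [f"control_{i:04d}" for i in range(1, config.n_controls + 1)]
    n_common_carriers = max(
        2, math.ceil(config.common_control_carrier_rate * config.n_controls)
    )

    true_index = 0
    for k, category in enumerate(categories):
        chrom, slot_start = slots[slot_idx[k]]
        length = int(rng.integers(50_000, 300_001))
        start = slot_start + int(rng.integers(0, 50_001))
        iv = GenomicInterval(chrom, start, start + length - 1)
        cnv_type = CnvType.DEL if rng.random() < 0.5 else CnvType.DUP
        copy_state = 1 if cnv_type is CnvType.DEL else 3

        lbf = float(rng.uniform(40.0, 90.0))
        n_markers = int(rng.integers(10, 61))
        if category == CATEGORY_LOW_LBF:
            lbf = float(rng.uniform(2.0, 29.9))
        elif category == CATEGORY_FEW_MARKERS:
            n_markers = int(rng.integers(1, 3))

        if category == CATEGORY_QC_FAILED:
            sample = list(sorted(fail_ids))[k - len(categories)
                                            + config.qc_fail_count]
        else:
            sample = str(rng.choice(passing_ids))

        call = CnvCall(
            sample_id=sample,
            interval=iv,
            cnv_type=cnv_type,
            log_bayes_factor=round(lbf, 2),
            n_markers=n_markers,
            copy_state=copy_state,
        )
        calls.append(call)

        # every planted call overlaps exactly one CNS-flagged gene so
        # that only the intended criterion can exclude it
        g_start = iv.start + iv.length // 10
        g_end = iv.start + (4 * iv.length) // 10
        genes.append(GeneModel(
            symbol=f"GENE{k:03d}",
            coding_span=GenomicInterval(chrom, g_start, g_end),
            cns_flag=True,
        ))

        # population-database background: fewer than five containing
        # reports for everything except the DGV-common class
        for _ in range(int(rng.integers(0, 3))):
            pad_l = int(rng.integers(1_000, 20_000))
            pad_r = int(rng.integers(1_000, 20_000))
            report_counter += 1
            popdb.append(PopulationCnvRecord(
                interval=GenomicInterval(
                    chrom, max(1, iv.start - pad_l), iv.end + pad_r
                ),
                cnv_type=PopCnvType(cnv_type.value),
                report_id=f"rep_{report_counter:05d}",
            ))
        if category == CATEGORY_COMMON_DGV:
            needed = config.dgv_reports_per_common_region
            for _ in range(needed):
                pad_l = int(rng.integers(0, 30_000))
                pad_r = int(rng.integers(0, 30_000))
                report_counter += 1
                popdb.append(PopulationCnvRecord(
                    interval=GenomicInterval(
                        chrom, max(1, iv.start - pad_l), iv.end + pad_r
                    ),
                    cnv_type=PopCnvType(cnv_type.value),
                    report_id=f"rep_{report_counter:05d}",
                ))

        # control cohort carriers
        if category == CATEGORY_COMMON_CONTROL:
            carriers = rng.choice(
                control_ids, size=n_common_carriers, replace=False
            )
        elif (category == CATEGORY_TRUE and 1 / config.n_controls <= 0.01
              and rng.random() < 0.3):
            # a rare true CNV may be seen once in controls, but only when
            # a single carrier stays at or below the 1% threshold
            carriers = rng.choice(control_ids, size=1, replace=False)
        else:
            carriers = []
        for cid in carriers:
            jitter_s = int(rng.integers(-iv.length // 10, iv.length // 10 + 1))
            jitter_e = int(rng.integers(-iv.length // 10, iv.length // 10 + 1))
            controls.append(CnvCall(
                sample_id=str(cid),
                interval=GenomicInterval(
                    chrom,
                    max(1, iv.start + jitter_s),
                    iv.end + jitter_e,
                ),
                cnv_type=cnv_type,
                log_bayes_factor=round(float(rng.uniform(30.0, 80.0)), 2),
                n_markers=int(rng.integers(5, 40)),
                copy_state=copy_state,
            ))

        # curated evidence: the first true CNV sits in an established
        # region, the second in a candidate region
        region_overlap = None
        if category == CATEGORY_TRUE:
            if true_index == 0:
                curated.append(CuratedRegion(
                    label="SIM_ESTABLISHED_0",
                    interval=GenomicInterval(chrom, g_start, g_end),
                    required_type=RequiredType(cnv_type.value),
                    tier=RegionTier.ESTABLISHED,
                    citation="synthetic established association",
                ))
                region_overlap = RegionTier.ESTABLISHED
            elif true_index == 1:
                curated.append(CuratedRegion(
                    label="SIM_CANDIDATE_1",
                    interval=GenomicInterval(chrom, g_start, g_end),
                    required_type=RequiredType.ANY,
                    tier=RegionTier.CANDIDATE,
                    citation="synthetic candidate association",
                ))
                region_overlap = RegionTier.CANDIDATE

        # trio measurements for true CNVs
        inheritance = ""
        if category == CATEGORY_TRUE:
            if rng.random() < config.de_novo_fraction:
                inheritance = "de_novo"
            else:
                inheritance = "maternal" if rng.random() < 0.5 else "paternal"
            aberrant = _aberrant_ratio(cnv_type)
            person_truth = {
                Person.FETUS: aberrant,
                Person.MOTHER: aberrant if inheritance == "maternal" else 1.0,
                Person.FATHER: aberrant if inheritance == "paternal" else 1.0,
            }
            n_loci = int(rng.integers(3, 5))
            for person, mean in person_truth.items():
                for j in range(n_loci):
                    ratio = float(
                        rng.normal(mean, config.ratio_noise_sd)
                    )
                    trios.append(TrioMeasurement(
                        cnv_id=call.call_id,
                        person=person,
                        locus_id=f"{call.call_id}_L{j + 1}",
                        ratio=round(max(ratio, 0.0), 6),
                    ))
            true_index += 1

        fate = {
            CATEGORY_TRUE: "retained",
            CATEGORY_LOW_LBF: "fail_I",
            CATEGORY_FEW_MARKERS: "fail_II",
            CATEGORY_COMMON_CONTROL: "fail_III",
            CATEGORY_COMMON_DGV: "fail_VI",
            CATEGORY_QC_FAILED: "dropped_qc",
        }[category]
        if category == CATEGORY_TRUE:
            if inheritance == "de_novo" or region_overlap is RegionTier.ESTABLISHED:
                intended = "DISEASE_CAUSING"
            elif region_overlap is RegionTier.CANDIDATE:
                intended = "PROBABLY_DISEASE_CAUSING"
            else:
                intended = "VUS"
        else:
            intended = ""
        inheritance_of[call.call_id] = inheritance
        truth.append(GroundTruthRecord(
            call_id=call.call_id,
            sample_id=sample,
            category=category,
            expected_fate=fate,
            inheritance=inheritance,
            intended_class=intended,
        ))

    # background genes in the remaining slots (some CNS, some not),
    # plus gene deserts implicitly in the slot gaps
    for j in range(n_background_genes):
        chrom, slot_start = slots[slot_idx[len(categories) + j]]
        g_len = int(rng.integers(10_000, 80_000))
        g_start = slot_start + int(rng.integers(0, 100_000))
        genes.append(GeneModel(
            symbol=f"BG{j:03d}",
            coding_span=GenomicInterval(chrom, g_start, g_start + g_len),
            cns_flag=bool(rng.random() < 0.4),
        ))

    return SyntheticBundle(
        config=config,
        calls=calls,
        sample_qc=sample_qc,
        fetus_sexes=fetus_sexes,
        cohort=ControlCohort(config.n_controls, controls),
        popdb=PopulationDb(popdb),
        genes=GeneSet(genes),
        trios=trios,
        curated_regions=curated,
        truth=truth,
    )


def simulate_trio_ratios(
    n_trios: int,
    ratio_noise_sd: float,
    seed: int,
    n_loci: int = 3,
    de_novo_fraction: float = 0.5,
) -> list[tuple[str, CnvType, dict[Person, list[float]]]]:
    """Simulate trio ratio panels with known inheritance, for recovery
    studies. Returns (true_inheritance, cnv_type, ratios-per-person)."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_trios):
        cnv_type = CnvType.DEL if rng.random() < 0.5 else CnvType.DUP
        if rng.random() < de_novo_fraction:
            label = "de_novo"
        else:
            label = "maternal" if rng.random() < 0.5 else "paternal"
        aberrant = _aberrant_ratio(cnv_type)
        means = {
            Person.FETUS: aberrant,
            Person.MOTHER: aberrant if label == "maternal" else 1.0,
            Person.FATHER: aberrant if label == "paternal" else 1.0,
        }
        ratios = {
            p: [max(0.0, float(rng.normal(m, ratio_noise_sd)))
                for _ in range(n_loci)]
            for p, m in means.items()
        }
        out.append((label, cnv_type, ratios))
    return out


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, str]:
    """Write every bundle table plus a sha256 manifest; returns the
    manifest (filename -> digest). Byte-identical for equal configs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    tio.write_calls(bundle.calls, outdir / "calls.tsv")
    tio.write_sample_qc(bundle.sample_qc, outdir / "sample_qc.tsv")
    tio.write_calls(bundle.cohort.calls, outdir / "controls.tsv")
    tio.write_population_db(bundle.popdb.records, outdir / "popdb.tsv")
    tio.write_genes(bundle.genes.genes, outdir / "genes.tsv")
    tio.write_trio_measurements(bundle.trios, outdir / "trios.csv")
    tio.write_curated_regions(
        bundle.curated_regions, outdir / "curated_regions.tsv"
    )

    with open(outdir / "fetus_sexes.tsv", "w") as fh:
        fh.write("sample_id\tsex\n")
        for fid, sex in bundle.fetus_sexes.items():
            fh.write(f"{fid}\t{sex.value}\n")

    with open(outdir / "ground_truth.tsv", "w") as fh:
        fh.write("call_id\tsample_id\tcategory\texpected_fate\t"
                 "inheritance\tintended_class\n")
        for t in bundle.truth:
            fh.write(f"{t.call_id}\t{t.sample_id}\t{t.category}\t"
                     f"{t.expected_fate}\t{t.inheritance}\t"
                     f"{t.intended_class}\n")

    cfg = dataclasses.asdict(bundle.config)
    cfg["genome"] = [list(pair) for pair in bundle.config.genome]
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(
            {"simulate": cfg, "cohort": {"n_controls": bundle.config.n_controls}},
            fh, sort_keys=True,
        )

    manifest = {}
    for name in sorted(p.name for p in outdir.iterdir()
                       if p.name != "manifest.json"):
        manifest[name] = hashlib.sha256(
            (outdir / name).read_bytes()
        ).hexdigest()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
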