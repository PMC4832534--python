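"""Trio confirmation and inheritance verdicts."""

import itertools

import numpy as np
import pytest

from cnvtriage.cascade import CnvCall, CnvType
from cnvtriage.intervals import GenomicInterval
from cnvtriage.segregation import (
    CopyState,
    InheritanceVerdict,
    Person,
    SegregationConfig,
    Sex,
    TrioMeasurement,
    UnconfirmedCnvError,
    analyze_trio,
    call_state,
    segregate,
)
from cnvtriage.sim import simulate_trio_ratios


class TestCallState:
    def test_consistent_loss(self):
        assert call_state([0.48, 0.52, 0.55]) is CopyState.LOSS

    def test_consistent_normal(self):
        assert call_state([1.02, 0.98, 1.01]) is CopyState.NORMAL

    def test_consistent_gain(self):
        assert call_state([1.48, 1.55, 1.39]) is CopyState.GAIN

    def test_majority_two_of_three(self):
        assert call_state([0.5, 0.52, 1.0]) is CopyState.LOSS

    def test_tie_is_unconfirmed(self):
        with pytest.raises(UnconfirmedCnvError):
            call_state([0.5, 1.5], config=SegregationConfig(min_consistent=1))

    def test_single_locus_below_min_consistent(self):
        with pytest.raises(UnconfirmedCnvError):
            call_state([0.5])

    def test_no_loci_rejected(self):
        with pytest.raises(UnconfirmedCnvError):
            call_state([])

    def test_male_x_hemizygous_duplication_is_gain(self):
        # 2 copies against a 1-copy male X reference: ratio 1.0 on the
        # two-copy scale, doubled to 2.0 after reference normalization
        assert call_state([1.0, 1.02, 0.98], sex=Sex.MALE, chrom="X") \
            is CopyState.GAIN

    def test_female_x_carrier_duplication_is_gain(self):
        assert call_state([1.5, 1.48, 1.52], sex=Sex.FEMALE, chrom="X") \
            is CopyState.GAIN

    def test_male_autosome_not_rescaled(self):
        assert call_state([1.0, 1.0, 1.0], sex=Sex.MALE, chrom="1") \
            is CopyState.NORMAL

    def test_state_recovery_under_noise(self):
        """>=99% of simulated persons recover their true state at
        Gaussian ratio noise sd=0.08."""
        rng = np.random.default_rng(11)
        truth_ratio = {CopyState.LOSS: 0.5, CopyState.NORMAL: 1.0,
                       CopyState.GAIN: 1.5}
        correct = total = 0
        for _ in range(500):
            truth = [CopyState.LOSS, CopyState.NORMAL, CopyState.GAIN][
                int(rng.integers(0, 3))]
            ratios = list(rng.normal(truth_ratio[truth], 0.08, size=3))
            total += 1
            try:
                correct += call_state(ratios) is truth
            except UnconfirmedCnvError:
                pass
        assert correct / total >= 0.99


class TestSegregate:
    def test_paper_style_verdicts(self):
        # maternally transmitted duplication
        assert segregate(CopyState.GAIN, CopyState.GAIN, CopyState.NORMAL) \
            is InheritanceVerdict.MATERNAL
        # de novo deletion
        assert segregate(CopyState.LOSS, CopyState.NORMAL, CopyState.NORMAL) \
            is InheritanceVerdict.DE_NOVO
        # father normal, mother unavailable
        assert segregate(CopyState.LOSS, CopyState.MISSING, CopyState.NORMAL) \
            is InheritanceVerdict.PATERNAL_EXCLUDED

    def test_unconfirmed_fetal_state_rejected(self):
        for state in (CopyState.NORMAL, CopyState.MISSING):
            with pytest.raises(UnconfirmedCnvError):
                segregate(state, CopyState.NORMAL, CopyState.NORMAL)

    @pytest.mark.parametrize("fetus", [CopyState.LOSS, CopyState.GAIN])
    def test_exhaustive_parent_grid(self, fetus):
        """segregate is total and deterministic over all 16 parental
        combinations, and the verdict logic matches a literal table."""
        states = [CopyState.LOSS, CopyState.NORMAL, CopyState.GAIN,
                  CopyState.MISSING]
        for mother, father in itertools.product(states, states):
            verdict = segregate(fetus, mother, father)
            m_carrier, f_carrier = mother == fetus, father == fetus
            m_missing = mother is CopyState.MISSING
            f_missing = father is CopyState.MISSING
            if m_carrier and f_carrier:
                expected = InheritanceVerdict.BIPARENTAL
            elif m_carrier:
                expected = InheritanceVerdict.MATERNAL
            elif f_carrier:
                expected = InheritanceVerdict.PATERNAL
            elif m_missing and f_missing:
                expected = InheritanceVerdict.NOT_TESTED
            elif m_missing:
                expected = InheritanceVerdict.PATERNAL_EXCLUDED
            elif f_missing:
                expected = InheritanceVerdict.MATERNAL_EXCLUDED
            else:
                expected = InheritanceVerdict.DE_NOVO
            assert verdict is expected
            # repeat call: deterministic
            assert segregate(fetus, mother, father) is verdict


def _measurements(call, ratios_by_person):
    out = []
    for person, ratios in ratios_by_person.items():
        for i, r in enumerate(ratios):
            out.append(TrioMeasurement(call.call_id, person, f"L{i}", r))
    return out


class TestAnalyzeTrio:
    def make_call(self, cnv_type=CnvType.DEL, chrom="1"):
        return CnvCall("f1", GenomicInterval(chrom, 1000, 2000), cnv_type,
                       50.0, 10)

    def test_de_novo_deletion(self):
        c = self.make_call()
        res = analyze_trio(c, _measurements(c, {
            Person.FETUS: [0.5, 0.52, 0.49],
            Person.MOTHER: [1.0, 0.99, 1.01],
            Person.FATHER: [1.02, 1.0, 0.97],
        }))
        assert res.confirmed
        assert res.verdict is InheritanceVerdict.DE_NOVO

    def test_absent_parents_not_tested(self):
        c = self.make_call()
        res = analyze_trio(c, _measurements(c, {
            Person.FETUS: [0.5, 0.52, 0.49],
        }))
        assert res.confirmed
        assert res.verdict is InheritanceVerdict.NOT_TESTED

    def test_fetal_state_mismatch_unconfirmed(self):
        """A deletion whose fetal ratios look normal is not confirmed and
        receives no inheritance verdict."""
        c = self.make_call()
        res = analyze_trio(c, _measurements(c, {
            Person.FETUS: [1.0, 1.01, 0.99],
            Person.MOTHER: [1.0, 1.0, 1.0],
            Person.FATHER: [1.0, 1.0, 1.0],
        }))
        assert not res.confirmed
        assert res.verdict is InheritanceVerdict.NOT_TESTED

    def test_maternal_x_duplication_in_male_fetus(self):
        """Carrier mother (3 of 2 copies) and hemizygous male fetus
        (2 of 1 copy) are both gains after reference normalization."""
        c = self.make_call(cnv_type=CnvType.DUP, chrom="X")
        res = analyze_trio(c, _measurements(c, {
            Person.FETUS: [1.0, 1.02, 0.98],    # 2 copies / male X
            Person.MOTHER: [1.5, 1.51, 1.47],   # 3 copies / female X
            Person.FATHER: [0.5, 0.49, 0.51],   # 1 copy  / male X
        }), fetus_sex=Sex.MALE)
        assert res.confirmed
        assert res.verdict is InheritanceVerdict.MATERNAL

    def test_foreign_measurement_rejected(self):
        c = self.make_call()
        bad = [TrioMeasurement("other_cnv", Person.FETUS, "L0", 0.5)]
        with pytest.raises(ValueError):
            analyze_trio(c, bad)


@pytest.mark.parametrize("sd, min_accuracy", [(0.0, 1.0), (0.1, 0.95)])
def test_end_to_end_inheritance_recovery(sd, min_accuracy):
    """Over 500 simulated trios, the verdict matches the planted
    inheritance label: perfectly with noiseless ratios, >=95% at sd=0.1."""
    panels = simulate_trio_ratios(500, ratio_noise_sd=sd, seed=123)
    correct = 0
    for label, cnv_type, ratios in panels:
        c = CnvCall("f", GenomicInterval("1", 1000, 2000), cnv_type, 50.0, 10)
        res = analyze_trio(c, _measurements(c, {
            p: ratios[p] for p in Person
        }))
        got = res.verdict.value.lower() if res.confirmed else "unconfirmed"
        correct += got == label
    assert correct / 500 >= min_accuracy
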