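"""Segregation cells, phenocopy/presymptomatic rules, verdicts, pooling."""

import dataclasses
import random

import pytest

from famseg.core_model import Affection, Genotype, StudyConfig
from famseg.segregation import (
    Verdict,
    aggregate_segregation,
    flag_phenocopies,
    flag_presymptomatic,
    segregate_family,
    summarize_family_carriers,
)
from famseg.synthetic_data import SimulationConfig, simulate_families


def _family(pedigrees, family_id):
    return next(f for f in pedigrees if f.family_id == family_id)


def brute_force_cells(family, variant_key):
    """Independent recount: iterate raw members and tally each cell."""
    counts = {"ac": 0, "anc": 0, "uc": 0, "unc": 0}
    for m in family.members:
        gt = m.genotypes.get(variant_key)
        if gt is None or gt is Genotype.UNTYPED:
            continue
        if m.affection is Affection.AFFECTED:
            counts["ac" if gt is Genotype.CARRIER else "anc"] += 1
        elif m.affection is Affection.UNAFFECTED:
            counts["uc" if gt is Genotype.CARRIER else "unc"] += 1
    return (counts["ac"], counts["anc"], counts["uc"], counts["unc"])


class TestSummaries:
    def test_grn_g515a_family_cells_and_means(self, reference_pedigrees):
        fam = _family(reference_pedigrees, "F_G515A_1")
        s = summarize_family_carriers(fam, "GRN:G515A")
        assert s.counts == (3, 0, 0, 1)
        assert s.aff_carrier_aao_mean == pytest.approx(80.0)
        assert s.unaff_noncarrier_age_mean == pytest.approx(66.0)

    def test_fully_untyped_family_counts_zero(self, reference_pedigrees):
        fam = _family(reference_pedigrees, "F_G515A_1")
        s = summarize_family_carriers(fam, "PSEN2:R62H")  # nobody typed
        assert s.counts == (0, 0, 0, 0)

    def test_counts_match_brute_force_recount_on_simulation(self):
        fams, _ = simulate_families(
            SimulationConfig(n_families=200, genotyping_completeness=0.8, seed=11)
        )
        key = SimulationConfig().causal_variant
        for fam in fams:
            s = summarize_family_carriers(fam, key)
            assert s.counts == brute_force_cells(fam, key)

    def test_single_carrier_sd_is_absent(self, reference_pedigrees):
        fam = _family(reference_pedigrees, "F_R493X_1")
        s = summarize_family_carriers(fam, "GRN:R493X")
        assert s.n_affected_carriers == 1
        assert s.aff_carrier_aao_sd is None


class TestPhenocopyRule:
    def test_psen1_a79v_late_onset_noncarrier_flagged(self, reference_pedigrees):
        fam = _family(reference_pedigrees, "F_A79V_1")
        ids, applicable = flag_phenocopies(fam, "PSEN1:A79V")
        assert applicable
        flagged = [m for m in fam.members if m.individual_id in ids]
        assert len(flagged) == 1 and flagged[0].age_onset == 77

    def test_grn_splice_noncarrier_at_74_flagged(self, reference_pedigrees):
        fam = _family(reference_pedigrees, "F_1414_1")
        ids, applicable = flag_phenocopies(fam, "GRN:c.1414-1G>T")
        assert applicable
        assert len(ids) == 1
        (m,) = [m for m in fam.members if m.individual_id in ids]
        assert m.age_onset == 74

    def test_onset_equal_to_carrier_mean_is_not_flagged(self, reference_pedigrees):
        fam = _family(reference_pedigrees, "F_G515A_1")
        clone = dataclasses.replace(fam)
        noncarrier = dataclasses.replace(
            fam.members[0],
            individual_id="extra",
            affection=Affection.AFFECTED,
            age_onset=80.0,  # exactly the carrier mean
            genotypes={"GRN:G515A": Genotype.NONCARRIER},
            is_proband=False,
        )
        clone.members = fam.members + [noncarrier]
        ids, _ = flag_phenocopies(clone, "GRN:G515A")
        assert ids == []

    def test_rule_inapplicable_without_affected_carriers(self, reference_pedigrees):
        fam = _family(reference_pedigrees, "F_G515A_1")
        ids, applicable = flag_phenocopies(fam, "PSEN2:R62H")
        assert ids == [] and not applicable


class TestPresymptomaticRule:
    def test_mapt_g201s_both_young_carriers_flagged(self, reference_pedigrees):
        fam = _family(reference_pedigrees, "F_G201S_1")
        ids, applicable = flag_presymptomatic(fam, "MAPT:G201S")
        assert applicable and len(ids) == 2
        ages = sorted(
            m.age_last_exam for m in fam.members if m.individual_id in ids
        )
        assert ages == [57, 65]

    def test_carrier_older_than_every_onset_not_flagged(self, reference_pedigrees):
        fam = _family(reference_pedigrees, "F_G201S_1")
        clone = dataclasses.replace(fam)
        elderly = dataclasses.replace(
            fam.members[0],
            individual_id="old_carrier",
            affection=Affection.UNAFFECTED,
            age_onset=None,
            age_last_exam=90.0,
            genotypes={"MAPT:G201S": Genotype.CARRIER},
            is_proband=False,
        )
        clone.members = fam.members + [elderly]
        ids, _ = flag_presymptomatic(clone, "MAPT:G201S")
        assert "old_carrier" not in ids

    def test_a79v_family_all_three_unaffected_carriers_flagged(
        self, reference_pedigrees
    ):
        fam = _family(reference_pedigrees, "F_A79V_1")
        ids, _ = flag_presymptomatic(fam, "PSEN1:A79V")
        assert len(ids) == 3


class TestVerdicts:
    @pytest.mark.parametrize(
        "family_id,variant,expected",
        [
            ("F_G206A_1", "PSEN1:G206A", Verdict.PERFECT),
            ("F_A79V_1", "PSEN1:A79V", Verdict.COMPATIBLE_WITH_PHENOCOPY),
            ("F_G322A_1", "APP:G322A", Verdict.NON_SEGREGATING),
            ("F_R493X_1", "GRN:R493X", Verdict.COMPATIBLE_WITH_PHENOCOPY),
            ("F_N660Y_1", "APP:N660Y", Verdict.PERFECT),
        ],
    )
    def test_reference_family_verdicts(
        self, reference_pedigrees, family_id, variant, expected
    ):
        fam = _family(reference_pedigrees, family_id)
        assert segregate_family(fam, variant).verdict is expected

    def test_below_min_informative_is_uninformative(self, reference_pedigrees):
        fam = _family(reference_pedigrees, "F_R493X_1")
        cfg = StudyConfig(min_informative=5)
        assert segregate_family(fam, "GRN:R493X", cfg).verdict is (
            Verdict.UNINFORMATIVE
        )

    def test_verdict_invariant_under_member_permutation(self, reference_pedigrees):
        rng = random.Random(3)
        for fam in reference_pedigrees:
            key = next(iter(fam.members[0].genotypes))
            base = segregate_family(fam, key)
            shuffled = dataclasses.replace(fam)
            shuffled.members = list(fam.members)
            rng.shuffle(shuffled.members)
            again = segregate_family(shuffled, key)
            assert again.verdict is base.verdict
            assert again.counts == base.counts
            assert sorted(again.phenocopy_ids) == sorted(base.phenocopy_ids)

    def test_perfect_implies_no_phenocopies(self, reference_pedigrees):
        for fam in reference_pedigrees:
            key = next(iter(fam.members[0].genotypes))
            s = segregate_family(fam, key)
            if s.verdict is Verdict.PERFECT:
                assert s.phenocopy_ids == []
            if s.verdict is Verdict.COMPATIBLE_WITH_PHENOCOPY:
                assert s.phenocopy_ids or s.presymptomatic_ids

    def test_raising_phenocopy_margin_is_monotone(self, reference_pedigrees):
        order = {
            Verdict.PERFECT: 0,
            Verdict.COMPATIBLE_WITH_PHENOCOPY: 1,
            Verdict.NON_SEGREGATING: 2,
        }
        for fam in reference_pedigrees:
            key = next(iter(fam.members[0].genotypes))
            prev = None
            for margin in (0.0, 2.0, 5.0, 20.0):
                v = segregate_family(
                    fam, key, StudyConfig(phenocopy_margin=margin)
                ).verdict
                if v is Verdict.UNINFORMATIVE:
                    continue
                if prev is not None:
                    assert order[v] >= order[prev]
                prev = v


class TestAggregation:
    def test_a79v_pooled_counts_across_four_families(self, reference_pedigrees):
        pooled, per_family = aggregate_segregation(
            reference_pedigrees, "PSEN1:A79V"
        )
        assert len(per_family) == 4
        assert pooled.counts == (10, 1, 3, 13)
        assert pooled.aff_carrier_aao_mean == pytest.approx(68.9)
        assert pooled.aff_carrier_aao_sd == pytest.approx(8.5, abs=0.1)

    def test_single_family_pooling_is_identity(self, reference_pedigrees):
        fam = _family(reference_pedigrees, "F_G515A_1")
        pooled, per_family = aggregate_segregation([fam], "GRN:G515A")
        assert pooled.counts == per_family[0].counts
        assert pooled.aff_carrier_aao_mean == per_family[0].aff_carrier_aao_mean

    def test_pooled_counts_are_additive_over_families(self):
        fams, _ = simulate_families(SimulationConfig(n_families=20, seed=21))
        key = SimulationConfig().causal_variant
        pooled, per_family = aggregate_segregation(fams, key)
        for i in range(4):
            assert pooled.counts[i] == sum(s.counts[i] for s in per_family)

    def test_absent_variant_yields_empty_pooled_summary(self, reference_pedigrees):
        pooled, per_family = aggregate_segregation(
            reference_pedigrees, "APP:Z999Z"
        )
        assert per_family == []
        assert pooled.counts == (0, 0, 0, 0)
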