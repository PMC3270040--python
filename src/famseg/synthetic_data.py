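"""Gene-dropping simulator for multiplex late-onset AD families.

The generator emulates the ascertainment of the reference cohort: families
reported to contain four or more demented relatives, with family mean onset
above 60 y, a dominantly transmitted causal variant of incomplete
age-dependent penetrance, background phenocopies among non-carriers, and
right-censored unaffected relatives.  Every family comes with a truth
record (carrier ids, parameters), so segregation, classification and
burden stages can be validated against known ground truth.

Model
-----
* Pedigree topology: two founders, a sibship of children (uniform size),
  married-in spouses, and one generation of grandchildren.  One founder
  introduces the causal allele; transmission is Mendelian (probability 1/2
  per meiosis), and married-in spouses are non-carriers.
* Affection: a carrier examined at age *a* is affected with probability
  ``sigmoid((a - loc) / scale)`` (age-dependent penetrance; defaults
  loc=72, scale=5, i.e. ~93% penetrant by 85).  Non-carriers become
  affected (phenocopies) at a configurable expected rate per family.
* Ages at onset are drawn from a family-centred normal: the family mean
  is itself normal (matching the reference cohort's family-mean
  distribution), individual onsets scatter around it, and each APOE4
  allele shifts onset earlier (centred so the marginal mean is
  preserved).  Onsets are truncated to the cohort's observed range.
* Affected individuals record an onset age; unaffected individuals record
  only a censoring age (uniform by generation), so no record is
  internally inconsistent.

The number of *reported* affected relatives is drawn from the reference
cohort's family-size histogram and may exceed the number of simulated
(sampled) affected members, exactly as family-history reports do.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .core_model import (
    Affection,
    CohortCount,
    CohortRole,
    Family,
    Genotype,
    Individual,
    Sex,
    StudyConfig,
    VariantEvidence,
)

__all__ = [
    "SimulationConfig",
    "FAMILY_SIZE_HISTOGRAM",
    "simulate_families",
    "simulate_control_cohort",
    "recovery_experiment",
]

# Reference-cohort distribution of reported affected individuals per family
# (439 families; more than half report 4 or 5 affected).
FAMILY_SIZE_HISTOGRAM: dict[int, int] = {
    28: 1, 20: 2, 19: 1, 17: 1, 16: 1, 15: 1, 14: 1, 13: 5, 12: 3, 11: 4,
    10: 13, 9: 14, 8: 27, 7: 32, 6: 54, 5: 107, 4: 172,
}


@dataclass
class SimulationConfig:
    """Generative parameters; defaults mirror the reference cohort."""

    n_families: int = 50
    affected_count_histogram: dict[int, int] = field(
        default_factory=lambda: dict(FAMILY_SIZE_HISTOGRAM)
    )
    family_mean_onset_mean: float = 72.80  # years
    family_mean_onset_sd: float = 5.62
    family_mean_onset_range: tuple[float, float] = (60.0, 89.0)
    within_family_aao_sd: float = 6.2  # sqrt(8.37^2 - 5.62^2): individual scatter
    aao_range: tuple[float, float] = (30.0, 92.0)
    penetrance_location: float = 72.0  # years; ~93% of carriers affected by 85
    penetrance_scale: float = 5.0
    phenocopy_rate: float = 0.05  # expected affected non-carriers per family
    genotyping_completeness: float = 1.0
    censor_age_range: tuple[float, float] = (55.0, 85.0)
    sibship_range: tuple[int, int] = (2, 6)
    causal_variant: str = "GENE1:M1V"
    prob_family_causal: float = 1.0
    apoe4_allele_freq: float = 0.7213  # allele frequency in familial cases
    apoe4_onset_shift: float = 3.0  # years earlier per epsilon-4 allele
    # case/control contrast for burden recovery experiments
    burden_case_freq: float = 0.064
    burden_control_freq: float = 0.030
    burden_n_case: int = 439
    burden_n_control: int = 12481
    seed: int = 0

    def penetrance(self, age: float, apoe4_dose: int = 0) -> float:
        """P(affected by ``age``) for a carrier."""
        shift = self.apoe4_onset_shift * (apoe4_dose - 2 * self.apoe4_allele_freq)
        x = (age - (self.penetrance_location + shift)) / self.penetrance_scale
        return 1.0 / (1.0 + math.exp(-x))


def _truncated_normal(
    rng: np.random.Generator, loc: float, scale: float, lo: float, hi: float
) -> float:
    for _ in range(200):
        v = rng.normal(loc, scale)
        if lo <= v <= hi:
            return float(v)
    return float(min(max(loc, lo), hi))


def _draw_onset(
    rng: np.random.Generator, cfg: SimulationConfig, fam_mean: float, dose: int
) -> float:
    # centring the APOE4 shift on its expected dose keeps the marginal mean
    center = fam_mean - cfg.apoe4_onset_shift * (dose - 2 * cfg.apoe4_allele_freq)
    return _truncated_normal(
        rng, center, cfg.within_family_aao_sd, *cfg.aao_range
    )


def _simulate_one_family(
    rng: np.random.Generator, cfg: SimulationConfig, family_id: str, causal: bool
) -> tuple[Family, dict] | None:
    key = cfg.causal_variant
    fam_mean = _truncated_normal(
        rng,
        cfg.family_mean_onset_mean,
        cfg.family_mean_onset_sd,
        *cfg.family_mean_onset_range,
    )
    lo_sib, hi_sib = cfg.sibship_range

    members: list[Individual] = []
    carrier: dict[str, bool] = {}
    exam_age: dict[str, float] = {}
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"{family_id}_{counter[0]:02d}"

    def add(person_id, father, mother, sex, is_carrier, age):
        carrier[person_id] = is_carrier
        exam_age[person_id] = age
        alleles = tuple(
            4 if rng.random() < cfg.apoe4_allele_freq else rng.choice((2, 3, 3, 3))
            for _ in range(2)
        )
        ind = Individual(
            individual_id=person_id,
            family_id=family_id,
            father_id=father,
            mother_id=mother,
            sex=sex,
            apoe=(int(alleles[0]), int(alleles[1])),
        )
        members.append(ind)
        return ind

    f1 = add(new_id(), None, None, Sex.MALE, causal, rng.uniform(75, 95))
    f2 = add(new_id(), None, None, Sex.FEMALE, False, rng.uniform(75, 95))
    n_children = int(rng.integers(lo_sib, hi_sib + 1))
    for _ in range(n_children):
        child_sex = Sex.MALE if rng.random() < 0.5 else Sex.FEMALE
        inherits = carrier[f1.individual_id] and rng.random() < 0.5
        child = add(
            new_id(), f1.individual_id, f2.individual_id, child_sex,
            inherits, rng.uniform(*cfg.censor_age_range),
        )
        spouse = add(
            new_id(), None, None,
            Sex.FEMALE if child_sex is Sex.MALE else Sex.MALE,
            False, rng.uniform(*cfg.censor_age_range),
        )
        n_grand = int(rng.integers(lo_sib, hi_sib + 1))
        for _ in range(n_grand):
            g_inherits = carrier[child.individual_id] and rng.random() < 0.5
            father, mother = (
                (child, spouse) if child.sex is Sex.MALE else (spouse, child)
            )
            add(
                new_id(), father.individual_id, mother.individual_id,
                Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
                g_inherits, rng.uniform(35, 60),
            )

    # affection: age-dependent penetrance for carriers
    for m in members:
        if carrier[m.individual_id]:
            p = cfg.penetrance(exam_age[m.individual_id], m.apoe4_dose or 0)
            if rng.random() < p:
                m.affection = Affection.AFFECTED
                m.age_onset = _draw_onset(rng, cfg, fam_mean, m.apoe4_dose or 0)

    # phenocopies: expected `phenocopy_rate` affected non-carriers per family
    non_carrier_adults = [
        m for m in members
        if not carrier[m.individual_id]
        and m.affection is not Affection.AFFECTED
        and exam_age[m.individual_id] >= 55
    ]
    n_pheno = min(int(rng.poisson(cfg.phenocopy_rate)), len(non_carrier_adults))
    if n_pheno:
        for idx in rng.choice(len(non_carrier_adults), n_pheno, replace=False):
            m = non_carrier_adults[int(idx)]
            m.affection = Affection.AFFECTED
            m.age_onset = _draw_onset(rng, cfg, fam_mean, m.apoe4_dose or 0)

    affected = [m for m in members if m.affection is Affection.AFFECTED]
    if not affected:
        return None  # multiplex ascertainment: regenerate

    for m in members:
        if m.affection is not Affection.AFFECTED:
            m.affection = Affection.UNAFFECTED
            # the censoring age is the same exam age that penetrance saw,
            # so presymptomatic carriers stay internally consistent
            m.age_last_exam = round(exam_age[m.individual_id], 1)
        else:
            m.age_onset = round(m.age_onset, 1)

    # genotyping (carrier truth recorded only for genotyped members)
    for m in members:
        if rng.random() < cfg.genotyping_completeness:
            m.genotypes[key] = (
                Genotype.CARRIER if carrier[m.individual_id] else Genotype.NONCARRIER
            )

    # proband: youngest affected member
    proband = min(affected, key=lambda m: m.age_onset)
    proband.is_proband = True

    hist = cfg.affected_count_histogram
    sizes = np.array(sorted(hist), dtype=int)
    weights = np.array([hist[s] for s in sizes], dtype=float)
    reported = int(rng.choice(sizes, p=weights / weights.sum()))
    fam = Family(
        family_id=family_id,
        members=members,
        n_affected_reported=max(reported, len(affected)),
        mean_onset_family=round(
            sum(m.age_onset for m in affected) / len(affected), 2
        ),
    )
    truth = {
        "family_id": family_id,
        "causal": causal,
        "variant_key": key,
        "carrier_ids": sorted(
            m.individual_id for m in members if carrier[m.individual_id]
        ),
        "phenocopy_ids": sorted(
            m.individual_id
            for m in members
            if m.affection is Affection.AFFECTED and not carrier[m.individual_id]
        ),
        "family_mean_onset": fam_mean,
    }
    return fam, truth


def simulate_families(
    config: SimulationConfig, seed: int | None = None
) -> tuple[list[Family], dict]:
    """Generate ``config.n_families`` multiplex families plus ground truth.

    Identical config and seed give identical output.  A family draw that
    produces no affected member (possible under weak penetrance) is
    regenerated, up to a bounded number of attempts.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    families: list[Family] = []
    truths: list[dict] = []
    for i in range(config.n_families):
        causal = bool(rng.random() < config.prob_family_causal)
        fam = None
        for _attempt in range(50):
            fam = _simulate_one_family(rng, config, f"SIM{i + 1:04d}", causal)
            if fam is not None:
                break
        if fam is None:
            raise RuntimeError(
                f"family {i}: no affected members after bounded resampling; "
                "penetrance/phenocopy configuration too weak"
            )
        families.append(fam[0])
        truths.append(fam[1])
    truth = {
        "families": truths,
        "parameters": {
            "penetrance_location": config.penetrance_location,
            "penetrance_scale": config.penetrance_scale,
            "phenocopy_rate": config.phenocopy_rate,
            "causal_variant": config.causal_variant,
        },
    }
    return families, truth


def simulate_control_cohort(
    n: int,
    carrier_freq: float,
    seed: int,
    cohort_name: str = "controls",
    role: CohortRole = CohortRole.CONTROL,
) -> CohortCount:
    """Binomial draw of carrier counts for an external cohort."""
    if not 0 <= carrier_freq <= 1:
        raise ValueError("carrier_freq must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    carriers = int(rng.binomial(n, carrier_freq))
    return CohortCount(
        cohort_name=cohort_name, carriers=carriers, n_total=n, role=role
    )


def recovery_experiment(
    config: SimulationConfig,
    n_replicates: int,
    seed: int | None = None,
    study_config: StudyConfig | None = None,
    n_classification_families: int = 100,
) -> dict:
    """Validation harness: burden OR recovery, null type-I error, and a
    classification confusion matrix against simulated truth.

    Per replicate, case and control carrier counts are drawn binomially at
    the configured frequencies and summarized by the 2x2 machinery; under
    a null contrast the Fisher rejection rate at alpha=0.05 estimates the
    test's type-I error.  The classification arm simulates causal
    families once, runs segregation and the rule cascade per family, and
    tallies the resulting categories against truth.
    """
    from .burden_stats import odds_ratio_2x2
    from .classification import classify_variant
    from .segregation import segregate_family

    if n_replicates == 0:
        return {}
    rng = np.random.default_rng(config.seed if seed is None else seed)
    study_config = study_config or StudyConfig()

    ors: list[float] = []
    rejections = 0
    for _ in range(n_replicates):
        a = int(rng.binomial(config.burden_n_case, config.burden_case_freq))
        c = int(rng.binomial(config.burden_n_control, config.burden_control_freq))
        res = odds_ratio_2x2(
            a, config.burden_n_case - a, c, config.burden_n_control - c,
            study_config,
        )
        if math.isfinite(res.odds_ratio):
            ors.append(res.odds_ratio)
        if res.p_fisher < 0.05:
            rejections += 1
    pc, pk = config.burden_case_freq, config.burden_control_freq
    true_or = (
        (pc / (1 - pc)) / (pk / (1 - pk)) if 0 < pk < 1 and 0 < pc < 1 else math.nan
    )

    # classification confusion matrix on simulated causal families
    cls_cfg = replace(
        config,
        n_families=n_classification_families,
        prob_family_causal=1.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    fams, truth = simulate_families(cls_cfg)
    confusion: dict[str, int] = {}
    for fam in fams:
        summary = segregate_family(fam, cls_cfg.causal_variant, study_config)
        ev = VariantEvidence(
            gene="GENE1",
            change=cls_cfg.causal_variant.split(":", 1)[1],
            novelty="novel",
            prediction="probably_damaging",
            cohort_counts=[
                CohortCount("controls", 0, 1346, CohortRole.CONTROL)
            ],
        )
        res = classify_variant(ev, [summary.verdict], study_config)
        confusion[res.category.value] = confusion.get(res.category.value, 0) + 1
    n_informative = sum(
        v for k, v in confusion.items() if k != "UNKNOWN"
    )
    recovered = confusion.get("PATHOGENIC", 0) + confusion.get(
        "LIKELY_PATHOGENIC", 0
    )
    return {
        "burden": {
            "true_or": true_or,
            "median_or": float(np.median(ors)) if ors else math.nan,
            "n_replicates": n_replicates,
        },
        "null_rejection_rate": rejections / n_replicates,
        "is_null_contrast": pc == pk,
        "classification": {
            "confusion": confusion,
            "n_families": len(fams),
            "recovered_causal_fraction": (
                recovered / n_informative if n_informative else math.nan
            ),
        },
    }
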