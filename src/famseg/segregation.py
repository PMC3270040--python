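"""Per-family segregation assessment of a candidate dominant variant.

For one family and one variant, genotyped members with known affection are
partitioned into the four cells affected/unaffected x carrier/non-carrier.
Two rules then excuse apparent failures of dominant segregation:

* **phenocopy** — an affected non-carrier whose age at onset is *later*
  than the mean onset of the family's affected carriers is attributed to
  background (sporadic) disease risk rather than the family variant;
* **presymptomatic carrier** — an unaffected carrier last examined at an
  age *below* the oldest onset observed among affected carriers may simply
  not have reached the family's onset range yet.

The verdict for the family is then

``PERFECT``
    every genotyped affected member carries the variant and every
    unaffected carrier (if any) is excused as presymptomatic;
``COMPATIBLE_WITH_PHENOCOPY``
    every affected non-carrier is a phenocopy and every unaffected carrier
    is presymptomatic;
``NON_SEGREGATING``
    at least one affected non-carrier is not a phenocopy, or an unaffected
    carrier has outlived the family's onset range;
``UNINFORMATIVE``
    fewer than ``config.min_informative`` genotyped affected members.

Both rules are strict inequalities; ``config.phenocopy_margin`` adds an
additive margin to the phenocopy comparison.  With a single affected
carrier its onset serves as both the mean and the maximum.  MCI and
affection-unknown individuals are excluded from every cell (configurable).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .core_model import (
    Affection,
    Family,
    Genotype,
    Individual,
    StudyConfig,
    mean_sd,
)

__all__ = [
    "Verdict",
    "SegregationSummary",
    "summarize_family_carriers",
    "flag_phenocopies",
    "flag_presymptomatic",
    "segregation_verdict",
    "segregate_family",
    "aggregate_segregation",
]


class Verdict(str, enum.Enum):
    PERFECT = "PERFECT"
    COMPATIBLE_WITH_PHENOCOPY = "COMPATIBLE_WITH_PHENOCOPY"
    NON_SEGREGATING = "NON_SEGREGATING"
    UNINFORMATIVE = "UNINFORMATIVE"


@dataclass
class SegregationSummary:
    """Table-4-shaped 2x2 partition for one (family, variant) pair."""

    family_id: str
    variant_key: str
    n_affected_carriers: int = 0
    aff_carrier_aao_mean: float | None = None
    aff_carrier_aao_sd: float | None = None
    n_affected_noncarriers: int = 0
    aff_noncarrier_aao_mean: float | None = None
    aff_noncarrier_aao_sd: float | None = None
    n_unaffected_carriers: int = 0
    unaff_carrier_age_mean: float | None = None
    unaff_carrier_age_sd: float | None = None
    n_unaffected_noncarriers: int = 0
    unaff_noncarrier_age_mean: float | None = None
    unaff_noncarrier_age_sd: float | None = None
    phenocopy_ids: list[str] = field(default_factory=list)
    presymptomatic_ids: list[str] = field(default_factory=list)
    phenocopy_rule_applicable: bool = True
    presymptomatic_rule_applicable: bool = True
    verdict: Verdict | None = None

    @property
    def counts(self) -> tuple[int, int, int, int]:
        """(affected carriers, affected non-carriers, unaffected carriers,
        unaffected non-carriers) — the Table-4 cell order."""
        return (
            self.n_affected_carriers,
            self.n_affected_noncarriers,
            self.n_unaffected_carriers,
            self.n_unaffected_noncarriers,
        )


def _cells(
    family: Family, variant_key: str, config: StudyConfig
) -> tuple[list[Individual], list[Individual], list[Individual], list[Individual]]:
    """Partition genotyped, affection-known members into the four cells."""
    aff_c: list[Individual] = []
    aff_nc: list[Individual] = []
    unaff_c: list[Individual] = []
    unaff_nc: list[Individual] = []
    for m in sorted(family.members, key=lambda x: x.individual_id):
        gt = m.genotype(variant_key)
        if gt is Genotype.UNTYPED:
            continue
        aff = m.affection
        if aff is Affection.MCI and config.include_mci:
            aff = Affection.AFFECTED
        if aff is Affection.AFFECTED:
            (aff_c if gt is Genotype.CARRIER else aff_nc).append(m)
        elif aff is Affection.UNAFFECTED:
            (unaff_c if gt is Genotype.CARRIER else unaff_nc).append(m)
        # MCI (when excluded) and unknown affection fall into no cell
    return aff_c, aff_nc, unaff_c, unaff_nc


def summarize_family_carriers(
    family: Family, variant_key: str, config: StudyConfig | None = None
) -> SegregationSummary:
    """Counts and age summaries over genotyped members; no verdict yet.

    A family with zero genotyped members yields an all-zero summary (which
    the verdict step will call UNINFORMATIVE), not an error.
    """
    config = config or StudyConfig()
    aff_c, aff_nc, unaff_c, unaff_nc = _cells(family, variant_key, config)
    s = SegregationSummary(family_id=family.family_id, variant_key=variant_key)
    s.n_affected_carriers = len(aff_c)
    s.aff_carrier_aao_mean, s.aff_carrier_aao_sd = mean_sd(
        [m.age_onset for m in aff_c]
    )
    s.n_affected_noncarriers = len(aff_nc)
    s.aff_noncarrier_aao_mean, s.aff_noncarrier_aao_sd = mean_sd(
        [m.age_onset for m in aff_nc]
    )
    s.n_unaffected_carriers = len(unaff_c)
    s.unaff_carrier_age_mean, s.unaff_carrier_age_sd = mean_sd(
        [m.age_last_exam for m in unaff_c]
    )
    s.n_unaffected_noncarriers = len(unaff_nc)
    s.unaff_noncarrier_age_mean, s.unaff_noncarrier_age_sd = mean_sd(
        [m.age_last_exam for m in unaff_nc]
    )
    return s


def flag_phenocopies(
    family: Family, variant_key: str, config: StudyConfig | None = None
) -> tuple[list[str], bool]:
    """Affected non-carriers with onset later than the affected carriers'
    mean onset (strict, plus ``phenocopy_margin``).

    Returns ``(ids, applicable)``; the rule is inapplicable (empty list,
    ``False``) when the family has no affected genotyped carrier with an
    onset to anchor the comparison.
    """
    config = config or StudyConfig()
    aff_c, aff_nc, _, _ = _cells(family, variant_key, config)
    onsets = [m.age_onset for m in aff_c if m.age_onset is not None]
    if not onsets:
        return [], False
    mean_onset = sum(onsets) / len(onsets)
    ids = [
        m.individual_id
        for m in aff_nc
        if m.age_onset is not None
        and m.age_onset > mean_onset + config.phenocopy_margin
    ]
    return ids, True


def flag_presymptomatic(
    family: Family, variant_key: str, config: StudyConfig | None = None
) -> tuple[list[str], bool]:
    """Unaffected carriers last examined strictly before the oldest onset
    among the family's affected carriers.

    Returns ``(ids, applicable)`` as for :func:`flag_phenocopies`.
    """
    config = config or StudyConfig()
    aff_c, _, unaff_c, _ = _cells(family, variant_key, config)
    onsets = [m.age_onset for m in aff_c if m.age_onset is not None]
    if not onsets:
        return [], False
    max_onset = max(onsets)
    ids = [
        m.individual_id
        for m in unaff_c
        if m.age_last_exam is not None and m.age_last_exam < max_onset
    ]
    return ids, True


def segregation_verdict(
    summary: SegregationSummary, config: StudyConfig | None = None
) -> Verdict:
    """Total, deterministic verdict from a populated summary."""
    config = config or StudyConfig()
    n_aff_genotyped = summary.n_affected_carriers + summary.n_affected_noncarriers
    if n_aff_genotyped < config.min_informative:
        return Verdict.UNINFORMATIVE
    unexcused_noncarriers = summary.n_affected_noncarriers - len(
        summary.phenocopy_ids
    )
    unexcused_carriers = summary.n_unaffected_carriers - len(
        summary.presymptomatic_ids
    )
    if unexcused_noncarriers > 0 or unexcused_carriers > 0:
        return Verdict.NON_SEGREGATING
    if summary.n_affected_noncarriers == 0:
        return Verdict.PERFECT
    return Verdict.COMPATIBLE_WITH_PHENOCOPY


def segregate_family(
    family: Family, variant_key: str, config: StudyConfig | None = None
) -> SegregationSummary:
    """Full per-family assessment: cells, both flag rules, verdict."""
    config = config or StudyConfig()
    s = summarize_family_carriers(family, variant_key, config)
    s.phenocopy_ids, s.phenocopy_rule_applicable = flag_phenocopies(
        family, variant_key, config
    )
    s.presymptomatic_ids, s.presymptomatic_rule_applicable = flag_presymptomatic(
        family, variant_key, config
    )
    s.verdict = segregation_verdict(s, config)
    return s


def aggregate_segregation(
    families: Iterable[Family],
    variant_key: str,
    config: StudyConfig | None = None,
) -> tuple[SegregationSummary, list[SegregationSummary]]:
    """Pool per-family summaries for one variant across carrier families.

    Counts are summed, means/sds recomputed from the pooled member ages
    (equivalent to n-weighted pooling), and the per-family summaries with
    their verdicts are returned alongside.  A variant absent from every
    family yields an empty pooled summary.
    """
    config = config or StudyConfig()
    carrier_fams = [f for f in families if f.carries(variant_key)]
    per_family = [segregate_family(f, variant_key, config) for f in carrier_fams]
    pooled = SegregationSummary(family_id="pooled", variant_key=variant_key)
    ages: dict[str, list[float]] = {k: [] for k in ("ac", "anc", "uc", "unc")}
    for f in carrier_fams:
        aff_c, aff_nc, unaff_c, unaff_nc = _cells(f, variant_key, config)
        pooled.n_affected_carriers += len(aff_c)
        pooled.n_affected_noncarriers += len(aff_nc)
        pooled.n_unaffected_carriers += len(unaff_c)
        pooled.n_unaffected_noncarriers += len(unaff_nc)
        ages["ac"] += [m.age_onset for m in aff_c if m.age_onset is not None]
        ages["anc"] += [m.age_onset for m in aff_nc if m.age_onset is not None]
        ages["uc"] += [
            m.age_last_exam for m in unaff_c if m.age_last_exam is not None
        ]
        ages["unc"] += [
            m.age_last_exam for m in unaff_nc if m.age_last_exam is not None
        ]
    pooled.aff_carrier_aao_mean, pooled.aff_carrier_aao_sd = mean_sd(ages["ac"])
    pooled.aff_noncarrier_aao_mean, pooled.aff_noncarrier_aao_sd = mean_sd(
        ages["anc"]
    )
    pooled.unaff_carrier_age_mean, pooled.unaff_carrier_age_sd = mean_sd(
        ages["uc"]
    )
    pooled.unaff_noncarrier_age_mean, pooled.unaff_noncarrier_age_sd = mean_sd(
        ages["unc"]
    )
    for s in per_family:
        pooled.phenocopy_ids += s.phenocopy_ids
        pooled.presymptomatic_ids += s.presymptomatic_ids
    return pooled, per_family


def summaries_to_records(
    summaries: Sequence[SegregationSummary],
) -> list[dict[str, object]]:
    """Flatten summaries into report rows (Table-4 cell layout + verdict)."""
    rows = []
    for s in summaries:
        rows.append(
            {
                "family_id": s.family_id,
                "variant_key": s.variant_key,
                "affected_carriers": s.n_affected_carriers,
                "aff_carrier_aao_mean": s.aff_carrier_aao_mean,
                "aff_carrier_aao_sd": s.aff_carrier_aao_sd,
                "affected_noncarriers": s.n_affected_noncarriers,
                "aff_noncarrier_aao_mean": s.aff_noncarrier_aao_mean,
                "aff_noncarrier_aao_sd": s.aff_noncarrier_aao_sd,
                "unaffected_carriers": s.n_unaffected_carriers,
                "unaff_carrier_age_mean": s.unaff_carrier_age_mean,
                "unaff_carrier_age_sd": s.unaff_carrier_age_sd,
                "unaffected_noncarriers": s.n_unaffected_noncarriers,
                "unaff_noncarrier_age_mean": s.unaff_noncarrier_age_mean,
                "unaff_noncarrier_age_sd": s.unaff_noncarrier_age_sd,
                "phenocopies": ";".join(s.phenocopy_ids),
                "presymptomatic": ";".join(s.presymptomatic_ids),
                "verdict": s.verdict.value if s.verdict else "NA",
            }
        )
    return rows
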