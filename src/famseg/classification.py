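"""Four-category pathogenicity classification of rare variants.

Evidence from four sources — prior mutation-database status, per-family
segregation verdicts, carrier screening in non-demented control panels, and
in-silico predictions (missense damage calls, splice-site score loss) — is
combined by a first-match rule cascade:

1. database-pathogenic variants keep that status unless some family shows
   outright non-segregation;
2. a variant segregating in every family (perfectly or up to excused
   phenocopies/presymptomatic carriers), absent from controls, and
   predicted damaging (or losing its splice site) is LIKELY_PATHOGENIC when
   novel and PATHOGENIC when previously reported — this step deliberately
   overrides a prior "not pathogenic" database label, which may reflect
   incomplete penetrance in the earlier report;
3. non-segregation in any family, or any carrier among control-role
   cohorts, makes the variant NOT_PATHOGENIC; when its case frequency
   still exceeds its control frequency it is additionally flagged as a
   candidate risk modifier (an annotation, not a fifth category);
4. anything else — no informative families, no discriminating evidence —
   remains UNKNOWN.

Unselected population panels (screened at ages well below dementia onset)
do not count as controls unless ``config.count_unselected_as_controls``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_model import CohortRole, StudyConfig, VariantEvidence
from .segregation import Verdict

__all__ = [
    "Category",
    "ClassificationResult",
    "classify_variant",
    "tabulate_classes",
    "class_summary_table",
]


class Category(str, enum.Enum):
    PATHOGENIC = "PATHOGENIC"
    LIKELY_PATHOGENIC = "LIKELY_PATHOGENIC"
    NOT_PATHOGENIC = "NOT_PATHOGENIC"
    UNKNOWN = "UNKNOWN"


SEGREGATING = {Verdict.PERFECT, Verdict.COMPATIBLE_WITH_PHENOCOPY}


@dataclass
class ClassificationResult:
    variant_key: str
    category: Category
    provenance: str  # previously_reported | novel
    evidence_notes: list[str] = field(default_factory=list)
    candidate_modifier: bool = False
    n_families: int | None = None  # families carrying the variant, if known


def _control_counts(
    evidence: VariantEvidence, config: StudyConfig
) -> tuple[int, int]:
    roles = [CohortRole.CONTROL]
    if config.count_unselected_as_controls:
        roles.append(CohortRole.UNSELECTED)
    return evidence.carriers_with_role(roles)


def _prediction_supports(evidence: VariantEvidence, config: StudyConfig) -> bool:
    if evidence.prediction in ("probably_damaging", "possibly_damaging"):
        return True
    if evidence.splice_scores is not None:
        wt, mut = evidence.splice_scores
        return wt >= config.splice_wt_min and mut < config.splice_loss
    return False


def classify_variant(
    evidence: VariantEvidence,
    verdicts: Sequence[Verdict],
    config: StudyConfig | None = None,
    n_families: int | None = None,
) -> ClassificationResult:
    """Apply the rule cascade to one variant; first matching rule wins."""
    config = config or StudyConfig()
    notes: list[str] = []
    res = ClassificationResult(
        variant_key=evidence.variant_key,
        category=Category.UNKNOWN,
        provenance=evidence.novelty,
        evidence_notes=notes,
        n_families=n_families if n_families is not None else len(verdicts) or None,
    )
    verdicts = list(verdicts)
    control_carriers, control_n = _control_counts(evidence, config)
    case_carriers, case_n = evidence.carriers_with_role([CohortRole.CASE])
    any_nonseg = Verdict.NON_SEGREGATING in verdicts
    all_segregating = bool(verdicts) and all(v in SEGREGATING for v in verdicts)

    if not verdicts and not evidence.cohort_counts:
        notes.append("no segregation or cohort evidence available")
        return res

    # rule 1: prior database status, unless contradicted by segregation
    if evidence.prior_db_status == "pathogenic" and not any_nonseg:
        notes.append("database-pathogenic, no non-segregating family")
        res.category = Category.PATHOGENIC
        return res

    # rule 2: full segregation + absence from controls + damaging prediction
    if (
        all_segregating
        and control_carriers == 0
        and _prediction_supports(evidence, config)
    ):
        notes.append(
            "segregates in all families, absent from controls, "
            "predicted damaging"
        )
        if evidence.prior_db_status == "not_pathogenic":
            notes.append("prior not-pathogenic label overridden")
        res.category = (
            Category.LIKELY_PATHOGENIC
            if evidence.novelty == "novel"
            else Category.PATHOGENIC
        )
        return res

    # rule 3: clear evidence against causality
    if any_nonseg or control_carriers > 0:
        if any_nonseg:
            notes.append("non-segregating in at least one family")
        if control_carriers > 0:
            notes.append(f"{control_carriers} control carriers")
        res.category = Category.NOT_PATHOGENIC
        if case_n and control_n:
            if case_carriers / case_n > control_carriers / control_n:
                res.candidate_modifier = True
                notes.append("case frequency exceeds control frequency")
        return res

    notes.append("segregation uninformative")
    return res


def tabulate_classes(
    results: Iterable[ClassificationResult],
    families: int | Mapping[str, Sequence[str]],
) -> pd.DataFrame:
    """Tidy class-by-provenance tally: one row per (gene, provenance,
    category) cell with variant (#mut) and family (#fam) counts.

    ``families`` is either the total number of sequenced families (family
    counts then come from each result's ``n_families``) or a mapping
    ``family_id -> [variant_key, ...]`` from which per-variant family
    counts and the deduplicated any-variant family total are derived.
    """
    results = list(results)
    if isinstance(families, int):
        n_total = families
        fam_count = {
            r.variant_key: (r.n_families or 0) for r in results
        }
        n_any = sum(fam_count.values())  # assumes one variant per family
    else:
        n_total = len(families)
        fam_count = {r.variant_key: 0 for r in results}
        n_any = 0
        for _, keys in families.items():
            hit = False
            for k in keys:
                if k in fam_count:
                    fam_count[k] += 1
                    hit = True
            if hit:
                n_any += 1
    rows = []
    for r in results:
        gene = r.variant_key.split(":", 1)[0]
        rows.append(
            {
                "gene": gene,
                "provenance": r.provenance,
                "category": r.category.value,
                "variant_key": r.variant_key,
                "n_fam": fam_count.get(r.variant_key, 0),
            }
        )
    df = pd.DataFrame(
        rows, columns=["gene", "provenance", "category", "variant_key", "n_fam"]
    )
    if df.empty:
        out = pd.DataFrame(
            columns=["gene", "provenance", "category", "n_mut", "n_fam", "pct_fam"]
        )
        out.attrs.update(n_total_families=n_total, n_families_any_variant=0)
        return out
    grouped = (
        df.groupby(["gene", "provenance", "category"], sort=True)
        .agg(n_mut=("variant_key", "nunique"), n_fam=("n_fam", "sum"))
        .reset_index()
    )
    grouped["pct_fam"] = 100.0 * grouped["n_fam"] / n_total
    grouped.attrs.update(
        n_total_families=n_total, n_families_any_variant=n_any
    )
    return grouped


def class_summary_table(
    tally: pd.DataFrame, pct_decimals: int = 1
) -> pd.DataFrame:
    """Wide summary with a totals row: (provenance, category) columns
    carrying ``#mut``/``#fam`` and a recomputed family percentage."""
    n_total = tally.attrs.get("n_total_families", 0)
    if tally.empty:
        return pd.DataFrame()
    wide = tally.pivot_table(
        index="gene",
        columns=["provenance", "category"],
        values=["n_mut", "n_fam"],
        aggfunc="sum",
        fill_value=0,
    )
    totals = wide.sum(axis=0)
    wide.loc["total"] = totals
    pct = {}
    for col in wide.columns:
        if col[0] == "n_fam" and n_total:
            pct[col] = round(100.0 * totals[col] / n_total, pct_decimals)
    wide.attrs["pct_fam_total"] = pct
    wide.attrs["n_total_families"] = n_total
    return wide
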