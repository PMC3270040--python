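"""Domain types, validation and tabular I/O for familial rare-variant analysis.

The central objects are :class:`Individual` and :class:`Family` (a multiplex
pedigree with one sequenced proband), :class:`VariantEvidence` (one rare
variant with its novelty, database status, in-silico predictions and
per-cohort carrier counts) and :class:`StudyConfig` (every tunable threshold
of the downstream rules in one place).

File dialects
-------------
Pedigrees travel as headered TSV whose first six columns follow PED
conventions (``family_id individual_id father_id mother_id sex affection``)
with phenotype extensions: ``age_onset`` (years, affected only),
``age_last_exam`` (years, unaffected), ``diagnosis``, ``apoe`` (two-digit
allele pair, e.g. ``34``), ``proband`` and ``n_affected_reported``.  ``0``
denotes a missing parent and ``NA`` a missing age.  Genotypes for variant
``GENE:CHANGE`` live in a column named ``gt:GENE:CHANGE`` coded ``+``
(carrier), ``-`` (non-carrier) or ``.`` (untyped).

Variant evidence travels as a wide TSV with one row per variant; carrier
counts for cohort *name* with role *role* sit in a column
``count:name:role`` as ``carriers/n_total`` (an empty cell means the cohort
was not screened, which is distinct from ``0/n``).  Percentages are always
recomputed from counts, never read from a file.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "Sex",
    "Affection",
    "Diagnosis",
    "Genotype",
    "CohortRole",
    "Individual",
    "Family",
    "CohortCount",
    "VariantEvidence",
    "StudyConfig",
    "PedigreeError",
    "VariantTableError",
    "read_pedigree_table",
    "write_pedigree_table",
    "read_variant_table",
    "write_variant_table",
    "read_cohort_table",
    "write_report",
]


class PedigreeError(ValueError):
    """Malformed pedigree input (duplicate ids, bad codes, missing ages)."""


class VariantTableError(ValueError):
    """Malformed variant evidence input."""


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Affection(str, enum.Enum):
    AFFECTED = "affected"
    UNAFFECTED = "unaffected"
    MCI = "mci"  # mild cognitive impairment: neither case nor control
    UNKNOWN = "unknown"


class Diagnosis(str, enum.Enum):
    DEFINITE = "definite"
    PROBABLE = "probable"
    POSSIBLE = "possible"
    BY_REPORT = "by_report"
    NONE = "none"


class Genotype(str, enum.Enum):
    CARRIER = "carrier"
    NONCARRIER = "noncarrier"
    UNTYPED = "untyped"


class CohortRole(str, enum.Enum):
    CASE = "case"
    CONTROL = "control"
    UNSELECTED = "unselected"


@dataclass
class Individual:
    """One person in a pedigree.

    ``age_onset`` is required (and must be positive) for affected
    individuals and must be absent for unaffected ones; unaffected
    individuals instead carry ``age_last_exam``, the age at last
    evaluation, used as a right-censoring time.
    """

    individual_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: Sex = Sex.UNKNOWN
    affection: Affection = Affection.UNKNOWN
    age_onset: float | None = None
    age_last_exam: float | None = None
    diagnosis: Diagnosis = Diagnosis.NONE
    apoe: tuple[int, int] | None = None
    genotypes: dict[str, Genotype] = field(default_factory=dict)
    is_proband: bool = False

    def validate(self) -> None:
        if self.affection is Affection.AFFECTED:
            if self.age_onset is None or self.age_onset <= 0:
                raise PedigreeError(
                    f"affected individual {self.individual_id!r} requires a "
                    f"positive age_onset (got {self.age_onset!r})"
                )
        elif self.affection is Affection.UNAFFECTED and self.age_onset is not None:
            raise PedigreeError(
                f"unaffected individual {self.individual_id!r} must not carry "
                f"an age_onset"
            )
        if self.apoe is not None and any(a not in (2, 3, 4) for a in self.apoe):
            raise PedigreeError(
                f"individual {self.individual_id!r}: APOE alleles must be 2/3/4"
            )

    @property
    def apoe4_dose(self) -> int | None:
        """Number of APOE epsilon-4 alleles (0-2), or None if untyped."""
        if self.apoe is None:
            return None
        return sum(1 for a in self.apoe if a == 4)

    def genotype(self, variant_key: str) -> Genotype:
        return self.genotypes.get(variant_key, Genotype.UNTYPED)


@dataclass
class Family:
    """A multiplex pedigree with exactly one sequenced proband.

    ``n_affected_reported`` is the family-history report and may exceed the
    number of affected members with records; ``mean_onset_family`` is the
    family mean age at onset and, when recomputable from members, must agree
    with the mean of the affected members' onsets to 0.1 y.
    """

    family_id: str
    members: list[Individual] = field(default_factory=list)
    n_affected_reported: int | None = None
    mean_onset_family: float | None = None

    def validate(self) -> None:
        ids = [m.individual_id for m in self.members]
        if len(ids) != len(set(ids)):
            raise PedigreeError(
                f"family {self.family_id!r}: duplicate individual ids"
            )
        for m in self.members:
            if m.family_id != self.family_id:
                raise PedigreeError(
                    f"individual {m.individual_id!r} assigned to family "
                    f"{m.family_id!r}, not {self.family_id!r}"
                )
            m.validate()
        n_prob = sum(m.is_proband for m in self.members)
        if n_prob != 1:
            raise PedigreeError(
                f"family {self.family_id!r}: expected exactly one proband, "
                f"found {n_prob}"
            )
        n_aff = sum(m.affection is Affection.AFFECTED for m in self.members)
        if self.n_affected_reported is not None and self.n_affected_reported < n_aff:
            raise PedigreeError(
                f"family {self.family_id!r}: n_affected_reported "
                f"({self.n_affected_reported}) below sampled affected ({n_aff})"
            )
        if self.mean_onset_family is not None:
            onsets = [
                m.age_onset
                for m in self.members
                if m.affection is Affection.AFFECTED and m.age_onset is not None
            ]
            if onsets:
                recomputed = sum(onsets) / len(onsets)
                if abs(recomputed - self.mean_onset_family) > 0.1:
                    raise PedigreeError(
                        f"family {self.family_id!r}: mean_onset_family "
                        f"{self.mean_onset_family} disagrees with members "
                        f"({recomputed:.2f})"
                    )

    @property
    def proband(self) -> Individual:
        for m in self.members:
            if m.is_proband:
                return m
        raise PedigreeError(f"family {self.family_id!r} has no proband")

    def affected(self) -> list[Individual]:
        return [m for m in self.members if m.affection is Affection.AFFECTED]

    def carries(self, variant_key: str) -> bool:
        return any(
            m.genotype(variant_key) is Genotype.CARRIER for m in self.members
        )


@dataclass
class CohortCount:
    """Carrier count for one variant in one named cohort."""

    cohort_name: str
    carriers: int
    n_total: int
    role: CohortRole = CohortRole.CONTROL

    def __post_init__(self) -> None:
        if isinstance(self.role, str):
            self.role = CohortRole(self.role)
        if self.carriers < 0 or self.n_total <= 0:
            raise VariantTableError(
                f"cohort {self.cohort_name!r}: counts must satisfy "
                f"0 <= carriers and n_total > 0"
            )
        if self.carriers > self.n_total:
            raise VariantTableError(
                f"cohort {self.cohort_name!r}: carriers ({self.carriers}) "
                f"exceed n_total ({self.n_total})"
            )

    @property
    def frequency(self) -> float:
        return self.carriers / self.n_total


KNOWN_GENES = ("APP", "PSEN1", "PSEN2", "MAPT", "GRN")


@dataclass
class VariantEvidence:
    """One rare variant and everything known about it outside the pedigrees."""

    gene: str
    change: str
    variant_class_raw: str = "missense"  # missense | nonsense | splice_site
    novelty: str = "novel"  # novel | previously_reported
    prior_db_status: str = "absent"  # pathogenic | not_pathogenic | unknown | absent
    prediction: str = "na"  # probably_damaging | possibly_damaging | benign | na
    splice_scores: tuple[float, float] | None = None  # (wild-type, mutant)
    maf: float = 0.0
    cohort_counts: list[CohortCount] = field(default_factory=list)
    annotations: dict[str, str] = field(default_factory=dict)

    @property
    def variant_key(self) -> str:
        return f"{self.gene}:{self.change}"

    def validate(self, rare_maf_threshold: float = 0.05) -> None:
        if not 0 <= self.maf < 1:
            raise VariantTableError(f"{self.variant_key}: MAF out of range")
        if self.maf >= rare_maf_threshold:
            raise VariantTableError(
                f"{self.variant_key}: MAF {self.maf} is not rare "
                f"(threshold {rare_maf_threshold})"
            )
        names = [c.cohort_name for c in self.cohort_counts]
        if len(names) != len(set(names)):
            raise VariantTableError(
                f"{self.variant_key}: duplicate cohort names"
            )

    def cohort(self, name: str) -> CohortCount | None:
        for c in self.cohort_counts:
            if c.cohort_name == name:
                return c
        return None

    def carriers_with_role(
        self, roles: Iterable[CohortRole | str]
    ) -> tuple[int, int]:
        """Summed (carriers, n_total) over cohorts with any of the roles."""
        roles = {CohortRole(r) for r in roles}
        cs = [c for c in self.cohort_counts if c.role in roles]
        return sum(c.carriers for c in cs), sum(c.n_total for c in cs)


@dataclass
class StudyConfig:
    """All tunable thresholds of the segregation/classification/burden rules.

    Defaults mirror the reference analysis: variants are rare below 5% MAF;
    an affected non-carrier is a phenocopy when its onset exceeds the mean
    onset of the family's affected carriers by more than
    ``phenocopy_margin`` (0 = strict inequality); an unaffected carrier is
    presymptomatic when last examined strictly before the oldest affected
    carrier's onset; families with fewer than ``min_informative`` genotyped
    affected members are uninformative; MCI individuals are excluded from
    segregation cells; unselected panels do not count as controls in the
    classification cascade.
    """

    rare_maf_threshold: float = 0.05
    phenocopy_margin: float = 0.0
    min_informative: int = 2
    include_mci: bool = False
    splice_loss: float = 0.2
    splice_wt_min: float = 0.8
    count_unselected_as_controls: bool = False
    ci_method: str = "woolf"
    primary_test: str = "fisher"
    pct_decimals_table: int = 1
    pct_decimals_text: int = 2
    or_decimals: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rare_maf_threshold <= 0 or self.min_informative < 0:
            raise ValueError("thresholds must be positive")
        if self.phenocopy_margin < 0:
            raise ValueError("phenocopy_margin must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(
            yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        )


# ---------------------------------------------------------------------------
# Pedigree I/O
# ---------------------------------------------------------------------------

PED_CORE = [
    "family_id",
    "individual_id",
    "father_id",
    "mother_id",
    "sex",
    "affection",
]
PED_EXT = [
    "age_onset",
    "age_last_exam",
    "diagnosis",
    "apoe",
    "proband",
    "n_affected_reported",
]

_SEX_IN = {"1": Sex.MALE, "2": Sex.FEMALE, "0": Sex.UNKNOWN, "NA": Sex.UNKNOWN}
_SEX_OUT = {Sex.MALE: "1", Sex.FEMALE: "2", Sex.UNKNOWN: "0"}
_AFF_IN = {
    "2": Affection.AFFECTED,
    "1": Affection.UNAFFECTED,
    "0": Affection.UNKNOWN,
    "-9": Affection.UNKNOWN,
    "mci": Affection.MCI,
}
_AFF_OUT = {
    Affection.AFFECTED: "2",
    Affection.UNAFFECTED: "1",
    Affection.UNKNOWN: "0",
    Affection.MCI: "mci",
}
_GT_IN = {"+": Genotype.CARRIER, "-": Genotype.NONCARRIER, ".": Genotype.UNTYPED}
_GT_OUT = {v: k for k, v in _GT_IN.items()}


def _parse_age(cell: str, row: int, col: str) -> float | None:
    if cell in ("", "NA", "."):
        return None
    try:
        v = float(cell)
    except ValueError as exc:
        raise PedigreeError(f"row {row}: bad {col} value {cell!r}") from exc
    return v


def _fmt_age(v: float | None) -> str:
    if v is None:
        return "NA"
    return format(v, "g")


def read_pedigree_table(path: str | Path, dialect: str = "tsv") -> list[Family]:
    """Read a PED-extended TSV into a list of validated families.

    Raises :class:`PedigreeError` on duplicate ids within a family, unknown
    affection codes, or affected rows missing an age at onset (all offending
    row numbers are listed for the latter).
    """
    if dialect != "tsv":
        raise ValueError(f"unsupported dialect {dialect!r}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in PED_CORE if c not in df.columns]
    if missing:
        raise PedigreeError(f"missing required columns: {missing}")
    gt_cols = [c for c in df.columns if c.startswith("gt:")]

    families: dict[str, Family] = {}
    rows_missing_onset: list[int] = []
    for idx, row in df.iterrows():
        rownum = int(idx) + 2  # 1-based plus header
        aff_code = row["affection"].strip().lower()
        if aff_code not in _AFF_IN:
            raise PedigreeError(
                f"row {rownum}: unknown affection code {row['affection']!r}"
            )
        affection = _AFF_IN[aff_code]
        sex_code = row.get("sex", "0").strip()
        if sex_code not in _SEX_IN:
            raise PedigreeError(f"row {rownum}: unknown sex code {sex_code!r}")
        age_onset = _parse_age(row.get("age_onset", "NA"), rownum, "age_onset")
        if affection is Affection.AFFECTED and age_onset is None:
            rows_missing_onset.append(rownum)
        apoe_cell = str(row.get("apoe", "NA")).strip()
        apoe = None
        if apoe_cell not in ("", "NA", "."):
            if len(apoe_cell) != 2 or not apoe_cell.isdigit():
                raise PedigreeError(f"row {rownum}: bad apoe value {apoe_cell!r}")
            apoe = (int(apoe_cell[0]), int(apoe_cell[1]))
        genotypes = {}
        for col in gt_cols:
            cell = row[col].strip()
            if cell == "":
                cell = "."
            if cell not in _GT_IN:
                raise PedigreeError(
                    f"row {rownum}: bad genotype {cell!r} in column {col}"
                )
            gt = _GT_IN[cell]
            if gt is not Genotype.UNTYPED:
                genotypes[col[3:]] = gt
        ind = Individual(
            individual_id=row["individual_id"].strip(),
            family_id=row["family_id"].strip(),
            father_id=row["father_id"].strip() or None
            if row["father_id"].strip() not in ("0", "") else None,
            mother_id=row["mother_id"].strip() or None
            if row["mother_id"].strip() not in ("0", "") else None,
            sex=_SEX_IN[sex_code],
            affection=affection,
            age_onset=age_onset,
            age_last_exam=_parse_age(
                row.get("age_last_exam", "NA"), rownum, "age_last_exam"
            ),
            diagnosis=Diagnosis(row.get("diagnosis", "none") or "none"),
            apoe=apoe,
            genotypes=genotypes,
            is_proband=str(row.get("proband", "0")).strip() == "1",
        )
        fam = families.setdefault(ind.family_id, Family(family_id=ind.family_id))
        if any(m.individual_id == ind.individual_id for m in fam.members):
            raise PedigreeError(
                f"row {rownum}: duplicate individual id "
                f"{ind.individual_id!r} in family {ind.family_id!r}"
            )
        fam.members.append(ind)
        nrep = str(row.get("n_affected_reported", "NA")).strip()
        if nrep not in ("", "NA", "."):
            fam.n_affected_reported = int(float(nrep))

    if rows_missing_onset:
        raise PedigreeError(
            f"affected rows without age_onset: rows {rows_missing_onset}"
        )
    out = list(families.values())
    for fam in out:
        # parent links must resolve within the family or be absent
        ids = {m.individual_id for m in fam.members}
        for m in fam.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in ids:
                    raise PedigreeError(
                        f"family {fam.family_id!r}: parent {pid!r} of "
                        f"{m.individual_id!r} not in family"
                    )
        fam.validate()
    return out


def write_pedigree_table(families: Sequence[Family], path: str | Path) -> None:
    """Write families in the same dialect ``read_pedigree_table`` accepts."""
    variant_keys = sorted(
        {k for f in families for m in f.members for k in m.genotypes}
    )
    cols = PED_CORE + PED_EXT + [f"gt:{k}" for k in variant_keys]
    rows = []
    for fam in families:
        for m in fam.members:
            row = {
                "family_id": m.family_id,
                "individual_id": m.individual_id,
                "father_id": m.father_id or "0",
                "mother_id": m.mother_id or "0",
                "sex": _SEX_OUT[m.sex],
                "affection": _AFF_OUT[m.affection],
                "age_onset": _fmt_age(m.age_onset),
                "age_last_exam": _fmt_age(m.age_last_exam),
                "diagnosis": m.diagnosis.value,
                "apoe": f"{m.apoe[0]}{m.apoe[1]}" if m.apoe else "NA",
                "proband": "1" if m.is_proband else "0",
                "n_affected_reported": (
                    str(fam.n_affected_reported)
                    if fam.n_affected_reported is not None
                    else "NA"
                ),
            }
            for k in variant_keys:
                row[f"gt:{k}"] = _GT_OUT[m.genotype(k)]
            rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variant evidence I/O
# ---------------------------------------------------------------------------

VARIANT_FIXED = [
    "gene",
    "change",
    "variant_class",
    "novelty",
    "prior_db_status",
    "prediction",
    "splice_wt",
    "splice_mut",
    "maf",
]


def _parse_count_cell(cell: str, key: str, col: str) -> tuple[int, int] | None:
    cell = cell.strip().replace(",", "")
    if cell in ("", "NA", "."):
        return None  # not screened: missing, not zero
    try:
        carriers_s, n_s = cell.split("/")
        return int(carriers_s), int(n_s)
    except ValueError as exc:
        raise VariantTableError(
            f"{key}: malformed count {cell!r} in column {col}"
        ) from exc


def read_variant_table(path: str | Path) -> list[VariantEvidence]:
    """Read a wide variant evidence TSV.

    Unknown gene symbols are retained with a warning note in
    ``annotations['warnings']``; ``carriers > n_total`` is a hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("gene", "change"):
        if col not in df.columns:
            raise VariantTableError(f"missing required column {col!r}")
    count_cols = [c for c in df.columns if c.startswith("count:")]
    extra_cols = [
        c for c in df.columns if c not in VARIANT_FIXED and not c.startswith("count:")
    ]
    out: list[VariantEvidence] = []
    for _, row in df.iterrows():
        gene = row["gene"].strip()
        key = f"{gene}:{row['change'].strip()}"
        splice = None
        if row.get("splice_wt", "").strip() not in ("", "NA"):
            splice = (float(row["splice_wt"]), float(row["splice_mut"]))
        counts = []
        for col in count_cols:
            parsed = _parse_count_cell(row[col], key, col)
            if parsed is None:
                continue
            _, name, role = col.split(":", 2)
            counts.append(
                CohortCount(
                    cohort_name=name,
                    carriers=parsed[0],
                    n_total=parsed[1],
                    role=CohortRole(role),
                )
            )
        ev = VariantEvidence(
            gene=gene,
            change=row["change"].strip(),
            variant_class_raw=row.get("variant_class", "missense") or "missense",
            novelty=row.get("novelty", "novel") or "novel",
            prior_db_status=row.get("prior_db_status", "absent") or "absent",
            prediction=row.get("prediction", "na") or "na",
            splice_scores=splice,
            maf=float(row.get("maf", "0") or 0),
            cohort_counts=counts,
            annotations={c: row[c] for c in extra_cols if row[c].strip() != ""},
        )
        if gene not in KNOWN_GENES:
            ev.annotations.setdefault(
                "warnings", f"unknown gene symbol {gene!r}"
            )
        ev.validate()
        out.append(ev)
    return out


def write_variant_table(variants: Sequence[VariantEvidence], path: str | Path) -> None:
    count_cols = sorted(
        {f"count:{c.cohort_name}:{c.role.value}" for v in variants for c in v.cohort_counts}
    )
    extra_cols = sorted({k for v in variants for k in v.annotations})
    rows = []
    for v in variants:
        row = {
            "gene": v.gene,
            "change": v.change,
            "variant_class": v.variant_class_raw,
            "novelty": v.novelty,
            "prior_db_status": v.prior_db_status,
            "prediction": v.prediction,
            "splice_wt": format(v.splice_scores[0], "g") if v.splice_scores else "NA",
            "splice_mut": format(v.splice_scores[1], "g") if v.splice_scores else "NA",
            "maf": format(v.maf, "g"),
        }
        for col in count_cols:
            _, name, _ = col.split(":", 2)
            c = v.cohort(name)
            row[col] = f"{c.carriers}/{c.n_total}" if c else ""
        for col in extra_cols:
            row[col] = v.annotations.get(col, "")
        rows.append(row)
    pd.DataFrame(rows, columns=VARIANT_FIXED + count_cols + extra_cols).to_csv(
        path, sep="\t", index=False
    )


def read_cohort_table(path: str | Path) -> dict[str, list[CohortCount]]:
    """Read a long-format cohort count TSV.

    Columns: ``variant_key cohort_name role carriers n_total``.  Returns a
    mapping from variant key to its cohort counts.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out: dict[str, list[CohortCount]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["variant_key"], []).append(
            CohortCount(
                cohort_name=row["cohort_name"],
                carriers=int(row["carriers"]),
                n_total=int(row["n_total"]),
                role=CohortRole(row["role"]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------


def write_report(
    results: Sequence[Mapping[str, object]] | pd.DataFrame,
    path: str | Path,
    format: str = "tsv",
) -> None:
    """Serialize a result table with deterministic column order.

    ``results`` is a sequence of dicts (or a DataFrame); the column order of
    the first record wins.  ``format`` is ``tsv`` or ``json``.  Float cells
    are written with ``repr`` precision so TSV round trips are exact.
    """
    if isinstance(results, pd.DataFrame):
        df = results.copy()
    else:
        results = list(results)
        cols: list[str] = []
        for r in results:
            for k in r:
                if k not in cols:
                    cols.append(k)
        df = pd.DataFrame(results, columns=cols)
    path = Path(path)
    if format == "tsv":
        df.to_csv(path, sep="\t", index=False, na_rep="NA")
    elif format == "json":
        records = json.loads(df.to_json(orient="records"))
        path.write_text(json.dumps(records, indent=1, sort_keys=False) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def mean_sd(values: Sequence[float]) -> tuple[float | None, float | None]:
    """Sample mean and sd (ddof=1); sd is None for n < 2, mean None for n=0."""
    vals = [v for v in values if v is not None]
    if not vals:
        return None, None
    m = sum(vals) / len(vals)
    if len(vals) < 2:
        return m, None
    var = sum((v - m) ** 2 for v in vals) / (len(vals) - 1)
    return m, math.sqrt(var)
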