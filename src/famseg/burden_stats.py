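"""Carrier collapsing and 2x2 case-control association statistics.

Rare-variant burden here is the simplest collapsing scheme: carriers of
*any* variant in a filtered set are pooled into a single 2x2 table of
carrier status by case/control status.  The table is summarized by the
cross-product odds ratio with a Woolf (log-OR normal) 95% confidence
interval, a two-sided Fisher exact p-value (primary, because expected
cell counts are small for rare variants) and a Pearson chi-square p-value
without continuity correction (reported alongside).  When any cell is
zero the Haldane-Anscombe +0.5 correction is applied to all four cells
for the OR and CI (flagged in ``method_notes``); the exact p-value never
needs it.  No multiple-testing adjustment is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from scipy import stats

from .core_model import StudyConfig, VariantEvidence

__all__ = [
    "TwoByTwoResult",
    "collapse_carriers",
    "odds_ratio_2x2",
    "odds_ratio_from_freqs",
    "carrier_fraction",
]

Z95 = 1.959963984540054  # normal quantile for a 95% two-sided interval


@dataclass
class TwoByTwoResult:
    a: int  # case carriers
    b: int  # case non-carriers
    c: int  # control carriers
    d: int  # control non-carriers
    odds_ratio: float = math.nan
    ci_low: float = math.nan
    ci_high: float = math.nan
    p_fisher: float = math.nan
    p_chi2: float = math.nan
    method_notes: list[str] = field(default_factory=list)


def collapse_carriers(
    variants: Iterable[VariantEvidence],
    category_filter,
    case_cohorts: Sequence[str],
    control_cohorts: Sequence[str],
) -> tuple[int, int, int, int]:
    """Pool carriers over a variant set: returns (a, n_case, c, n_control).

    ``category_filter`` is a predicate on :class:`VariantEvidence` (or
    ``None`` for all variants).  Carrier counts are summed over the
    selected variants within each named cohort; denominators are the
    cohort sizes (summed over the distinct named cohorts), not sums over
    variants.  A cohort name appearing with two different sizes is a hard
    error.  Each proband is assumed to carry at most one variant in the
    set; overlapping carriage would require individual-level dedup.
    """
    selected = [
        v for v in variants if category_filter is None or category_filter(v)
    ]

    def pool(names: Sequence[str]) -> tuple[int, int]:
        sizes: dict[str, int] = {}
        carriers = 0
        for v in selected:
            for name in names:
                cc = v.cohort(name)
                if cc is None:
                    continue
                if name in sizes and sizes[name] != cc.n_total:
                    raise ValueError(
                        f"cohort {name!r} has inconsistent sizes "
                        f"({sizes[name]} vs {cc.n_total})"
                    )
                sizes[name] = cc.n_total
                carriers += cc.carriers
        return carriers, sum(sizes.values())

    a, n_case = pool(case_cohorts)
    c, n_control = pool(control_cohorts)
    if not selected:
        # empty filter: zero carriers over the full named denominators is
        # only known if the cohorts appear somewhere; report zeros.
        return 0, n_case, 0, n_control
    return a, n_case, c, n_control


def odds_ratio_2x2(
    a: int, b: int, c: int, d: int, config: StudyConfig | None = None
) -> TwoByTwoResult:
    """Cross-product OR with Woolf CI, Fisher exact and chi-square p.

    An all-zero margin (no carriers anywhere, or no cases, ...) leaves the
    OR as NaN with an explanatory note.
    """
    config = config or StudyConfig()
    res = TwoByTwoResult(a=a, b=b, c=c, d=d)
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        res.method_notes.append("degenerate margin: odds ratio undefined")
        if (a + b) and (c + d):
            # table is testable even with an empty carrier margin
            res.p_fisher = 1.0
        return res
    aa, bb, cc, dd = float(a), float(b), float(c), float(d)
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        res.method_notes.append("Haldane-Anscombe +0.5 applied (zero cell)")
    res.odds_ratio = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    res.ci_low = math.exp(math.log(res.odds_ratio) - Z95 * se)
    res.ci_high = math.exp(math.log(res.odds_ratio) + Z95 * se)
    res.method_notes.append("Woolf 95% CI on the log odds ratio")
    _, res.p_fisher = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    try:
        chi2, p_chi2, _, _ = stats.chi2_contingency(
            [[a, b], [c, d]], correction=False
        )
        res.p_chi2 = float(p_chi2)
    except ValueError:
        res.method_notes.append("chi-square undefined for this table")
    return res


def odds_ratio_from_freqs(p_case: float, p_control: float) -> float:
    """Odds ratio from two (carrier or allele) frequencies.

    Boundary frequencies give explicit 0/inf rather than an error.
    """
    for p in (p_case, p_control):
        if not 0 <= p <= 1:
            raise ValueError("frequencies must lie in [0, 1]")
    if p_control in (0.0, 1.0) or p_case in (0.0, 1.0):
        if p_case in (0.0,) or p_control in (1.0,):
            return 0.0
        return math.inf
    return (p_case / (1 - p_case)) / (p_control / (1 - p_control))


def carrier_fraction(carriers: int, n: int, decimals: int = 1) -> float:
    """Percentage 100*carriers/n rounded to ``decimals`` places.

    ``n == 0`` returns NaN (undefined) rather than raising.
    """
    if carriers < 0 or carriers > n:
        raise ValueError("carriers must lie in [0, n]")
    if n == 0:
        return math.nan
    return round(100.0 * carriers / n, decimals)
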