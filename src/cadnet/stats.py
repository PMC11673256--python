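"""Detection rates, sex-stratified odds ratios, and top-k tables.

The detection rate of a term is the percentage of hospitalization records
that contain it, DR = 100 * N_term / N_total. Sex association is measured
by the odds ratio of a 2x2 sex-by-condition table with the
Haldane–Anscombe continuity correction (+0.5 added to every cell) applied
unconditionally, and a Wald confidence interval on the log-odds scale using
the corrected cells. When one sex has zero events the tables report a
sentinel (INF when no affected females exist, ZERO when no affected males)
rather than a finite corrected estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum

from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .records import Category, Cohort, Sex

__all__ = [
    "ContingencyTable2x2",
    "RateEstimate",
    "OrSentinel",
    "OddsRatioResult",
    "StratifiedTable",
    "detection_rate",
    "sex_table",
    "odds_ratio",
    "or_confidence_interval",
    "rate_confidence_interval",
    "age_bin",
    "stratified_top_k",
    "round_half_up",
    "sex_association_table",
    "AGE_BIN_EDGES",
    "EMPTY_MARKER",
]

Z_95 = 1.959964  # norm.ppf(0.975) to the precision used in rendered tables
EMPTY_MARKER = "/"  # padding marker for under-filled top-k strata


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding as used in the rendered tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Sex-by-condition counts: a/b males with/without, c/d females."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_male(self) -> int:
        return self.a + self.b

    @property
    def n_female(self) -> int:
        return self.c + self.d

    def swapped(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class RateEstimate:
    numerator: int
    denominator: int
    rate: float  # percent
    ci_low: float | None = None
    ci_high: float | None = None
    ci_method: str = "none"


class OrSentinel(str, Enum):
    INF = "INF"
    ZERO = "ZERO"
    UNDEFINED = "UNDEFINED"


@dataclass(frozen=True)
class OddsRatioResult:
    estimate: float | OrSentinel
    table: ContingencyTable2x2
    corrected: bool = True
    ci_low: float | None = None
    ci_high: float | None = None

    @property
    def is_finite(self) -> bool:
        return not isinstance(self.estimate, OrSentinel)

    def rendered(self, ndigits: int = 2) -> str:
        if not self.is_finite:
            return self.estimate.value
        return f"{round_half_up(self.estimate, ndigits):.{ndigits}f}"


def detection_rate(
    n_term: int,
    n_total: int,
    ci: bool = False,
    level: float = 0.95,
    ci_method: str = "wilson",
) -> RateEstimate:
    """DR = 100 * n_term / n_total, optionally with a binomial CI."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_term <= n_total:
        raise ValueError("n_term must lie in [0, n_total]")
    rate = 100.0 * n_term / n_total
    if not ci:
        return RateEstimate(n_term, n_total, rate)
    low, high = rate_confidence_interval(n_term, n_total, level=level, method=ci_method)
    return RateEstimate(n_term, n_total, rate, low, high, ci_method)


def rate_confidence_interval(
    numerator: int,
    denominator: int,
    level: float = 0.95,
    method: str = "wilson",
) -> tuple[float, float]:
    """Binomial CI for a detection rate, in percent, clipped to [0, 100]."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if method not in ("wilson", "wald"):
        raise ValueError(f"unknown CI method {method!r}")
    sm_method = "wilson" if method == "wilson" else "normal"
    low, high = proportion_confint(numerator, denominator, alpha=1 - level, method=sm_method)
    low = 0.0 if numerator == 0 else max(0.0, 100.0 * float(low))  # exact at the boundary
    high = 100.0 if numerator == denominator else min(100.0, 100.0 * float(high))
    return (low, high)


def sex_table(cohort: Cohort, term: str, category: Category | str) -> ContingencyTable2x2:
    """Count records with/without the term, split by sex."""
    category = Category(category)
    if term not in cohort.vocabulary(category):
        raise KeyError(f"term {term!r} not in the {category.value} vocabulary")
    a = b = c = d = 0
    for r in cohort:
        has = term in r.terms(category)
        if r.sex is Sex.MALE:
            a, b = a + has, b + (not has)
        else:
            c, d = c + has, d + (not has)
    return ContingencyTable2x2(a, b, c, d)


def odds_ratio(table: ContingencyTable2x2, ci: bool = True, level: float = 0.95) -> OddsRatioResult:
    """Haldane–Anscombe-corrected odds ratio for a sex-by-condition table.

    Sentinels mirror the published table convention: INF when the condition
    is absent in females but present in males, ZERO for the reverse,
    UNDEFINED when absent in both.
    """
    if table.n_male == 0 or table.n_female == 0:
        raise ValueError("both sex margins must be positive")
    if table.a == 0 and table.c == 0:
        return OddsRatioResult(OrSentinel.UNDEFINED, table)
    if table.c == 0:
        return OddsRatioResult(OrSentinel.INF, table)
    if table.a == 0:
        return OddsRatioResult(OrSentinel.ZERO, table)
    a, b, c, d = (table.a + 0.5, table.b + 0.5, table.c + 0.5, table.d + 0.5)
    estimate = (a * d) / (b * c)
    result = OddsRatioResult(estimate, table, corrected=True)
    if ci:
        low, high = or_confidence_interval(result, level=level)
        result = OddsRatioResult(estimate, table, corrected=True, ci_low=low, ci_high=high)
    return result


def or_confidence_interval(result: OddsRatioResult, level: float = 0.95) -> tuple[float, float]:
    """Wald CI on the log scale from the corrected cells."""
    if not result.is_finite:
        raise ValueError(f"no CI for sentinel odds ratio {result.estimate}")
    t = result.table
    a, b, c, d = (t.a + 0.5, t.b + 0.5, t.c + 0.5, t.d + 0.5)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = Z_95 if abs(level - 0.95) < 1e-12 else float(norm.ppf(0.5 + level / 2))
    return (result.estimate * math.exp(-z * se), result.estimate * math.exp(z * se))


def sex_association_table(cohort: Cohort, category: Category | str, top_k: int | None = None):
    """Per-term count, DR, per-sex rates and OR/CI — the top-20 table analogue.

    Returns a list of dict rows ranked by descending count (alphabetical
    tie-break), truncated to ``top_k`` when given.
    """
    import pandas as pd

    category = Category(category)
    n_sex = cohort.n_by_sex()
    n_total = len(cohort)
    rows = []
    for term in sorted(cohort.vocabulary(category)):
        t = sex_table(cohort, term, category)
        count = t.a + t.c
        orr = odds_ratio(t)
        rows.append(
            {
                "term": term,
                "count": count,
                "rate_pct": detection_rate(count, n_total).rate,
                "male_count": t.a,
                "male_rate_pct": 100.0 * t.a / n_sex[Sex.MALE] if n_sex[Sex.MALE] else float("nan"),
                "female_count": t.c,
                "female_rate_pct": 100.0 * t.c / n_sex[Sex.FEMALE] if n_sex[Sex.FEMALE] else float("nan"),
                "odds_ratio": orr.estimate if orr.is_finite else float("nan"),
                "or_rendered": orr.rendered(),
                "ci_low": orr.ci_low,
                "ci_high": orr.ci_high,
            }
        )
    rows.sort(key=lambda r: (-r["count"], r["term"]))
    if top_k is not None:
        rows = rows[:top_k]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stratification

AGE_BIN_EDGES = list(range(30, 100, 10))  # [30,40), ..., [80,90)


def age_bin(age: int) -> str:
    """Decade bin label ("30–39" … "80–89"); out-of-range ages → "other"."""
    if age < 0:
        raise ValueError("age must be non-negative")
    if 30 <= age < 90:
        lo = (age // 10) * 10
        return f"{lo}–{lo + 9}"
    return "other"


@dataclass(frozen=True)
class StratifiedTable:
    stratifier: str  # age_bin | sex | admission_year
    rows: dict  # stratum label -> list of (term, count, rate_pct) or EMPTY_MARKER

    def to_frame(self):
        import pandas as pd

        recs = []
        for stratum, ranked in self.rows.items():
            for rank, entry in enumerate(ranked, start=1):
                if entry == EMPTY_MARKER:
                    recs.append({"stratum": stratum, "rank": rank, "term": EMPTY_MARKER,
                                 "count": None, "rate_pct": None})
                else:
                    term, count, rate = entry
                    recs.append({"stratum": stratum, "rank": rank, "term": term,
                                 "count": count, "rate_pct": rate})
        return pd.DataFrame(recs)


def _stratum_of(record, stratifier: str) -> str:
    if stratifier == "sex":
        return record.sex.value
    if stratifier == "age_bin":
        return age_bin(record.age)
    if stratifier == "admission_year":
        return str(record.admission_year)
    raise ValueError(f"unknown stratifier {stratifier!r}")


def stratified_top_k(
    cohort: Cohort, stratifier: str, category: Category | str, k: int = 5
) -> StratifiedTable:
    """Top-k terms per stratum by record count, alphabetical tie-break.

    Strata with fewer than k distinct terms are padded with the "/" marker,
    following the published table convention.
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    category = Category(category)
    counts: dict[str, dict[str, int]] = {}
    sizes: dict[str, int] = {}
    for r in cohort:
        stratum = _stratum_of(r, stratifier)
        sizes[stratum] = sizes.get(stratum, 0) + 1
        bucket = counts.setdefault(stratum, {})
        for term in r.terms(category):
            bucket[term] = bucket.get(term, 0) + 1
    rows = {}
    for stratum in sorted(counts):
        ranked = sorted(counts[stratum].items(), key=lambda kv: (-kv[1], kv[0]))[:k]
        entries: list = [
            (term, n, 100.0 * n / sizes[stratum]) for term, n in ranked
        ]
        entries.extend([EMPTY_MARKER] * (k - len(entries)))
        rows[stratum] = entries
    return StratifiedTable(stratifier=stratifier, rows=rows)
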