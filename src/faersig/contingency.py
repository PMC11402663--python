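"""Per-drug 2x2 contingency tables, drug ranking and descriptive summaries.

The unit of counting is the deduplicated case: a case contributes at most
once to a drug-event cell however many times it mentions the drug or the
preferred term.  A report-level sensitivity mode is available by building
the :class:`~faersig.io.EventDataset` with ``dedup=False``.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._util import percentage
from .io import EventDataset, normalize_drug_name

#: Age bands used in the demographic summary (years; right-open except the last).
AGE_BANDS = (
    ("<18", 0.0, 18.0),
    ("18-39", 18.0, 40.0),
    ("40-64", 40.0, 65.0),
    (">=65", 65.0, float("inf")),
)


@dataclass(frozen=True)
class ContingencyTable:
    """The 2x2 drug-event table: a = drug & event, b = drug only,
    c = event only, d = neither.  Counts are floats so that tables
    reconstructed from published margins (non-integer solved cells) are
    representable."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency cells must be non-negative")

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def drug_margin(self) -> float:
        return self.a + self.b

    @property
    def event_margin(self) -> float:
        return self.a + self.c

    @property
    def expected(self) -> float:
        """Expected count of cell a under row/column independence."""
        return self.drug_margin * self.event_margin / self.n

    @classmethod
    def from_margins_and_ror(
        cls, a: float, n: float, event_margin: float, ror: float
    ) -> "ContingencyTable":
        """Reconstruct the table from a, N, the event margin and a published ROR.

        Solving ror = a*d / (b*c) with c = event_margin - a and
        d = N - a - b - c gives b = a*(N - a - c) / (ror*c + a).  This is how
        published signal-score rows can be turned back into full tables when
        the drug margin itself is not printed.
        """
        c = event_margin - a
        if c <= 0 or ror <= 0:
            raise ValueError("need event_margin > a and ror > 0")
        b = a * (n - a - c) / (ror * c + a)
        d = n - a - b - c
        return cls(a=a, b=b, c=c, d=d)


def count_event_by_drug(dataset: EventDataset, pt: str) -> pd.Series:
    """Cases with the target event, counted per primary-suspect drug.

    Each case counts at most once per drug; a case with several PS drugs
    contributes once to each.  Returns an empty Series when the PT does not
    occur.
    """
    event_cases = dataset.event_caseids(pt)
    if not event_cases:
        return pd.Series(dtype=int, name="a")
    mentions = dataset.drugs.loc[
        dataset.drugs["caseid"].isin(event_cases), ["caseid", "drugname"]
    ].drop_duplicates()
    counts = mentions.groupby("drugname").size().sort_index()
    counts.name = "a"
    return counts


def rank_top(
    counts: pd.Series,
    n: int,
    event_total: int,
    atc_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Top-n drugs by event frequency.

    Sorted by frequency descending, ties broken by drug name ascending;
    percentage = a / event_total * 100, half-up rounded to 2 decimals.
    When fewer than n drugs exist, all are returned.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    df = counts.rename("frequency").rename_axis("drug").reset_index()
    df = df.sort_values(["frequency", "drug"], ascending=[False, True],
                        kind="mergesort").head(n).reset_index(drop=True)
    df.insert(0, "rank", range(1, len(df) + 1))
    df["percentage"] = [percentage(f, event_total, 2) for f in df["frequency"]]
    df["atc_class"] = [
        (atc_map or {}).get(normalize_drug_name(d), "") for d in df["drug"]
    ]
    return df


def build_table(dataset: EventDataset, drug: str, pt: str) -> ContingencyTable:
    """Build the case-level 2x2 table for one drug-event pair."""
    event_cases = dataset.event_caseids(pt)
    drug_cases = dataset.drug_caseids(drug)
    a = len(event_cases & drug_cases)
    b = len(drug_cases) - a
    c = len(event_cases) - a
    d = dataset.n_cases - a - b - c
    return ContingencyTable(a=a, b=b, c=c, d=d)


def build_all_tables(
    dataset: EventDataset, pt: str, drugs: list[str] | None = None
) -> dict[str, ContingencyTable]:
    """2x2 tables for every (or the given) primary-suspect drug vs the event."""
    event_cases = dataset.event_caseids(pt)
    n_total = dataset.n_cases
    n_event = len(event_cases)
    names = [normalize_drug_name(d) for d in drugs] if drugs is not None \
        else dataset.drug_names()
    out: dict[str, ContingencyTable] = {}
    grouped = dataset.drugs.groupby("drugname")["caseid"]
    case_sets = {name: set(g) for name, g in grouped}
    for name in names:
        dc = case_sets.get(name, set())
        a = len(dc & event_cases)
        out[name] = ContingencyTable(
            a=a, b=len(dc) - a, c=n_event - a, d=n_total - len(dc) - n_event + a
        )
    return out


def _period_of(quarter_tag: str, granularity: str) -> str:
    return quarter_tag[:4] if granularity == "year" else quarter_tag


def trend_series(
    dataset: EventDataset,
    pt: str,
    granularity: str = "year",
    drug: str | None = None,
) -> pd.DataFrame:
    """Event counts and percentages per period (calendar year or quarter).

    For each period present in the data (periods between the first and last
    are included even when empty): the number of target-event cases, the
    number of all cases, and the percentage (2 decimals, half-up).  With
    ``drug`` given, both counts are restricted to cases naming that drug as
    primary suspect — the per-drug reporting-share trend.
    """
    if granularity not in ("year", "quarter"):
        raise ValueError("granularity must be 'year' or 'quarter'")
    cases = dataset.cases
    if drug is not None:
        cases = cases.loc[cases.index.isin(dataset.drug_caseids(drug))]
    event_ids = dataset.event_caseids(pt)
    tags = cases["quarter"]
    known = tags[tags != ""]
    if known.empty:
        return pd.DataFrame(columns=["period", "event_count", "total_count", "percentage"])
    periods = sorted(known.map(lambda t: _period_of(t, granularity)).unique())
    periods = _fill_periods(periods, granularity)
    per = known.map(lambda t: _period_of(t, granularity))
    total = per.groupby(per).size()
    ev = per[known.index.isin(event_ids)]
    evn = ev.groupby(ev).size()
    rows = []
    for p in periods:
        t = int(total.get(p, 0))
        e = int(evn.get(p, 0))
        rows.append({"period": p, "event_count": e, "total_count": t,
                     "percentage": percentage(e, t, 2)})
    return pd.DataFrame(rows)


def _fill_periods(periods: list[str], granularity: str) -> list[str]:
    if not periods:
        return periods
    if granularity == "year":
        y0, y1 = int(periods[0]), int(periods[-1])
        return [str(y) for y in range(y0, y1 + 1)]
    y0, q0 = int(periods[0][:4]), int(periods[0][5])
    y1, q1 = int(periods[-1][:4]), int(periods[-1][5])
    out = []
    y, q = y0, q0
    while (y, q) <= (y1, q1):
        out.append(f"{y}Q{q}")
        q += 1
        if q == 5:
            y, q = y + 1, 1
    return out


def demographic_summary(
    dataset: EventDataset, pt: str, top_countries: int = 5
) -> pd.DataFrame:
    """Counts and percentages of event cases by age band, sex and country.

    Percentages are over all event cases, half-up rounded to 1 decimal.
    Returns a tidy frame with columns category / level / count / percentage.
    """
    ids = dataset.event_caseids(pt)
    sub = dataset.cases.loc[dataset.cases.index.isin(ids)]
    total = len(sub)
    rows = [{"category": "total", "level": "total", "count": total,
             "percentage": 100.0 if total else 0.0}]

    def band_of(age):
        if age is None or pd.isna(age):
            return "unknown"
        for label, lo, hi in AGE_BANDS:
            if lo <= age < hi:
                return label
        return "unknown"

    bands = sub["age_years"].map(band_of)
    for label in [b[0] for b in AGE_BANDS] + ["unknown"]:
        c = int((bands == label).sum())
        rows.append({"category": "age", "level": label, "count": c,
                     "percentage": percentage(c, total, 1)})
    for label in ("M", "F", "unknown"):
        c = int((sub["sex"] == label).sum())
        rows.append({"category": "sex", "level": label, "count": c,
                     "percentage": percentage(c, total, 1)})
    countries = sub.loc[sub["country"] != "", "country"]
    top = countries.groupby(countries).size().sort_values(ascending=False)
    top = top.loc[sorted(top.index)].sort_values(ascending=False, kind="mergesort")
    for name, c in top.head(top_countries).items():
        rows.append({"category": "country", "level": name, "count": int(c),
                     "percentage": percentage(int(c), total, 1)})
    return pd.DataFrame(rows)
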