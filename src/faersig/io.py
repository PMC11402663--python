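"""Readers and normalisers for FAERS quarterly ASCII extracts.

FAERS (the FDA Adverse Event Reporting System) publishes quarterly
"$"-delimited text tables, one header line followed by one record per line.
The tables consumed here are DEMO (one row per report version, with
demographics and the FDA receipt / event dates), DRUG (drug mentions with
role codes), REAC (MedDRA preferred-term event strings) and THER (therapy
start/end dates); INDI, OUTC and RPSR are accepted and carried as opaque
extras.  A patient case (CASEID) may appear as several report versions
(PRIMARYID); analyses run on deduplicated cases, keeping the most recent
version of each case.

Legacy extracts (pre-2012Q4) use ISR/CASE column names; a column-alias map
normalises those on read, autodetected from the header.
"""
from __future__ import annotations

import csv
import datetime
import glob as _glob
import logging
import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

TABLE_KINDS = ("DEMO", "DRUG", "REAC", "THER", "INDI", "OUTC", "RPSR")

#: legacy / variant column names -> canonical names
COLUMN_ALIASES = {
    "isr": "primaryid",
    "case": "caseid",
    "case_num": "caseid",
    "gndr_cod": "sex",
    "drug_rec_act": "drug_rec_act",
}

#: AGE_COD unit -> multiplier to years
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}


class FaersFormatError(ValueError):
    """A file does not conform to the FAERS ASCII dialect."""


# ---------------------------------------------------------------------------
# dates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RawDate:
    """A FAERS date field: 4, 6 or 8 digits with year/month/day precision.

    ``precision`` is one of ``day``, ``month``, ``year``, ``missing`` or
    ``invalid``; ``date`` is populated only at day precision.
    """

    text: str
    precision: str
    date: datetime.date | None = None

    @property
    def is_day(self) -> bool:
        return self.precision == "day"

    @property
    def year(self) -> int | None:
        return int(self.text[:4]) if self.precision in ("day", "month", "year") else None

    @property
    def month(self) -> int | None:
        return int(self.text[4:6]) if self.precision in ("day", "month") else None

    def sort_key(self) -> str:
        """Chronological sort key; partial dates compare as their earliest day."""
        if self.precision in ("day", "month", "year"):
            return self.text.ljust(8, "0")
        return "00000000"

    def quarter_tag(self) -> str | None:
        """Calendar quarter label 'YYYYQn'; year-only dates map to Q1."""
        if self.precision == "day" or self.precision == "month":
            return f"{self.year}Q{(self.month - 1) // 3 + 1}"
        if self.precision == "year":
            return f"{self.year}Q1"
        return None


def parse_raw_date(text: object) -> RawDate:
    """Parse a FAERS numeric date string into a :class:`RawDate`.

    8 digits -> day precision (or ``invalid`` if not a real calendar date),
    6 -> month, 4 -> year; anything else (empty, non-digit, odd length)
    -> ``missing``.  Never raises.
    """
    s = "" if text is None else str(text).strip()
    if s.endswith(".0"):  # tolerate float round-trips of numeric columns
        s = s[:-2]
    if not s or not s.isdigit():
        return RawDate("", "missing")
    if len(s) == 4:
        return RawDate(s, "year")
    if len(s) == 6:
        if 1 <= int(s[4:6]) <= 12:
            return RawDate(s, "month")
        return RawDate(s, "invalid")
    if len(s) == 8:
        try:
            d = datetime.date(int(s[:4]), int(s[4:6]), int(s[6:8]))
        except ValueError:
            return RawDate(s, "invalid")
        return RawDate(s, "day", d)
    return RawDate(s, "invalid")


# ---------------------------------------------------------------------------
# raw table reading
# ---------------------------------------------------------------------------

def _read_one_file(path: str) -> tuple[pd.DataFrame, int]:
    if not os.path.exists(path):
        raise FileNotFoundError(f"FAERS table file not found: {path}")
    with open(path, newline="", encoding="utf-8", errors="replace") as fh:
        reader = csv.reader(fh, delimiter="$")
        try:
            header = next(reader)
        except StopIteration:
            raise FaersFormatError(f"{path}: empty file, no header line")
        cols = [COLUMN_ALIASES.get(c.strip().lower(), c.strip().lower()) for c in header]
        if "primaryid" not in cols:
            raise FaersFormatError(
                f"{path}: header lacks the key column PRIMARYID/ISR (got {header!r})"
            )
        n_cols = len(cols)
        rows: list[list[str]] = []
        n_malformed = 0
        for lineno, rec in enumerate(reader, start=2):
            if len(rec) != n_cols:
                if not rec or (len(rec) == 1 and not rec[0].strip()):
                    continue  # blank trailing line
                n_malformed += 1
                continue
            rows.append([v.strip() for v in rec])
    if n_malformed:
        log.warning("%s: %d malformed line(s) excluded (field count mismatch)", path, n_malformed)
    df = pd.DataFrame(rows, columns=cols, dtype=str)
    return df, n_malformed


def read_quarter(paths: list[str] | str, table_kind: str) -> pd.DataFrame:
    """Read one or more "$"-delimited FAERS files of a given table kind.

    Returns a string-typed DataFrame with lower-cased, alias-normalised column
    names.  Malformed lines (field count differing from the header) are
    counted in ``df.attrs["n_malformed"]`` and logged, not fatal.  A missing
    file raises :class:`FileNotFoundError` naming the path; a header without
    the PRIMARYID/ISR key column raises :class:`FaersFormatError`.
    """
    kind = table_kind.upper()
    if kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind {table_kind!r}; expected one of {TABLE_KINDS}")
    if isinstance(paths, (str, os.PathLike)):
        paths = [paths]
    frames, n_bad = [], 0
    for p in paths:
        df, bad = _read_one_file(os.fspath(p))
        frames.append(df)
        n_bad += bad
    out = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    out.attrs["n_malformed"] = n_bad
    out.attrs["table_kind"] = kind
    return out


@dataclass
class RawReportTables:
    """The joined raw quarter tables, prior to case-level normalisation."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    extras: dict = field(default_factory=dict)
    malformed: dict = field(default_factory=dict)

    @classmethod
    def from_directory(cls, directory: str) -> "RawReportTables":
        """Load every ``<KIND>*.txt`` file found under ``directory``."""
        parts: dict[str, pd.DataFrame] = {}
        malformed: dict[str, int] = {}
        for kind in TABLE_KINDS:
            paths = sorted(_glob.glob(os.path.join(directory, f"{kind}*.txt")))
            paths += sorted(_glob.glob(os.path.join(directory, f"{kind.lower()}*.txt")))
            if paths:
                df = read_quarter(paths, kind)
                parts[kind] = df
                malformed[kind] = df.attrs.get("n_malformed", 0)
        for required in ("DEMO", "DRUG", "REAC"):
            if required not in parts:
                raise FileNotFoundError(f"no {required}*.txt files found in {directory}")
        n_files = {k: len(_glob.glob(os.path.join(directory, f"{k}*.txt")))
                   + len(_glob.glob(os.path.join(directory, f"{k.lower()}*.txt")))
                   for k in ("DEMO", "DRUG", "REAC", "THER")}
        if len(set(n_files.values())) > 1:
            log.warning("partial quarter set: file counts differ per table %s", n_files)
        return cls(
            demo=parts["DEMO"],
            drug=parts["DRUG"],
            reac=parts["REAC"],
            ther=parts.get("THER", pd.DataFrame(columns=["primaryid", "dsg_drug_seq", "start_dt", "end_dt"])),
            extras={k: v for k, v in parts.items() if k in ("INDI", "OUTC", "RPSR")},
            malformed=malformed,
        )


# ---------------------------------------------------------------------------
# normalisation helpers
# ---------------------------------------------------------------------------

_WS = re.compile(r"\s+")


def normalize_drug_name(raw: object, synonym_map: dict[str, str] | None = None) -> str:
    """Trim, upper-case and collapse internal whitespace in a drug name.

    ``synonym_map`` (exact match after casefolding both sides) maps brand or
    salt variants onto one preferred name, e.g. ``{"REVLIMID": "LENALIDOMIDE"}``.
    """
    s = _WS.sub(" ", str(raw or "").strip()).upper()
    if synonym_map:
        folded = {str(k).strip().upper(): _WS.sub(" ", str(v).strip()).upper()
                  for k, v in synonym_map.items()}
        s = folded.get(s, s)
    return s


def normalize_pt(raw: object) -> str:
    """Upper-case, whitespace-trimmed MedDRA preferred term."""
    return _WS.sub(" ", str(raw or "").strip()).upper()


def convert_age_years(age: object, age_cod: object) -> float | None:
    """AGE + AGE_COD -> age in years; None when missing or unparseable."""
    s = str(age or "").strip()
    if not s:
        return None
    try:
        v = float(s)
    except ValueError:
        return None
    unit = str(age_cod or "YR").strip().upper() or "YR"
    mult = AGE_UNIT_TO_YEARS.get(unit)
    if mult is None:
        return None
    years = v * mult
    return years if years >= 0 else None


def _normalize_sex(raw: object) -> str:
    s = str(raw or "").strip().upper()
    return s if s in ("M", "F") else "unknown"


def _pid_sort_key(pid: str) -> str:
    """Orderable key: numeric ids compare numerically and above non-numeric."""
    p = str(pid).strip()
    return "1" + p.zfill(24) if p.isdigit() else "0" + p


# ---------------------------------------------------------------------------
# deduplication
# ---------------------------------------------------------------------------

def deduplicate_cases(demo: pd.DataFrame) -> pd.DataFrame:
    """Collapse report versions to one record per CASEID.

    The retained version is the one with the greatest FDA_DT; ties are broken
    by the greatest PRIMARYID (numeric comparison when both ids are integers,
    lexicographic otherwise).  Records with a missing CASEID become singleton
    cases keyed by their PRIMARYID (counted in ``df.attrs["n_missing_caseid"]``
    and warned about).  Output is sorted by caseid, so the operation is
    deterministic and idempotent.
    """
    df = demo.copy()
    for col in ("caseid", "primaryid", "fda_dt"):
        if col not in df.columns:
            df[col] = ""
        df[col] = df[col].fillna("").astype(str).str.strip()
    missing = df["caseid"] == ""
    n_missing = int(missing.sum())
    if n_missing:
        log.warning("%d demo record(s) lack CASEID; treated as singleton cases", n_missing)
        df.loc[missing, "caseid"] = "PID:" + df.loc[missing, "primaryid"]
    df["_fda_key"] = df["fda_dt"].map(lambda t: parse_raw_date(t).sort_key())
    df["_pid_key"] = df["primaryid"].map(_pid_sort_key)
    df = df.sort_values(["caseid", "_fda_key", "_pid_key"], kind="mergesort")
    out = df.groupby("caseid", sort=True).tail(1).sort_values("caseid", kind="mergesort")
    out = out.drop(columns=["_fda_key", "_pid_key"]).reset_index(drop=True)
    out.attrs["n_missing_caseid"] = n_missing
    out.attrs["n_input"] = len(demo)
    return out


# ---------------------------------------------------------------------------
# event dataset
# ---------------------------------------------------------------------------

@dataclass
class EventDataset:
    """Joined, deduplicated case-level view of a set of FAERS quarters.

    cases   : one row per case (index: caseid) — primaryid, fda_dt, event_dt,
              quarter, age_years, sex, country
    drugs   : primary-suspect drug mentions (caseid, drug_seq, drugname)
    events  : reaction preferred terms (caseid, pt)
    therapy : therapy starts joined to PS mentions (caseid, dsg_drug_seq, start_dt)
    drop_counts : per-table accounting of rows dropped and why; for every
              table, input rows == retained + sum of named drop reasons.
    """

    cases: pd.DataFrame
    drugs: pd.DataFrame
    events: pd.DataFrame
    therapy: pd.DataFrame
    drop_counts: dict = field(default_factory=dict)
    dedup: bool = True

    @property
    def n_cases(self) -> int:
        return len(self.cases)

    def event_caseids(self, pt: str) -> set[str]:
        p = normalize_pt(pt)
        return set(self.events.loc[self.events["pt"] == p, "caseid"])

    def drug_caseids(self, drug: str) -> set[str]:
        d = normalize_drug_name(drug)
        return set(self.drugs.loc[self.drugs["drugname"] == d, "caseid"])

    def drug_names(self) -> list[str]:
        return sorted(self.drugs["drugname"].unique())


def build_event_dataset(
    raw: RawReportTables,
    dedup: bool = True,
    synonym_map: dict[str, str] | None = None,
) -> EventDataset:
    """Join REAC/DRUG/THER to retained DEMO cases and normalise.

    Non-primary-suspect drug mentions (role codes SS, C, I) are dropped;
    REAC/DRUG/THER rows whose primaryid is absent from DEMO are counted as
    orphans and dropped; rows pointing at superseded (deduplicated-away)
    report versions are counted separately.  With ``dedup=False`` every
    report version becomes its own "case" keyed by primaryid (report-level
    sensitivity mode).
    """
    demo = raw.demo.copy()
    for col in ("primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
                "sex", "reporter_country", "occr_country"):
        if col not in demo.columns:
            demo[col] = ""
        demo[col] = demo[col].fillna("").astype(str).str.strip()

    if dedup:
        retained = deduplicate_cases(demo)
    else:
        retained = demo.copy()
        retained["caseid"] = retained["primaryid"]
        retained = retained.sort_values("caseid", kind="mergesort").reset_index(drop=True)
        retained.attrs["n_missing_caseid"] = 0
        retained.attrs["n_input"] = len(demo)

    country = retained["reporter_country"].where(
        retained["reporter_country"] != "", retained["occr_country"]
    )
    cases = pd.DataFrame(
        {
            "caseid": retained["caseid"],
            "primaryid": retained["primaryid"],
            "fda_dt": retained["fda_dt"],
            "event_dt": retained["event_dt"],
            "quarter": retained["fda_dt"].map(lambda t: parse_raw_date(t).quarter_tag() or ""),
            "age_years": [convert_age_years(a, c) for a, c in
                          zip(retained["age"], retained["age_cod"])],
            "sex": retained["sex"].map(_normalize_sex),
            "country": country.str.upper().str.strip(),
        }
    ).set_index("caseid", drop=False)

    pid_to_case = dict(zip(retained["primaryid"], retained["caseid"]))
    all_pids = set(demo["primaryid"])

    def _attach(df: pd.DataFrame, cols: list[str]) -> tuple[pd.DataFrame, dict]:
        d = df.copy()
        for col in cols:
            if col not in d.columns:
                d[col] = ""
            d[col] = d[col].fillna("").astype(str).str.strip()
        n_in = len(d)
        orphan = ~d["primaryid"].isin(all_pids)
        n_orphan = int(orphan.sum())
        d = d[~orphan]
        kept = d["primaryid"].isin(pid_to_case.keys())
        n_superseded = int((~kept).sum())
        d = d[kept].copy()
        d["caseid"] = d["primaryid"].map(pid_to_case)
        return d, {"input": n_in, "orphan": n_orphan, "superseded": n_superseded}

    drug, drug_drops = _attach(raw.drug, ["primaryid", "drug_seq", "role_cod", "drugname"])
    non_ps = drug["role_cod"].str.upper() != "PS"
    drug_drops["non_primary_suspect"] = int(non_ps.sum())
    drug = drug[~non_ps].copy()
    drug["drugname"] = drug["drugname"].map(lambda s: normalize_drug_name(s, synonym_map))
    drug_drops["retained"] = len(drug)
    drugs = drug[["caseid", "drug_seq", "drugname"]].sort_values(
        ["caseid", "drug_seq"], kind="mergesort").reset_index(drop=True)

    reac, reac_drops = _attach(raw.reac, ["primaryid", "pt"])
    reac["pt"] = reac["pt"].map(normalize_pt)
    events = reac[["caseid", "pt"]].drop_duplicates().sort_values(
        ["caseid", "pt"], kind="mergesort").reset_index(drop=True)
    reac_drops["duplicate_pt"] = reac_drops["input"] - reac_drops["orphan"] - \
        reac_drops["superseded"] - len(events)
    reac_drops["retained"] = len(events)

    ther, ther_drops = _attach(raw.ther, ["primaryid", "dsg_drug_seq", "start_dt", "end_dt"])
    ps_keys = set(zip(drugs["caseid"], drugs["drug_seq"]))
    matched = np.fromiter(
        ((c, s) in ps_keys for c, s in zip(ther["caseid"], ther["dsg_drug_seq"])),
        dtype=bool, count=len(ther),
    )
    ther_drops["no_ps_match"] = int(len(ther) - matched.sum())
    ther = ther[matched]
    ther_drops["retained"] = len(ther)
    therapy = ther[["caseid", "dsg_drug_seq", "start_dt", "end_dt"]].sort_values(
        ["caseid", "dsg_drug_seq", "start_dt"], kind="mergesort").reset_index(drop=True)

    demo_drops = {
        "input": retained.attrs.get("n_input", len(demo)),
        "superseded": retained.attrs.get("n_input", len(demo)) - len(retained),
        "missing_caseid": retained.attrs.get("n_missing_caseid", 0),
        "retained": len(retained),
    }

    return EventDataset(
        cases=cases,
        drugs=drugs,
        events=events,
        therapy=therapy,
        drop_counts={"demo": demo_drops, "drug": drug_drops,
                     "reac": reac_drops, "ther": ther_drops},
        dedup=dedup,
    )


# ---------------------------------------------------------------------------
# writing (FAERS dialect emitter, shared with the synthetic generator)
# ---------------------------------------------------------------------------

def write_table(path: str, df: pd.DataFrame) -> None:
    """Write a DataFrame as a "$"-delimited FAERS ASCII table."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("$".join(str(c) for c in df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write("$".join("" if v is None else str(v) for v in row) + "\n")


def quarter_file_name(kind: str, quarter: str) -> str:
    """'DEMO', '2023Q1' -> 'DEMO23Q1.txt' (the FAERS naming convention)."""
    year, q = quarter.split("Q")
    return f"{kind.upper()}{year[2:]}Q{q}.txt"


def dataset_to_tables(ds: EventDataset) -> RawReportTables:
    """Reconstruct raw-format tables from an :class:`EventDataset`.

    Used for round-trip checks: writing these tables and re-reading them
    reproduces the dataset's normalized records.
    """
    demo = pd.DataFrame(
        {
            "primaryid": ds.cases["primaryid"],
            "caseid": ds.cases["caseid"],
            "fda_dt": ds.cases["fda_dt"],
            "event_dt": ds.cases["event_dt"],
            "age": ["" if a is None else repr(float(a)) for a in ds.cases["age_years"]],
            "age_cod": ["" if a is None else "YR" for a in ds.cases["age_years"]],
            "sex": ["" if s == "unknown" else s for s in ds.cases["sex"]],
            "reporter_country": ds.cases["country"],
        }
    ).reset_index(drop=True)
    case_to_pid = dict(zip(ds.cases["caseid"], ds.cases["primaryid"]))
    drug = pd.DataFrame(
        {
            "primaryid": ds.drugs["caseid"].map(case_to_pid),
            "caseid": ds.drugs["caseid"],
            "drug_seq": ds.drugs["drug_seq"],
            "role_cod": "PS",
            "drugname": ds.drugs["drugname"],
        }
    )
    reac = pd.DataFrame(
        {
            "primaryid": ds.events["caseid"].map(case_to_pid),
            "caseid": ds.events["caseid"],
            "pt": ds.events["pt"],
        }
    )
    ther = pd.DataFrame(
        {
            "primaryid": ds.therapy["caseid"].map(case_to_pid),
            "caseid": ds.therapy["caseid"],
            "dsg_drug_seq": ds.therapy["dsg_drug_seq"],
            "start_dt": ds.therapy["start_dt"],
            "end_dt": ds.therapy["end_dt"],
        }
    )
    return RawReportTables(demo=demo, drug=drug, reac=reac, ther=ther)
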