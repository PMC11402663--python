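"""End-to-end orchestration: ingest -> dedup -> rank -> signals -> TTO.

Two entry points:

* :func:`run` executes the full pipeline on a directory of FAERS-format
  quarterly files and writes the output bundle (ranking, trends,
  demographics, signal table, TTO table, manifest, reconciliation log).
* :func:`replicate_from_printed` applies the signal criteria directly to a
  table of published statistics (ROR/CI, PRR/chi2, EBGM/EB05, IC/IC025) —
  no raw data needed — returning per-algorithm signal counts and flags.
  The package ships such a table for the 30 drugs of the source analysis.
"""
from __future__ import annotations

import dataclasses
import importlib.resources
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd

from ._util import round_half_up
from .contingency import build_all_tables, count_event_by_drug, demographic_summary, \
    rank_top, trend_series
from .disproportionality import MgpsFitError, SignalCriteria, compute_signal_row, \
    mgps_fit_prior
from .io import EventDataset, RawReportTables, build_event_dataset, normalize_drug_name
from .tto import collect_tto_sample, tto_result

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one pipeline run needs; serialisable to/from YAML or JSON."""

    input_dir: str
    out_dir: str
    target_pt: str = "CONSTIPATION"
    top_n: int = 30
    chi2_yates: bool = False
    mgps_mode: str = "simplified"  # or "full"
    bcpnn_mode: str = "paper_compat"  # or "noren"
    count_mode: str = "cases"  # or "reports"
    criteria: SignalCriteria = field(default_factory=SignalCriteria)
    synonym_map: dict = field(default_factory=dict)
    atc_map: dict = field(default_factory=dict)
    seed: int = 0
    min_n_tto: int = 3

    def __post_init__(self):
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if self.mgps_mode not in ("simplified", "full"):
            raise ValueError("mgps_mode must be 'simplified' or 'full'")
        if self.bcpnn_mode not in ("paper_compat", "noren"):
            raise ValueError("bcpnn_mode must be 'paper_compat' or 'noren'")
        if self.count_mode not in ("cases", "reports"):
            raise ValueError("count_mode must be 'cases' or 'reports'")


def load_atc_map() -> dict[str, str]:
    """The shipped drug -> ATC first-letter class map (user-editable fixture)."""
    with importlib.resources.files("faersig.data").joinpath("atc_classes.csv").open() as fh:
        df = pd.read_csv(fh, dtype=str)
    return dict(zip(df["drug"].map(normalize_drug_name), df["atc_class"]))


def load_printed_signal_table() -> pd.DataFrame:
    """The published 30-drug signal-score table shipped with the package."""
    with importlib.resources.files("faersig.data") \
            .joinpath("printed_signal_table.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass
class RunResult:
    config: RunConfig
    dataset: EventDataset
    ranking: pd.DataFrame
    trends_year: pd.DataFrame
    trends_quarter: pd.DataFrame
    demographics: pd.DataFrame
    signals: pd.DataFrame
    tto: pd.DataFrame
    manifest: dict
    log_lines: list


def _signal_frame(rows) -> pd.DataFrame:
    recs = []
    for r in rows:
        recs.append({
            "drug": r.drug, "a": r.a,
            "ror": r.ror, "ror_lo": r.ror_lo, "ror_hi": r.ror_hi,
            "prr": r.prr, "chi2": r.chi2, "rrr": r.rrr,
            "ebgm": r.ebgm, "eb05": r.eb05, "ic": r.ic, "ic025": r.ic025,
            "ror_signal": r.flags.ror, "prr_signal": r.flags.prr,
            "mgps_signal": r.flags.mgps, "bcpnn_signal": r.flags.bcpnn,
            "any_signal": r.flags.any,
        })
    return pd.DataFrame(recs)


def run(config: RunConfig, raw: RawReportTables | None = None) -> RunResult:
    """Execute the pipeline and write the output bundle to ``config.out_dir``.

    Raises ``ValueError`` when the target PT yields no cases.  The run log
    reconciles every filter: for each input table, rows in = retained + the
    named drop reasons.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    lines: list[str] = []

    def say(msg: str):
        lines.append(msg)
        log.info(msg)

    if raw is None:
        raw = RawReportTables.from_directory(config.input_dir)
    say(f"input rows: demo={len(raw.demo)} drug={len(raw.drug)} "
        f"reac={len(raw.reac)} ther={len(raw.ther)}")
    for kind, n_bad in (raw.malformed or {}).items():
        if n_bad:
            say(f"{kind}: {n_bad} malformed line(s) excluded")

    ds = build_event_dataset(raw, dedup=(config.count_mode == "cases"),
                             synonym_map=config.synonym_map or None)
    for table, drops in ds.drop_counts.items():
        named = {k: v for k, v in drops.items() if k not in ("input", "retained")}
        total = drops["retained"] + sum(named.values())
        say(f"{table}: input={drops['input']} retained={drops['retained']} "
            + " ".join(f"{k}={v}" for k, v in named.items())
            + (" [RECONCILED]" if total == drops["input"] else " [MISMATCH]"))

    event_ids = ds.event_caseids(config.target_pt)
    if not event_ids:
        raise ValueError(f"no cases with target PT {config.target_pt!r}")
    say(f"cases={ds.n_cases} event_cases={len(event_ids)}")

    counts = count_event_by_drug(ds, config.target_pt)
    atc = config.atc_map or load_atc_map()
    ranking = rank_top(counts, config.top_n, len(event_ids), atc_map=atc)
    top_drugs = list(ranking["drug"])

    trends_year = trend_series(ds, config.target_pt, "year")
    trends_quarter = trend_series(ds, config.target_pt, "quarter")
    demographics = demographic_summary(ds, config.target_pt)

    tables = build_all_tables(ds, config.target_pt, drugs=top_drugs)
    prior = None
    if config.mgps_mode == "full":
        all_tables = build_all_tables(ds, config.target_pt)
        try:
            prior = mgps_fit_prior(list(all_tables.values()), seed=config.seed)
        except MgpsFitError as exc:
            prior = exc.best
            if prior is None:
                raise
            say(f"warning: MGPS prior fit unconverged, using best found ({exc})")
    rows = [
        compute_signal_row(d, tables[d], criteria=config.criteria, prior=prior,
                           mgps_mode=config.mgps_mode, bcpnn_mode=config.bcpnn_mode,
                           yates=config.chi2_yates)
        for d in top_drugs
    ]
    signals = _signal_frame(rows)
    say("signals: " + " ".join(
        f"{alg}={int(signals[alg + '_signal'].sum())}"
        for alg in ("ror", "prr", "mgps", "bcpnn"))
        + f" any={int(signals['any_signal'].sum())}")

    tto_rows = []
    for r in rows:
        if not r.flags.any:
            continue
        sample = collect_tto_sample(ds, r.drug, config.target_pt)
        if sample.n < 1:
            continue
        res = tto_result(sample, min_n_fit=config.min_n_tto, seed=config.seed)
        tto_rows.append({
            "drug": res.drug, "n": res.n,
            "median": round_half_up(res.median, 1),
            "q1": round_half_up(res.q1, 1), "q3": round_half_up(res.q3, 1),
            "alpha": res.fit.alpha if res.fit else float("nan"),
            "alpha_lo": res.fit.alpha_lo if res.fit else float("nan"),
            "alpha_hi": res.fit.alpha_hi if res.fit else float("nan"),
            "beta": res.fit.beta if res.fit else float("nan"),
            "beta_lo": res.fit.beta_lo if res.fit else float("nan"),
            "beta_hi": res.fit.beta_hi if res.fit else float("nan"),
            "failure_type": res.failure_type,
            **{f"excluded_{k}": v for k, v in res.n_excluded_by_reason.items()},
        })
    tto = pd.DataFrame(tto_rows)

    outputs = {
        "ranking": ranking, "trends_year": trends_year,
        "trends_quarter": trends_quarter, "demographics": demographics,
        "signals": signals, "tto": tto,
    }
    paths = {}
    for name, df in outputs.items():
        p = os.path.join(config.out_dir, f"{name}.csv")
        df.to_csv(p, index=False)
        paths[name] = p
    manifest = {
        "target_pt": config.target_pt,
        "count_mode": config.count_mode,
        "n_cases": ds.n_cases,
        "n_event_cases": len(event_ids),
        "top_n": config.top_n,
        "signal_counts": {
            alg: int(signals[alg + "_signal"].sum())
            for alg in ("ror", "prr", "mgps", "bcpnn")
        } | {"any": int(signals["any_signal"].sum())},
        "modes": {"mgps": config.mgps_mode, "bcpnn": config.bcpnn_mode,
                  "chi2_yates": config.chi2_yates},
        "seed": config.seed,
        "outputs": {k: os.path.basename(v) for k, v in paths.items()},
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(os.path.join(config.out_dir, "run.log"), "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return RunResult(config=config, dataset=ds, ranking=ranking,
                     trends_year=trends_year, trends_quarter=trends_quarter,
                     demographics=demographics, signals=signals, tto=tto,
                     manifest=manifest, log_lines=lines)


# ---------------------------------------------------------------------------
# replication from printed statistics
# ---------------------------------------------------------------------------

REQUIRED_PRINTED_COLS = ("drug", "frequency", "ror", "ror_lo", "ror_hi",
                         "prr", "chi2", "ebgm", "eb05", "ic", "ic025")


def replicate_from_printed(
    table: pd.DataFrame | None = None,
    criteria: SignalCriteria = SignalCriteria(),
) -> tuple[pd.DataFrame, dict]:
    """Apply the signal criteria to published statistics rows directly.

    ``table`` needs columns drug, frequency (the a cell), ror_lo, prr, chi2,
    eb05 and ic025; defaults to the shipped 30-drug table.  Returns the table
    with computed flag columns appended, plus per-algorithm and union counts.
    A row with a missing required value raises ``ValueError`` naming the drug.
    """
    from .disproportionality import classify_signals

    if table is None:
        table = load_printed_signal_table()
    df = table.copy()
    missing_cols = [c for c in REQUIRED_PRINTED_COLS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"printed table lacks columns: {missing_cols}")
    flags = []
    for row in df.itertuples(index=False):
        vals = [row.frequency, row.ror_lo, row.prr, row.chi2, row.eb05, row.ic025]
        if any(pd.isna(v) for v in vals):
            raise ValueError(f"malformed printed row for drug {row.drug!r}")
        f = classify_signals(row.frequency, row.ror_lo, row.prr, row.chi2,
                             row.eb05, row.ic025, criteria)
        flags.append(f)
    df["ror_signal"] = [f.ror for f in flags]
    df["prr_signal"] = [f.prr for f in flags]
    df["mgps_signal"] = [f.mgps for f in flags]
    df["bcpnn_signal"] = [f.bcpnn for f in flags]
    df["any_signal"] = [f.any for f in flags]
    counts = {
        "ror": int(df["ror_signal"].sum()),
        "prr": int(df["prr_signal"].sum()),
        "mgps": int(df["mgps_signal"].sum()),
        "bcpnn": int(df["bcpnn_signal"].sum()),
        "any": int(df["any_signal"].sum()),
    }
    return df, counts


def config_from_file(path: str) -> RunConfig:
    """Load a RunConfig from a YAML or JSON file."""
    import yaml

    with open(path) as fh:
        d = yaml.safe_load(fh)
    if "criteria" in d and isinstance(d["criteria"], dict):
        d["criteria"] = SignalCriteria(**d["criteria"])
    return RunConfig(**d)


def config_to_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    return d
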