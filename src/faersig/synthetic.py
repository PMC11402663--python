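"""Synthetic FAERS-format data with controlled statistical structure.

The generator emits the same "$"-delimited quarterly DEMO/DRUG/REAC/THER
files the readers consume, plus a ground-truth ledger (JSON) recording the
true 2x2 cells and onset-time parameters per drug, so every pipeline stage
can be exercised and checked without downloading the real database.

The generative model, per report: a primary-suspect drug is sampled from
configured marginal shares; the target event occurs with probability
min(1, background_event_rate * rrr_target(drug)), so a drug's true relative
reporting ratio is (approximately) its configured multiplier; onset days are
drawn from the drug's Weibull and realised as EVENT_DT = START_DT +
round(onset); a configurable fraction of cases gains a duplicate report
version (same CASEID, fresh PRIMARYID, later FDA_DT); date corruption
(missing / partial-precision / event-before-start) is applied at configured
rates.  Identical seeds produce byte-identical files.
"""
from __future__ import annotations

import datetime
import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np

from .io import quarter_file_name

TARGET_PT_DEFAULT = "CONSTIPATION"

DECOY_PTS = (
    "NAUSEA", "HEADACHE", "DIARRHOEA", "FATIGUE", "DIZZINESS",
    "VOMITING", "RASH", "PYREXIA", "INSOMNIA", "PRURITUS",
)

CONCOMITANT_DRUGS = ("ASPIRIN", "PARACETAMOL", "OMEPRAZOLE", "METFORMIN")


@dataclass(frozen=True)
class DrugSpec:
    """One synthetic drug: its share of reports, its event-association
    multiplier (the relative reporting rate it should show), and its true
    Weibull onset distribution (scale in days, shape)."""

    name: str
    share: float
    rrr_target: float = 1.0
    weibull_alpha: float = 60.0
    weibull_beta: float = 0.6


def _default_drugs() -> tuple[DrugSpec, ...]:
    # A mix of strongly associated, weakly associated, null and protective
    # drugs, with onset scales/shapes in the range seen for real early-failure
    # adverse events (shape < 1, scales of days to months).  The associated
    # drugs get small market shares so the share-weighted event-rate
    # multiplier stays near 1: a drug's measured relative reporting rate is
    # its multiplier divided by that weighted mean, so keeping the mean close
    # to 1 keeps measured RRR close to rrr_target (the exact implied value is
    # recorded in the ledger as rrr_implied).
    return (
        DrugSpec("SEVELAMER", 0.003, rrr_target=20.0, weibull_alpha=32.0, weibull_beta=0.6),
        DrugSpec("ORLISTAT", 0.005, rrr_target=11.0, weibull_alpha=9.0, weibull_beta=0.55),
        DrugSpec("LENALIDOMIDE", 0.015, rrr_target=3.8, weibull_alpha=110.0, weibull_beta=0.6),
        DrugSpec("OXYCODONE", 0.03, rrr_target=1.1, weibull_alpha=175.0, weibull_beta=0.5),
        DrugSpec("PREGABALIN", 0.03, rrr_target=0.9, weibull_alpha=80.0, weibull_beta=0.6),
        DrugSpec("DRUG_NULL_A", 0.31, rrr_target=1.0),
        DrugSpec("DRUG_NULL_B", 0.31, rrr_target=1.0),
        DrugSpec("DRUG_NULL_C", 0.297, rrr_target=1.0),
    )


@dataclass
class SyntheticConfig:
    """Generative parameters; the defaults emulate the structure (duplicate
    rate, demographics, early-failure onsets) of real spontaneous-report
    data at a size every stage can process in seconds."""

    seed: int = 0
    n_reports: int = 20000
    quarters: tuple[str, ...] = (
        "2022Q1", "2022Q2", "2022Q3", "2022Q4",
        "2023Q1", "2023Q2", "2023Q3", "2023Q4",
    )
    drugs: tuple[DrugSpec, ...] = field(default_factory=_default_drugs)
    background_event_rate: float = 0.02
    duplicate_case_rate: float = 0.014
    date_missing_rate: float = 0.30
    date_partial_rate: float = 0.10
    event_before_start_rate: float = 0.02
    # demographics: the marginal mixes observed in large US-dominated
    # spontaneous-report cohorts (female-predominant, many unknowns)
    sex_dist: dict = field(default_factory=lambda: {"F": 0.566, "M": 0.333, "": 0.101})
    age_band_dist: dict = field(default_factory=lambda: {
        "<18": 0.018, "18-39": 0.061, "40-64": 0.248, ">=65": 0.281, "": 0.392})
    country_dist: dict = field(default_factory=lambda: {
        "US": 0.712, "CA": 0.057, "GB": 0.039, "JP": 0.024, "DE": 0.022, "FR": 0.146})
    target_pt: str = TARGET_PT_DEFAULT
    decoy_pts: tuple[str, ...] = DECOY_PTS
    concomitant_rate: float = 0.3
    multi_ps_rate: float = 0.0  # probability of a second PS drug on a report

    def validate(self) -> list[str]:
        """Sanity-check ranges; returns warnings (expected a < 1 per drug)."""
        shares = [d.share for d in self.drugs]
        probs = [self.background_event_rate, self.duplicate_case_rate,
                 self.date_missing_rate, self.date_partial_rate,
                 self.event_before_start_rate, *shares]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("shares and probabilities must lie in [0, 1]")
        if abs(sum(shares) - 1.0) > 1e-9:
            raise ValueError(f"drug shares must sum to 1, got {sum(shares)}")
        for d in self.drugs:
            if d.rrr_target <= 0 or d.weibull_alpha <= 0 or d.weibull_beta <= 0:
                raise ValueError(f"{d.name}: rrr_target and Weibull parameters must be > 0")
        warnings = []
        for d in self.drugs:
            exp_a = self.n_reports * d.share * min(
                1.0, self.background_event_rate * d.rrr_target)
            if exp_a < 1.0:
                warnings.append(
                    f"{d.name}: expected event count {exp_a:.2f} < 1; "
                    "signal statistics will be unstable")
        return warnings


_AGE_BAND_RANGES = {"<18": (1, 17), "18-39": (18, 39), "40-64": (40, 64), ">=65": (65, 90)}


def _quarter_bounds(tag: str) -> tuple[datetime.date, datetime.date]:
    year, q = int(tag[:4]), int(tag[5])
    start = datetime.date(year, 3 * (q - 1) + 1, 1)
    end = (datetime.date(year + 1, 1, 1) if q == 4
           else datetime.date(year, 3 * q + 1, 1)) - datetime.timedelta(days=1)
    return start, end


def _fmt(d: datetime.date) -> str:
    return d.strftime("%Y%m%d")


def _choice(rng: np.random.Generator, dist: dict) -> str:
    keys = list(dist.keys())
    p = np.array([dist[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def generate(config: SyntheticConfig, out_dir: str) -> dict:
    """Write one DEMO/DRUG/REAC/THER file set per quarter plus ledger.json.

    Returns the ground-truth ledger: per drug the true (a, b, c, d) counted
    over cases (duplicate versions collapse onto their case) and the true
    Weibull onset parameters; plus overall totals.  Config warnings
    (expected a < 1) are included under ``"warnings"``.
    """
    warnings = config.validate()
    rng = np.random.default_rng(config.seed)
    os.makedirs(out_dir, exist_ok=True)

    drug_names = [d.name for d in config.drugs]
    shares = np.array([d.share for d in config.drugs], dtype=float)
    specs = {d.name: d for d in config.drugs}

    rows: dict[str, dict[str, list]] = {
        q: {"DEMO": [], "DRUG": [], "REAC": [], "THER": []} for q in config.quarters
    }
    truth_a = {n: 0 for n in drug_names}
    truth_drug_margin = {n: 0 for n in drug_names}
    n_event_cases = 0
    tto_clean = {n: [] for n in drug_names}

    for i in range(config.n_reports):
        caseid = str(10_000_000 + i)
        q = config.quarters[int(rng.integers(0, len(config.quarters)))]
        q_start, q_end = _quarter_bounds(q)
        fda = q_start + datetime.timedelta(days=int(rng.integers(0, (q_end - q_start).days + 1)))

        case_drugs = [drug_names[int(rng.choice(len(drug_names), p=shares))]]
        if config.multi_ps_rate > 0 and rng.random() < config.multi_ps_rate:
            extra = drug_names[int(rng.choice(len(drug_names), p=shares))]
            if extra not in case_drugs:
                case_drugs.append(extra)
        # the (first) PS drug drives the event probability
        spec = specs[case_drugs[0]]
        p_event = min(1.0, config.background_event_rate * spec.rrr_target)
        has_event = bool(rng.random() < p_event)

        if has_event:
            onset = float(spec.weibull_alpha *
                          rng.weibull(spec.weibull_beta))
        else:
            onset = float(rng.exponential(30.0))
        onset_days = int(round(onset))
        delay = int(rng.integers(0, 31))
        start = fda - datetime.timedelta(days=delay + onset_days)
        event = start + datetime.timedelta(days=onset_days)

        start_s, event_s = _fmt(start), _fmt(event)
        corrupted = True
        u = rng.random()
        which = rng.random() < 0.5
        if u < config.date_missing_rate:
            if which:
                event_s = ""
            else:
                start_s = ""
        elif u < config.date_missing_rate + config.date_partial_rate:
            if which:
                event_s = event_s[:6]
            else:
                start_s = start_s[:6]
        elif u < (config.date_missing_rate + config.date_partial_rate
                  + config.event_before_start_rate):
            event_s = _fmt(start - datetime.timedelta(days=int(rng.integers(1, 31))))
        else:
            corrupted = False

        sex = _choice(rng, config.sex_dist)
        band = _choice(rng, config.age_band_dist)
        if band:
            lo, hi = _AGE_BAND_RANGES[band]
            age, age_cod = str(int(rng.integers(lo, hi + 1))), "YR"
        else:
            age, age_cod = "", ""
        country = _choice(rng, config.country_dist)

        pt = config.target_pt if has_event else \
            config.decoy_pts[int(rng.integers(0, len(config.decoy_pts)))]

        versions = [(caseid + "1", fda)]
        if rng.random() < config.duplicate_case_rate:
            bump = int(rng.integers(1, 46))
            fda2 = min(fda + datetime.timedelta(days=bump), q_end)
            versions.append((caseid + "2", fda2))

        for pid, fda_v in versions:
            rows[q]["DEMO"].append(
                [pid, caseid, _fmt(fda_v), event_s, age, age_cod, sex, country])
            seq = 0
            for name in case_drugs:
                seq += 1
                rows[q]["DRUG"].append([pid, caseid, str(seq), "PS", name])
                rows[q]["THER"].append([pid, caseid, str(seq), start_s, ""])
            if rng.random() < config.concomitant_rate:
                seq += 1
                conc = CONCOMITANT_DRUGS[int(rng.integers(0, len(CONCOMITANT_DRUGS)))]
                rows[q]["DRUG"].append([pid, caseid, str(seq), "C", conc])
            rows[q]["REAC"].append([pid, caseid, pt])

        for name in case_drugs:
            truth_drug_margin[name] += 1
            if has_event:
                truth_a[name] += 1
        if has_event:
            n_event_cases += 1
            if not corrupted:
                for name in case_drugs:
                    tto_clean[name].append(max(onset_days, 0.5))

    headers = {
        "DEMO": ["primaryid", "caseid", "fda_dt", "event_dt", "age", "age_cod",
                 "sex", "reporter_country"],
        "DRUG": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname"],
        "REAC": ["primaryid", "caseid", "pt"],
        "THER": ["primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"],
    }
    paths = []
    for q in config.quarters:
        for kind in ("DEMO", "DRUG", "REAC", "THER"):
            path = os.path.join(out_dir, quarter_file_name(kind, q))
            with open(path, "w", newline="", encoding="utf-8") as fh:
                fh.write("$".join(headers[kind]) + "\n")
                for rec in rows[q][kind]:
                    fh.write("$".join(rec) + "\n")
            paths.append(path)

    n_cases = config.n_reports
    # the RRR the generative model actually implies for each drug: its event
    # probability over the share-weighted mean event probability
    p_event = {d.name: min(1.0, config.background_event_rate * d.rrr_target)
               for d in config.drugs}
    p_mean = sum(d.share * p_event[d.name] for d in config.drugs)
    ledger = {
        "seed": config.seed,
        "target_pt": config.target_pt,
        "n_cases": n_cases,
        "n_event_cases": n_event_cases,
        "background_event_rate": config.background_event_rate,
        "drugs": {
            name: {
                "a": truth_a[name],
                "b": truth_drug_margin[name] - truth_a[name],
                "c": n_event_cases - truth_a[name],
                "d": n_cases - truth_drug_margin[name] - n_event_cases + truth_a[name],
                "rrr_target": specs[name].rrr_target,
                "rrr_implied": p_event[name] / p_mean,
                "weibull_alpha": specs[name].weibull_alpha,
                "weibull_beta": specs[name].weibull_beta,
                "n_tto_clean": len(tto_clean[name]),
            }
            for name in drug_names
        },
        "warnings": warnings,
        "files": [os.path.basename(p) for p in paths],
    }
    with open(os.path.join(out_dir, "ledger.json"), "w", encoding="utf-8") as fh:
        json.dump(ledger, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return ledger


def ledger_check(dataset, ledger: dict, fit_weibull: bool = True) -> dict:
    """Compare pipeline estimates on generated files against ledger truth.

    2x2 cells must match the ledger exactly (date corruption never touches
    the drug/event structure); Weibull estimates are compared by whether the
    true parameters fall inside the fitted 95% CIs.  Returns a per-drug
    report plus overall booleans.
    """
    from .contingency import build_all_tables
    from .tto import collect_tto_sample, weibull_fit, WeibullFitError

    pt = ledger["target_pt"]
    tables = build_all_tables(dataset, pt, drugs=list(ledger["drugs"]))
    report: dict = {"drugs": {}, "all_tables_exact": True}
    for name, truth in ledger["drugs"].items():
        t = tables[name]
        exact = (t.a == truth["a"] and t.b == truth["b"]
                 and t.c == truth["c"] and t.d == truth["d"])
        entry: dict = {
            "table_exact": exact,
            "observed": {"a": t.a, "b": t.b, "c": t.c, "d": t.d},
            "truth": {k: truth[k] for k in "abcd"},
        }
        if not exact:
            report["all_tables_exact"] = False
        if fit_weibull and truth["n_tto_clean"] >= 10:
            sample = collect_tto_sample(dataset, name, pt)
            try:
                fit = weibull_fit(sample.values)
                entry["weibull"] = {
                    "n": fit.n,
                    "alpha_hat": fit.alpha,
                    "beta_hat": fit.beta,
                    "alpha_in_ci": fit.alpha_lo <= truth["weibull_alpha"] <= fit.alpha_hi,
                    "beta_in_ci": fit.beta_lo <= truth["weibull_beta"] <= fit.beta_hi,
                }
            except WeibullFitError as exc:
                entry["weibull"] = {"error": str(exc)}
        report["drugs"][name] = entry
    return report


def config_from_dict(d: dict) -> SyntheticConfig:
    """Build a config from a plain dict (parsed YAML/JSON)."""
    d = dict(d)
    if "drugs" in d:
        d["drugs"] = tuple(
            s if isinstance(s, DrugSpec) else DrugSpec(**s) for s in d["drugs"]
        )
    if "quarters" in d:
        d["quarters"] = tuple(d["quarters"])
    return SyntheticConfig(**d)


def config_to_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["drugs"] = [asdict(s) for s in config.drugs]
    d["quarters"] = list(config.quarters)
    d["decoy_pts"] = list(config.decoy_pts)
    return d
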