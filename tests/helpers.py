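"""Builders for tiny in-memory FAERS-style inputs used across tests."""
from __future__ import annotations

import pandas as pd

from faersig.io import RawReportTables, build_event_dataset


def toy_raw_tables(case_specs: list[dict]) -> RawReportTables:
    """Build raw tables from compact per-case specs.

    Each spec: caseid (str); optional primaryid, fda_dt, event_dt, age,
    age_cod, sex, country; drugs = list of (name, role) or (name, role, seq);
    pts = list of PT strings; starts = {seq: start_dt_text}.
    """
    demo_rows, drug_rows, reac_rows, ther_rows = [], [], [], []
    for spec in case_specs:
        cid = spec["caseid"]
        pid = spec.get("primaryid", cid + "1")
        demo_rows.append({
            "primaryid": pid, "caseid": cid,
            "fda_dt": spec.get("fda_dt", "20230110"),
            "event_dt": spec.get("event_dt", ""),
            "age": spec.get("age", ""), "age_cod": spec.get("age_cod", ""),
            "sex": spec.get("sex", ""), "reporter_country": spec.get("country", ""),
        })
        for i, d in enumerate(spec.get("drugs", []), start=1):
            name, role, *rest = d
            seq = str(rest[0]) if rest else str(i)
            drug_rows.append({"primaryid": pid, "drug_seq": seq,
                              "role_cod": role, "drugname": name})
        for pt in spec.get("pts", []):
            reac_rows.append({"primaryid": pid, "pt": pt})
        for seq, start in spec.get("starts", {}).items():
            ther_rows.append({"primaryid": pid, "dsg_drug_seq": str(seq),
                              "start_dt": start, "end_dt": ""})
    empty = {"DRUG": ["primaryid", "drug_seq", "role_cod", "drugname"],
             "REAC": ["primaryid", "pt"],
             "THER": ["primaryid", "dsg_drug_seq", "start_dt", "end_dt"]}
    return RawReportTables(
        demo=pd.DataFrame(demo_rows, dtype=str),
        drug=pd.DataFrame(drug_rows, dtype=str) if drug_rows
        else pd.DataFrame(columns=empty["DRUG"], dtype=str),
        reac=pd.DataFrame(reac_rows, dtype=str) if reac_rows
        else pd.DataFrame(columns=empty["REAC"], dtype=str),
        ther=pd.DataFrame(ther_rows, dtype=str) if ther_rows
        else pd.DataFrame(columns=empty["THER"], dtype=str),
    )


def toy_dataset(case_specs: list[dict], dedup: bool = True):
    return build_event_dataset(toy_raw_tables(case_specs), dedup=dedup)
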