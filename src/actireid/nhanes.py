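"""Optional adapter for the public NHANES physical activity monitor
(PAM) files.

Maps the SAS transport (XPT) PAM minute files (PAXRAW-style: one row
per minute with an intensity column) and the demographics files onto
the package's canonical cohort tables. The mapping is configuration
driven because variable codes differ between survey cycles; the adapter
is provided untested against live downloads and is excluded from the
test suite — the synthetic generator covers all testing.

Example mapping config (YAML)::

    activity:
      path: paxraw_c.xpt
      record_id: SEQN
      day: PAXDAY        # 1 = Sunday in some cycles: set day_offset
      minute: PAXN       # running minute 1..10080 (set minute_is_weekly)
      intensity: PAXINTEN
      minute_is_weekly: true
      day_offset: 0
    demographics:
      path: demo_c.xpt
      record_id: SEQN
      age: RIDAGEYR
      sex: {var: RIAGENDR, map: {1: male, 2: female}}
      education: {var: DMDEDUC2, map: {1: "<=HS", 2: "<=HS", 3: "<=HS", 4: ">HS", 5: ">HS"}}
      child_education: {var: DMDEDUC3}   # grade codes, recategorised for ages 18-19
      income: {var: INDHHINC, map: {1: "<25k", ...}}
      race_ethnicity: {var: RIDRETH1, map: {...}}
      birth_country: {var: DMDBORN, map: {1: US, 2: non-US, 3: non-US}}
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import ACTIVITY_COLUMNS, DEMOGRAPHIC_COLUMNS, MINUTES_PER_DAY
from .preprocess import recategorize_child_education


def _mapped(series: pd.Series, spec) -> pd.Series:
    if isinstance(spec, str):
        return series
    mapping = {float(k) if str(k).replace(".", "").isdigit() else k: v
               for k, v in spec.get("map", {}).items()}
    return series.map(lambda v: mapping.get(v, mapping.get(float(v)) if pd.notna(v) else None))


def convert_nhanes(config_path: str | Path, out_prefix: str | Path) -> None:
    """Convert an NHANES PAM + demographics XPT pair to the canonical
    CSV pair, per a YAML column-mapping config (see module docstring)."""
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)

    act_cfg = cfg["activity"]
    act = pd.read_sas(act_cfg["path"], format="xport")
    rid = act[act_cfg["record_id"]].astype(int).astype(str)
    if act_cfg.get("minute_is_weekly"):
        weekly = act[act_cfg["minute"]].astype(int) - 1
        day = weekly // MINUTES_PER_DAY + 1
        minute = weekly % MINUTES_PER_DAY + 1
    else:
        day = act[act_cfg["day"]].astype(int) + int(act_cfg.get("day_offset", 0))
        minute = act[act_cfg["minute"]].astype(int)
    out_act = pd.DataFrame(
        {
            "record_id": rid,
            "day_index": day,
            "minute_index": minute,
            "intensity": act[act_cfg["intensity"]].fillna(0).astype(np.int64),
        },
        columns=list(ACTIVITY_COLUMNS),
    )

    demo_cfg = cfg["demographics"]
    demo = pd.read_sas(demo_cfg["path"], format="xport")
    age = demo[demo_cfg["age"]].astype(int)
    education = _mapped(demo[demo_cfg["education"]["var"]], demo_cfg["education"])
    if "child_education" in demo_cfg:
        child_codes = demo[demo_cfg["child_education"]["var"]]
        needs = education.isna() & age.between(18, 19) & child_codes.notna()
        education = education.mask(
            needs, child_codes.map(lambda c: recategorize_child_education(int(c)))
        )
    out_demo = pd.DataFrame(
        {
            "record_id": demo[demo_cfg["record_id"]].astype(int).astype(str),
            "age_years": age,
            "sex": _mapped(demo[demo_cfg["sex"]["var"]], demo_cfg["sex"]),
            "education": education,
            "income": _mapped(demo[demo_cfg["income"]["var"]], demo_cfg["income"]),
            "race_ethnicity": _mapped(
                demo[demo_cfg["race_ethnicity"]["var"]], demo_cfg["race_ethnicity"]
            ),
            "birth_country": _mapped(
                demo[demo_cfg["birth_country"]["var"]], demo_cfg["birth_country"]
            ),
        },
        columns=list(DEMOGRAPHIC_COLUMNS),
    )
    out_demo = out_demo[out_demo["record_id"].isin(set(out_act["record_id"]))]
    out_act.to_csv(f"{out_prefix}_activity.csv", index=False)
    out_demo.fillna("").to_csv(f"{out_prefix}_demographics.csv", index=False)
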