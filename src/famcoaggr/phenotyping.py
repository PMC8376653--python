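"""Binary lifetime adult phenotypes from raw diagnosis and prescription records.

A person is flagged for a condition if any diagnosis record matches one of the
catalog's ICD prefixes for that condition (after dot stripping), at or above
the minimum adult age, inside the register observation window for the record's
setting (inpatient vs outpatient; calendar year is reconstructed as birth year
+ age when explicit dates are absent).  Exclusion prefixes remove matching
records before flagging — e.g. narcolepsy codes never count towards the
sleep-disorders flag.  ADHD is flagged from either a qualifying ICD record or
a qualifying stimulant (ATC N06BA) prescription at adult age.

All phenotypes are lifetime presence/absence: absence of records means 0,
never missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .catalog import ConditionCatalog, normalize_code

__all__ = [
    "classify_adhd",
    "classify_conditions",
    "aggregate_groups",
    "build_phenotypes",
]

_DIAG_COLS = ("person_id", "icd_version", "code", "age_years", "setting")


def _validate_diagnoses(diagnoses: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in _DIAG_COLS if c not in diagnoses.columns]
    if missing:
        raise ValueError(f"diagnosis table missing columns: {missing}")
    versions = set(pd.unique(diagnoses["icd_version"].dropna()))
    bad = versions - {8, 9, 10}
    if bad:
        raise ValueError(f"unknown ICD versions in diagnosis table: {sorted(bad)}")
    return diagnoses


def _admissible(
    diagnoses: pd.DataFrame, persons: pd.DataFrame, catalog: ConditionCatalog
) -> pd.DataFrame:
    """Subset of diagnosis records satisfying age and calendar-window rules."""
    d = _validate_diagnoses(diagnoses)
    if d.empty:
        return d.assign(norm_code=pd.Series(dtype=str))
    d = d.merge(persons[["person_id", "birth_year"]], on="person_id", how="left")
    year = d["birth_year"] + d["age_years"]
    adult = d["age_years"] >= catalog.min_age_years
    inp_lo, inp_hi = catalog.inpatient_window
    out_lo, out_hi = catalog.outpatient_window
    in_window = np.where(
        d["setting"].astype(str).str.lower().eq("inpatient"),
        (year >= inp_lo) & (year <= inp_hi),
        (year >= out_lo) & (year <= out_hi),
    )
    keep = d[adult & in_window].copy()
    keep["norm_code"] = keep["code"].map(normalize_code)
    return keep


def _prefix_match(codes: pd.Series, prefixes: tuple[str, ...]) -> pd.Series:
    if not prefixes:
        return pd.Series(False, index=codes.index)
    return codes.str.startswith(prefixes)


def classify_adhd(
    diagnoses: pd.DataFrame,
    prescriptions: pd.DataFrame,
    catalog: ConditionCatalog,
    persons: pd.DataFrame,
) -> pd.Series:
    """Lifetime adult ADHD flag per person (index: person_id, values 0/1).

    Flag = 1 iff a qualifying ICD diagnosis (prefix match on the catalog's ADHD
    rule, adult age, inside the register window) OR a qualifying stimulant
    prescription (exact ATC code, adult age) exists.
    """
    adm = _admissible(diagnoses, persons, catalog)
    flagged: set = set()
    if not adm.empty:
        hit = pd.Series(False, index=adm.index)
        for version in (8, 9, 10):
            pref = catalog.adhd_rule.prefixes(version)
            if pref:
                sub = adm["icd_version"] == version
                hit |= sub & _prefix_match(adm["norm_code"], pref)
        flagged |= set(adm.loc[hit, "person_id"])
    if prescriptions is not None and len(prescriptions):
        rx = prescriptions
        ok = rx["atc_code"].astype(str).isin(catalog.adhd_rule.atc_codes) & (
            rx["age_years"] >= catalog.min_age_years
        )
        flagged |= set(rx.loc[ok, "person_id"])
    out = pd.Series(0, index=pd.Index(persons["person_id"], name="person_id"), dtype=np.int8)
    if flagged:
        out.loc[out.index.isin(flagged)] = 1
    return out.rename("adhd")


def classify_conditions(
    diagnoses: pd.DataFrame,
    catalog: ConditionCatalog,
    persons: pd.DataFrame,
) -> pd.DataFrame:
    """Lifetime adult flags for every catalog condition.

    Returns a DataFrame indexed by person_id with one 0/1 column per condition.
    Exclusion prefixes drop matching records for that condition before
    flagging.  Codes matching no rule are registry noise and are ignored.
    """
    adm = _admissible(diagnoses, persons, catalog)
    idx = pd.Index(persons["person_id"], name="person_id")
    out = pd.DataFrame(0, index=idx, columns=list(catalog.condition_names), dtype=np.int8)
    if adm.empty:
        return out
    for cond in catalog.conditions:
        hit = pd.Series(False, index=adm.index)
        for version in (8, 9, 10):
            pref = cond.prefixes(version)
            if not pref:
                continue
            sub = adm["icd_version"] == version
            match = sub & _prefix_match(adm["norm_code"], pref)
            excl = cond.exclusions(version)
            if excl:
                match &= ~_prefix_match(adm["norm_code"], excl)
            hit |= match
        ids = adm.loc[hit, "person_id"]
        if len(ids):
            out.loc[out.index.isin(set(ids)), cond.name] = 1
    return out


def aggregate_groups(
    condition_table: pd.DataFrame, catalog: ConditionCatalog
) -> pd.DataFrame:
    """Disease-group flags: logical OR over each group's member conditions."""
    cols = {}
    for group in catalog.groups:
        members = [m for m in catalog.group_members(group) if m in condition_table.columns]
        if not members:
            continue
        cols[f"grp_{group}"] = (
            condition_table[members].to_numpy().max(axis=1).astype(np.int8)
        )
    return pd.DataFrame(cols, index=condition_table.index)


def build_phenotypes(
    persons: pd.DataFrame,
    diagnoses: pd.DataFrame,
    prescriptions: pd.DataFrame,
    catalog: ConditionCatalog,
) -> pd.DataFrame:
    """Full phenotype table: person_id + ADHD + condition + group columns."""
    adhd = classify_adhd(diagnoses, prescriptions, catalog, persons)
    conds = classify_conditions(diagnoses, catalog, persons)
    groups = aggregate_groups(conds, catalog)
    table = pd.concat([adhd, conds, groups], axis=1)
    return table.reset_index()
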