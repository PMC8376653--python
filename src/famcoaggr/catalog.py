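"""Condition catalog: mapping from ICD/ATC codes to conditions and disease groups.

A catalog declares, for each physical condition, the ICD code prefixes (per ICD
revision 8/9/10) that identify it in diagnosis records, the broader disease group
it belongs to, and optional exclusion prefixes (e.g. narcolepsy is excluded from
the sleep-disorders definition because ADHD medication is occasionally used
off-label for it).  The catalog also carries the ADHD case definition (ICD
prefixes plus ATC stimulant-prescription codes) and the register observation
windows for inpatient and outpatient records.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import yaml

#: Canonical disease groups (ICD-10 chapter structure).
DISEASE_GROUPS = (
    "circulatory",
    "endocrine_metabolic",
    "gastrointestinal",
    "genitourinary",
    "musculoskeletal",
    "nervous_system",
    "respiratory",
    "skin",
)


class CatalogError(ValueError):
    """Raised when a catalog file violates the schema."""


def normalize_code(code: str) -> str:
    """Normalise an ICD code for prefix matching: strip dots, upper-case.

    Register dumps vary in dot usage ("F90.0" vs "F900"); matching is performed
    on the dot-free form.
    """
    return str(code).replace(".", "").replace(" ", "").upper()


@dataclass(frozen=True)
class ConditionRule:
    """ICD matching rule for one physical condition."""

    name: str
    group: str
    icd10: tuple[str, ...]
    icd9: tuple[str, ...] = ()
    icd8: tuple[str, ...] = ()
    exclude_icd10: tuple[str, ...] = ()
    exclude_icd9: tuple[str, ...] = ()
    exclude_icd8: tuple[str, ...] = ()

    def prefixes(self, icd_version: int) -> tuple[str, ...]:
        try:
            raw = {8: self.icd8, 9: self.icd9, 10: self.icd10}[int(icd_version)]
        except KeyError:
            raise CatalogError(f"unknown ICD version: {icd_version!r}") from None
        return tuple(normalize_code(p) for p in raw)

    def exclusions(self, icd_version: int) -> tuple[str, ...]:
        raw = {8: self.exclude_icd8, 9: self.exclude_icd9, 10: self.exclude_icd10}[
            int(icd_version)
        ]
        return tuple(normalize_code(p) for p in raw)


@dataclass(frozen=True)
class AdhdRule:
    """ADHD case definition: ICD prefixes per revision plus ATC medication codes."""

    icd_prefixes: dict[int, tuple[str, ...]]
    atc_codes: tuple[str, ...]

    def prefixes(self, icd_version: int) -> tuple[str, ...]:
        return tuple(
            normalize_code(p) for p in self.icd_prefixes.get(int(icd_version), ())
        )


@dataclass(frozen=True)
class ConditionCatalog:
    conditions: tuple[ConditionRule, ...]
    adhd_rule: AdhdRule
    min_age_years: int = 18
    inpatient_window: tuple[int, int] = (1973, 2013)
    outpatient_window: tuple[int, int] = (2001, 2013)

    def __post_init__(self) -> None:
        problems = []
        seen: set[str] = set()
        for cond in self.conditions:
            if cond.name in seen:
                problems.append(f"duplicate condition name: {cond.name}")
            seen.add(cond.name)
            if cond.group not in DISEASE_GROUPS:
                problems.append(f"unknown group {cond.group!r} for {cond.name}")
            if not cond.icd10:
                problems.append(f"empty ICD-10 prefix list for {cond.name}")
        if not self.adhd_rule.atc_codes:
            problems.append("ADHD rule has no ATC codes")
        if problems:
            raise CatalogError("; ".join(problems))

    @property
    def condition_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.conditions)

    @property
    def groups(self) -> tuple[str, ...]:
        """Groups actually used, in canonical order."""
        used = {c.group for c in self.conditions}
        return tuple(g for g in DISEASE_GROUPS if g in used)

    def group_members(self, group: str) -> tuple[str, ...]:
        return tuple(c.name for c in self.conditions if c.group == group)

    def condition(self, name: str) -> ConditionRule:
        for c in self.conditions:
            if c.name == name:
                return c
        raise KeyError(name)

    def to_dict(self) -> dict:
        conds = []
        for c in self.conditions:
            d = {"name": c.name, "group": c.group, "icd10": list(c.icd10)}
            if c.icd9:
                d["icd9"] = list(c.icd9)
            if c.icd8:
                d["icd8"] = list(c.icd8)
            if c.exclude_icd10:
                d["exclude_icd10"] = list(c.exclude_icd10)
            if c.exclude_icd9:
                d["exclude_icd9"] = list(c.exclude_icd9)
            if c.exclude_icd8:
                d["exclude_icd8"] = list(c.exclude_icd8)
            conds.append(d)
        return {
            "min_age_years": self.min_age_years,
            "inpatient_window": list(self.inpatient_window),
            "outpatient_window": list(self.outpatient_window),
            "adhd_rule": {
                "icd_prefixes": {
                    int(v): list(p) for v, p in self.adhd_rule.icd_prefixes.items()
                },
                "atc_codes": list(self.adhd_rule.atc_codes),
            },
            "conditions": conds,
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "ConditionCatalog":
        try:
            conds = tuple(
                ConditionRule(
                    name=str(c["name"]),
                    group=str(c["group"]),
                    icd10=tuple(str(x) for x in c.get("icd10", ())),
                    icd9=tuple(str(x) for x in c.get("icd9", ()) or ()),
                    icd8=tuple(str(x) for x in c.get("icd8", ()) or ()),
                    exclude_icd10=tuple(str(x) for x in c.get("exclude_icd10", ()) or ()),
                    exclude_icd9=tuple(str(x) for x in c.get("exclude_icd9", ()) or ()),
                    exclude_icd8=tuple(str(x) for x in c.get("exclude_icd8", ()) or ()),
                )
                for c in raw["conditions"]
            )
            adhd = raw["adhd_rule"]
            rule = AdhdRule(
                icd_prefixes={
                    int(v): tuple(str(x) for x in p)
                    for v, p in adhd["icd_prefixes"].items()
                },
                atc_codes=tuple(str(x) for x in adhd["atc_codes"]),
            )
        except (KeyError, TypeError) as exc:
            raise CatalogError(f"malformed catalog: {exc}") from exc
        return cls(
            conditions=conds,
            adhd_rule=rule,
            min_age_years=int(raw.get("min_age_years", 18)),
            inpatient_window=tuple(raw.get("inpatient_window", (1973, 2013))),
            outpatient_window=tuple(raw.get("outpatient_window", (2001, 2013))),
        )


def load_catalog(path) -> ConditionCatalog:
    """Load and validate a catalog from a YAML (or JSON) file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise CatalogError(f"catalog file {path} did not parse to a mapping")
    return ConditionCatalog.from_dict(raw)


def save_catalog(catalog: ConditionCatalog, path) -> None:
    """Write a catalog to YAML; load_catalog(save_catalog(c)) == c."""
    with open(path, "w") as fh:
        yaml.safe_dump(catalog.to_dict(), fh, sort_keys=False)


def default_catalog() -> ConditionCatalog:
    """The packaged provisional catalog: 35 conditions in 8 disease groups."""
    ref = importlib.resources.files("famcoaggr.data") / "default_catalog.yaml"
    raw = yaml.safe_load(ref.read_text())
    cat = ConditionCatalog.from_dict(raw)
    assert len(cat.conditions) == 35 and len(cat.groups) == 8
    return cat
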