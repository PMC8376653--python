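"""Study inclusion rules, sibling-pair construction and family clusters.

The analysis population is restricted to persons born 1932-1995 who were alive
and resident at the start of 2005.  Sibling pairs are classified from parent
links: same mother and father -> full siblings; same mother, different father
-> maternal half siblings.  The full-sibling cohort additionally excludes
twins and anyone who has a half-sibling (maternal or paternal), so it is
uncontaminated by half-sibships.  Every unordered qualifying pair is
double-entered (each member once as exposure and once as outcome), and family
clusters are the connected components of the person-parent link graph.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "apply_exclusions",
    "build_pairs",
    "build_clusters",
    "filter_age_gap",
]

logger = logging.getLogger(__name__)

BIRTH_WINDOW = (1932, 1995)
REGISTER_CUTOFF_YEAR = 2005


def apply_exclusions(
    persons: pd.DataFrame,
    birth_window: tuple[int, int] = BIRTH_WINDOW,
    cutoff_year: int = REGISTER_CUTOFF_YEAR,
) -> pd.DataFrame:
    """Apply cohort-level exclusions and annotate pair-eligibility flags.

    Removes persons who died or emigrated before ``cutoff_year`` and persons
    born outside ``birth_window``.  Adds a ``has_half_sibling`` column (any
    shared-mother-different-father or shared-father-different-mother link in
    the post-exclusion population); ``build_pairs`` uses it together with
    ``is_twin`` to keep the full-sibling cohort uncontaminated.
    """
    p = persons.copy()
    alive = p["death_emig_year"].isna() | (p["death_emig_year"] >= cutoff_year)
    born = p["birth_year"].between(birth_window[0], birth_window[1])
    p = p[alive & born].copy()

    n_unlinked = int(p["mother_id"].isna().sum())
    if n_unlinked:
        logger.info(
            "%d persons lack a mother link and cannot enter pair formation",
            n_unlinked,
        )

    # half-sib detection: within a mother, >1 distinct father (and vice versa)
    has_half = pd.Series(False, index=p.index)
    for parent, other in (("mother_id", "father_id"), ("father_id", "mother_id")):
        linked = p[parent].notna() & p[other].notna()
        sub = p.loc[linked, [parent, other]]
        n_other = sub.groupby(parent)[other].transform("nunique")
        has_half.loc[linked] |= n_other > 1
    p["has_half_sibling"] = has_half.to_numpy()
    return p.reset_index(drop=True)


def build_pairs(persons: pd.DataFrame) -> pd.DataFrame:
    """All double-entered sibling pairs with relation and birth-year gap.

    Returns one row per ordered pair: columns exposure_id, outcome_id,
    relation ('full' | 'maternal_half'), birth_year_gap.  Full-sibling pairs
    require both members non-twin and free of half-siblings; maternal
    half-sibling pairs require shared mother and different (known) fathers.
    Persons without a mother link are excluded from pair formation.
    """
    p = persons[persons["mother_id"].notna()][
        ["person_id", "mother_id", "father_id", "birth_year", "is_twin"]
    ]
    if "has_half_sibling" not in persons.columns:
        raise ValueError("run apply_exclusions first (has_half_sibling missing)")
    p = p.merge(
        persons[["person_id", "has_half_sibling"]], on="person_id", how="left"
    )
    # ordered pairs sharing a mother
    m = p.merge(p, on="mother_id", suffixes=("_x", "_y"))
    m = m[m["person_id_x"] != m["person_id_y"]]
    same_father = (
        m["father_id_x"].notna()
        & m["father_id_y"].notna()
        & (m["father_id_x"] == m["father_id_y"])
    )
    diff_father = (
        m["father_id_x"].notna()
        & m["father_id_y"].notna()
        & (m["father_id_x"] != m["father_id_y"])
    )
    fs_ok = (
        same_father
        & ~m["is_twin_x"] & ~m["is_twin_y"]
        & ~m["has_half_sibling_x"] & ~m["has_half_sibling_y"]
    )
    pairs = m[fs_ok | diff_father].copy()
    pairs["relation"] = np.where(same_father[fs_ok | diff_father], "full", "maternal_half")
    pairs["birth_year_gap"] = (pairs["birth_year_x"] - pairs["birth_year_y"]).abs()
    out = pairs.rename(
        columns={"person_id_x": "exposure_id", "person_id_y": "outcome_id"}
    )[["exposure_id", "outcome_id", "relation", "birth_year_gap"]]
    return out.sort_values(["relation", "exposure_id", "outcome_id"], kind="stable").reset_index(drop=True)


def build_clusters(persons: pd.DataFrame) -> pd.DataFrame:
    """Family clusters: connected components of the person-parent graph.

    Two persons share a cluster iff they are linked through any chain of
    parent-child relations (so half-siblings bridge their fathers' sibships).
    Cluster ids are deterministic: components are numbered by their smallest
    member person_id.
    """
    g = nx.Graph()
    ids = persons["person_id"].tolist()
    g.add_nodes_from(ids)
    for col in ("mother_id", "father_id"):
        sub = persons[persons[col].notna()]
        g.add_edges_from(
            zip(sub["person_id"], ("p:" + sub[col].astype(str)))
        )
    comp_of: dict = {}
    components = []
    for comp in nx.connected_components(g):
        members = sorted(x for x in comp if not (isinstance(x, str) and x.startswith("p:")))
        if members:
            components.append(members)
    components.sort(key=lambda mem: mem[0])
    rows = []
    for cid, members in enumerate(components):
        rows.extend((cid, pid) for pid in members)
    return pd.DataFrame(rows, columns=["cluster_id", "person_id"])


def filter_age_gap(pairs: pd.DataFrame, max_gap: int = 10) -> pd.DataFrame:
    """Retain pairs born at most ``max_gap`` years apart (boundary inclusive)."""
    return pairs[pairs["birth_year_gap"] <= max_gap].reset_index(drop=True)
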