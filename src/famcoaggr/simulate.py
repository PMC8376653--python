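"""Synthetic register cohorts under a bivariate liability-threshold ACE model.

Each person carries two correlated binary lifetime phenotypes (trait 1 is ADHD,
trait 2 a physical condition).  Liability for each trait is a standard-normal
latent variable composed of additive-genetic (A), shared-environmental (C) and
non-shared-environmental (E) parts; a trait is present when liability exceeds
the threshold Phi^-1(1 - prevalence).  Siblings share A at the expected
coefficient of relationship (0.5 for full siblings, 0.25 for maternal half
siblings), share C completely, and have independent E.  Cross-trait overlap is
injected through correlations rA, rC, rE between the two traits' components,
so the within-person cross-trait liability correlation is

    r_ph = a1*a2*rA + c1*c2*rC + e1*e2*rE.

Present traits are emitted as register-style diagnosis records (and, for ADHD,
stimulant-prescription records), so the cohort can be pushed through the same
phenotyping and analysis code paths that a real register extract would use.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import ConditionCatalog, default_catalog

__all__ = [
    "AceTruth",
    "FamilySpec",
    "SyntheticCohort",
    "simulate_ace_families",
    "simulate_bernoulli_pairs",
    "solve_joint_cell",
    "empirical_component_correlation",
]

#: expected cross-sibling correlation of the additive-genetic component
A_SHARING = {"full": 0.5, "maternal_half": 0.25}


@dataclass(frozen=True)
class AceTruth:
    """Ground-truth parameters of the bivariate liability-threshold ACE model.

    ``a1, c1, e1`` (and ``a2, c2, e2``) are standardized loadings, so the A/C/E
    variance shares of trait *t* are ``a_t**2, c_t**2, e_t**2`` and must sum to
    one.  ``rA, rC, rE`` are the cross-trait correlations of the component
    pairs.  ``beta_sex`` / ``beta_byear`` shift the liability mean linearly
    (units: liability SD per unit covariate; sex is coded -0.5/+0.5 and birth
    year per decade from the midpoint of the sampled range).
    """

    a1: float
    c1: float
    e1: float
    a2: float
    c2: float
    e2: float
    rA: float
    rC: float
    rE: float
    prev1: float = 0.0129
    prev2: float = 0.0257
    beta_sex: tuple[float, float] = (0.0, 0.0)
    beta_byear: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        for t, (a, c, e) in enumerate(
            [(self.a1, self.c1, self.e1), (self.a2, self.c2, self.e2)], start=1
        ):
            tot = a * a + c * c + e * e
            if abs(tot - 1.0) > 1e-8:
                raise ValueError(
                    f"trait {t} loadings not standardized: a^2+c^2+e^2={tot:.6f}"
                )
        for name in ("rA", "rC", "rE"):
            r = getattr(self, name)
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"{name}={r} outside [-1, 1]")
        for name in ("prev1", "prev2"):
            p = getattr(self, name)
            if not 0.0 < p < 1.0:
                raise ValueError(f"{name}={p} outside (0, 1)")
        if not -1.0 <= self.r_ph <= 1.0:
            raise ValueError(f"implied phenotypic correlation {self.r_ph} invalid")

    # -- implied quantities -------------------------------------------------
    @property
    def cov_a(self) -> float:
        """Additive-genetic contribution to the cross-trait correlation."""
        return self.a1 * self.a2 * self.rA

    @property
    def cov_c(self) -> float:
        return self.c1 * self.c2 * self.rC

    @property
    def cov_e(self) -> float:
        return self.e1 * self.e2 * self.rE

    @property
    def r_ph(self) -> float:
        """Within-person cross-trait liability correlation."""
        return self.cov_a + self.cov_c + self.cov_e

    def cross_sib_same_trait(self, trait: int, relation: str) -> float:
        """Implied cross-sibling correlation of one trait's liability."""
        phi = A_SHARING[relation]
        a, c = (self.a1, self.c1) if trait == 1 else (self.a2, self.c2)
        return phi * a * a + c * c

    def cross_sib_cross_trait(self, relation: str) -> float:
        phi = A_SHARING[relation]
        return phi * self.cov_a + self.cov_c

    @classmethod
    def from_variance_shares(
        cls,
        h2_1: float,
        c2_1: float,
        h2_2: float,
        c2_2: float,
        rA: float = 0.0,
        rC: float = 0.0,
        rE: float = 0.0,
        **kwargs,
    ) -> "AceTruth":
        """Build from per-trait A/C variance shares (E takes the remainder)."""
        e2_1 = 1.0 - h2_1 - c2_1
        e2_2 = 1.0 - h2_2 - c2_2
        if e2_1 < 0 or e2_2 < 0:
            raise ValueError("variance shares exceed 1")
        return cls(
            a1=math.sqrt(h2_1), c1=math.sqrt(c2_1), e1=math.sqrt(e2_1),
            a2=math.sqrt(h2_2), c2=math.sqrt(c2_2), e2=math.sqrt(e2_2),
            rA=rA, rC=rC, rE=rE, **kwargs,
        )

    @classmethod
    def from_cross_trait_shares(
        cls,
        r_ph: float,
        share_a: float,
        share_c: float,
        h2_1: float,
        c2_1: float,
        h2_2: float,
        c2_2: float,
        **kwargs,
    ) -> "AceTruth":
        """Build a truth whose cross-trait correlation decomposes as requested.

        ``share_a`` and ``share_c`` are the fractions of ``r_ph`` carried by A
        and C (E takes the remainder); the component correlations are solved
        from the loadings, e.g. ``rA = share_a * r_ph / (a1 * a2)``.
        """
        base = cls.from_variance_shares(h2_1, c2_1, h2_2, c2_2)
        share_e = 1.0 - share_a - share_c
        rA = share_a * r_ph / (base.a1 * base.a2)
        rC = share_c * r_ph / (base.c1 * base.c2)
        rE = share_e * r_ph / (base.e1 * base.e2)
        return cls.from_variance_shares(
            h2_1, c2_1, h2_2, c2_2, rA=rA, rC=rC, rE=rE, **kwargs
        )


@dataclass(frozen=True)
class FamilySpec:
    """Layout of the simulated sibships."""

    n_fullsib_families: int
    n_halfsib_families: int
    pair_size: int = 2
    birth_year_range: tuple[int, int] = (1932, 1995)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_fullsib_families < 0 or self.n_halfsib_families < 0:
            raise ValueError("family counts must be non-negative")
        if self.pair_size < 2:
            raise ValueError("pair_size must be at least 2")
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SyntheticCohort:
    """Register-style tables produced by the generator, plus the truth used."""

    persons: pd.DataFrame
    diagnoses: pd.DataFrame
    prescriptions: pd.DataFrame
    truth: AceTruth
    latent: pd.DataFrame | None = None

    def write(self, outdir) -> None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.persons.to_csv(out / "persons.csv", index=False)
        self.diagnoses.to_csv(out / "diagnoses.csv", index=False)
        self.prescriptions.to_csv(out / "prescriptions.csv", index=False)


def _component_corr_check(truth: AceTruth) -> None:
    # each cross-trait component block [[1, r], [r, 1]] must be PSD
    for name in ("rA", "rC", "rE"):
        r = getattr(truth, name)
        if abs(r) > 1.0:
            raise ValueError(
                f"component covariance not positive definite: {name}={r}"
            )


def _draw_bivariate(rng: np.random.Generator, n: int, r: float) -> np.ndarray:
    """n draws from a standard bivariate normal with correlation r, shape (n, 2)."""
    z = rng.standard_normal((n, 2))
    out = np.empty_like(z)
    out[:, 0] = z[:, 0]
    out[:, 1] = r * z[:, 0] + math.sqrt(max(0.0, 1.0 - r * r)) * z[:, 1]
    return out


def simulate_ace_families(
    truth: AceTruth,
    spec: FamilySpec,
    catalog: ConditionCatalog | None = None,
    condition: str = "sleep_disorders",
    keep_latent: bool = False,
) -> SyntheticCohort:
    """Simulate sibships with two thresholded ACE liabilities per person.

    Each family contributes ``spec.pair_size`` siblings.  Components are built
    as ``sqrt(rho) * family_part + sqrt(1 - rho) * individual_part`` with
    rho = 0.5 (FS) / 0.25 (HS) for A, 1 for C, 0 for E, which reproduces the
    expected sibling sharing exactly; the family and individual parts are drawn
    jointly across traits with correlations ``rA, rC, rE``.

    Present traits are emitted as outpatient ICD-10 diagnosis records dated
    (via age + birth year) inside the outpatient register window, so that
    downstream phenotyping recovers the simulated flags exactly.  ADHD cases
    receive a diagnosis, a stimulant prescription, or both.
    """
    _component_corr_check(truth)
    catalog = catalog or default_catalog()
    rule = catalog.condition(condition)
    cond_code = rule.icd10[0]
    adhd_code = (catalog.adhd_rule.icd_prefixes.get(10) or ("F90",))[0]
    atc_code = catalog.adhd_rule.atc_codes[0]
    rng = np.random.default_rng(spec.seed)

    blocks = []
    offset = 0
    for relation, n_fam in (
        ("full", spec.n_fullsib_families),
        ("maternal_half", spec.n_halfsib_families),
    ):
        if n_fam == 0:
            continue
        k = spec.pair_size
        n = n_fam * k
        rho_a = A_SHARING[relation]

        # family-shared and individual component parts, jointly bivariate
        fam_a = np.repeat(_draw_bivariate(rng, n_fam, truth.rA), k, axis=0)
        ind_a = _draw_bivariate(rng, n, truth.rA)
        A = math.sqrt(rho_a) * fam_a + math.sqrt(1.0 - rho_a) * ind_a
        C = np.repeat(_draw_bivariate(rng, n_fam, truth.rC), k, axis=0)
        E = _draw_bivariate(rng, n, truth.rE)

        liab1 = truth.a1 * A[:, 0] + truth.c1 * C[:, 0] + truth.e1 * E[:, 0]
        liab2 = truth.a2 * A[:, 1] + truth.c2 * C[:, 1] + truth.e2 * E[:, 1]

        fam_idx = np.repeat(np.arange(n_fam), k)
        sib_idx = np.tile(np.arange(k), n_fam)
        pid = offset + np.arange(n)
        fid = offset + fam_idx

        lo, hi = spec.birth_year_range
        base = rng.integers(lo, max(lo + 1, hi - 3 * (k - 1)), size=n_fam)
        gaps = rng.integers(1, 5, size=(n_fam, k))
        gaps[:, 0] = 0
        byear = np.minimum(base[fam_idx] + np.cumsum(gaps, axis=1).ravel(), hi)
        sex = rng.integers(1, 3, size=n)

        sex_c = np.where(sex == 2, 0.5, -0.5)
        byear_c = (byear - (lo + hi) / 2.0) / 10.0
        shift1 = truth.beta_sex[0] * sex_c + truth.beta_byear[0] * byear_c
        shift2 = truth.beta_sex[1] * sex_c + truth.beta_byear[1] * byear_c

        tau1 = stats.norm.ppf(1.0 - truth.prev1)
        tau2 = stats.norm.ppf(1.0 - truth.prev2)
        trait1 = (liab1 + shift1 > tau1).astype(np.int8)
        trait2 = (liab2 + shift2 > tau2).astype(np.int8)

        # mother shared within family; fathers shared only for full sibs
        mother = np.char.add("M", fid.astype(str))
        if relation == "full":
            father = np.char.add("F", fid.astype(str))
        else:
            father = np.char.add(
                "F", np.char.add(fid.astype(str), np.char.add("_", sib_idx.astype(str)))
            )

        blocks.append(
            pd.DataFrame(
                {
                    "person_id": pid,
                    "family_id": fid,
                    "mother_id": mother,
                    "father_id": father,
                    "sex": sex,
                    "birth_year": byear,
                    "death_emig_year": np.full(n, np.nan),
                    "is_twin": np.zeros(n, dtype=bool),
                    "relation": relation,
                    "trait1": trait1,
                    "trait2": trait2,
                    "A1": A[:, 0], "A2": A[:, 1],
                    "C1": C[:, 0], "C2": C[:, 1],
                    "E1": E[:, 0], "E2": E[:, 1],
                    "liab1": liab1, "liab2": liab2,
                }
            )
        )
        offset += n

    cols_person = [
        "person_id", "family_id", "mother_id", "father_id",
        "sex", "birth_year", "death_emig_year", "is_twin",
    ]
    if blocks:
        full = pd.concat(blocks, ignore_index=True)
    else:
        full = pd.DataFrame(
            columns=cols_person + ["relation", "trait1", "trait2",
                                   "A1", "A2", "C1", "C2", "E1", "E2",
                                   "liab1", "liab2"]
        )
    persons = full[cols_person].copy()

    def _ages(byears: np.ndarray) -> np.ndarray:
        """Diagnosis ages placing the record inside the outpatient window."""
        lo_w, hi_w = catalog.outpatient_window
        amin = np.maximum(catalog.min_age_years, lo_w - byears)
        amax = hi_w - byears
        u = rng.random(byears.size)
        return np.floor(amin + u * (amax - amin + 1)).astype(int)

    # trait 2 -> condition diagnoses
    mask2 = full["trait2"].to_numpy(dtype=bool) if len(full) else np.zeros(0, bool)
    by2 = full.loc[mask2, "birth_year"].to_numpy()
    diag2 = pd.DataFrame(
        {
            "person_id": full.loc[mask2, "person_id"].to_numpy(),
            "icd_version": 10,
            "code": cond_code,
            "age_years": _ages(by2),
            "setting": "outpatient",
        }
    )

    # trait 1 -> ADHD: diagnosis only / both / prescription only
    mask1 = full["trait1"].to_numpy(dtype=bool) if len(full) else np.zeros(0, bool)
    pid1 = full.loc[mask1, "person_id"].to_numpy()
    by1 = full.loc[mask1, "birth_year"].to_numpy()
    u = rng.random(pid1.size)
    rx_only = u < 0.2
    both = (u >= 0.2) & (u < 0.5)
    dx = ~rx_only
    rx = rx_only | both
    diag1 = pd.DataFrame(
        {
            "person_id": pid1[dx],
            "icd_version": 10,
            "code": adhd_code,
            "age_years": _ages(by1[dx]),
            "setting": "outpatient",
        }
    )
    prescriptions = pd.DataFrame(
        {
            "person_id": pid1[rx],
            "atc_code": atc_code,
            "age_years": _ages(by1[rx]),
        }
    )
    diagnoses = pd.concat([diag1, diag2], ignore_index=True)
    if diagnoses.empty:
        diagnoses = pd.DataFrame(
            columns=["person_id", "icd_version", "code", "age_years", "setting"]
        )
    if prescriptions.empty:
        prescriptions = pd.DataFrame(columns=["person_id", "atc_code", "age_years"])

    latent = None
    if keep_latent:
        latent = full[
            ["person_id", "family_id", "relation", "trait1", "trait2",
             "A1", "A2", "C1", "C2", "E1", "E2", "liab1", "liab2"]
        ].copy()
    return SyntheticCohort(
        persons=persons,
        diagnoses=diagnoses.sort_values("person_id", kind="stable").reset_index(drop=True),
        prescriptions=prescriptions,
        truth=truth,
        latent=latent,
    )


def solve_joint_cell(odds_ratio: float, p1: float, p2: float) -> float:
    """Joint success probability P(X=1, Y=1) given both margins and the OR.

    Solves the quadratic ``(OR-1) p11^2 - [(OR-1)(p1+p2) + 1] p11 + OR p1 p2 = 0``
    for the root inside the Frechet bounds.
    """
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    if not (0 < p1 < 1 and 0 < p2 < 1):
        raise ValueError("margins must be in (0, 1)")
    lo = max(0.0, p1 + p2 - 1.0)
    hi = min(p1, p2)
    if odds_ratio == 1.0:
        p11 = p1 * p2
    else:
        a = odds_ratio - 1.0
        b = -(a * (p1 + p2) + 1.0)
        c = odds_ratio * p1 * p2
        disc = b * b - 4.0 * a * c
        if disc < 0:
            raise ValueError("infeasible odds ratio / margin combination")
        r1 = (-b - math.sqrt(disc)) / (2.0 * a)
        r2 = (-b + math.sqrt(disc)) / (2.0 * a)
        cands = [r for r in (r1, r2) if lo - 1e-12 <= r <= hi + 1e-12]
        if not cands:
            raise ValueError("infeasible odds ratio / margin combination")
        p11 = min(cands, key=lambda r: abs(r - (lo + hi) / 2))
    cells = {
        "p11": p11,
        "p10": p1 - p11,
        "p01": p2 - p11,
        "p00": 1.0 - p1 - p2 + p11,
    }
    if any(v <= 0 for v in cells.values()):
        raise ValueError(
            f"infeasible odds ratio / margin combination (cells {cells})"
        )
    return p11


def simulate_bernoulli_pairs(
    odds_ratio: float,
    prev_exposure: float,
    prev_outcome: float,
    n: int,
    seed: int,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Draw iid binary (exposure, outcome) pairs with given margins and OR.

    Returns the sampled two-column table and the exact cell probabilities the
    sample was drawn from.
    """
    p11 = solve_joint_cell(odds_ratio, prev_exposure, prev_outcome)
    cells = {
        "p11": p11,
        "p10": prev_exposure - p11,
        "p01": prev_outcome - p11,
        "p00": 1.0 - prev_exposure - prev_outcome + p11,
    }
    rng = np.random.default_rng(seed)
    draw = rng.choice(4, size=n, p=[cells["p11"], cells["p10"], cells["p01"], cells["p00"]])
    exposure = (draw <= 1).astype(np.int8)
    outcome = ((draw == 0) | (draw == 2)).astype(np.int8)
    return pd.DataFrame({"exposure": exposure, "outcome": outcome}), cells


def empirical_component_correlation(
    cohort: SyntheticCohort,
    component: str,
    relation: str,
    trait: int = 1,
) -> float:
    """Pearson correlation of a latent component across sibling pairs.

    Requires the cohort to have been generated with ``keep_latent=True``.
    All within-family sibling pairs of the requested relation contribute, in
    both orderings (the symmetrised estimate).
    """
    if cohort.latent is None:
        raise ValueError("cohort was generated without latent component draws")
    if component not in ("A", "C", "E"):
        raise ValueError(f"unknown component {component!r}")
    col = f"{component}{trait}"
    lat = cohort.latent.loc[
        cohort.latent["relation"] == relation, ["family_id", "person_id", col]
    ]
    if lat.empty:
        raise ValueError(f"no families with relation {relation!r}")
    # self-merge on family yields every ordered sibling pair (double entry)
    pairs = lat.merge(lat, on="family_id", suffixes=("_x", "_y"))
    pairs = pairs[pairs["person_id_x"] != pairs["person_id_y"]]
    return float(np.corrcoef(pairs[f"{col}_x"], pairs[f"{col}_y"])[0, 1])
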