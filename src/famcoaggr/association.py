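"""Within-individual and cross-sibling ADHD-condition associations.

Associations are odds ratios from logistic regressions adjusted for sex and
birth year, with variance estimated by the cluster-robust sandwich over family
clusters (which also absorbs the dependence induced by double-entered sibling
pairs).  Full-sibling vs maternal-half-sibling odds ratios are contrasted with
a two-sided Wald z on the log-OR difference, and significance across the
condition family is controlled by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "ORResult",
    "ContrastResult",
    "fit_within_individual",
    "fit_between_sibling",
    "adjust_for_outcome_adhd",
    "stratify_by_sex",
    "contrast_fs_hs",
    "fdr_contrasts",
]

#: normal 97.5% quantile used for all CIs (not t)
Z_CRIT = 1.959964


class AssociationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ORResult:
    """Odds ratio with cluster-robust 95% CI for one condition in one cohort."""

    condition: str
    cohort: str  # 'individual' | 'full_sib' | 'maternal_half_sib'
    or_estimate: float
    ci_low: float
    ci_high: float
    log_or_se: float
    p_value: float
    n_effective: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.or_estimate <= self.ci_high):
            raise ValueError("CI does not bracket the estimate")


@dataclass
class ContrastResult:
    """Wald contrast of the FS vs HS log odds ratios for one condition."""

    condition: str
    fs: ORResult
    hs: ORResult
    z: float
    p_raw: float
    p_significant_after_fdr: bool | None = None


def _fit_logit(
    y: np.ndarray,
    X: pd.DataFrame,
    clusters: np.ndarray | None,
    condition: str,
    cohort: str,
) -> ORResult:
    """Logistic fit; OR for the first non-constant column; sandwich variance."""
    n_cases = int(np.sum(y))
    if n_cases == 0 or n_cases == len(y):
        raise AssociationError(
            f"{condition} ({cohort}): outcome has {n_cases} cases out of {len(y)}"
        )
    # drop constant covariates (e.g. sex within a sex stratum)
    keep = [c for c in X.columns if c == "const" or X[c].nunique() > 1]
    X = X[keep]
    exog = sm.add_constant(X, has_constant="add")
    model = sm.Logit(np.asarray(y, dtype=float), np.asarray(exog, dtype=float))
    try:
        if clusters is None:
            res = model.fit(disp=0, cov_type="HC0", maxiter=200)
        else:
            res = model.fit(
                disp=0,
                cov_type="cluster",
                cov_kwds={"groups": np.asarray(clusters)},
                maxiter=200,
            )
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise AssociationError(f"{condition} ({cohort}): {exc}") from exc
    if not res.mle_retvals.get("converged", True):
        raise AssociationError(f"{condition} ({cohort}): logistic fit did not converge")
    names = list(exog.columns)
    j = names.index(X.columns[0]) if X.columns[0] in names else 1
    beta = float(res.params[j])
    if abs(beta) > 15:
        raise AssociationError(
            f"{condition} ({cohort}): quasi-separation (|logOR|={beta:.1f})"
        )
    se = float(res.bse[j])
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    return ORResult(
        condition=condition,
        cohort=cohort,
        or_estimate=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z_CRIT * se)),
        ci_high=float(np.exp(beta + Z_CRIT * se)),
        log_or_se=se,
        p_value=float(p),
        n_effective=len(y),
    )


def _cluster_of(person_ids: pd.Series, clusters: pd.DataFrame | None) -> np.ndarray | None:
    if clusters is None:
        return None
    mapping = clusters.set_index("person_id")["cluster_id"]
    out = person_ids.map(mapping)
    if out.isna().any():
        raise AssociationError("some persons have no family cluster assignment")
    return out.to_numpy()


def fit_within_individual(
    phenotypes: pd.DataFrame,
    persons: pd.DataFrame,
    condition: str,
    clusters: pd.DataFrame | None = None,
    covariates: tuple[str, ...] = ("sex", "birth_year"),
) -> ORResult:
    """OR for condition | ADHD within individuals, adjusted for sex/birth year.

    ``clusters=None`` treats every person as their own cluster (HC0 sandwich).
    """
    df = phenotypes.merge(persons[["person_id", *covariates]] if covariates else
                          persons[["person_id"]], on="person_id")
    y = df[condition].to_numpy()
    X = pd.DataFrame({"adhd": df["adhd"].to_numpy()})
    for cov in covariates:
        X[cov] = df[cov].to_numpy()
    groups = _cluster_of(df["person_id"], clusters)
    return _fit_logit(y, X, groups, condition, "individual")


def _pair_frame(
    pairs: pd.DataFrame,
    phenotypes: pd.DataFrame,
    persons: pd.DataFrame,
    condition: str,
    relation: str,
) -> pd.DataFrame:
    sub = pairs[pairs["relation"] == relation]
    if sub.empty:
        raise AssociationError(f"no pairs with relation {relation!r}")
    ph = phenotypes.set_index("person_id")
    pe = persons.set_index("person_id")
    df = pd.DataFrame(
        {
            "exposure_adhd": ph["adhd"].reindex(sub["exposure_id"]).to_numpy(),
            "outcome_y": ph[condition].reindex(sub["outcome_id"]).to_numpy(),
            "sex_exposure": pe["sex"].reindex(sub["exposure_id"]).to_numpy(),
            "sex_outcome": pe["sex"].reindex(sub["outcome_id"]).to_numpy(),
            "byear_exposure": pe["birth_year"].reindex(sub["exposure_id"]).to_numpy(),
            "byear_outcome": pe["birth_year"].reindex(sub["outcome_id"]).to_numpy(),
            "outcome_adhd": ph["adhd"].reindex(sub["outcome_id"]).to_numpy(),
            "exposure_id": sub["exposure_id"].to_numpy(),
            "outcome_id": sub["outcome_id"].to_numpy(),
        }
    )
    return df


_COHORT_NAME = {"full": "full_sib", "maternal_half": "maternal_half_sib"}


def fit_between_sibling(
    pairs: pd.DataFrame,
    phenotypes: pd.DataFrame,
    persons: pd.DataFrame,
    condition: str,
    relation: str,
    clusters: pd.DataFrame | None = None,
    covariates: bool = True,
    extra_covariates: tuple[str, ...] = (),
) -> ORResult:
    """OR for condition in the outcome sibling given ADHD in the exposure sibling.

    Fitted on double-entered pairs; covariates are sex and birth year of both
    members; the sandwich is clustered on the outcome member's family cluster
    (pairs lie within families, so both members share it).
    """
    df = _pair_frame(pairs, phenotypes, persons, condition, relation)
    y = df["outcome_y"].to_numpy()
    cols = ["exposure_adhd"]
    if covariates:
        cols += ["sex_exposure", "sex_outcome", "byear_exposure", "byear_outcome"]
    cols += list(extra_covariates)
    X = df[cols]
    for c in extra_covariates:
        if df[c].nunique() < 2:
            raise AssociationError(
                f"{condition}: adjustment covariate {c!r} is constant"
            )
    groups = _cluster_of(df["outcome_id"], clusters)
    return _fit_logit(y, X, groups, condition, _COHORT_NAME[relation])


def adjust_for_outcome_adhd(
    pairs: pd.DataFrame,
    phenotypes: pd.DataFrame,
    persons: pd.DataFrame,
    condition: str,
    clusters: pd.DataFrame | None = None,
) -> ORResult:
    """Sensitivity analysis: FS between-sibling OR additionally adjusted for
    ADHD in the outcome individual."""
    return fit_between_sibling(
        pairs,
        phenotypes,
        persons,
        condition,
        relation="full",
        clusters=clusters,
        extra_covariates=("outcome_adhd",),
    )


def stratify_by_sex(
    pairs: pd.DataFrame,
    phenotypes: pd.DataFrame,
    persons: pd.DataFrame,
    condition: str,
    relation: str,
    clusters: pd.DataFrame | None = None,
) -> dict[int, ORResult]:
    """Between-sibling ORs fitted separately by sex of the exposure individual.

    Within a stratum the exposure sex is constant and is dropped as covariate.
    """
    df_all = _pair_frame(pairs, phenotypes, persons, condition, relation)
    out: dict[int, ORResult] = {}
    for sex in sorted(df_all["sex_exposure"].unique()):
        df = df_all[df_all["sex_exposure"] == sex]
        if df["exposure_adhd"].sum() == 0:
            raise AssociationError(
                f"{condition}: no exposed cases in sex stratum {sex}"
            )
        X = df[["exposure_adhd", "sex_outcome", "byear_exposure", "byear_outcome"]]
        groups = None
        if clusters is not None:
            groups = _cluster_of(df["outcome_id"], clusters)
        out[int(sex)] = _fit_logit(
            df["outcome_y"].to_numpy(), X, groups, condition,
            f"{_COHORT_NAME[relation]}_sex{int(sex)}",
        )
    return out


def contrast_fs_hs(fs: ORResult, hs: ORResult) -> ContrastResult:
    """Two-sided Wald z contrast of the FS vs HS log odds ratios."""
    if fs.log_or_se <= 0 or hs.log_or_se <= 0:
        raise ValueError("missing or non-positive standard errors")
    z = (np.log(fs.or_estimate) - np.log(hs.or_estimate)) / np.hypot(
        fs.log_or_se, hs.log_or_se
    )
    p = 2.0 * stats.norm.sf(abs(z))
    return ContrastResult(condition=fs.condition, fs=fs, hs=hs, z=float(z), p_raw=float(p))


def fdr_contrasts(
    contrasts: list[ContrastResult], alpha: float = 0.05
) -> tuple[list[ContrastResult], float]:
    """Benjamini-Hochberg across a family of contrasts.

    Sets each contrast's significance flag in place and returns the contrasts
    together with the realized p-value threshold (the largest raw p rejected;
    0.0 when nothing is rejected).
    """
    if not contrasts:
        return contrasts, 0.0
    p = np.array([c.p_raw for c in contrasts])
    reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    threshold = float(p[reject].max()) if reject.any() else 0.0
    for c, r in zip(contrasts, reject):
        c.p_significant_after_fdr = bool(r)
    return contrasts, threshold
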