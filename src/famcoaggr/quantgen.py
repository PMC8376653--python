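"""Bivariate liability-threshold ACE model for sibling-pair contingency data.

The model assumes each binary trait reflects a standard-normal liability that
is decomposed into additive-genetic (A), shared-environment (C) and non-shared
environment (E) parts.  A correlates across siblings at 0.5 (full) / 0.25
(maternal half), C at 1, E at 0.  With standardized loadings (a_t, c_t, e_t)
per trait and cross-trait component correlations (rA, rC, rE), the implied
liability correlations are

    cross-sib same trait   phi * a_t^2 + c_t^2            (phi = 0.5 or 0.25)
    within-person cross    a1 a2 rA + c1 c2 rC + e1 e2 rE  (= r_ph)
    cross-sib cross trait  phi * a1 a2 rA + c1 c2 rC

Estimation is two-stage: tetrachoric correlations (with asymptotic SEs) are
estimated from the 2x2 tables of each sibling group, then the structural
parameters minimise the inverse-variance weighted sum of squared deviations
between observed and implied correlations (diagonally weighted least squares).
Thresholds are free per sibling group, so prevalences may differ between full
and half siblings.  Sampling uncertainty is propagated by a non-parametric
bootstrap that resamples whole family clusters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "ContingencyTable2x2",
    "TetraEstimate",
    "SiblingMoments",
    "AceFit",
    "BootstrapSummary",
    "estimate_threshold",
    "bvn_cdf",
    "tetrachoric",
    "pooled_tetrachoric",
    "pair_tables",
    "compute_moments",
    "fit_bivariate_ace",
    "fit_from_pairs",
    "decompose",
    "bootstrap",
    "ace_bootstrap",
]

A_SHARING = {"full": 0.5, "maternal_half": 0.25}
RHO_BOUND = 0.999


class QuantgenError(RuntimeError):
    pass


def estimate_threshold(prevalence: float) -> float:
    """Liability threshold tau = Phi^-1(1 - prevalence), in liability SD units."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence {prevalence} outside (0, 1)")
    return float(stats.norm.ppf(1.0 - prevalence))


def bvn_cdf(h, k, rho):
    """Standard bivariate normal CDF P(X <= h, Y <= k) at correlation rho.

    Vectorised Owen's-T formula: Phi2 = (Phi(h) + Phi(k))/2 - T(h, a_h)
    - T(k, a_k) - delta, with delta = 1/2 when h and k have opposite signs.
    Exact zeros in h or k are nudged by 1e-12 (the formula is continuous
    there); |rho| must stay strictly below 1.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    h = np.where(np.abs(h) < 1e-12, 1e-12, h)
    k = np.where(np.abs(k) < 1e-12, 1e-12, k)
    s = np.sqrt(1.0 - rho * rho)
    ah = (k - rho * h) / (h * s)
    ak = (h - rho * k) / (k * s)
    delta = np.where(h * k < 0, 0.5, 0.0)
    out = (
        0.5 * (special.ndtr(h) + special.ndtr(k))
        - special.owens_t(h, ah)
        - special.owens_t(k, ak)
        - delta
    )
    return np.clip(out, 0.0, 1.0)


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts for a pair of binary variables: n[xy] = #(X=x, Y=y)."""

    n11: float
    n10: float
    n01: float
    n00: float

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise ValueError("negative cell count")
        if self.total <= 0:
            raise ValueError("empty table")

    @property
    def total(self) -> float:
        return self.n11 + self.n10 + self.n01 + self.n00

    @property
    def margin_x(self) -> float:
        return (self.n11 + self.n10) / self.total

    @property
    def margin_y(self) -> float:
        return (self.n11 + self.n01) / self.total

    @classmethod
    def from_arrays(cls, x, y, weights=None) -> "ContingencyTable2x2":
        x = np.asarray(x, dtype=int)
        y = np.asarray(y, dtype=int)
        w = np.ones_like(x, dtype=float) if weights is None else np.asarray(weights, float)
        idx = 2 * x + y  # 3=11, 2=10, 1=01, 0=00
        sums = np.bincount(idx, weights=w, minlength=4)
        return cls(n11=sums[3], n10=sums[2], n01=sums[1], n00=sums[0])


@dataclass(frozen=True)
class TetraEstimate:
    """Tetrachoric correlation with thresholds and asymptotic SE."""

    rho: float
    tau1: float
    tau2: float
    se_rho: float
    n: float
    continuity_corrected: bool = False


def _phi2_scalar(h: float, k: float, rho: float) -> float:
    """Scalar fast path of ``bvn_cdf`` (no array wrapping; hot loop of the
    tetrachoric MLE and the cluster bootstrap)."""
    if abs(h) < 1e-12:
        h = 1e-12
    if abs(k) < 1e-12:
        k = 1e-12
    s = math.sqrt(1.0 - rho * rho)
    val = (
        0.5 * (special.ndtr(h) + special.ndtr(k))
        - float(special.owens_t(h, (k - rho * h) / (h * s)))
        - float(special.owens_t(k, (h - rho * k) / (k * s)))
    )
    if h * k < 0:
        val -= 0.5
    return min(1.0, max(0.0, val))


def _cell_probs(tau1: float, tau2: float, rho: float) -> tuple:
    phi2 = _phi2_scalar(tau1, tau2, rho)
    P1 = float(special.ndtr(tau1))  # P(Z1 <= tau1)
    P2 = float(special.ndtr(tau2))
    p00 = phi2
    p01 = P1 - phi2
    p10 = P2 - phi2
    p11 = 1.0 - P1 - P2 + phi2
    return p11, p10, p01, p00


def _loglik(table: ContingencyTable2x2, tau1: float, tau2: float, rho: float) -> float:
    p11, p10, p01, p00 = _cell_probs(tau1, tau2, rho)
    tiny = 1e-300
    return (
        table.n11 * math.log(max(p11, tiny))
        + table.n10 * math.log(max(p10, tiny))
        + table.n01 * math.log(max(p01, tiny))
        + table.n00 * math.log(max(p00, tiny))
    )


def tetrachoric(table: ContingencyTable2x2) -> TetraEstimate:
    """Two-step tetrachoric correlation from a 2x2 table.

    Thresholds are fixed at the marginal normal quantiles; rho maximises the
    multinomial likelihood whose cell probabilities are bivariate-normal
    orthant probabilities, searched on (-0.999, 0.999).  The SE comes from the
    observed information (numerical curvature of the profile log-likelihood;
    threshold uncertainty is neglected).  Tables with a zero cell are re-fit
    with a +0.5 continuity correction on every cell and flagged; a zero margin
    is an error.
    """
    if (
        table.n11 + table.n10 == 0
        or table.n01 + table.n00 == 0
        or table.n11 + table.n01 == 0
        or table.n10 + table.n00 == 0
    ):
        raise QuantgenError(f"zero margin in table {table}")
    corrected = False
    work = table
    if min(table.n11, table.n10, table.n01, table.n00) == 0:
        corrected = True
        work = ContingencyTable2x2(
            table.n11 + 0.5, table.n10 + 0.5, table.n01 + 0.5, table.n00 + 0.5
        )
    tau1 = estimate_threshold(work.margin_x)
    tau2 = estimate_threshold(work.margin_y)

    res = optimize.minimize_scalar(
        lambda r: -_loglik(work, tau1, tau2, r),
        bounds=(-RHO_BOUND, RHO_BOUND),
        method="bounded",
        options={"xatol": 1e-8},
    )
    rho = float(res.x)
    # observed information via central differences on the profile likelihood
    hstep = 1e-4
    lo = max(-RHO_BOUND, rho - hstep)
    hi = min(RHO_BOUND, rho + hstep)
    l0 = _loglik(work, tau1, tau2, rho)
    lm = _loglik(work, tau1, tau2, lo)
    lp = _loglik(work, tau1, tau2, hi)
    d2 = (lp - 2.0 * l0 + lm) / ((hi - rho) * (rho - lo) + 1e-300)
    se = float(1.0 / math.sqrt(-d2)) if d2 < 0 else float("inf")
    return TetraEstimate(
        rho=rho, tau1=tau1, tau2=tau2, se_rho=se, n=table.total,
        continuity_corrected=corrected,
    )


def pooled_tetrachoric(tables: list[ContingencyTable2x2]) -> TetraEstimate:
    """Inverse-variance pooled tetrachoric across covariate strata.

    Covariate adjustment for the threshold model: estimate rho within each
    stratum (e.g. sex x birth decade), then pool the stratum estimates with
    weights 1/se^2.  Strata whose tables have a zero margin are skipped.
    """
    ests = []
    for t in tables:
        try:
            ests.append(tetrachoric(t))
        except QuantgenError:
            continue
    if not ests:
        raise QuantgenError("no stratum yielded a tetrachoric estimate")
    w = np.array([1.0 / e.se_rho**2 for e in ests])
    rho = float(np.sum(w * [e.rho for e in ests]) / w.sum())
    se = float(1.0 / math.sqrt(w.sum()))
    n = float(sum(e.n for e in ests))
    # pooled thresholds are weighted by stratum size (descriptive only)
    ns = np.array([e.n for e in ests])
    tau1 = float(np.sum(ns * [e.tau1 for e in ests]) / ns.sum())
    tau2 = float(np.sum(ns * [e.tau2 for e in ests]) / ns.sum())
    return TetraEstimate(rho=rho, tau1=tau1, tau2=tau2, se_rho=se, n=n,
                         continuity_corrected=any(e.continuity_corrected for e in ests))


# ---------------------------------------------------------------------------
# moment extraction from double-entered pairs
# ---------------------------------------------------------------------------

TABLE_NAMES = ("cross_sib_trait1", "cross_sib_trait2", "within_person", "cross_sib_cross")


def _pair_values(
    pairs: pd.DataFrame,
    phenotypes: pd.DataFrame,
    relation: str,
    condition: str,
    trait1: str,
) -> pd.DataFrame:
    sub = pairs[pairs["relation"] == relation]
    if sub.empty:
        raise QuantgenError(f"no pairs with relation {relation!r}")
    ph = phenotypes.set_index("person_id")
    return pd.DataFrame(
        {
            "exposure_id": sub["exposure_id"].to_numpy(),
            "outcome_id": sub["outcome_id"].to_numpy(),
            "t1_x": ph[trait1].reindex(sub["exposure_id"]).to_numpy(),
            "t1_y": ph[trait1].reindex(sub["outcome_id"]).to_numpy(),
            "t2_x": ph[condition].reindex(sub["exposure_id"]).to_numpy(),
            "t2_y": ph[condition].reindex(sub["outcome_id"]).to_numpy(),
        }
    )


def pair_tables(
    pairs: pd.DataFrame,
    phenotypes: pd.DataFrame,
    relation: str,
    condition: str,
    trait1: str = "adhd",
) -> dict[str, ContingencyTable2x2]:
    """The four 2x2 tables for one sibling group.

    cross_sib_trait1 / cross_sib_trait2: same trait across the two siblings;
    within_person: the two traits within each distinct person appearing in
    pairs of this relation; cross_sib_cross: trait 1 in the exposure member
    against trait 2 in the outcome member (double entry pools the two
    symmetric orientations).
    """
    pv = _pair_values(pairs, phenotypes, relation, condition, trait1)
    ph = phenotypes.set_index("person_id")
    members = pd.unique(np.concatenate([pv["exposure_id"], pv["outcome_id"]]))
    w1 = ph[trait1].reindex(members).to_numpy()
    w2 = ph[condition].reindex(members).to_numpy()
    return {
        "cross_sib_trait1": ContingencyTable2x2.from_arrays(pv["t1_x"], pv["t1_y"]),
        "cross_sib_trait2": ContingencyTable2x2.from_arrays(pv["t2_x"], pv["t2_y"]),
        "within_person": ContingencyTable2x2.from_arrays(w1, w2),
        "cross_sib_cross": ContingencyTable2x2.from_arrays(pv["t1_x"], pv["t2_y"]),
    }


@dataclass(frozen=True)
class SiblingMoments:
    """Tetrachoric moments of one sibling group."""

    relation: str
    cross_sib_trait1: TetraEstimate
    cross_sib_trait2: TetraEstimate
    within_person: TetraEstimate
    cross_sib_cross: TetraEstimate

    @property
    def prev1(self) -> float:
        return 1.0 - stats.norm.cdf(self.within_person.tau1)

    @property
    def prev2(self) -> float:
        return 1.0 - stats.norm.cdf(self.within_person.tau2)


def compute_moments(
    tables: Mapping[str, ContingencyTable2x2], relation: str
) -> SiblingMoments:
    return SiblingMoments(
        relation=relation,
        **{name: tetrachoric(tables[name]) for name in TABLE_NAMES},
    )


# ---------------------------------------------------------------------------
# WLS structural fit
# ---------------------------------------------------------------------------


@dataclass
class AceFit:
    """Fitted bivariate liability-threshold ACE parameters."""

    a1: float
    c1: float
    e1: float
    a2: float
    c2: float
    e2: float
    rA: float
    rC: float
    rE: float
    thresholds: dict  # {relation: (tau1, tau2)}
    wls_discrepancy: float
    n_starts: int
    boundary: bool
    phi: dict = field(default_factory=lambda: dict(A_SHARING))

    @property
    def cov_a(self) -> float:
        return self.a1 * self.a2 * self.rA

    @property
    def cov_c(self) -> float:
        return self.c1 * self.c2 * self.rC

    @property
    def cov_e(self) -> float:
        return self.e1 * self.e2 * self.rE

    @property
    def r_ph(self) -> float:
        return self.cov_a + self.cov_c + self.cov_e

    def implied_correlations(self, relation: str) -> dict[str, float]:
        phi = self.phi[relation]
        return {
            "cross_sib_trait1": phi * self.a1**2 + self.c1**2,
            "cross_sib_trait2": phi * self.a2**2 + self.c2**2,
            "within_person": self.r_ph,
            "cross_sib_cross": phi * self.cov_a + self.cov_c,
        }

    def implied_matrix(self, relation: str) -> np.ndarray:
        """4x4 liability correlation matrix, order (t1_s1, t2_s1, t1_s2, t2_s2)."""
        m = self.implied_correlations(relation)
        r11, r22 = m["cross_sib_trait1"], m["cross_sib_trait2"]
        rw, rx = m["within_person"], m["cross_sib_cross"]
        return np.array(
            [
                [1.0, rw, r11, rx],
                [rw, 1.0, rx, r22],
                [r11, rx, 1.0, rw],
                [rx, r22, rw, 1.0],
            ]
        )

    def to_dict(self) -> dict:
        d = decompose(self)
        return {
            "a1": self.a1, "c1": self.c1, "e1": self.e1,
            "a2": self.a2, "c2": self.c2, "e2": self.e2,
            "rA": self.rA, "rC": self.rC, "rE": self.rE,
            "r_ph": self.r_ph,
            "cov_a": self.cov_a, "cov_c": self.cov_c, "cov_e": self.cov_e,
            "share_a": d["share_a"], "share_c": d["share_c"], "share_e": d["share_e"],
            "thresholds": {k: list(v) for k, v in self.thresholds.items()},
            "wls_discrepancy": self.wls_discrepancy,
            "boundary": self.boundary,
        }


def _falconer_start(fs: SiblingMoments, hs: SiblingMoments) -> np.ndarray:
    """Closed-form initializer from the classical sibling-correlation contrasts.

    a_t^2 ~ 4 (r_FS - r_HS), c_t^2 ~ 2 r_HS - r_FS per trait; the cross-trait
    contributions use the same contrast on the cross-sib cross-trait moments.
    """
    def shares(r_fs: float, r_hs: float) -> tuple[float, float]:
        a2 = min(0.95, max(0.05, 4.0 * (r_fs - r_hs)))
        c2 = min(0.9, max(0.02, 2.0 * r_hs - r_fs))
        if a2 + c2 > 0.97:
            scale = 0.97 / (a2 + c2)
            a2, c2 = a2 * scale, c2 * scale
        return a2, c2

    a1s, c1s = shares(fs.cross_sib_trait1.rho, hs.cross_sib_trait1.rho)
    a2s, c2s = shares(fs.cross_sib_trait2.rho, hs.cross_sib_trait2.rho)
    a1, c1, a2, c2 = map(math.sqrt, (a1s, c1s, a2s, c2s))
    e1 = math.sqrt(1.0 - a1s - c1s)
    e2 = math.sqrt(1.0 - a2s - c2s)
    cov_a = 4.0 * (fs.cross_sib_cross.rho - hs.cross_sib_cross.rho)
    cov_c = 2.0 * hs.cross_sib_cross.rho - fs.cross_sib_cross.rho
    r_w = 0.5 * (fs.within_person.rho + hs.within_person.rho)
    cov_e = r_w - cov_a - cov_c
    rA = np.clip(cov_a / (a1 * a2), -0.95, 0.95)
    rC = np.clip(cov_c / (c1 * c2), -0.95, 0.95)
    rE = np.clip(cov_e / (e1 * e2), -0.95, 0.95)
    return np.array([a1, c1, a2, c2, rA, rC, rE])


def fit_bivariate_ace(
    fs: SiblingMoments,
    hs: SiblingMoments,
    phi_fs: float = 0.5,
    phi_hs: float = 0.25,
    n_random_starts: int = 8,
    start_seed: int = 0,
    tol: float = 1e-9,
) -> AceFit:
    """Diagonally weighted least-squares fit of the bivariate ACE model.

    Minimises sum_k w_k (r_hat_k - r_k(theta))^2 over the 8 observed
    correlations (4 per sibling group) with w_k = 1 / se_k^2, theta =
    (a1, c1, a2, c2, rA, rC, rE), e_t = sqrt(1 - a_t^2 - c_t^2).  Loadings are
    box-constrained to [0, 1] (signs are carried by the component
    correlations, constrained to [-1, 1]); a smooth penalty keeps
    a_t^2 + c_t^2 <= 1.  Optimisation is bounded L-BFGS-B from the Falconer
    closed-form start plus ``n_random_starts`` random starts.
    """
    obs = []
    wts = []
    phis = []
    kinds = []
    for mom, phi in ((fs, phi_fs), (hs, phi_hs)):
        for name in TABLE_NAMES:
            est: TetraEstimate = getattr(mom, name)
            if not np.isfinite(est.se_rho) or est.se_rho <= 0:
                raise QuantgenError(f"non-finite SE for moment {name} ({mom.relation})")
            obs.append(est.rho)
            wts.append(1.0 / est.se_rho**2)
            phis.append(phi)
            kinds.append(name)
    obs = np.array(obs)
    wts = np.array(wts)
    phis = np.array(phis)

    def implied(theta: np.ndarray) -> np.ndarray:
        a1, c1, a2, c2, rA, rC, rE = theta
        e1sq = max(0.0, 1.0 - a1 * a1 - c1 * c1)
        e2sq = max(0.0, 1.0 - a2 * a2 - c2 * c2)
        e1, e2 = math.sqrt(e1sq), math.sqrt(e2sq)
        cov_a, cov_c, cov_e = a1 * a2 * rA, c1 * c2 * rC, e1 * e2 * rE
        out = np.empty(len(kinds))
        for i, (name, phi) in enumerate(zip(kinds, phis)):
            if name == "cross_sib_trait1":
                out[i] = phi * a1 * a1 + c1 * c1
            elif name == "cross_sib_trait2":
                out[i] = phi * a2 * a2 + c2 * c2
            elif name == "within_person":
                out[i] = cov_a + cov_c + cov_e
            else:
                out[i] = phi * cov_a + cov_c
        return out

    def objective(theta: np.ndarray) -> float:
        a1, c1, a2, c2 = theta[:4]
        pen = 0.0
        for a, c in ((a1, c1), (a2, c2)):
            excess = a * a + c * c - 1.0
            if excess > 0:
                pen += 1e6 * excess * excess
        resid = obs - implied(theta)
        return float(np.sum(wts * resid * resid) + pen)

    bounds = [(0.0, 1.0)] * 4 + [(-1.0, 1.0)] * 3
    rng = np.random.default_rng(start_seed)
    starts = [_falconer_start(fs, hs)]
    for _ in range(n_random_starts):
        starts.append(
            np.concatenate([rng.uniform(0.05, 0.85, 4), rng.uniform(-0.8, 0.8, 3)])
        )

    best = None
    for x0 in starts:
        res = optimize.minimize(
            objective, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": tol, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise QuantgenError("ACE fit failed to converge from any start")

    a1, c1, a2, c2, rA, rC, rE = best.x
    e1 = math.sqrt(max(0.0, 1.0 - a1 * a1 - c1 * c1))
    e2 = math.sqrt(max(0.0, 1.0 - a2 * a2 - c2 * c2))
    boundary = bool(
        np.any(np.isclose(best.x[:4], 0.0, atol=1e-6))
        or np.any(np.isclose(best.x[:4], 1.0, atol=1e-6))
        or np.any(np.isclose(np.abs(best.x[4:]), 1.0, atol=1e-6))
    )
    return AceFit(
        a1=float(a1), c1=float(c1), e1=float(e1),
        a2=float(a2), c2=float(c2), e2=float(e2),
        rA=float(rA), rC=float(rC), rE=float(rE),
        thresholds={
            "full": (fs.within_person.tau1, fs.within_person.tau2),
            "maternal_half": (hs.within_person.tau1, hs.within_person.tau2),
        },
        wls_discrepancy=float(best.fun),
        n_starts=len(starts),
        boundary=boundary,
        phi={"full": phi_fs, "maternal_half": phi_hs},
    )


def fit_from_pairs(
    pairs: pd.DataFrame,
    phenotypes: pd.DataFrame,
    condition: str,
    trait1: str = "adhd",
    **fit_kwargs,
) -> AceFit:
    """Convenience: tables -> tetrachoric moments -> WLS fit, both sibling groups."""
    fs_tab = pair_tables(pairs, phenotypes, "full", condition, trait1)
    hs_tab = pair_tables(pairs, phenotypes, "maternal_half", condition, trait1)
    fs = compute_moments(fs_tab, "full")
    hs = compute_moments(hs_tab, "maternal_half")
    return fit_bivariate_ace(fs, hs, **fit_kwargs)


def decompose(fit: AceFit) -> dict[str, float]:
    """A/C/E contributions to the cross-trait correlation and their shares.

    Shares are cov_X / r_ph; they sum to one exactly, may be negative, and may
    exceed one (offsetting contributions).
    """
    r = fit.r_ph
    if r == 0:
        raise QuantgenError("phenotypic correlation is zero; shares undefined")
    return {
        "cov_a": fit.cov_a,
        "cov_c": fit.cov_c,
        "cov_e": fit.cov_e,
        "r_ph": r,
        "share_a": fit.cov_a / r,
        "share_c": fit.cov_c / r,
        "share_e": fit.cov_e / r,
    }


# ---------------------------------------------------------------------------
# family-cluster bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapSummary:
    """Replicate estimates and percentile CIs from the cluster bootstrap."""

    replicates: pd.DataFrame  # one row per successful replicate
    ci_low: pd.Series  # 2.5 percentile per parameter
    ci_high: pd.Series  # 97.5 percentile per parameter
    n_replicates: int
    n_failed: int
    seed: int


def bootstrap(
    fit_fn: Callable[[np.ndarray], Mapping[str, float]],
    cluster_ids: np.ndarray,
    n_reps: int = 1000,
    seed: int = 0,
    max_failure_frac: float = 0.1,
) -> BootstrapSummary:
    """Non-parametric bootstrap over family clusters.

    Each replicate draws ``len(cluster_ids)`` clusters with replacement and
    calls ``fit_fn`` with the sampled id array (with multiplicity); replicate
    seeds are derived from the master seed by counter.  Replicates where
    ``fit_fn`` raises are recorded as failures; exceeding the failure ceiling
    is an error.  CIs are the 2.5/97.5 percentiles (skew is allowed: the point
    estimate need not be bracketed).
    """
    cluster_ids = np.asarray(cluster_ids)
    if cluster_ids.size == 0:
        raise QuantgenError("no clusters to resample")
    rows = []
    n_failed = 0
    for rep in range(n_reps):
        rng = np.random.default_rng([seed, rep])
        sampled = rng.choice(cluster_ids, size=cluster_ids.size, replace=True)
        try:
            rows.append(dict(fit_fn(sampled)))
        except Exception:
            n_failed += 1
    if n_failed > max_failure_frac * n_reps:
        raise QuantgenError(
            f"bootstrap failure fraction {n_failed}/{n_reps} exceeds ceiling "
            f"{max_failure_frac:.2f}"
        )
    reps = pd.DataFrame(rows)
    if reps.empty:
        raise QuantgenError("all bootstrap replicates failed")
    return BootstrapSummary(
        replicates=reps,
        ci_low=reps.quantile(0.025),
        ci_high=reps.quantile(0.975),
        n_replicates=len(reps),
        n_failed=n_failed,
        seed=seed,
    )


def _per_cluster_cells(
    pairs: pd.DataFrame,
    phenotypes: pd.DataFrame,
    clusters: pd.DataFrame,
    condition: str,
    trait1: str = "adhd",
) -> tuple[np.ndarray, dict[tuple[str, str], np.ndarray]]:
    """Per-cluster 2x2 cell counts for each (relation, table).

    Returns the sorted unique cluster ids and, per (relation, table), an
    (n_clusters, 4) matrix of counts in order (n11, n10, n01, n00), so a
    bootstrap replicate's tables are multiplicity-weighted row sums.
    """
    cmap = clusters.set_index("person_id")["cluster_id"]
    ids = np.sort(clusters["cluster_id"].unique())
    pos = pd.Series(np.arange(ids.size), index=ids)
    mats: dict[tuple[str, str], np.ndarray] = {}
    ph = phenotypes.set_index("person_id")
    for relation in ("full", "maternal_half"):
        pv = _pair_values(pairs, phenotypes, relation, condition, trait1)
        cl = pos.loc[cmap.loc[pv["exposure_id"]].to_numpy()].to_numpy()
        for name, (x, y) in {
            "cross_sib_trait1": (pv["t1_x"], pv["t1_y"]),
            "cross_sib_trait2": (pv["t2_x"], pv["t2_y"]),
            "cross_sib_cross": (pv["t1_x"], pv["t2_y"]),
        }.items():
            cell = 2 * np.asarray(x, int) + np.asarray(y, int)  # 3,2,1,0
            mat = np.zeros((ids.size, 4))
            np.add.at(mat, (cl, 3 - cell), 1.0)  # col order n11,n10,n01,n00
            mats[(relation, name)] = mat
        members = pd.unique(np.concatenate([pv["exposure_id"], pv["outcome_id"]]))
        mcl = pos.loc[cmap.loc[members].to_numpy()].to_numpy()
        w1 = ph[trait1].reindex(members).to_numpy(dtype=int)
        w2 = ph[condition].reindex(members).to_numpy(dtype=int)
        cell = 2 * w1 + w2
        mat = np.zeros((ids.size, 4))
        np.add.at(mat, (mcl, 3 - cell), 1.0)
        mats[(relation, "within_person")] = mat
    return ids, mats


def ace_bootstrap(
    pairs: pd.DataFrame,
    phenotypes: pd.DataFrame,
    clusters: pd.DataFrame,
    condition: str,
    trait1: str = "adhd",
    n_reps: int = 1000,
    seed: int = 0,
    max_failure_frac: float = 0.1,
    **fit_kwargs,
) -> BootstrapSummary:
    """Family-cluster bootstrap of the full tables -> tetrachorics -> ACE fit
    pipeline.

    Per-cluster cell counts are precomputed once; each replicate re-weights
    them by the sampled cluster multiplicities, recomputes all eight
    tetrachoric moments and refits the model.
    """
    ids, mats = _per_cluster_cells(pairs, phenotypes, clusters, condition, trait1)
    id_pos = pd.Series(np.arange(ids.size), index=ids)

    def fit_fn(sampled: np.ndarray) -> Mapping[str, float]:
        mult = np.bincount(id_pos.loc[sampled].to_numpy(), minlength=ids.size).astype(float)
        moments = {}
        for relation in ("full", "maternal_half"):
            tabs = {}
            for name in TABLE_NAMES:
                c = mult @ mats[(relation, name)]
                tabs[name] = ContingencyTable2x2(c[0], c[1], c[2], c[3])
            moments[relation] = compute_moments(tabs, relation)
        fit = fit_bivariate_ace(moments["full"], moments["maternal_half"], **fit_kwargs)
        d = decompose(fit)
        return {
            "a1": fit.a1, "c1": fit.c1, "e1": fit.e1,
            "a2": fit.a2, "c2": fit.c2, "e2": fit.e2,
            "rA": fit.rA, "rC": fit.rC, "rE": fit.rE,
            "r_ph": fit.r_ph,
            "share_a": d["share_a"], "share_c": d["share_c"], "share_e": d["share_e"],
        }

    return bootstrap(fit_fn, ids, n_reps=n_reps, seed=seed,
                     max_failure_frac=max_failure_frac)
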