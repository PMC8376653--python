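"""Configured, logged, seed-reproducible orchestration of the full analysis.

Stages: simulate -> phenotype -> build-cohort -> associate -> quantgen ->
report.  A single YAML config drives the run; every output directory carries a
``run.json`` with the config hash, master seed, stage timings and record
counts, so two runs with identical config and seed produce byte-identical
tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
import time
from dataclasses import dataclass, field, asdict

import pandas as pd
import yaml

from . import association, cohort, phenotyping, quantgen, simulate
from .catalog import default_catalog, load_catalog

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    out_dir: str = "famcoaggr_run"
    catalog_path: str | None = None  # None -> packaged default catalog
    seed: int = 0
    # simulate stage
    n_fullsib_families: int = 20000
    n_halfsib_families: int = 4000
    pair_size: int = 2
    condition: str = "sleep_disorders"
    truth: dict = field(
        default_factory=lambda: {
            "h2_1": 0.64, "c2_1": 0.04, "h2_2": 0.36, "c2_2": 0.09,
            "rA": 0.3, "rC": 0.3, "rE": 0.1,
            "prev1": 0.0129, "prev2": 0.0257,
        }
    )
    # associate stage
    fdr_alpha: float = 0.05
    sensitivity_adjust_outcome_adhd: bool = False
    sensitivity_max_gap_10: bool = False
    sensitivity_sex_strata: bool = False
    # quantgen stage
    bootstrap_reps: int = 0  # 0 disables the bootstrap

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(raw) - known
        if bad:
            raise PipelineError(f"unknown config keys: {sorted(bad)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def validate(self) -> None:
        if self.catalog_path is not None and not pathlib.Path(self.catalog_path).exists():
            raise PipelineError(f"catalog file not found: {self.catalog_path}")
        if self.seed is None:
            raise PipelineError("seed is mandatory")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the run report dict (also written to disk)."""
    config.validate()
    out = pathlib.Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cat = load_catalog(config.catalog_path) if config.catalog_path else default_catalog()
    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    def stage(name):
        def wrap(fn):
            t0 = time.perf_counter()
            try:
                counts = fn()
            except Exception as exc:
                (out / "FAILED").write_text(f"stage {name}: {exc}\n")
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            report["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3),
                **counts,
            }

        return wrap

    state: dict = {}

    @stage("simulate")
    def _simulate():
        truth = simulate.AceTruth.from_variance_shares(**config.truth)
        spec = simulate.FamilySpec(
            n_fullsib_families=config.n_fullsib_families,
            n_halfsib_families=config.n_halfsib_families,
            pair_size=config.pair_size,
            seed=config.seed,
        )
        coh = simulate.simulate_ace_families(
            truth, spec, catalog=cat, condition=config.condition
        )
        coh.write(out)
        state["cohort"] = coh
        return {
            "persons": len(coh.persons),
            "diagnoses": len(coh.diagnoses),
            "prescriptions": len(coh.prescriptions),
        }

    @stage("phenotype")
    def _phenotype():
        coh = state["cohort"]
        ph = phenotyping.build_phenotypes(
            coh.persons, coh.diagnoses, coh.prescriptions, cat
        )
        ph.to_csv(out / "phenotypes.csv", index=False)
        state["phenotypes"] = ph
        return {"persons": len(ph), "adhd_cases": int(ph["adhd"].sum())}

    @stage("build_cohort")
    def _cohort():
        persons = cohort.apply_exclusions(state["cohort"].persons)
        pairs = cohort.build_pairs(persons)
        if config.sensitivity_max_gap_10:
            pairs = cohort.filter_age_gap(pairs, 10)
        clusters = cohort.build_clusters(persons)
        pairs.to_csv(out / "pairs.csv", index=False)
        clusters.to_csv(out / "clusters.csv", index=False)
        state.update(persons=persons, pairs=pairs, clusters=clusters)
        return {
            "persons": len(persons),
            "analytical_pairs": len(pairs),
            "clusters": int(clusters["cluster_id"].nunique()),
        }

    @stage("associate")
    def _associate():
        ph, persons = state["phenotypes"], state["persons"]
        pairs, clusters = state["pairs"], state["clusters"]
        targets = [
            c for c in ph.columns
            if c not in ("person_id", "adhd") and ph[c].sum() > 0
        ]
        rows, contrasts = [], {}
        for cond_name in targets:
            try:
                ind = association.fit_within_individual(
                    ph, persons, cond_name, clusters
                )
                fs = association.fit_between_sibling(
                    pairs, ph, persons, cond_name, "full", clusters
                )
                hs = association.fit_between_sibling(
                    pairs, ph, persons, cond_name, "maternal_half", clusters
                )
            except association.AssociationError as exc:
                logger.warning("skipping %s: %s", cond_name, exc)
                continue
            for res in (ind, fs, hs):
                rows.append(
                    {
                        "condition": res.condition,
                        "cohort": res.cohort,
                        "or_estimate": res.or_estimate,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "log_or_se": res.log_or_se,
                        "p_value": res.p_value,
                        "n_effective": res.n_effective,
                    }
                )
            contrasts[cond_name] = association.contrast_fs_hs(fs, hs)
            if config.sensitivity_adjust_outcome_adhd:
                try:
                    adj = association.adjust_for_outcome_adhd(
                        pairs, ph, persons, cond_name, clusters
                    )
                    rows.append(
                        {
                            "condition": cond_name,
                            "cohort": "full_sib_adj_outcome_adhd",
                            "or_estimate": adj.or_estimate,
                            "ci_low": adj.ci_low,
                            "ci_high": adj.ci_high,
                            "log_or_se": adj.log_or_se,
                            "p_value": adj.p_value,
                            "n_effective": adj.n_effective,
                        }
                    )
                except association.AssociationError as exc:
                    logger.warning("adjustment skipped for %s: %s", cond_name, exc)
            if config.sensitivity_sex_strata:
                try:
                    strata = association.stratify_by_sex(
                        pairs, ph, persons, cond_name, "full", clusters
                    )
                    for sex, res in strata.items():
                        rows.append(
                            {
                                "condition": cond_name,
                                "cohort": res.cohort,
                                "or_estimate": res.or_estimate,
                                "ci_low": res.ci_low,
                                "ci_high": res.ci_high,
                                "log_or_se": res.log_or_se,
                                "p_value": res.p_value,
                                "n_effective": res.n_effective,
                            }
                        )
                except association.AssociationError as exc:
                    logger.warning("sex strata skipped for %s: %s", cond_name, exc)

        # correct conditions and groups as separate FDR families
        cond_family = [c for n, c in contrasts.items() if not n.startswith("grp_")]
        grp_family = [c for n, c in contrasts.items() if n.startswith("grp_")]
        thresholds = {}
        for fam, label in ((cond_family, "conditions"), (grp_family, "groups")):
            _, thr = association.fdr_contrasts(fam, config.fdr_alpha)
            thresholds[label] = thr
        pd.DataFrame(rows).to_csv(out / "associations.csv", index=False)
        pd.DataFrame(
            [
                {
                    "condition": c.condition,
                    "or_fs": c.fs.or_estimate,
                    "or_hs": c.hs.or_estimate,
                    "z": c.z,
                    "p_raw": c.p_raw,
                    "significant_after_fdr": c.p_significant_after_fdr,
                }
                for c in contrasts.values()
            ]
        ).to_csv(out / "contrasts.csv", index=False)
        state["fdr_thresholds"] = thresholds
        return {"associations": len(rows), "contrasts": len(contrasts)}

    @stage("quantgen")
    def _quantgen():
        ph, pairs = state["phenotypes"], state["pairs"]
        target = config.condition
        fit = quantgen.fit_from_pairs(pairs, ph, target)
        payload = {"condition": target, **fit.to_dict()}
        if config.bootstrap_reps > 0:
            boot = quantgen.ace_bootstrap(
                pairs, ph, state["clusters"], target,
                n_reps=config.bootstrap_reps, seed=config.seed,
            )
            boot.replicates.to_csv(out / "bootstrap.csv", index=False)
            payload["bootstrap"] = {
                "n_replicates": boot.n_replicates,
                "n_failed": boot.n_failed,
                "ci_low": boot.ci_low.to_dict(),
                "ci_high": boot.ci_high.to_dict(),
            }
        (out / "acefit.json").write_text(json.dumps(payload, indent=2))
        state["acefit"] = payload
        return {"r_ph": round(payload["r_ph"], 4)}

    @stage("report")
    def _report():
        return render_report(out, fdr_thresholds=state.get("fdr_thresholds"))

    report["outputs"] = sorted(p.name for p in out.iterdir() if p.is_file())
    (out / "run.json").write_text(json.dumps(report, indent=2))
    return report


def _plot_or_triplets(rep: pd.DataFrame, path) -> None:
    """Dot plot of the individual / FS / HS odds-ratio triplets per condition."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, max(2, 0.4 * len(rep))))
    y = range(len(rep))
    for col, marker, label in (
        ("or_individual", "o", "within individual"),
        ("or_full_sib", "s", "full siblings"),
        ("or_maternal_half_sib", "^", "maternal half siblings"),
    ):
        ax.scatter(rep[col], y, marker=marker, label=label)
    ax.axvline(1.0, color="grey", lw=0.8)
    ax.set_yticks(list(y), rep["condition"])
    ax.set_xlabel("odds ratio")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_report(out_dir, fdr_thresholds: dict | None = None) -> dict:
    """Assemble the per-condition OR summary table and decomposition CSV.

    Produces ``report_associations.csv`` with one row per condition carrying
    the individual / full-sibling / maternal-half-sibling OR triplet and the
    contrast p-value, and (when an ACE fit exists) ``report_decomposition.csv``
    with the A/C/E contribution bars.  Empty inputs yield empty outputs.
    """
    out = pathlib.Path(out_dir)
    counts = {}
    assoc_path = out / "associations.csv"
    rows = []
    if assoc_path.exists():
        assoc = pd.read_csv(assoc_path)
        contr = (
            pd.read_csv(out / "contrasts.csv")
            if (out / "contrasts.csv").exists() and (out / "contrasts.csv").stat().st_size > 1
            else pd.DataFrame(columns=["condition", "p_raw", "significant_after_fdr"])
        )
        if len(assoc):
            wide = assoc.pivot_table(
                index="condition", columns="cohort", values="or_estimate", aggfunc="first"
            )
            for cond_name, r in wide.iterrows():
                crow = contr[contr["condition"] == cond_name]
                rows.append(
                    {
                        "condition": cond_name,
                        "or_individual": r.get("individual"),
                        "or_full_sib": r.get("full_sib"),
                        "or_maternal_half_sib": r.get("maternal_half_sib"),
                        "contrast_p": float(crow["p_raw"].iloc[0]) if len(crow) else None,
                        "significant_after_fdr": (
                            bool(crow["significant_after_fdr"].iloc[0]) if len(crow) else None
                        ),
                    }
                )
    rep = pd.DataFrame(
        rows,
        columns=[
            "condition", "or_individual", "or_full_sib",
            "or_maternal_half_sib", "contrast_p", "significant_after_fdr",
        ],
    )
    rep.to_csv(out / "report_associations.csv", index=False)
    counts["report_rows"] = len(rep)
    if len(rep):
        _plot_or_triplets(rep, out / "report_associations.png")
    if fdr_thresholds:
        counts["realized_fdr_thresholds"] = fdr_thresholds

    ace_path = out / "acefit.json"
    if ace_path.exists():
        fitd = json.loads(ace_path.read_text())
        pd.DataFrame(
            [
                {
                    "condition": fitd.get("condition"),
                    "r_ph": fitd["r_ph"],
                    "cov_a": fitd["cov_a"],
                    "cov_c": fitd["cov_c"],
                    "cov_e": fitd["cov_e"],
                    "share_a": fitd["share_a"],
                    "share_c": fitd["share_c"],
                    "share_e": fitd["share_e"],
                }
            ]
        ).to_csv(out / "report_decomposition.csv", index=False)
        counts["decomposition_rows"] = 1
    return counts
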