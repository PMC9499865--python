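"""Seed-deterministic pipeline: simulate -> programs -> outcomes -> report.

``RunConfig`` gathers the analysis constants (bootstrap replicates,
cophenetic threshold 0.75, responder fold threshold 1.5, the 28/42/183-day
windows) in one place; ``run_pipeline`` executes the stages in order,
writing per-stage artifacts plus a checksummed manifest so identical
(config, seed) runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import outcomes as oc
from . import programs as pg
from .data import (
    CohortDataset,
    load_cohort,
    select_cytokine_subcohort,
    write_cohort,
    write_results,
)
from .errors import ParameterError, StageError
from .simulate import generate_cohort
from .stats import clopper_pearson, round_half_up

__all__ = ["RunConfig", "run_pipeline", "summarize_tables"]


@dataclass
class RunConfig:
    seed: int = 17
    out_dir: str = "results/run"
    input_dir: str | None = None  # load tables instead of simulating
    n_vaccinated: int = 64
    n_unvaccinated: int = 26
    n_serum_subcohort: int = 36
    n_boot: int = 10000
    cophenetic_threshold: float = 0.75
    fold_threshold: float = 1.5
    top_fold_threshold: float = 1.7
    baseline_window_days: int = 183
    post_window_days: int = 42
    ae_split_days: int = 28
    landmark_date: str | None = None  # ISO date; required for the landmark stage
    aggregation: str = "patient_mean"  # or "first_post"
    ae_counting: str = "first_event"  # or "all_events"
    resample_unit: str = "sample"  # or "patient"
    propensity_covariates: tuple = ("age", "sex", "insurance")
    stages: tuple = ("simulate", "programs", "outcomes", "report")

    def __post_init__(self):
        if self.n_boot < 1:
            raise ParameterError("n_boot must be >= 1")
        if self.cophenetic_threshold <= 0 or self.fold_threshold <= 0:
            raise ParameterError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        for key in ("propensity_covariates", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["propensity_covariates"] = list(self.propensity_covariates)
        d["stages"] = list(self.stages)
        return d

    def sha256(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()


def _log(stage: str, message: str, log_lines: list):
    line = f"{datetime.datetime.now().isoformat(timespec='seconds')} [{stage}] {message}"
    print(line, file=sys.stderr)
    log_lines.append(line)


def _fmt_pct(k: int, n: int) -> str:
    return f"{k} ({round_half_up(100.0 * k / n, 1)})"


def _fmt_pct_ci(k: int, n: int) -> str:
    pct, lo, hi = clopper_pearson(k, n).as_percent(1)
    return f"{k} ({pct}, {lo}-{hi})"


def summarize_tables(dataset: CohortDataset, ae_window_days: int = 28) -> dict:
    """Report tables: baseline characteristics, early adverse events
    (first dose until ``ae_window_days`` after the second), and
    immune-related adverse events with exact binomial CIs per row."""
    vacc = [p for p in dataset.patients if p.vaccinated]
    unvacc = [p for p in dataset.patients if not p.vaccinated]
    n_v, n_u = len(vacc), len(unvacc)

    def count_pct(group, pred):
        n = len(group)
        k = sum(1 for p in group if pred(p))
        return _fmt_pct(k, n) if n else "0 (0.0)"

    baseline = {
        "n": {"vaccinated": n_v, "unvaccinated": n_u},
        "male": {
            "vaccinated": count_pct(vacc, lambda p: p.sex == "male"),
            "unvaccinated": count_pct(unvacc, lambda p: p.sex == "male"),
        },
        "age_gt60": {
            "vaccinated": count_pct(vacc, lambda p: p.age_group == "gt60"),
            "unvaccinated": count_pct(unvacc, lambda p: p.age_group == "gt60"),
        },
        "private_insurance": {
            "vaccinated": count_pct(vacc, lambda p: p.insurance == "private"),
            "unvaccinated": count_pct(unvacc, lambda p: p.insurance == "private"),
        },
        "ecog_gt1": {
            "vaccinated": count_pct(vacc, lambda p: p.ecog > 1),
            "unvaccinated": count_pct(unvacc, lambda p: p.ecog > 1),
        },
    }

    ae_by_patient: dict[str, list] = {}
    for a in dataset.adverse_events:
        ae_by_patient.setdefault(a.patient_id, []).append(a)

    def early_aes(p):
        if not p.vaccinated:
            return []
        end = (p.vax2_date or p.vax1_date) + datetime.timedelta(days=ae_window_days)
        return [
            a for a in ae_by_patient.get(p.patient_id, [])
            if p.vax1_date <= a.onset_date <= end
        ]

    early = {}
    if n_v:
        k_any = sum(1 for p in vacc if early_aes(p))
        k_g3 = sum(1 for p in vacc if any(a.grade >= 3 for a in early_aes(p)))
        early = {
            "any_grade": _fmt_pct_ci(k_any, n_v),
            "grade_ge3": _fmt_pct_ci(k_g3, n_v),
            "window_days_after_last_dose": ae_window_days,
        }

    irae_terms = sorted(
        {a.term for a in dataset.adverse_events if a.is_irae}
    )
    irae = {}
    for term in irae_terms:
        row = {}
        for label, group, n in (("vaccinated", vacc, n_v), ("unvaccinated", unvacc, n_u)):
            if n == 0:
                continue
            k = sum(
                1
                for p in group
                if any(
                    a.is_irae and a.term == term
                    for a in ae_by_patient.get(p.patient_id, [])
                )
            )
            row[label] = _fmt_pct_ci(k, n)
        irae[term] = row

    return {"baseline_characteristics": baseline, "early_adverse_events": early,
            "immune_related_adverse_events": irae}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    t0 = time.time()
    files: dict[str, str] = {}

    def record(manifest: dict, subdir: str):
        for name, digest in manifest["files"].items():
            files[f"{subdir}/{name}"] = digest

    # --- stage: simulate or load ---------------------------------------
    stage = "simulate"
    try:
        if config.input_dir:
            _log(stage, f"loading cohort tables from {config.input_dir}", log_lines)
            dataset = load_cohort(config.input_dir)
        else:
            _log(stage, f"generating synthetic cohort (seed={config.seed})", log_lines)
            dataset = generate_cohort(
                n_vaccinated=config.n_vaccinated,
                n_unvaccinated=config.n_unvaccinated,
                seed=config.seed,
                n_serum_subcohort=config.n_serum_subcohort,
                baseline_window_days=config.baseline_window_days,
                post_window_days=config.post_window_days,
            )
        cohort_dir = out_dir / "cohort"
        paths = write_cohort(dataset, cohort_dir)
        for name, path in paths.items():
            files[f"cohort/{name}"] = hashlib.sha256(path.read_bytes()).hexdigest()
        _log(
            stage,
            f"{len(dataset.patients)} patients, {len(dataset.samples)} samples, "
            f"{len(dataset.adverse_events)} adverse events",
            log_lines,
        )
    except Exception as exc:
        raise StageError(stage, exc) from exc

    results_meta = {"seed": config.seed, "config_sha256": config.sha256()}

    # --- stage: programs -------------------------------------------------
    if "programs" in config.stages:
        stage = "programs"
        try:
            selection = select_cytokine_subcohort(
                dataset,
                baseline_window_days=config.baseline_window_days,
                post_window_days=config.post_window_days,
            )
            _log(
                stage,
                f"serum subcohort: {selection.n_qualifying} qualifying, "
                f"{selection.n_analyzed} analyzed "
                f"({len(selection.excluded_baseline_irae)} baseline-irAE exclusion)",
                log_lines,
            )
            fc = pg.build_fold_change_matrix(dataset, selection)
            corr, dist, excluded = pg.correlation_matrix(fc)
            assignment = pg.upgma_flat_clusters(dist, config.cophenetic_threshold)
            cocluster = pg.bootstrap_cocluster(
                fc,
                n_boot=config.n_boot,
                threshold=config.cophenetic_threshold,
                seed=config.seed,
                resample_unit=config.resample_unit,
            )
            scores = pg.program_scores(fc, assignment, aggregation=config.aggregation)
            stats_list = pg.program_inference(scores, assignment)
            _log(
                stage,
                f"{assignment.n_programs} programs from {corr.shape[0]} cytokines; "
                f"n_boot={config.n_boot}",
                log_lines,
            )
            program_json = [
                {
                    "program_id": s.program_id,
                    "members": s.members,
                    "n_patients": len(s.patient_scores),
                    "wilcoxon_w": s.wilcoxon.w,
                    "wilcoxon_mode": s.wilcoxon.mode,
                    "p": s.p,
                    "q": s.q,
                    "cohens_d": s.cohens_d,
                    "patient_scores": s.patient_scores,
                }
                for s in stats_list
            ]
            responders = {}
            for s in stats_list:
                cls = pg.classify_responders(
                    s.patient_scores, fold_threshold=config.fold_threshold
                )
                pct, lo, hi = cls.ci.as_percent(1)
                responders[f"program_{s.program_id}"] = {
                    "k": cls.k,
                    "n": cls.n,
                    "fold_threshold": cls.fold_threshold,
                    "percent": pct,
                    "ci_percent": [lo, hi],
                    "top_patients": pg.top_induced(
                        s.patient_scores, config.top_fold_threshold
                    ).to_dict("records"),
                }
            artifacts = {
                "fold_changes": fc.values,
                "correlation": corr,
                "cocluster_probability": cocluster.matrix,
                "program_stats": program_json,
                "responders": responders,
                "subcohort": {
                    "n_qualifying": selection.n_qualifying,
                    "n_analyzed": selection.n_analyzed,
                    "excluded_baseline_irae": selection.excluded_baseline_irae,
                    "zero_variance_cytokines": excluded,
                    "degenerate_resample_counts": cocluster.degenerate_counts,
                },
            }
            manifest = write_results(artifacts, out_dir / "programs", results_meta)
            record(manifest, "programs")
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # --- stage: outcomes -------------------------------------------------
    if "outcomes" in config.stages:
        stage = "outcomes"
        try:
            vacc = [p for p in dataset.patients if p.vaccinated]
            unvacc = [p for p in dataset.patients if not p.vaccinated]
            artifacts: dict = {}
            if vacc and unvacc:
                a = (
                    [p.survival_days for p in vacc],
                    [p.death_observed for p in vacc],
                )
                b = (
                    [p.survival_days for p in unvacc],
                    [p.death_observed for p in unvacc],
                )
                km_v = oc.km_estimator(*a)
                km_u = oc.km_estimator(*b)
                lr = oc.logrank_test(a, b)
                _log(
                    stage,
                    f"log-rank chi2={lr.statistic:.3f} p={lr.p:.4g} "
                    f"HR={lr.hazard_ratio:.3f} ({lr.hr_method})",
                    log_lines,
                )
                artifacts["km_vaccinated"] = km_v.as_frame()
                artifacts["km_unvaccinated"] = km_u.as_frame()
                artifacts["logrank"] = {
                    "statistic": lr.statistic,
                    "p": lr.p,
                    "hazard_ratio": lr.hazard_ratio,
                    "hr_ci": list(lr.hr_ci),
                    "hr_method": lr.hr_method,
                }
                if config.landmark_date:
                    lm = oc.landmark_analysis(
                        dataset, datetime.date.fromisoformat(config.landmark_date)
                    )
                    artifacts["landmark"] = {
                        "landmark_date": config.landmark_date,
                        "flags": lm.flags,
                        "n_pre": list(lm.n_pre),
                        "n_post": list(lm.n_post),
                        "pre": None
                        if lm.pre is None
                        else {"statistic": lm.pre.statistic, "p": lm.pre.p,
                              "hazard_ratio": lm.pre.hazard_ratio},
                        "post": None
                        if lm.post is None
                        else {"statistic": lm.post.statistic, "p": lm.post.p,
                              "hazard_ratio": lm.post.hazard_ratio},
                    }
                rates = oc.event_rate_intervals(
                    dataset, split_days=config.ae_split_days, counting=config.ae_counting
                )
                artifacts["event_rates"] = {
                    k: {"events": r.events, "days_at_risk": r.days_at_risk, "rate": r.rate}
                    for k, r in rates.items()
                }
                features = oc.encode_covariates(dataset, config.propensity_covariates)
                labels = pd.Series(
                    {p.patient_id: int(p.vaccinated) for p in dataset.patients}
                )
                model = oc.fit_propensity(features, labels)
                match = oc.match_with_replacement(model)
                artifacts["matched_pairs"] = match.pairs.set_index("unvaccinated_id")
                artifacts["balance"] = match.balance
            manifest = write_results(artifacts, out_dir / "outcomes", results_meta)
            record(manifest, "outcomes")
        except Exception as exc:
            raise StageError(stage, exc) from exc

    # --- stage: report ----------------------------------------------------
    if "report" in config.stages:
        stage = "report"
        try:
            tables = summarize_tables(dataset, ae_window_days=config.ae_split_days)
            manifest = write_results({"report_tables": tables}, out_dir / "report", results_meta)
            record(manifest, "report")
        except Exception as exc:
            raise StageError(stage, exc) from exc

    manifest = {
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": config.sha256(),
        "files": dict(sorted(files.items())),
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    _log("done", f"wrote {len(files)} files in {time.time() - t0:.1f}s", log_lines)
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    return manifest
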