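"""Synthetic cohort generator.

Emulates the statistical structure of a vaccination-under-immunotherapy
cohort: ~90 patients (64 vaccinated / 26 unvaccinated), a serum subcohort
with one baseline sample up to 6 months before the first vaccine dose and
1-2 samples within 6 weeks after it, block-correlated post-vaccination
cytokine responses ("programs") planted through a latent per-patient
activation factor, bead-assay measurement through a 5PL standard curve with
LLOD flooring, per-period Poisson adverse events and exponential survival
with a planted vaccinated/unvaccinated hazard ratio.

All randomness flows from one root seed through three named substreams
(cohort biology, assay measurement, clinical outcomes), so each layer can
be regenerated independently and identical (config, seed) pairs yield
identical datasets.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field

import numpy as np

from .assay import FivePLParams, five_pl_forward, five_pl_invert
from .data import AdverseEventRecord, CohortDataset, Patient, SerumSample
from .errors import SpecError

__all__ = [
    "DEFAULT_PANEL",
    "PROGRAM_BLOCK_1",
    "PROGRAM_BLOCK_2",
    "ProgramPlantSpec",
    "AssaySpec",
    "OutcomeSpec",
    "generate_cohort",
    "simulate_survival_times",
    "simulate_confounded_covariates",
]

# CRS-associated mediators named in the multiplex panel, plus common
# companions to fill a 26-plex storm panel.
PROGRAM_BLOCK_1 = ["IL-6", "CXCL8", "IL-2", "CCL2", "sIL-1R"]
PROGRAM_BLOCK_2 = ["IL-18", "sIL-2RA", "IFN-gamma", "IL-10", "IL-16"]
DEFAULT_PANEL = PROGRAM_BLOCK_1 + PROGRAM_BLOCK_2 + [
    "TNF-alpha", "IL-1beta", "IFN-alpha", "IL-4", "IL-5", "IL-7",
    "IL-12p70", "IL-13", "IL-15", "IL-17A", "IL-21", "IL-23",
    "IL-33", "CXCL9", "CXCL10", "GM-CSF",
]

# Baseline log10 medians (pg/ml) for the named mediators; the remaining
# panel members are spread over a plausible serum range.
_BASE_LOG10_MEDIAN = {
    "IL-6": 1.2, "CXCL8": 1.5, "IL-2": 0.8, "CCL2": 2.2, "sIL-1R": 2.0,
    "IL-18": 1.8, "sIL-2RA": 2.3, "IFN-gamma": 0.9, "IL-10": 0.8, "IL-16": 2.0,
}

TUMOR_TYPES = [
    "melanoma", "hepatocellular carcinoma", "renal cell carcinoma",
    "urothelial carcinoma", "uveal melanoma", "NSCLC", "head and neck SCC",
    "breast cancer", "pancreatic adenocarcinoma", "other",
]
THERAPY_CLASSES = [
    "PD-1/PD-L1 mono", "CTLA-4 + PD-1/PD-L1", "PD-1/PD-L1 + CTX",
    "PD-1/PD-L1 + TKI", "PD-1/PD-L1 + VEGF", "other",
]
AE_TERMS = [
    "fatigue", "fever", "nausea", "arthralgia", "muscle weakness",
    "thrombocytopenia", "anemia", "diarrhea", "colitis", "hepatitis",
    "bilirubin increase", "creatinine increase",
]


@dataclass(frozen=True)
class ProgramPlantSpec:
    """Planted block-correlation structure of post-vaccination responses.

    Each block is a disjoint set of cytokines whose log10 fold changes share
    a latent per-patient activation: a fraction ``responder_fraction`` of
    vaccinated patients activates the block, and activated responses are
    Gaussian with the given mean/sd on the log10 scale.  Correlations are
    ``within_block_correlation`` inside a block and
    ``cross_block_correlation`` between blocks.
    """

    blocks: tuple = (tuple(PROGRAM_BLOCK_1), tuple(PROGRAM_BLOCK_2))
    within_block_correlation: float = 0.8
    cross_block_correlation: float = 0.05
    response_log10_mean: tuple = (0.45, 0.25)
    response_log10_sd: tuple = (0.30, 0.25)
    responder_fraction: tuple = (0.45, 0.5)

    def __post_init__(self):
        flat = [c for b in self.blocks for c in b]
        if len(flat) != len(set(flat)):
            raise SpecError("program blocks must be disjoint")
        if not 0.0 < self.within_block_correlation < 1.0:
            raise SpecError("within_block_correlation must lie in (0, 1)")
        if not 0.0 <= self.cross_block_correlation < self.within_block_correlation:
            raise SpecError("cross_block_correlation must lie in [0, within)")
        k = len(self.blocks)
        for name, vals in (
            ("response_log10_mean", self.response_log10_mean),
            ("response_log10_sd", self.response_log10_sd),
            ("responder_fraction", self.responder_fraction),
        ):
            if len(vals) != k:
                raise SpecError(f"{name} must have one entry per block")
        if any(s <= 0 for s in self.response_log10_sd):
            raise SpecError("response_log10_sd entries must be positive")
        if any(not 0.0 <= f <= 1.0 for f in self.responder_fraction):
            raise SpecError("responder_fraction entries must lie in [0, 1]")

    def validate_against_panel(self, panel):
        missing = [c for b in self.blocks for c in b if c not in panel]
        if missing:
            raise SpecError(f"block cytokines absent from panel: {missing}")


@dataclass(frozen=True)
class AssaySpec:
    """Bead-assay measurement stage: 1:2 serum dilution, 5PL interpolation
    and LLOD flooring.  ``noise_cv`` adds multiplicative signal noise."""

    params: FivePLParams = field(
        default_factory=lambda: FivePLParams(a=45.0, d=28000.0, c=120.0, b=1.15, g=0.9)
    )
    llod_pg_ml: float = 1.0
    dilution: float = 2.0
    noise_cv: float = 0.0


@dataclass(frozen=True)
class OutcomeSpec:
    """Adverse-event rates (events per patient-day) per follow-up period and
    the exponential survival model with a vaccinated log hazard ratio."""

    ae_rate_per_period: dict = field(
        default_factory=lambda: {
            "pre_vax": 0.004,
            "post_le28d": 0.012,
            "post_gt28d": 0.006,
            "unvaccinated": 0.015,
        }
    )
    baseline_hazard: float = 0.002  # per day, unvaccinated
    log_hazard_ratio_vaccinated: float = math.log(0.21)
    censor_date: datetime.date = datetime.date(2022, 3, 1)
    irae_fraction: float = 0.3
    hospitalization_given_grade3: float = 0.7

    def __post_init__(self):
        if any(r < 0 for r in self.ae_rate_per_period.values()):
            raise SpecError("adverse-event rates must be non-negative")
        if self.baseline_hazard < 0:
            raise SpecError("baseline hazard must be non-negative")


def _measure(conc: float, assay: AssaySpec | None, rng) -> float:
    """Push a true concentration through the assay stage (dilute, read the
    5PL signal, invert, floor at the LLOD, undilute)."""
    if assay is None:
        return conc
    signal = five_pl_forward(conc / assay.dilution, assay.params)
    if assay.noise_cv > 0:
        signal = signal * (1.0 + assay.noise_cv * rng.standard_normal())
        lo = min(assay.params.a, assay.params.d)
        hi = max(assay.params.a, assay.params.d)
        signal = float(np.clip(signal, lo, hi - 1e-9 * max(abs(hi), 1.0)))
    back = five_pl_invert(signal, assay.params, llod_pg_ml=assay.llod_pg_ml / assay.dilution)
    return back * assay.dilution


def _date_plus(d: datetime.date, days: int) -> datetime.date:
    return d + datetime.timedelta(days=int(days))


def generate_cohort(
    n_vaccinated: int = 64,
    n_unvaccinated: int = 26,
    plant: ProgramPlantSpec | None = None,
    outcomes: OutcomeSpec | None = None,
    seed: int = 0,
    panel=None,
    n_serum_subcohort: int = 36,
    n_baseline_irae_exclusions: int = 1,
    baseline_window_days: int = 183,
    post_window_days: int = 42,
    assay: AssaySpec | None = AssaySpec(),
) -> CohortDataset:
    """Generate a validated synthetic cohort; deterministic given ``seed``.

    ``n_serum_subcohort`` vaccinated patients receive one qualifying
    baseline sample and 1-2 post-vaccination samples;
    ``n_baseline_irae_exclusions`` of them additionally carry a grade-3
    immune-related adverse event inside the baseline window, so the
    analyzed serum subcohort has ``n_serum_subcohort - exclusions``
    patients.  Unvaccinated patients get longitudinal samples with no
    planted response.
    """
    if n_vaccinated < 0 or n_unvaccinated < 0:
        raise SpecError("cohort sizes must be non-negative")
    plant = plant if plant is not None else ProgramPlantSpec()
    outcomes = outcomes if outcomes is not None else OutcomeSpec()
    panel = list(panel) if panel is not None else list(DEFAULT_PANEL)
    plant.validate_against_panel(panel)
    n_serum = min(n_serum_subcohort, n_vaccinated)
    n_excl = min(n_baseline_irae_exclusions, n_serum)

    ss = np.random.SeedSequence(seed)
    r_bio, r_assay, r_out = (np.random.default_rng(s) for s in ss.spawn(3))

    base_medians = {}
    others = [c for c in panel if c not in _BASE_LOG10_MEDIAN]
    spread = np.linspace(0.5, 2.5, max(len(others), 1))
    for c in panel:
        if c in _BASE_LOG10_MEDIAN:
            base_medians[c] = _BASE_LOG10_MEDIAN[c]
        else:
            base_medians[c] = float(spread[others.index(c)])

    cyto_block = {}
    for bi, block in enumerate(plant.blocks):
        for c in block:
            cyto_block[c] = bi

    patients, samples, aes = [], [], []

    serum_idx = set()
    if n_serum > 0:
        serum_idx = set(sorted(r_bio.choice(n_vaccinated, size=n_serum, replace=False)))
    excluded_idx = set(sorted(serum_idx)[:n_excl])

    vax_windows = {}
    for i in range(n_vaccinated + n_unvaccinated):
        vaccinated = i < n_vaccinated
        pid = f"V{i:03d}" if vaccinated else f"U{i - n_vaccinated:03d}"
        if vaccinated:
            ici_start = _date_plus(datetime.date(2020, 3, 1), r_bio.integers(0, 420))
            earliest = max(_date_plus(ici_start, 14), datetime.date(2021, 1, 4))
            vax1 = _date_plus(earliest, r_bio.integers(0, 120))
            if vax1 > datetime.date(2021, 7, 20):
                vax1 = datetime.date(2021, 7, 20)
            if vax1 <= ici_start:
                vax1 = _date_plus(ici_start, 14)
            vax2 = _date_plus(vax1, r_bio.integers(21, 43))
            vtype = str(
                r_bio.choice(
                    ["BNT162b2", "mRNA-1273", "AZD1222", "AZD1222/mRNA-1273"],
                    p=[0.781, 0.047, 0.156, 0.016],
                )
            )
            vax_windows[pid] = (vax1, vax2)
        else:
            ici_start = _date_plus(datetime.date(2020, 7, 1), r_bio.integers(0, 390))
            vax1 = vax2 = None
            vtype = "none"
        sex = "male" if r_bio.random() < 0.69 else "female"
        age = int(np.clip(round(r_bio.normal(64, 11)), 22, 92))
        ecog = int(r_bio.choice([0, 1, 2], p=[0.20, 0.68, 0.12]))
        insurance = "private" if r_bio.random() < 0.145 else "general"
        tumor = str(r_bio.choice(TUMOR_TYPES))
        therapy = str(r_bio.choice(THERAPY_CLASSES))

        hazard = outcomes.baseline_hazard * math.exp(
            outcomes.log_hazard_ratio_vaccinated if vaccinated else 0.0
        )
        cap = max((outcomes.censor_date - ici_start).days, 1)
        t = r_out.exponential(1.0 / hazard) if hazard > 0 else math.inf
        survival_days = float(min(round(t), cap)) if math.isfinite(t) else float(cap)
        survival_days = max(survival_days, 1.0)
        death = t <= cap

        patients.append(
            Patient(
                patient_id=pid, vaccinated=vaccinated, vaccine_type=vtype,
                vax1_date=vax1, vax2_date=vax2, ici_start_date=ici_start,
                sex=sex, age_years=age, ecog=ecog, insurance=insurance,
                tumor_type=tumor, therapy_class=therapy,
                survival_days=survival_days, death_observed=bool(death),
            )
        )

    # --- planted fold changes for the serum subcohort -------------------
    rw = plant.within_block_correlation
    rc = plant.cross_block_correlation
    share = math.sqrt(rc / rw) if rw > 0 else 0.0
    n_blocks = len(plant.blocks)

    serum_pids = [f"V{i:03d}" for i in sorted(serum_idx)]
    fold_changes = {}
    for pid in serum_pids:
        g = r_bio.standard_normal()  # global factor, couples blocks
        fc = {}
        block_u = [
            share * g + math.sqrt(max(1.0 - share**2, 0.0)) * r_bio.standard_normal()
            for _ in range(n_blocks)
        ]
        block_on = [r_bio.random() < plant.responder_fraction[b] for b in range(n_blocks)]
        for c in panel:
            if c in cyto_block:
                b = cyto_block[c]
                if block_on[b]:
                    eps = r_bio.standard_normal()
                    fc[c] = plant.response_log10_mean[b] + plant.response_log10_sd[b] * (
                        math.sqrt(rw) * block_u[b] + math.sqrt(1.0 - rw) * eps
                    )
                else:
                    fc[c] = 0.05 * r_bio.standard_normal()
            else:
                fc[c] = 0.12 * r_bio.standard_normal()
        fold_changes[pid] = fc

    sample_counter = 0

    def add_sample(pid, draw_date, log10_conc: dict):
        nonlocal sample_counter
        conc = {}
        for c in panel:
            true = 10.0 ** log10_conc[c]
            conc[c] = _measure(true, assay, r_assay)
        samples.append(
            SerumSample(
                sample_id=f"S{sample_counter:04d}",
                patient_id=pid,
                draw_date=draw_date,
                concentrations=conc,
            )
        )
        sample_counter += 1

    for pid in serum_pids:
        vax1, _vax2 = vax_windows[pid]
        p = next(q for q in patients if q.patient_id == pid)
        base_log10 = {
            c: base_medians[c] + 0.4 * r_bio.standard_normal() for c in panel
        }
        baseline_date = _date_plus(vax1, -int(r_bio.integers(14, 170)))
        if baseline_date < p.ici_start_date:
            baseline_date = p.ici_start_date
        add_sample(pid, baseline_date, base_log10)
        n_post = 1 + int(r_bio.random() < 0.5)
        post_days = [int(r_bio.integers(7, 29))]
        if n_post == 2:
            post_days.append(int(r_bio.integers(29, 43)))
        for dd in post_days:
            jitter = {c: 0.05 * r_bio.standard_normal() for c in panel}
            post_log10 = {c: base_log10[c] + fold_changes[pid][c] + jitter[c] for c in panel}
            add_sample(pid, _date_plus(vax1, dd), post_log10)

    # longitudinal samples without planted response for unvaccinated patients
    for i in range(n_unvaccinated):
        pid = f"U{i:03d}"
        p = next(q for q in patients if q.patient_id == pid)
        base_log10 = {c: base_medians[c] + 0.4 * r_bio.standard_normal() for c in panel}
        for dd in (30, 120):
            drift = {c: 0.12 * r_bio.standard_normal() for c in panel}
            add_sample(pid, _date_plus(p.ici_start_date, dd),
                       {c: base_log10[c] + drift[c] for c in panel})

    # --- adverse events: Poisson per period at the spec rates ------------
    def draw_events(p, start_day, end_day, rate):
        """Events in the half-open day interval (start_day, end_day]."""
        days = end_day - start_day
        if days <= 0 or rate <= 0:
            return
        for _ in range(r_out.poisson(rate * days)):
            onset = start_day + 1 + int(r_out.integers(0, days))
            term = str(r_out.choice(AE_TERMS))
            grade = int(r_out.choice([1, 2, 3, 4], p=[0.50, 0.27, 0.17, 0.06]))
            is_irae = bool(r_out.random() < outcomes.irae_fraction)
            hosp = grade >= 3 and r_out.random() < outcomes.hospitalization_given_grade3
            aes.append(
                AdverseEventRecord(
                    patient_id=p.patient_id, term=term, grade=grade,
                    onset_date=_date_plus(p.ici_start_date, onset),
                    is_irae=is_irae, hospitalization=bool(hosp),
                )
            )

    for p in patients:
        end = int(p.survival_days)
        if p.vaccinated:
            v1 = (p.vax1_date - p.ici_start_date).days
            rates = outcomes.ae_rate_per_period
            draw_events(p, -1, min(v1, end), rates["pre_vax"])
            if v1 < end:
                draw_events(p, v1, min(v1 + 28, end), rates["post_le28d"])
            if v1 + 28 < end:
                draw_events(p, v1 + 28, end, rates["post_gt28d"])
        else:
            draw_events(p, -1, end, outcomes.ae_rate_per_period["unvaccinated"])

    # keep baseline windows of retained serum patients free of grade>=3
    # irAEs so the planted exclusion count is exact; random events there are
    # demoted to non-immune-related (the planted exclusions come next)
    retained = {f"V{i:03d}" for i in serum_idx - excluded_idx}
    for k, a in enumerate(aes):
        if a.patient_id in retained and a.is_irae and a.grade >= 3:
            vax1, _ = vax_windows[a.patient_id]
            lo = _date_plus(vax1, -baseline_window_days)
            if lo <= a.onset_date <= vax1:
                aes[k] = AdverseEventRecord(
                    patient_id=a.patient_id, term=a.term, grade=a.grade,
                    onset_date=a.onset_date, is_irae=False,
                    hospitalization=a.hospitalization,
                )

    # planted baseline-window irAE for the excluded subcohort patients
    for i in sorted(excluded_idx):
        pid = f"V{i:03d}"
        p = next(q for q in patients if q.patient_id == pid)
        vax1, _ = vax_windows[pid]
        v1 = (vax1 - p.ici_start_date).days
        onset = max(0, min(v1 - 7, int(p.survival_days)))
        aes.append(
            AdverseEventRecord(
                patient_id=pid, term="arthritis", grade=3,
                onset_date=_date_plus(p.ici_start_date, onset),
                is_irae=True, hospitalization=False,
            )
        )

    dataset = CohortDataset(
        patients=patients, samples=samples, adverse_events=aes, panel=panel
    )
    return dataset.validate()


def simulate_survival_times(
    n_a: int, n_b: int, baseline_hazard: float, hazard_ratio: float,
    censor_days: float, rng,
):
    """Two exponential survival arms; arm a has ``hazard_ratio`` times the
    baseline hazard of arm b.  Returns (times_a, events_a, times_b, events_b)."""
    ta = rng.exponential(1.0 / (baseline_hazard * hazard_ratio), size=n_a)
    tb = rng.exponential(1.0 / baseline_hazard, size=n_b)
    ea = ta <= censor_days
    eb = tb <= censor_days
    return (
        np.minimum(ta, censor_days), ea,
        np.minimum(tb, censor_days), eb,
    )


def simulate_confounded_covariates(n: int, beta, seed: int):
    """Covariates and a treatment label drawn from a logistic model.

    ``beta`` = (intercept, age coefficient per standardized year, sex
    coefficient).  Returns (features DataFrame with columns age/sex,
    labels Series) for exercising propensity fitting and matching.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    age = rng.normal(64, 11, size=n)
    sex = (rng.random(n) < 0.3).astype(float)  # 1 = female
    z = (age - 64.0) / 11.0
    lin = beta[0] + beta[1] * z + beta[2] * sex
    labels = (rng.random(n) < 1.0 / (1.0 + np.exp(-lin))).astype(int)
    features = pd.DataFrame(
        {"age": age, "sex": sex},
        index=[f"P{i:04d}" for i in range(n)],
    )
    return features, pd.Series(labels, index=features.index, name="vaccinated")
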