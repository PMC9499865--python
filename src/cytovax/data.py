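"""Cohort data model, delimited-table IO and validation.

The analysis operates on three tables: patients, serum samples (one row per
sample x cytokine, concentrations in pg/ml with 0 encoding below-LLOD) and
CTCAE-graded adverse events.  ``CohortDataset`` bundles them with the
cytokine panel registry and validates referential integrity before any
computation runs.  Dates are ISO-8601; all date arithmetic is in whole days
with day 0 at the first vaccine dose.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .errors import ReferentialError, SchemaError, ValidationError

__all__ = [
    "Patient",
    "SerumSample",
    "AdverseEventRecord",
    "CohortDataset",
    "SubcohortSelection",
    "load_cohort",
    "write_cohort",
    "select_cytokine_subcohort",
    "write_results",
    "VACCINE_TYPES",
]

VACCINE_TYPES = ("BNT162b2", "mRNA-1273", "AZD1222", "AZD1222/mRNA-1273", "none")
SEXES = ("male", "female")
INSURANCE_TYPES = ("general", "private")

PATIENT_COLUMNS = [
    "patient_id", "vaccinated", "vaccine_type", "vax1_date", "vax2_date",
    "ici_start_date", "sex", "age_years", "ecog", "insurance", "tumor_type",
    "therapy_class", "survival_days", "death_observed",
]
SAMPLE_COLUMNS = [
    "sample_id", "patient_id", "draw_date", "cytokine",
    "concentration_pg_ml", "below_llod",
]
AE_COLUMNS = ["patient_id", "term", "grade", "onset_date", "is_irae", "hospitalization"]


def _parse_date(value) -> datetime.date | None:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, datetime.date):
        return value
    return datetime.date.fromisoformat(str(value))


@dataclass(frozen=True)
class Patient:
    patient_id: str
    vaccinated: bool
    vaccine_type: str
    vax1_date: datetime.date | None
    vax2_date: datetime.date | None
    ici_start_date: datetime.date
    sex: str
    age_years: int
    ecog: int
    insurance: str
    tumor_type: str
    therapy_class: str
    survival_days: float
    death_observed: bool

    def __post_init__(self):
        if self.vaccinated != (self.vax1_date is not None):
            raise ValidationError(
                f"patient {self.patient_id}: vaccinated={self.vaccinated} but "
                f"vax1_date={'present' if self.vax1_date else 'absent'}"
            )
        if self.vax1_date and self.vax2_date and self.vax2_date < self.vax1_date:
            raise ValidationError(f"patient {self.patient_id}: vax2_date before vax1_date")
        if self.vaccine_type not in VACCINE_TYPES:
            raise ValidationError(
                f"patient {self.patient_id}: unknown vaccine_type {self.vaccine_type!r}"
            )
        if not self.vaccinated and self.vaccine_type != "none":
            raise ValidationError(
                f"patient {self.patient_id}: unvaccinated but vaccine_type set"
            )
        if self.sex not in SEXES:
            raise ValidationError(f"patient {self.patient_id}: unknown sex {self.sex!r}")
        if self.insurance not in INSURANCE_TYPES:
            raise ValidationError(
                f"patient {self.patient_id}: unknown insurance {self.insurance!r}"
            )
        if self.age_years <= 0:
            raise ValidationError(f"patient {self.patient_id}: age_years must be positive")
        if not 0 <= self.ecog <= 5:
            raise ValidationError(f"patient {self.patient_id}: ecog outside 0..5")
        if self.survival_days < 0:
            raise ValidationError(f"patient {self.patient_id}: negative survival_days")

    @property
    def age_group(self) -> str:
        """Age stratum: 'gt60' above 60 years, 'le60' otherwise."""
        return "gt60" if self.age_years > 60 else "le60"

    @property
    def followup_end(self) -> datetime.date:
        return self.ici_start_date + datetime.timedelta(days=round(self.survival_days))


@dataclass(frozen=True)
class SerumSample:
    sample_id: str
    patient_id: str
    draw_date: datetime.date
    concentrations: dict  # cytokine name -> pg/ml; 0 encodes below-LLOD
    below_llod: dict = field(default_factory=dict)

    def __post_init__(self):
        for cytokine, conc in self.concentrations.items():
            if conc < 0:
                raise ValidationError(
                    f"sample {self.sample_id}: negative concentration for {cytokine}"
                )
        if not self.below_llod:
            object.__setattr__(
                self,
                "below_llod",
                {c: (v == 0) for c, v in self.concentrations.items()},
            )


@dataclass(frozen=True)
class AdverseEventRecord:
    patient_id: str
    term: str
    grade: int
    onset_date: datetime.date
    is_irae: bool
    hospitalization: bool

    def __post_init__(self):
        if not 1 <= self.grade <= 5:
            raise ValidationError(
                f"adverse event for {self.patient_id}: grade {self.grade} outside 1..5"
            )


@dataclass
class CohortDataset:
    """Patients, serum samples, adverse events and the cytokine panel."""

    patients: list
    samples: list
    adverse_events: list
    panel: list

    def validate(self) -> "CohortDataset":
        ids = [p.patient_id for p in self.patients]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate patient ids: {dupes}")
        known = set(ids)
        dangling = sorted(
            {s.patient_id for s in self.samples if s.patient_id not in known}
            | {a.patient_id for a in self.adverse_events if a.patient_id not in known}
        )
        if dangling:
            raise ReferentialError(f"records reference unknown patients: {dangling}")
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValidationError("duplicate sample ids")
        panel = set(self.panel)
        for s in self.samples:
            extra = set(s.concentrations) - panel
            if extra:
                raise ValidationError(
                    f"sample {s.sample_id}: cytokines outside panel registry: {sorted(extra)}"
                )
        by_id = {p.patient_id: p for p in self.patients}
        for a in self.adverse_events:
            p = by_id[a.patient_id]
            if not p.ici_start_date <= a.onset_date <= p.followup_end:
                raise ValidationError(
                    f"adverse event for {a.patient_id} on {a.onset_date} "
                    f"outside follow-up window"
                )
        return self

    def patient(self, patient_id: str) -> Patient:
        for p in self.patients:
            if p.patient_id == patient_id:
                return p
        raise KeyError(patient_id)

    def patients_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.patients:
            d = dataclasses.asdict(p)
            for k in ("vax1_date", "vax2_date", "ici_start_date"):
                d[k] = d[k].isoformat() if d[k] else ""
            rows.append(d)
        return pd.DataFrame(rows, columns=PATIENT_COLUMNS)

    def samples_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            for cytokine in self.panel:
                if cytokine in s.concentrations:
                    rows.append(
                        {
                            "sample_id": s.sample_id,
                            "patient_id": s.patient_id,
                            "draw_date": s.draw_date.isoformat(),
                            "cytokine": cytokine,
                            "concentration_pg_ml": s.concentrations[cytokine],
                            "below_llod": s.below_llod.get(cytokine, False),
                        }
                    )
        return pd.DataFrame(rows, columns=SAMPLE_COLUMNS)

    def adverse_events_frame(self) -> pd.DataFrame:
        rows = []
        for a in self.adverse_events:
            d = dataclasses.asdict(a)
            d["onset_date"] = a.onset_date.isoformat()
            rows.append(d)
        return pd.DataFrame(rows, columns=AE_COLUMNS)


def _require_columns(df: pd.DataFrame, required, name: str):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")


def load_cohort(directory, panel=None) -> CohortDataset:
    """Read patients.csv / samples.csv / adverse_events.csv from a directory.

    The panel defaults to the cytokines present in samples.csv (first-seen
    order).  Referential and field validation runs before returning.
    """
    directory = Path(directory)
    pat_path = directory / "patients.csv"
    smp_path = directory / "samples.csv"
    ae_path = directory / "adverse_events.csv"
    for p in (pat_path, smp_path, ae_path):
        if not p.exists():
            raise SchemaError(f"missing input file: {p}")

    pat_df = pd.read_csv(pat_path, dtype=str, keep_default_na=False)
    smp_df = pd.read_csv(smp_path, dtype=str, keep_default_na=False)
    ae_df = pd.read_csv(ae_path, dtype=str, keep_default_na=False)
    _require_columns(pat_df, PATIENT_COLUMNS, "patients.csv")
    _require_columns(smp_df, SAMPLE_COLUMNS[:5], "samples.csv")
    _require_columns(ae_df, AE_COLUMNS, "adverse_events.csv")

    patients = []
    for row in pat_df.to_dict("records"):
        patients.append(
            Patient(
                patient_id=row["patient_id"],
                vaccinated=row["vaccinated"].lower() == "true",
                vaccine_type=row["vaccine_type"] or "none",
                vax1_date=_parse_date(row["vax1_date"]),
                vax2_date=_parse_date(row["vax2_date"]),
                ici_start_date=_parse_date(row["ici_start_date"]),
                sex=row["sex"],
                age_years=int(row["age_years"]),
                ecog=int(row["ecog"]),
                insurance=row["insurance"],
                tumor_type=row["tumor_type"],
                therapy_class=row["therapy_class"],
                survival_days=float(row["survival_days"]),
                death_observed=row["death_observed"].lower() == "true",
            )
        )

    samples: dict[str, dict] = {}
    order: list[str] = []
    seen_cytokines: list[str] = []
    for row in smp_df.to_dict("records"):
        sid = row["sample_id"]
        if sid not in samples:
            samples[sid] = {
                "patient_id": row["patient_id"],
                "draw_date": _parse_date(row["draw_date"]),
                "concentrations": {},
                "below_llod": {},
            }
            order.append(sid)
        conc = float(row["concentration_pg_ml"])
        if conc < 0:
            raise ValidationError(
                f"sample {sid}: negative concentration for {row['cytokine']}"
            )
        samples[sid]["concentrations"][row["cytokine"]] = conc
        flag = row.get("below_llod", "")
        samples[sid]["below_llod"][row["cytokine"]] = (
            flag.lower() == "true" if flag else conc == 0
        )
        if row["cytokine"] not in seen_cytokines:
            seen_cytokines.append(row["cytokine"])
    sample_objs = [SerumSample(sample_id=sid, **samples[sid]) for sid in order]

    aes = [
        AdverseEventRecord(
            patient_id=row["patient_id"],
            term=row["term"],
            grade=int(row["grade"]),
            onset_date=_parse_date(row["onset_date"]),
            is_irae=row["is_irae"].lower() == "true",
            hospitalization=row["hospitalization"].lower() == "true",
        )
        for row in ae_df.to_dict("records")
    ]

    dataset = CohortDataset(
        patients=patients,
        samples=sample_objs,
        adverse_events=aes,
        panel=list(panel) if panel is not None else seen_cytokines,
    )
    return dataset.validate()


def write_cohort(dataset: CohortDataset, directory) -> dict:
    """Write the three cohort tables; returns {name: path}."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (
        ("patients.csv", dataset.patients_frame()),
        ("samples.csv", dataset.samples_frame()),
        ("adverse_events.csv", dataset.adverse_events_frame()),
    ):
        path = directory / name
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths


@dataclass
class SubcohortSelection:
    """Vaccinated patients with a qualifying baseline and post-vax sample.

    ``n_qualifying`` counts patients with qualifying windows before the
    baseline-irAE exclusion; ``n_analyzed`` counts those retained.
    """

    baseline: dict  # patient_id -> SerumSample (latest pre-vaccination)
    post: dict  # patient_id -> [SerumSample] sorted by draw date
    excluded_baseline_irae: list
    n_qualifying: int

    @property
    def n_analyzed(self) -> int:
        return len(self.baseline)

    @property
    def patient_ids(self) -> list:
        return list(self.baseline)


def select_cytokine_subcohort(
    dataset: CohortDataset,
    baseline_window_days: int = 183,
    post_window_days: int = 42,
    exclusion_grade: int = 3,
) -> SubcohortSelection:
    """Select the serum-analysis subcohort.

    A vaccinated patient qualifies with >=1 sample in
    [vax1 - baseline_window_days, vax1) (the latest one is the baseline) and
    >=1 sample in (vax1, vax1 + post_window_days].  Patients with an
    immune-related adverse event of grade >= ``exclusion_grade`` with onset
    inside the baseline window are excluded after counting.
    """
    by_patient: dict[str, list] = {}
    for s in dataset.samples:
        by_patient.setdefault(s.patient_id, []).append(s)

    baseline: dict[str, SerumSample] = {}
    post: dict[str, list] = {}
    excluded: list[str] = []
    n_qualifying = 0
    for p in dataset.patients:
        if not p.vaccinated or p.vax1_date is None:
            continue
        lo = p.vax1_date - datetime.timedelta(days=baseline_window_days)
        hi = p.vax1_date + datetime.timedelta(days=post_window_days)
        pre = sorted(
            (s for s in by_patient.get(p.patient_id, [])
             if lo <= s.draw_date < p.vax1_date),
            key=lambda s: s.draw_date,
        )
        post_samples = sorted(
            (s for s in by_patient.get(p.patient_id, [])
             if p.vax1_date < s.draw_date <= hi),
            key=lambda s: (s.draw_date, s.sample_id),
        )
        if not pre or not post_samples:
            continue
        n_qualifying += 1
        has_baseline_irae = any(
            a.is_irae and a.grade >= exclusion_grade and lo <= a.onset_date <= p.vax1_date
            for a in dataset.adverse_events
            if a.patient_id == p.patient_id
        )
        if has_baseline_irae:
            excluded.append(p.patient_id)
            continue
        baseline[p.patient_id] = pre[-1]
        post[p.patient_id] = post_samples
    return SubcohortSelection(
        baseline=baseline,
        post=post,
        excluded_baseline_irae=excluded,
        n_qualifying=n_qualifying,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _json_default(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, (datetime.date, datetime.datetime)):
        return obj.isoformat()
    if hasattr(obj, "item"):  # numpy scalars
        return obj.item()
    if hasattr(obj, "tolist"):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_results(artifacts: dict, out_dir, run_meta: dict | None = None) -> dict:
    """Write result artifacts and a checksummed manifest.

    DataFrames become labeled CSV files; everything else becomes JSON with
    sorted keys.  The manifest records run metadata and a sha256 per file,
    so identical inputs and seed yield byte-identical output trees.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = {}
    for name, obj in sorted(artifacts.items()):
        if isinstance(obj, pd.DataFrame):
            path = out_dir / f"{name}.csv"
            obj.to_csv(path, index=True)
        else:
            path = out_dir / f"{name}.json"
            path.write_text(
                json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n"
            )
        files[path.name] = _sha256(path)
    manifest = {"run_meta": run_meta or {}, "files": files}
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
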