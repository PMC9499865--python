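"""Cytokine program discovery: transform, fold changes, correlation
structure, UPGMA flat clusters, bootstrap co-clustering, program scores,
inference and responder classification.

Concentrations c (pg/ml) are transformed as c_t = log10(c + 1) so that
below-LLOD values (encoded 0) stay at 0.  Post-vaccination values are
baseline-normalized by subtracting the patient's baseline c_t, giving log10
fold changes.  Cytokine-cytokine Pearson correlation r over those fold
changes yields the distance d = 1 - r used for UPGMA (average-linkage)
clustering; flat clusters ("programs") come from cutting the dendrogram at
a cophenetic distance threshold.  Cluster stability is quantified by
resampling the fold-change rows with replacement and counting, over many
replicates, how often each cytokine pair lands in the same flat cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import CohortDataset, SubcohortSelection
from .errors import (
    DegenerateInputError,
    MissingDataError,
    ParameterError,
    SmallSampleError,
)
from .stats import (
    ProportionCI,
    WilcoxonResult,
    benjamini_hochberg,
    clopper_pearson,
    cohens_d_one_sample,
    wilcoxon_signed_rank,
)

__all__ = [
    "FoldChangeMatrix",
    "ProgramAssignment",
    "CoClusterProbabilityMatrix",
    "ProgramStats",
    "ResponderClassification",
    "transform_log1p",
    "compute_fold_changes",
    "build_fold_change_matrix",
    "correlation_matrix",
    "upgma_linkage",
    "flat_clusters_from_linkage",
    "upgma_flat_clusters",
    "bootstrap_cocluster",
    "program_scores",
    "program_inference",
    "classify_responders",
    "top_induced",
]


@dataclass
class FoldChangeMatrix:
    """Per post-vaccination sample x cytokine log10 fold changes."""

    values: pd.DataFrame  # index sample_id, columns cytokine names
    patient_ids: pd.Series  # sample_id -> patient_id
    dose_labels: pd.Series  # sample_id -> 'post_dose1' | 'post_dose2'


@dataclass
class ProgramAssignment:
    """Flat-cluster (program) membership from a UPGMA cut."""

    labels: dict  # cytokine -> program id (1..K, contiguous)
    linkage: np.ndarray  # scipy-style (n-1, 4) merge record
    threshold: float
    excluded: list = field(default_factory=list)  # zero-variance cytokines

    @property
    def programs(self) -> dict:
        """program id -> member cytokines (input order)."""
        out: dict[int, list] = {}
        for cytokine, pid in self.labels.items():
            out.setdefault(pid, []).append(cytokine)
        return dict(sorted(out.items()))

    @property
    def n_programs(self) -> int:
        return len(set(self.labels.values()))


@dataclass
class CoClusterProbabilityMatrix:
    """Bootstrap co-clustering probabilities (symmetric, unit diagonal)."""

    matrix: pd.DataFrame
    n_boot: int
    seed: int
    threshold: float
    degenerate_counts: dict = field(default_factory=dict)


@dataclass
class ProgramStats:
    program_id: int
    members: list
    patient_scores: dict  # patient_id -> mean log10 fold change over members
    wilcoxon: WilcoxonResult
    p: float
    q: float
    cohens_d: float

    @property
    def geometric_mean_fold_changes(self) -> dict:
        return {pid: 10.0**s for pid, s in self.patient_scores.items()}


@dataclass
class ResponderClassification:
    flags: dict  # patient_id -> bool
    k: int
    n: int
    fold_threshold: float
    ci: ProportionCI


def transform_log1p(samples, panel) -> pd.DataFrame:
    """log10(c + 1) matrix, one row per sample, one column per panel cytokine."""
    rows = {}
    for s in samples:
        vals = []
        for cytokine in panel:
            if cytokine not in s.concentrations:
                raise MissingDataError(
                    f"sample {s.sample_id} lacks a measurement for {cytokine}"
                )
            vals.append(np.log10(s.concentrations[cytokine] + 1.0))
        rows[s.sample_id] = vals
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(panel))


def compute_fold_changes(
    transformed: pd.DataFrame,
    baseline_of: dict,
    patient_of: dict,
    dose_label_of: dict | None = None,
) -> FoldChangeMatrix:
    """Subtract each patient's baseline row from its post-vaccination rows.

    ``baseline_of`` maps patient_id -> baseline sample_id; ``patient_of``
    maps every sample_id in ``transformed`` to its patient.  Baseline rows
    are dropped from the output.
    """
    baseline_ids = set(baseline_of.values())
    post_ids = [sid for sid in transformed.index if sid not in baseline_ids]
    missing = sorted(
        {patient_of[sid] for sid in post_ids if patient_of[sid] not in baseline_of}
    )
    if missing:
        raise MissingDataError(f"patients without a baseline sample: {missing}")
    out = {}
    for sid in post_ids:
        base_sid = baseline_of[patient_of[sid]]
        out[sid] = transformed.loc[sid] - transformed.loc[base_sid]
    values = pd.DataFrame.from_dict(out, orient="index", columns=transformed.columns)
    patient_ids = pd.Series({sid: patient_of[sid] for sid in post_ids}, name="patient_id")
    labels = pd.Series(
        {sid: (dose_label_of or {}).get(sid, "post_dose1") for sid in post_ids},
        name="dose_label",
    )
    return FoldChangeMatrix(values=values, patient_ids=patient_ids, dose_labels=labels)


def build_fold_change_matrix(
    dataset: CohortDataset, selection: SubcohortSelection
) -> FoldChangeMatrix:
    """Fold-change matrix for a selected serum subcohort."""
    all_samples = [selection.baseline[pid] for pid in selection.patient_ids]
    for pid in selection.patient_ids:
        all_samples.extend(selection.post[pid])
    transformed = transform_log1p(all_samples, dataset.panel)
    baseline_of = {pid: s.sample_id for pid, s in selection.baseline.items()}
    patient_of = {s.sample_id: s.patient_id for s in all_samples}
    dose_label_of = {}
    for pid in selection.patient_ids:
        p = dataset.patient(pid)
        for s in selection.post[pid]:
            second = p.vax2_date is not None and s.draw_date > p.vax2_date
            dose_label_of[s.sample_id] = "post_dose2" if second else "post_dose1"
    return compute_fold_changes(transformed, baseline_of, patient_of, dose_label_of)


def correlation_matrix(fc: FoldChangeMatrix) -> tuple[pd.DataFrame, pd.DataFrame, list]:
    """Pearson cytokine-cytokine correlation and distance 1 - r.

    Cytokines with zero variance have undefined correlation; they are
    excluded from clustering and returned as warnings.  Requires >= 3 rows.
    """
    X = fc.values
    if len(X) < 3:
        raise SmallSampleError("correlation needs at least 3 fold-change rows")
    sd = X.std(axis=0, ddof=1)
    excluded = [c for c in X.columns if sd[c] == 0]
    kept = [c for c in X.columns if c not in excluded]
    if len(kept) < 2:
        raise DegenerateInputError("fewer than 2 cytokines with nonzero variance")
    corr = X[kept].corr(method="pearson")
    dist = 1.0 - corr
    return corr, dist, excluded


def _check_distance(D: np.ndarray):
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ParameterError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise ParameterError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-10):
        raise ParameterError("distance matrix must have a zero diagonal")


def upgma_linkage(distance) -> np.ndarray:
    """UPGMA (average-linkage) agglomeration of a distance matrix.

    Returns a scipy-style linkage record: row k merges cluster ids Z[k,0]
    and Z[k,1] at height Z[k,2] into cluster n+k of size Z[k,3].  The
    merged distance is the size-weighted arithmetic mean of the children's
    distances.  Equal-height candidate merges are broken toward the pair
    with the leftmost original indices, which makes the result
    deterministic.
    """
    D = np.asarray(distance, dtype=float)
    _check_distance(D)
    n = D.shape[0]
    if n < 2:
        raise ParameterError("need at least 2 items to cluster")
    W = D.copy()
    np.fill_diagonal(W, np.inf)
    ids = list(range(n))
    sizes = np.ones(n)
    Z = np.zeros((n - 1, 4))
    for step in range(n - 1):
        m = W.shape[0]
        # row-major argmin over positions ordered by smallest original leaf
        # index implements the lexicographic tie-break
        flat = int(np.argmin(W))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        h = W[i, j]
        Z[step] = (ids[i], ids[j], h, sizes[i] + sizes[j])
        merged = (sizes[i] * W[i] + sizes[j] * W[j]) / (sizes[i] + sizes[j])
        W[i, :] = merged
        W[:, i] = merged
        W[i, i] = np.inf
        keep = np.arange(m) != j
        W = W[np.ix_(keep, keep)]
        sizes[i] += sizes[j]
        sizes = sizes[keep]
        ids[i] = n + step
        del ids[j]
    return Z


def flat_clusters_from_linkage(Z: np.ndarray, n: int, threshold: float) -> np.ndarray:
    """Flat clusters after cutting all merges with height > threshold.

    Returns integer labels 1..K, contiguous, numbered in order of first
    appearance over the original items.
    """
    parent = list(range(n + len(Z)))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for k, (a, b, h, _) in enumerate(Z):
        if h <= threshold:
            root = n + k
            parent[find(int(a))] = root
            parent[find(int(b))] = root
    labels = np.zeros(n, dtype=int)
    mapping: dict[int, int] = {}
    for leaf in range(n):
        r = find(leaf)
        if r not in mapping:
            mapping[r] = len(mapping) + 1
        labels[leaf] = mapping[r]
    return labels


def upgma_flat_clusters(
    distance, threshold: float = 0.75, names=None
) -> ProgramAssignment:
    """UPGMA linkage plus a flat cut at the given cophenetic distance."""
    if isinstance(distance, pd.DataFrame):
        names = list(distance.columns)
        D = distance.to_numpy(dtype=float)
    else:
        D = np.asarray(distance, dtype=float)
        names = list(names) if names is not None else list(range(D.shape[0]))
    Z = upgma_linkage(D)
    labels = flat_clusters_from_linkage(Z, D.shape[0], threshold)
    return ProgramAssignment(
        labels={name: int(lbl) for name, lbl in zip(names, labels)},
        linkage=Z,
        threshold=threshold,
    )


def _cluster_labels_for_resample(X: np.ndarray, threshold: float):
    """Correlation -> distance -> UPGMA flat labels for one (re)sample.

    Zero-variance columns get correlation 0 (distance 1) to every other
    cytokine for this replicate; the caller records them in a diagnostics
    counter.
    """
    sd = X.std(axis=0)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X, rowvar=False)
    r = np.where(np.isfinite(r), r, 0.0)
    np.fill_diagonal(r, 1.0)
    D = 1.0 - r
    np.fill_diagonal(D, 0.0)
    Z = upgma_linkage(D)
    return flat_clusters_from_linkage(Z, X.shape[1], threshold), degenerate


def bootstrap_cocluster(
    fc: FoldChangeMatrix,
    n_boot: int = 10000,
    threshold: float = 0.75,
    seed: int = 0,
    resample_unit: str = "sample",
) -> CoClusterProbabilityMatrix:
    """Bootstrap co-clustering probabilities for every cytokine pair.

    Each replicate resamples fold-change rows with replacement at the
    original size, recomputes correlation, distance, UPGMA and the flat cut,
    and counts co-membership per pair; the returned entries are counts
    divided by ``n_boot``.  ``resample_unit="patient"`` switches to a block
    bootstrap over patients instead of individual rows.
    """
    if n_boot < 1:
        raise ParameterError("n_boot must be >= 1")
    if resample_unit not in ("sample", "patient"):
        raise ParameterError("resample_unit must be 'sample' or 'patient'")
    X = fc.values.to_numpy(dtype=float)
    if X.size == 0:
        raise DegenerateInputError("empty fold-change matrix")
    names = list(fc.values.columns)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    counts = np.zeros((p, p))
    degenerate_counts = np.zeros(p)

    patient_rows = None
    if resample_unit == "patient":
        patients = list(dict.fromkeys(fc.patient_ids))
        patient_rows = [
            np.flatnonzero(fc.patient_ids.to_numpy() == pid) for pid in patients
        ]

    for _ in range(n_boot):
        if resample_unit == "sample":
            idx = rng.integers(0, n, size=n)
        else:
            picks = rng.integers(0, len(patient_rows), size=len(patient_rows))
            idx = np.concatenate([patient_rows[k] for k in picks])
        labels, degenerate = _cluster_labels_for_resample(X[idx], threshold)
        counts += labels[:, None] == labels[None, :]
        degenerate_counts += degenerate

    prob = counts / n_boot
    matrix = pd.DataFrame(prob, index=names, columns=names)
    return CoClusterProbabilityMatrix(
        matrix=matrix,
        n_boot=n_boot,
        seed=seed,
        threshold=threshold,
        degenerate_counts={
            names[k]: int(degenerate_counts[k])
            for k in range(p)
            if degenerate_counts[k] > 0
        },
    )


def program_scores(
    fc: FoldChangeMatrix,
    assignment: ProgramAssignment,
    aggregation: str = "patient_mean",
) -> pd.DataFrame:
    """Per-patient, per-program scores (mean log10 fold change).

    A sample's program score averages the log10 fold changes over the
    program's member cytokines; a patient's score then averages over their
    post-vaccination samples (``aggregation="patient_mean"``) or takes the
    earliest sample (``"first_post"``).  Geometric-mean fold change is
    10**score.
    """
    if aggregation not in ("patient_mean", "first_post"):
        raise ParameterError("aggregation must be 'patient_mean' or 'first_post'")
    programs = assignment.programs
    if any(len(members) == 0 for members in programs.values()):
        raise ParameterError("empty program")
    missing = [c for c in assignment.labels if c not in fc.values.columns]
    if missing:
        raise ParameterError(f"assignment covers cytokines absent from matrix: {missing}")
    per_row = pd.DataFrame(
        {pid: fc.values[members].mean(axis=1) for pid, members in programs.items()}
    )
    per_row["patient_id"] = fc.patient_ids
    if aggregation == "patient_mean":
        scores = per_row.groupby("patient_id", sort=False).mean()
    else:
        first_rows = (
            pd.Series(np.arange(len(per_row)), index=per_row.index)
            .groupby(fc.patient_ids, sort=False)
            .min()
        )
        scores = per_row.iloc[first_rows.to_numpy()].set_index("patient_id")
    scores.columns = [f"program_{pid}" for pid in programs]
    return scores


def program_inference(
    scores: pd.DataFrame,
    assignment: ProgramAssignment,
    exact_max_n: int = 25,
) -> list:
    """Wilcoxon signed-rank vs 0 per program, BH-adjusted across programs,
    plus Cohen's D; requires >= 2 programs and >= 5 patients per test."""
    programs = assignment.programs
    if scores.shape[1] < 2:
        raise ParameterError("BH adjustment needs at least 2 programs")
    if len(scores) < 5:
        raise SmallSampleError(f"need >= 5 patients, got {len(scores)}")
    results = []
    p_values = []
    for pid in programs:
        col = scores[f"program_{pid}"].to_numpy()
        wres = wilcoxon_signed_rank(col, exact_max_n=exact_max_n)
        d = cohens_d_one_sample(col)
        results.append((pid, wres, d))
        p_values.append(wres.p_two_sided)
    q_values = benjamini_hochberg(p_values)
    out = []
    for (pid, wres, d), q in zip(results, q_values):
        out.append(
            ProgramStats(
                program_id=pid,
                members=programs[pid],
                patient_scores=dict(scores[f"program_{pid}"]),
                wilcoxon=wres,
                p=wres.p_two_sided,
                q=float(q),
                cohens_d=d,
            )
        )
    return out


def classify_responders(
    patient_scores: dict, fold_threshold: float = 1.5, alpha: float = 0.05
) -> ResponderClassification:
    """Responder = geometric-mean fold change (10**score) above threshold;
    proportion reported with an exact Clopper-Pearson interval."""
    if not patient_scores:
        raise DegenerateInputError("no patient scores")
    flags = {
        pid: bool(10.0**score > fold_threshold)
        for pid, score in patient_scores.items()
    }
    k = sum(flags.values())
    n = len(flags)
    return ResponderClassification(
        flags=flags, k=k, n=n, fold_threshold=fold_threshold,
        ci=clopper_pearson(k, n, alpha=alpha),
    )


def top_induced(
    patient_scores: dict, fold_threshold: float = 1.7
) -> pd.DataFrame:
    """Patients with geometric-mean fold change at or above the threshold,
    sorted by fold change (descending; ties by patient id)."""
    # tolerance guards against round-trip noise in 10**log10(fc) at the cut
    rows = [
        {"patient_id": pid, "fold_change": 10.0**score}
        for pid, score in patient_scores.items()
        if 10.0**score >= fold_threshold - 1e-9
    ]
    frame = pd.DataFrame(rows, columns=["patient_id", "fold_change"])
    return frame.sort_values(
        ["fold_change", "patient_id"], ascending=[False, True]
    ).reset_index(drop=True)
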