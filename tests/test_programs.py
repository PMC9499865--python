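"""Cytokine program discovery: transform, fold changes, UPGMA, bootstrap
co-clustering, scores, inference and responder classification."""

import datetime

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from cytovax import programs as pg
from cytovax.data import select_cytokine_subcohort
from cytovax.errors import (
    DegenerateInputError,
    MissingDataError,
    ParameterError,
    SmallSampleError,
)
from cytovax.simulate import ProgramPlantSpec, generate_cohort

from conftest import make_sample

d = datetime.date


def _fc(values, columns, patients=None):
    """Build a FoldChangeMatrix from a raw array for unit tests."""
    values = np.asarray(values, dtype=float)
    idx = [f"S{i}" for i in range(len(values))]
    pats = patients or [f"P{i}" for i in range(len(values))]
    return pg.FoldChangeMatrix(
        values=pd.DataFrame(values, index=idx, columns=columns),
        patient_ids=pd.Series(pats, index=idx),
        dose_labels=pd.Series(["post_dose1"] * len(values), index=idx),
    )


TWO_BLOCK_PLANT = ProgramPlantSpec(
    blocks=(("IL-6", "CXCL8", "IL-2", "CCL2", "sIL-1R"),
            ("IL-18", "sIL-2RA", "IFN-gamma", "IL-10", "IL-16")),
    within_block_correlation=0.8,
    cross_block_correlation=0.0,
    response_log10_mean=(0.5, 0.4),
    response_log10_sd=(0.3, 0.3),
    responder_fraction=(1.0, 1.0),
)
TEN_PANEL = [c for b in TWO_BLOCK_PLANT.blocks for c in b]


class TestTransform:
    @pytest.mark.parametrize("conc,expected", [(0.0, 0.0), (9.0, 1.0), (99.0, 2.0)])
    def test_log1p_values(self, conc, expected):
        s = make_sample("S1", "P1", d(2021, 1, 1), {"IL-6": conc})
        out = pg.transform_log1p([s], ["IL-6"])
        assert out.loc["S1", "IL-6"] == pytest.approx(expected)

    def test_missing_cytokine_named(self):
        s = make_sample("S1", "P1", d(2021, 1, 1), {"IL-6": 1.0})
        with pytest.raises(MissingDataError, match="S1.*CXCL8"):
            pg.transform_log1p([s], ["IL-6", "CXCL8"])


class TestFoldChanges:
    def test_subtraction(self):
        t = pd.DataFrame(
            {"IL-6": [1.0, 3.0], "CXCL8": [1.0, 1.0]}, index=["B", "Q"]
        )
        fc = pg.compute_fold_changes(t, {"P1": "B"}, {"B": "P1", "Q": "P1"})
        assert fc.values.loc["Q", "IL-6"] == pytest.approx(2.0)
        assert fc.values.loc["Q", "CXCL8"] == pytest.approx(0.0)
        assert "B" not in fc.values.index

    def test_log_ratio_identity(self):
        # baseline c=9, post c=999 -> log10(1000) - log10(10) = 2
        base = make_sample("B", "P1", d(2021, 1, 1), {"IL-6": 9.0})
        post = make_sample("Q", "P1", d(2021, 2, 1), {"IL-6": 999.0})
        t = pg.transform_log1p([base, post], ["IL-6"])
        fc = pg.compute_fold_changes(t, {"P1": "B"}, {"B": "P1", "Q": "P1"})
        assert fc.values.loc["Q", "IL-6"] == pytest.approx(2.0)

    def test_missing_baseline_listed(self):
        t = pd.DataFrame({"IL-6": [1.0]}, index=["Q"])
        with pytest.raises(MissingDataError, match="P1"):
            pg.compute_fold_changes(t, {}, {"Q": "P1"})

    def test_scale_equivariance_at_high_concentration(self):
        """Scaling a patient's raw concentrations leaves fold changes
        unchanged when c >> 1 (the +1 offset becomes negligible)."""
        base = make_sample("B", "P1", d(2021, 1, 1), {"IL-6": 2e3})
        post = make_sample("Q", "P1", d(2021, 2, 1), {"IL-6": 8e3})
        scaled = [
            make_sample("B", "P1", d(2021, 1, 1), {"IL-6": 2e4}),
            make_sample("Q", "P1", d(2021, 2, 1), {"IL-6": 8e4}),
        ]
        args = ({"P1": "B"}, {"B": "P1", "Q": "P1"})
        fc1 = pg.compute_fold_changes(pg.transform_log1p([base, post], ["IL-6"]), *args)
        fc2 = pg.compute_fold_changes(pg.transform_log1p(scaled, ["IL-6"]), *args)
        assert fc1.values.loc["Q", "IL-6"] == pytest.approx(
            fc2.values.loc["Q", "IL-6"], abs=1e-3
        )


class TestCorrelation:
    def test_duplicate_and_negated_columns(self):
        fc = _fc([[1, 1, -1], [2, 2, -2], [3, 3, -3], [5, 5, -5]], ["a", "b", "c"])
        corr, dist, excluded = pg.correlation_matrix(fc)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        assert dist.loc["a", "b"] == pytest.approx(0.0)
        assert dist.loc["a", "c"] == pytest.approx(2.0)
        assert excluded == []

    def test_perfect_linearity(self):
        fc = _fc([[1, 2], [2, 4], [3, 6], [4, 8]], ["a", "b"])
        corr, _, _ = pg.correlation_matrix(fc)
        assert corr.loc["a", "b"] == pytest.approx(1.0)

    def test_zero_variance_flagged_and_excluded(self):
        fc = _fc([[1, 7, 1], [2, 7, 3], [3, 7, 2]], ["a", "const", "b"])
        corr, _, excluded = pg.correlation_matrix(fc)
        assert excluded == ["const"]
        assert list(corr.columns) == ["a", "b"]

    def test_too_few_rows_refused(self):
        with pytest.raises(SmallSampleError):
            pg.correlation_matrix(_fc([[1, 2], [2, 1]], ["a", "b"]))


class TestUPGMA:
    def test_three_item_forced_arithmetic(self):
        D = np.array([[0.0, 0.1, 0.9], [0.1, 0.0, 0.7], [0.9, 0.7, 0.0]])
        asn = pg.upgma_flat_clusters(D, threshold=0.75, names=["A", "B", "C"])
        Z = asn.linkage
        assert Z[0, 2] == pytest.approx(0.1)
        assert Z[1, 2] == pytest.approx(0.8)  # (0.9 + 0.7) / 2
        assert asn.labels["A"] == asn.labels["B"] != asn.labels["C"]

    def test_all_zero_distances_single_program(self):
        D = np.zeros((4, 4))
        asn = pg.upgma_flat_clusters(D, threshold=0.75)
        assert asn.n_programs == 1

    def test_planted_two_block_distance(self):
        D = np.full((6, 6), 1.0)
        for i in range(3):
            for j in range(3):
                D[i, j] = 0.2 if i != j else 0.0
                D[i + 3, j + 3] = 0.2 if i != j else 0.0
        np.fill_diagonal(D, 0.0)
        asn = pg.upgma_flat_clusters(D, threshold=0.75)
        labels = list(asn.labels.values())
        assert labels[:3] == [labels[0]] * 3
        assert labels[3:] == [labels[3]] * 3
        assert labels[0] != labels[3]

    def test_matches_scipy_reference_up_to_n8(self):
        """Heights and flat cuts match scipy's average-linkage reference on
        random (tie-free) distance matrices up to n = 8."""
        rng = np.random.default_rng(99)
        for n in range(2, 9):
            for _ in range(25):
                X = rng.random((n, 5))
                D = squareform(
                    np.round(
                        squareform(
                            np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
                        ),
                        10,
                    )
                )
                Z_mine = pg.upgma_linkage(D)
                Z_ref = linkage(squareform(D), method="average")
                assert np.allclose(np.sort(Z_mine[:, 2]), np.sort(Z_ref[:, 2]))
                for t in (0.25, 0.5, 1.0, 2.0):
                    mine = pg.flat_clusters_from_linkage(Z_mine, n, t)
                    ref = fcluster(Z_ref, t=t, criterion="distance")
                    # same partition up to label permutation
                    assert len(set(zip(mine, ref))) == len(set(mine)) == len(set(ref))

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(5)
        X = rng.random((7, 4))
        D = squareform(squareform(np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)))
        Z = pg.upgma_linkage(D)
        counts = [
            len(set(pg.flat_clusters_from_linkage(Z, 7, t)))
            for t in np.linspace(0.0, 3.0, 30)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_rejects_asymmetric(self):
        D = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ParameterError):
            pg.upgma_linkage(D)


class TestBootstrap:
    def test_identical_columns_always_cocluster(self):
        fc = _fc(
            np.column_stack([v := np.random.default_rng(0).random(10), v,
                             np.random.default_rng(1).random(10)]),
            ["a", "b", "c"],
        )
        cc = pg.bootstrap_cocluster(fc, n_boot=50, seed=3)
        assert cc.matrix.loc["a", "b"] == 1.0

    def test_determinism(self):
        rng = np.random.default_rng(2)
        fc = _fc(rng.random((12, 4)), ["a", "b", "c", "d"])
        m1 = pg.bootstrap_cocluster(fc, n_boot=10, seed=7).matrix
        m2 = pg.bootstrap_cocluster(fc, n_boot=10, seed=7).matrix
        pd.testing.assert_frame_equal(m1, m2)

    def test_matrix_invariants(self):
        rng = np.random.default_rng(4)
        fc = _fc(rng.random((15, 5)), list("abcde"))
        cc = pg.bootstrap_cocluster(fc, n_boot=40, seed=1)
        M = cc.matrix.to_numpy()
        assert np.allclose(M, M.T)
        assert np.allclose(np.diag(M), 1.0)
        assert np.all((M >= 0) & (M <= 1))

    def test_column_order_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.random((14, 4))
        cols = ["a", "b", "c", "d"]
        fc1 = _fc(X, cols)
        fc2 = _fc(X[:, [2, 0, 3, 1]], [cols[i] for i in [2, 0, 3, 1]])
        m1 = pg.bootstrap_cocluster(fc1, n_boot=25, seed=11).matrix
        m2 = pg.bootstrap_cocluster(fc2, n_boot=25, seed=11).matrix
        pd.testing.assert_frame_equal(m1, m2.loc[cols, cols])

    def test_rejects_bad_n_boot(self):
        fc = _fc(np.random.default_rng(0).random((5, 3)), ["a", "b", "c"])
        with pytest.raises(ParameterError):
            pg.bootstrap_cocluster(fc, n_boot=0)


class TestScores:
    def test_row_score_is_member_mean(self):
        fc = _fc([[0.2, 0.4]], ["X", "Y"], patients=["P1"])
        asn = pg.ProgramAssignment(labels={"X": 1, "Y": 1},
                                   linkage=np.zeros((1, 4)), threshold=0.75)
        scores = pg.program_scores(fc, asn)
        assert scores.loc["P1", "program_1"] == pytest.approx(0.3)
        assert 10 ** scores.loc["P1", "program_1"] == pytest.approx(1.995, abs=0.001)

    def test_all_zero_fold_changes(self):
        fc = _fc([[0.0, 0.0]], ["X", "Y"], patients=["P1"])
        asn = pg.ProgramAssignment(labels={"X": 1, "Y": 1},
                                   linkage=np.zeros((1, 4)), threshold=0.75)
        scores = pg.program_scores(fc, asn)
        assert scores.loc["P1", "program_1"] == 0.0

    def test_patient_mean_over_rows(self):
        fc = _fc([[0.1], [0.5]], ["X"], patients=["P1", "P1"])
        asn = pg.ProgramAssignment(labels={"X": 1}, linkage=np.zeros((0, 4)),
                                   threshold=0.75)
        scores = pg.program_scores(fc, asn)
        assert scores.loc["P1", "program_1"] == pytest.approx(0.3)

    def test_first_post_aggregation(self):
        fc = _fc([[0.1], [0.5]], ["X"], patients=["P1", "P1"])
        asn = pg.ProgramAssignment(labels={"X": 1}, linkage=np.zeros((0, 4)),
                                   threshold=0.75)
        scores = pg.program_scores(fc, asn, aggregation="first_post")
        assert scores.loc["P1", "program_1"] == pytest.approx(0.1)


class TestInference:
    def _two_program_scores(self, col1, col2):
        n = len(col1)
        return pd.DataFrame(
            {"program_1": col1, "program_2": col2},
            index=[f"P{i}" for i in range(n)],
        )

    def test_all_positive_scores_maximal_w(self):
        """Uniformly positive program scores give the maximal rank sum and
        the exact sign-enumeration p-value 2/2^8."""
        from cytovax.stats import wilcoxon_signed_rank

        res = wilcoxon_signed_rank([0.3] * 8)
        assert res.w == 8 * 9 / 2
        assert res.p_two_sided == pytest.approx(2 / 256, abs=0)
        # through program_inference, scores with spread behave identically
        rng = np.random.default_rng(1)
        pos = 0.3 + 0.01 * rng.random(8)
        scores = self._two_program_scores(list(pos), [0.1, -0.2, 0.4, -0.1,
                                                      0.2, -0.3, 0.5, -0.4])
        asn = pg.ProgramAssignment(labels={"X": 1, "Y": 2},
                                   linkage=np.zeros((1, 4)), threshold=0.75)
        stats = pg.program_inference(scores, asn)
        assert stats[0].wilcoxon.w == 36.0
        assert stats[0].p == pytest.approx(2 / 256)
        assert stats[0].q >= stats[0].p

    def test_small_sample_refused(self):
        scores = self._two_program_scores([0.1] * 4, [0.2] * 4)
        asn = pg.ProgramAssignment(labels={"X": 1, "Y": 2},
                                   linkage=np.zeros((1, 4)), threshold=0.75)
        with pytest.raises(SmallSampleError):
            pg.program_inference(scores, asn)

    def test_zero_sd_program_errors(self):
        scores = self._two_program_scores([0.0] * 8, [0.1, 0.2, 0.3, 0.4,
                                                      0.5, 0.6, 0.7, 0.8])
        asn = pg.ProgramAssignment(labels={"X": 1, "Y": 2},
                                   linkage=np.zeros((1, 4)), threshold=0.75)
        with pytest.raises(DegenerateInputError):
            pg.program_inference(scores, asn)

    def test_bh_family_adjustment(self):
        rng = np.random.default_rng(21)
        scores = pd.DataFrame(
            {
                "program_1": rng.normal(0.5, 0.3, 12),
                "program_2": rng.normal(0.0, 0.3, 12),
                "program_3": rng.normal(0.0, 0.3, 12),
            },
            index=[f"P{i}" for i in range(12)],
        )
        asn = pg.ProgramAssignment(
            labels={"X": 1, "Y": 2, "Z": 3}, linkage=np.zeros((2, 4)), threshold=0.75
        )
        stats = pg.program_inference(scores, asn)
        assert all(s.q >= s.p for s in stats)


class TestResponders:
    def test_abstract_proportion(self):
        # 14 of 35 patients above the 1.5-fold threshold
        scores = {f"P{i:02d}": (0.3 if i < 14 else 0.0) for i in range(35)}
        cls = pg.classify_responders(scores, fold_threshold=1.5)
        assert (cls.k, cls.n) == (14, 35)
        assert cls.ci.as_percent(1) == (40.0, 23.9, 57.9)

    def test_all_zero_scores(self):
        cls = pg.classify_responders({f"P{i}": 0.0 for i in range(10)})
        assert cls.k == 0
        assert cls.ci.lower == 0.0

    def test_table_fold_cut_retains_all_ten(self):
        printed = [12.6, 9.0, 4.8, 2.5, 2.3, 2.3, 2.2, 1.8, 1.8, 1.7]
        scores = {f"P{i:02d}": np.log10(fc) for i, fc in enumerate(printed + [1.6])}
        top = pg.top_induced(scores, fold_threshold=1.7)
        assert len(top) == 10
        assert top["fold_change"].iloc[0] == pytest.approx(12.6)

    def test_empty_scores_error(self):
        with pytest.raises(DegenerateInputError):
            pg.classify_responders({})


class TestPlantedRecovery:
    def test_point_estimate_partition_recovery(self):
        """With within-block correlation 0.8 and cross 0, the UPGMA cut at
        0.75 recovers the planted two-block partition in >= 95% of seeds."""
        hits = 0
        n_seeds = 100
        for seed in range(n_seeds):
            ds = generate_cohort(
                n_vaccinated=35, n_unvaccinated=0, plant=TWO_BLOCK_PLANT,
                seed=seed, panel=TEN_PANEL, n_serum_subcohort=35,
                n_baseline_irae_exclusions=0,
            )
            sel = select_cytokine_subcohort(ds)
            fc = pg.build_fold_change_matrix(ds, sel)
            _, dist, _ = pg.correlation_matrix(fc)
            asn = pg.upgma_flat_clusters(dist, 0.75)
            block_labels = [
                {asn.labels[c] for c in block} for block in TWO_BLOCK_PLANT.blocks
            ]
            if (
                all(len(s) == 1 for s in block_labels)
                and block_labels[0] != block_labels[1]
                and asn.n_programs == 2
            ):
                hits += 1
        assert hits >= 0.95 * n_seeds

    def test_planted_mean_fold_change(self):
        """responder_fraction 1 and response mean 1 give geometric-mean
        block fold change near 10 (Monte-Carlo tolerance)."""
        plant = ProgramPlantSpec(
            blocks=(("IL-6", "CXCL8"),),
            within_block_correlation=0.8,
            cross_block_correlation=0.0,
            response_log10_mean=(1.0,),
            response_log10_sd=(0.3,),
            responder_fraction=(1.0,),
        )
        ds = generate_cohort(
            n_vaccinated=60, n_unvaccinated=0, plant=plant, seed=4,
            panel=["IL-6", "CXCL8"], n_serum_subcohort=60,
            n_baseline_irae_exclusions=0,
        )
        sel = select_cytokine_subcohort(ds)
        fc = pg.build_fold_change_matrix(ds, sel)
        asn = pg.ProgramAssignment(labels={"IL-6": 1, "CXCL8": 1},
                                   linkage=np.zeros((1, 4)), threshold=0.75)
        scores = pg.program_scores(fc, asn)
        mean_score = scores["program_1"].mean()
        assert 10 ** mean_score == pytest.approx(10.0, rel=0.25)
        assert mean_score == pytest.approx(1.0, abs=0.1)
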