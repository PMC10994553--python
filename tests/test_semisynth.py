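import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pathblend import (
    OutcomeVector,
    SyntheticBaseConfig,
    cv_auroc,
    downsample_experiment,
    evaluate_detection,
    fisher_combine_conditional,
    generate_base,
    make_realisation,
    mwu_test,
    nested_lv_selection,
    univariate_experiment,
)


class TestGenerator:
    def test_same_seed_bit_identical(self):
        cfg = SyntheticBaseConfig(n_samples=40, n_pathways=10, seed=3)
        b1, y1, p1 = generate_base(cfg)
        b2, y2, p2 = generate_base(cfg)
        for a, b in zip(b1, b2):
            np.testing.assert_array_equal(a.values, b.values)
        assert (y1.values == y2.values).all()
        assert p1.ids == p2.ids

    def test_outcome_balanced_and_independent_of_data(self, synthetic_base):
        _, y, _ = synthetic_base
        counts = y.values.value_counts()
        assert abs(counts.iloc[0] - counts.iloc[1]) <= 1

    def test_zero_correlation_gives_near_independent_features(self):
        cfg = SyntheticBaseConfig(
            n_samples=500, n_pathways=20, within_correlation=0.0,
            overlap_fraction=0.0, seed=11,
        )
        blocks, _, pathways = generate_base(cfg)
        bound = 3 / np.sqrt(500)
        for p in list(pathways)[:5]:
            cols = [f for f in blocks[0].feature_ids if f in p.members]
            if len(cols) < 2:
                continue
            C = np.corrcoef(blocks[0].data[cols].to_numpy().T)
            off = C[np.triu_indices_from(C, 1)]
            assert np.abs(off).mean() < bound

    def test_requested_within_pathway_correlation(self):
        cfg = SyntheticBaseConfig(
            n_samples=500, n_pathways=30, within_correlation=0.7,
            overlap_fraction=0.0, seed=12,
        )
        blocks, _, pathways = generate_base(cfg)
        vals = []
        for p in pathways:
            for b in blocks:
                cols = [f for f in b.feature_ids if f in p.members]
                if len(cols) < 2:
                    continue
                C = np.corrcoef(b.data[cols].to_numpy().T)
                vals.extend(C[np.triu_indices_from(C, 1)])
        assert 0.6 <= float(np.mean(vals)) <= 0.8

    def test_pathways_written_as_valid_gmt(self, synthetic_base, tmp_path):
        from pathblend import read_gmt, write_gmt

        _, _, pathways = synthetic_base
        f = tmp_path / "p.gmt"
        write_gmt(pathways, f)
        assert read_gmt(f).ids == pathways.ids


class TestRealisation:
    def test_zero_effect_leaves_data_identical(self, synthetic_base):
        blocks, y, pathways = synthetic_base
        real = make_realisation(blocks, y, pathways, pathways.ids[0], 0.0, seed=1)
        for a, b in zip(real.blocks, blocks):
            np.testing.assert_array_equal(a.values, b.values)
        # labels are shuffled but class sizes preserved
        assert sorted(real.y.values.value_counts()) == sorted(
            y.values.value_counts()
        )

    def test_spike_is_exactly_alpha_on_cases_only(self, synthetic_base):
        blocks, y, pathways = synthetic_base
        target = pathways.ids[3]
        alpha = 0.5
        real = make_realisation(blocks, y, pathways, target, alpha, seed=2)
        case = (real.y.values == real.case_level).to_numpy()
        members = pathways[target].members
        n_changed = 0
        for a, b in zip(real.blocks, blocks):
            diff = a.values - b.values
            member_cols = [f in members for f in b.feature_ids]
            np.testing.assert_array_equal(diff[:, ~np.array(member_cols)], 0.0)
            sub = diff[:, np.array(member_cols)]
            np.testing.assert_array_equal(sub[~case], 0.0)
            np.testing.assert_allclose(sub[case], alpha, atol=1e-12)
            n_changed += sub[case].size
        assert n_changed == case.sum() * len(
            members & (set(blocks[0].feature_ids) | set(blocks[1].feature_ids))
        )

    def test_low_coverage_target_rejected(self, synthetic_base):
        from pathblend import PathwayCollection, PathwayDef

        blocks, y, pathways = synthetic_base
        thin = PathwayCollection(
            pathways=[PathwayDef("thin", "t", frozenset([blocks[0].feature_ids[0]]))]
        )
        with pytest.raises(ValueError, match="covered"):
            make_realisation(blocks, y, thin, "thin", 1.0)


class TestMwu:
    def test_identical_groups_give_midpoint_u(self):
        u, p = mwu_test([1, 2, 3, 4], [1, 2, 3, 4])
        assert u == 8.0  # n1*n2/2
        assert p > 0.9

    def test_separated_groups_exact_enumeration(self):
        u, p = mwu_test([1, 2, 3], [4, 5, 6])
        assert u in (0.0, 9.0)
        assert p == pytest.approx(0.1)  # 2/20 arrangements as extreme

    def test_swap_symmetric(self, rng):
        a, b = rng.standard_normal(10), rng.standard_normal(12)
        _, p1 = mwu_test(a, b)
        _, p2 = mwu_test(b, a)
        assert p1 == pytest.approx(p2)


class TestFisherConditional:
    def test_no_significant_members_sets_one(self):
        assert fisher_combine_conditional([0.5, 0.6, 0.7]) == 1.0

    def test_all_significant_chi_square_oracle(self):
        p = fisher_combine_conditional([0.01, 0.01])
        stat = -2 * (np.log(0.01) + np.log(0.01))
        assert stat == pytest.approx(18.4207, abs=1e-3)
        assert p == pytest.approx(stats.chi2.sf(stat, df=4))
        assert p == pytest.approx(1.0e-3, rel=0.05)

    def test_half_significant_boundary_is_inclusive(self):
        p = fisher_combine_conditional([0.01, 0.9])  # exactly 50%
        assert p < 1.0

    def test_empty_and_zero_inputs(self):
        with pytest.raises(ValueError, match="empty"):
            fisher_combine_conditional([])
        with pytest.warns(UserWarning, match="clamped"):
            p = fisher_combine_conditional([0.0, 0.01])
        assert 0 <= p < 1


class TestDetection:
    def test_perfect_and_inverted_rankings(self):
        p = pd.Series([0.0] + [1.0] * 9,
                      index=[f"P{i}" for i in range(10)])
        out = evaluate_detection(p, "P0")
        assert (out.tp, out.fp, out.fn, out.tn) == (1, 0, 0, 9)
        assert out.auc == 1.0
        inv = pd.Series([1.0] + [0.0] * 9, index=p.index)
        out2 = evaluate_detection(inv, "P0")
        assert (out2.tp, out2.fp, out2.fn, out2.tn) == (0, 9, 1, 0)
        assert out2.auc == 0.0

    def test_counts_partition_all_pathways(self, rng):
        p = pd.Series(rng.random(30), index=[f"P{i}" for i in range(30)])
        out = evaluate_detection(p, "P7")
        assert out.tp + out.fn == 1
        assert out.tp + out.fp + out.tn + out.fn == 30

    def test_random_pvalues_auc_centred_at_half(self):
        rng = np.random.default_rng(5)
        aucs = [
            evaluate_detection(
                pd.Series(rng.random(50), index=[f"P{i}" for i in range(50)]),
                "P0",
            ).auc
            for _ in range(1000)
        ]
        assert abs(np.mean(aucs) - 0.5) < 0.03


class TestPipelines:
    @pytest.fixture(scope="class")
    @staticmethod
    def small_base():
        cfg = SyntheticBaseConfig(
            n_samples=80, n_pathways=20, seed=77,
        )
        return generate_base(cfg)

    def test_cv_auroc_null_near_half(self, small_base):
        blocks, y, pathways = small_base
        real = make_realisation(blocks, y, pathways, pathways.ids[0], 0.0, seed=4)
        mean, _, _ = cv_auroc(
            real.blocks, real.y, pathways, R=1, n_repeats=2, seed=0
        )
        assert 0.4 <= mean <= 0.6

    def test_separable_outcome_gives_auc_one(self, small_base):
        from pathblend import (
            apply_standardizer,
            filter_coverage,
            fit_sspa,
            fit_standardizer,
            transform_sspa,
        )

        blocks, y, pathways = small_base
        b0 = blocks[0]
        std = fit_standardizer(b0)
        bs = apply_standardizer(std, b0)
        filt, _ = filter_coverage(pathways, set(b0.feature_ids), 2)
        t = fit_sspa(bs, filt)
        A = transform_sspa(t, bs)
        y_sep = OutcomeVector(
            values=pd.Series(
                (A.scores.iloc[:, 0] > A.scores.iloc[:, 0].median()).astype(int),
                index=b0.sample_ids,
            )
        )
        from pathblend import PathwayCollection

        defining = PathwayCollection(pathways=[pathways[A.pathway_ids[0]]])
        mean, _, _ = cv_auroc(blocks, y_sep, defining, R=1, n_repeats=1, seed=0)
        assert mean == pytest.approx(1.0)

    def test_power_monotone_in_effect_size(self, small_base):
        blocks, y, pathways = small_base
        table = univariate_experiment(
            blocks, y, pathways, [0.0, 1.5], level="pathway",
            n_real=20, seed=6, sspa_method="svd",
        )
        prop = table.set_index("effect_size")["proportion_significant"]
        assert prop.loc[1.5] >= prop.loc[0.0]
        assert prop.loc[0.0] <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / 20)

    def test_molecular_level_runs_and_is_calibrated_at_null(self, small_base):
        blocks, y, pathways = small_base
        table = univariate_experiment(
            blocks, y, pathways, [0.0], level="molecular", n_real=20, seed=8
        )
        assert table["proportion_significant"].iloc[0] <= 0.05 + 3 * np.sqrt(
            0.05 * 0.95 / 20
        )

    def test_nested_selection_grid_of_one(self, small_base):
        blocks, y, pathways = small_base
        real = make_realisation(blocks, y, pathways, pathways.ids[1], 1.0, seed=9)
        R_sel, curve = nested_lv_selection(
            real.blocks, real.y, pathways, R_grid=(2,), seed=0
        )
        assert R_sel == 2
        assert list(curve["R"]) == [2]

    def test_downsample_ratio_and_full_size_consistency(self, small_base):
        blocks, y, pathways = small_base
        n = len(y.sample_ids)
        table = downsample_experiment(
            blocks, y, pathways, sizes=[40, n], seed=10,
            R=1, n_repeats=1, n_folds=5,
        )
        assert (table["size"] % 2 == 0).all()
        full_row = table[table["size"] == n].iloc[0]
        mean, _, _ = cv_auroc(
            blocks, y, pathways, R=1, n_repeats=1, n_folds=5, seed=10
        )
        assert full_row["mean_auc"] == pytest.approx(mean, abs=1e-12)
        with pytest.raises(ValueError, match="n_folds"):
            downsample_experiment(
                blocks, y, pathways, sizes=[6], seed=0, R=1, n_folds=5
            )
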