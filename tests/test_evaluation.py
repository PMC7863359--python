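"""Concordance index against independent oracles; splits; baselines;
experiment report integrity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import sigsurvnet as ssn
from sigsurvnet.evaluation import restrict_to_pathways

finite_floats = st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False)


def survival_vectors(min_size=3, max_size=30):
    return st.integers(min_size, max_size).flatmap(
        lambda n: st.tuples(arrays(float, n, elements=st.integers(0, 10).map(float)),
                            arrays(float, n, elements=finite_floats)))


def brute_force_cindex(t, p, tied_truth="exclude"):
    """Independent O(n^2) pair enumerator (pure Python)."""
    C = D = T = 0
    n = len(t)
    for i in range(n):
        for j in range(i + 1, n):
            if t[i] == t[j]:
                if tied_truth == "count":
                    T += 1
                continue
            hi, lo = (i, j) if t[i] > t[j] else (j, i)
            if p[hi] > p[lo]:
                C += 1
            elif p[hi] < p[lo]:
                D += 1
            else:
                T += 1
    return C, D, T, (C + 0.5 * T) / (C + D + T)


class TestConcordanceIndex:
    def test_perfect_concordance(self):
        r = ssn.concordance_index([1, 2, 3], [10, 20, 30])
        assert (r.concordant, r.discordant, r.tied, r.value) == (3, 0, 0, 1.0)

    def test_all_tied_predictions_get_half_credit(self):
        r = ssn.concordance_index([1, 2, 3], [5, 5, 5])
        assert (r.concordant, r.discordant, r.tied) == (0, 0, 3)
        assert r.value == 0.5

    def test_matches_brute_force_on_100_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(2, 51))
            t = rng.integers(0, 20, n).astype(float)  # many ties
            p = np.round(rng.normal(size=n), 1)
            if np.ptp(t) == 0:
                continue
            r = ssn.concordance_index(t, p)
            C, D, T, v = brute_force_cindex(t, p)
            assert (r.concordant, r.discordant, r.tied) == (C, D, T)
            assert abs(r.value - v) <= 1e-12

    def test_matches_lifelines_on_event_only_data(self):
        from lifelines.utils import concordance_index as ll_cindex
        rng = np.random.default_rng(7)
        t = rng.uniform(1, 3000, 80)
        p = t + rng.normal(0, 500, 80)
        assert ssn.concordance_index(t, p).value == pytest.approx(
            ll_cindex(t, p), abs=1e-12)

    def test_antisymmetry_under_prediction_negation(self):
        rng = np.random.default_rng(1)
        t, p = rng.uniform(0, 1, 30), rng.uniform(0, 1, 30)
        v = ssn.concordance_index(t, p).value
        assert ssn.concordance_index(t, -p).value == pytest.approx(1 - v, abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(2)
        t, p = rng.uniform(0, 1, 40), rng.uniform(0, 1, 40)
        base = ssn.concordance_index(t, p)
        for f in (np.exp, lambda x: 3 * x - 7, np.cbrt):
            r = ssn.concordance_index(t, f(p))
            assert (r.concordant, r.discordant, r.tied) == (
                base.concordant, base.discordant, base.tied)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(survival_vectors())
    def test_property_value_in_unit_interval_and_matches_oracle(self, tp):
        t, p = tp
        if np.ptp(t) == 0:
            return
        r = ssn.concordance_index(t, p)
        C, D, T, v = brute_force_cindex(t, p)
        assert (r.concordant, r.discordant, r.tied) == (C, D, T)
        assert 0.0 <= r.value <= 1.0
        assert abs(r.value - v) <= 1e-12

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(survival_vectors(),
           st.sampled_from([0.25, 0.5, 1.0, 2.0, 4.0]),
           st.integers(-100, 100))
    def test_property_affine_prediction_invariance(self, tp, scale, shift):
        # dyadic predictions and power-of-two scales keep the transform exact
        # in floating point, so order (and hence every pair count) is intact
        t, p = tp
        if np.ptp(t) == 0:
            return
        p = np.round(p * 8) / 8
        base = ssn.concordance_index(t, p)
        moved = ssn.concordance_index(t, scale * p + float(shift))
        assert moved.value == pytest.approx(base.value, abs=1e-12)

    def test_all_equal_truth_is_undefined(self):
        with pytest.raises(ValueError, match="no evaluable pairs"):
            ssn.concordance_index([5, 5, 5], [1, 2, 3])

    def test_alternative_reading_counts_tied_truths(self):
        r = ssn.concordance_index([1, 1, 2], [3, 4, 5], tied_truth="count")
        C, D, T, v = brute_force_cindex([1, 1, 2], [3, 4, 5], tied_truth="count")
        assert (r.concordant, r.discordant, r.tied) == (C, D, T)
        assert r.value == pytest.approx(v)

    def test_counts_partition_evaluated_pairs(self):
        rng = np.random.default_rng(3)
        t = rng.integers(0, 10, 25).astype(float)
        p = rng.integers(0, 5, 25).astype(float)
        r = ssn.concordance_index(t, p)
        n_distinct = sum(1 for i in range(25) for j in range(i + 1, 25) if t[i] != t[j])
        assert r.n_pairs == n_distinct


class TestSplitSamples:
    def test_sizes_disjoint_and_complete(self):
        tr, te = ssn.split_samples(10, 0.8, seed=0)
        assert len(tr) == 8 and len(te) == 2
        assert set(tr) | set(te) == set(range(10))
        assert not set(tr) & set(te)

    def test_reproducible_for_fixed_seed(self):
        assert np.array_equal(ssn.split_samples(50, 0.7, 9)[0],
                              ssn.split_samples(50, 0.7, 9)[0])

    def test_membership_frequency_uniform_over_seeds(self):
        counts = np.zeros(100)
        for seed in range(1000):
            tr, _ = ssn.split_samples(100, 0.8, seed)
            counts[tr] += 1
        freq = counts / 1000
        assert freq.min() >= 0.75 and freq.max() <= 0.85

    @pytest.mark.parametrize("n,frac", [(10, 0.01), (10, 0.999), (1, 0.5)])
    def test_degenerate_partitions_rejected(self, n, frac):
        with pytest.raises(ValueError):
            ssn.split_samples(n, frac, 0)


class TestTreeBaseline:
    def test_seeded_runs_identical(self, small_cohort, small_split):
        a = ssn.tree_baseline(small_cohort["data"], small_split, seed=4)
        b = ssn.tree_baseline(small_cohort["data"], small_split, seed=4)
        assert a[0].value == b[0].value and a[1].value == b[1].value

    def test_beats_chance_on_separable_signal(self, small_cohort, small_split):
        tr, te = ssn.tree_baseline(small_cohort["data"], small_split, seed=4)
        assert te.value > 0.5

    def test_overfits_train_relative_to_test(self, small_cohort, small_split):
        tr, te = ssn.tree_baseline(small_cohort["data"], small_split, seed=4)
        assert tr.value > te.value

    def test_degenerate_targets_rejected(self, small_cohort):
        base = small_cohort["data"].subset_samples(range(20))
        clinical = base.clinical.copy()
        clinical["survival_days"] = 1000
        data = ssn.OmicsDataset(expression=base.expression,
                                copy_number=base.copy_number,
                                clinical=clinical,
                                survival_days=clinical["survival_days"])
        with pytest.raises(ValueError, match="degenerate"):
            ssn.tree_baseline(data, (np.arange(10), np.arange(10, 20)))


@pytest.fixture(scope="module")
def tiny_report(small_cohort):
    return ssn.ratio_sweep_experiment(
        small_cohort["data"], small_cohort["mask"],
        ratios=(0.8,), reps=2, epochs=2, seed=77,
        model_kwargs={"dense_units": 8})


class TestExperiments:
    def test_means_equal_row_averages(self, tiny_report):
        recs = tiny_report.records
        means = tiny_report.means()
        for method in recs["method"].unique():
            sub = recs[recs["method"] == method]
            row = means[(means["method"] == method) & (means["cell"] == 0.8)]
            assert row["test_cindex"].iloc[0] == pytest.approx(sub["test_cindex"].mean())

    def test_master_seed_reproducible(self, small_cohort, tiny_report):
        again = ssn.ratio_sweep_experiment(
            small_cohort["data"], small_cohort["mask"],
            ratios=(0.8,), reps=2, epochs=2, seed=77,
            model_kwargs={"dense_units": 8})
        pd.testing.assert_frame_equal(again.records, tiny_report.records)

    def test_report_round_trips_to_files(self, tiny_report, tmp_path):
        tiny_report.to_files(tmp_path / "r.tsv", tmp_path / "s.json")
        back = pd.read_csv(tmp_path / "r.tsv", sep="\t")
        assert len(back) == len(tiny_report.records)

    def test_restrict_to_pathways_keeps_member_genes_only(self, small_cohort):
        data, mask = small_cohort["data"], small_cohort["mask"]
        sub_data, sub_mask = restrict_to_pathways(data, mask, [0, 3])
        assert sub_mask.pathway_index == (mask.pathway_index[0], mask.pathway_index[3])
        assert (sub_mask.matrix.sum(axis=1) > 0).all()
        expected = {mask.gene_index[g]
                    for g in np.flatnonzero(mask.matrix[:, [0, 3]].sum(axis=1))}
        assert set(sub_mask.gene_index) == expected
        assert list(sub_data.expression.columns) == list(sub_mask.gene_index)

    def test_subset_equal_to_all_pathways_is_plain_training(self, small_cohort):
        data, mask = small_cohort["data"], small_cohort["mask"]
        sub_data, sub_mask = restrict_to_pathways(data, mask, range(mask.n_pathways))
        assert sub_mask.gene_index == mask.gene_index
        pd.testing.assert_frame_equal(sub_data.expression, data.expression)
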