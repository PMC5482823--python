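import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bodymap.core import ExpressionMatrix, SampleMetadata
from bodymap.differential import (
    benjamini_hochberg,
    deg_count_matrix,
    pairwise_deg,
    sex_dominated,
    tissue_specific,
)
from bodymap.landscape import LogMatrix, make_log_matrix
from conftest import oracle_bh, oracle_welch_p


def _meta_ab(n_a=4, n_b=4):
    ids = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
    return SampleMetadata(
        pd.DataFrame(
            {
                "tissue": ["A"] * n_a + ["B"] * n_b,
                "sex": (["female", "male"] * (n_a + n_b))[: n_a + n_b],
                "individual": ["m1"] * (n_a + n_b),
                "sexual_tissue": [False] * (n_a + n_b),
            },
            index=pd.Index(ids, name="sample_id"),
        )
    )


def _logm(arr, samples):
    return LogMatrix(
        pd.DataFrame(
            arr, index=pd.Index([f"g{i}" for i in range(len(arr))], name="gene_id"),
            columns=samples,
        ),
        (),
        1.0,
    )


class TestBenjaminiHochberg:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 200))
            np.testing.assert_array_equal(benjamini_hochberg(p), oracle_bh(p))

    def test_q_in_unit_interval_and_bounded_below_by_p(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(0, 1, 500)
        q = benjamini_hochberg(p)
        assert ((q >= p - 1e-15) & (q <= 1.0)).all()

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=0.0, max_value=1.0, allow_nan=False),
            min_size=1,
            max_size=60,
        )
    )
    def test_oracle_property(self, ps):
        p = np.array(ps)
        np.testing.assert_allclose(benjamini_hochberg(p), oracle_bh(p), atol=0)


class TestPairwiseDeg:
    def test_identical_groups_no_calls(self):
        meta = _meta_ab()
        rng = np.random.default_rng(0)
        block = rng.normal(3, 1, (50, 4))
        logm = _logm(np.hstack([block, block]), meta.sample_ids)
        deg = pairwise_deg(logm, meta, "A", "B")
        assert (deg.table["call"] == "none").all()
        assert (deg.table["p_value"] == 1.0).all()  # zero diff, both groups equal

    def test_welch_p_matches_oracle(self):
        meta = _meta_ab()
        rng = np.random.default_rng(21)
        arr = rng.normal(4, 1.5, (1000, 8))
        logm = _logm(arr, meta.sample_ids)
        deg = pairwise_deg(logm, meta, "A", "B")
        for i in range(0, 1000, 7):
            expected = oracle_welch_p(arr[i, :4], arr[i, 4:])
            assert deg.table["p_value"].iloc[i] == pytest.approx(expected, abs=1e-10)

    def test_bh_family_is_the_pair(self):
        meta = _meta_ab()
        rng = np.random.default_rng(3)
        arr = rng.normal(4, 1, (300, 8))
        logm = _logm(arr, meta.sample_ids)
        deg = pairwise_deg(logm, meta, "A", "B")
        np.testing.assert_array_equal(
            deg.table["q_value"].to_numpy(),
            oracle_bh(deg.table["p_value"].to_numpy()),
        )

    def test_too_few_samples_errors(self):
        meta = _meta_ab(1, 4)
        logm = _logm(np.ones((5, 5)), meta.sample_ids)
        with pytest.raises(ValueError, match="need >= 2"):
            pairwise_deg(logm, meta, "A", "B")

    def test_null_simulation_fdr_controlled(self):
        # global null: every rejection is a false discovery, so mean FDP
        # over seeds is the fraction of seeds with >= 1 call
        meta = _meta_ab()
        fdp = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            arr = rng.normal(5, 1, (2000, 8))
            logm = _logm(arr, meta.sample_ids)
            deg = pairwise_deg(logm, meta, "A", "B", alpha=0.05, fc=2.0)
            fdp.append(float((deg.table["call"] != "none").any()))
        assert np.mean(fdp) <= 0.075


class TestDegCountMatrix:
    def test_two_tissue_antisymmetry(self):
        meta = _meta_ab()
        rng = np.random.default_rng(4)
        arr = rng.normal(4, 1, (200, 8))
        arr[:30, :4] += 4.0
        logm = _logm(arr, meta.sample_ids)
        counts = deg_count_matrix(logm, meta)
        deg = pairwise_deg(logm, meta, "A", "B")
        assert counts.loc["A", "B"] == len(deg.up_in_a)
        assert counts.loc["B", "A"] == len(deg.down_in_a)

    def test_identical_tissues_all_zero(self):
        meta = _meta_ab()
        block = np.tile(np.arange(20, dtype=float)[:, None], (1, 8))
        block += np.random.default_rng(0).normal(0, 0.01, block.shape)
        logm = _logm(np.abs(block), meta.sample_ids)
        counts = deg_count_matrix(logm, meta)
        assert (counts.to_numpy() == 0).all()

    def test_planted_recovery(self):
        meta = _meta_ab()
        rng = np.random.default_rng(33)
        base = rng.normal(4, 1, 2000)
        arr = base[:, None] + rng.normal(0, 0.25, (2000, 8))
        arr[:50, :4] += 3.0  # 8-fold up in A
        logm = _logm(arr, meta.sample_ids)
        counts = deg_count_matrix(logm, meta)
        assert 45 <= counts.loc["A", "B"] <= 55

    def test_full_matrix_antisymmetric_on_synthetic(self, sim_dataset):
        _, (matrix, _, meta, _) = sim_dataset
        # restrict to 4 tissues to keep runtime low
        keep = [s for s in matrix.sample_ids
                if meta.tissue_of(s) in ("brain", "liver", "kidney", "testis")]
        sub_meta = meta.subset(keep)
        logm = make_log_matrix(matrix.subset_samples(keep))
        counts = deg_count_matrix(logm, sub_meta)
        for a in counts.index:
            for b in counts.columns:
                if a == b:
                    assert counts.loc[a, b] == 0
                else:
                    deg = pairwise_deg(logm, sub_meta, a, b)
                    assert counts.loc[a, b] == len(deg.up_in_a)
                    assert counts.loc[b, a] == len(deg.down_in_a)


class TestTissueSpecific:
    def _matrix(self, rows, meta):
        return ExpressionMatrix(
            pd.DataFrame(
                np.asarray(rows, dtype=float),
                index=pd.Index([f"g{i}" for i in range(len(rows))], name="gene_id"),
                columns=meta.sample_ids,
            )
        )

    def test_strong_gene_specific_at_all_thresholds(self):
        meta = _meta_ab(2, 2)
        mx = self._matrix([[100.0, 100.0, 1.0, 1.0]], meta)
        calls = tissue_specific(mx, meta)
        for f in (2, 4, 8, 16, 32):
            assert calls.calls_at(f) == {"g0": "A"}

    def test_flat_gene_never_called(self):
        meta = _meta_ab(2, 2)
        mx = self._matrix([[5.0, 5.0, 5.0, 5.0]], meta)
        calls = tissue_specific(mx, meta)
        for f in (2, 4, 8, 16, 32):
            assert calls.calls_at(f) == {}

    def test_near_silent_gene_excluded(self):
        meta = _meta_ab(2, 2)
        mx = self._matrix([[0.05, 0.05, 0.0, 0.0]], meta)
        calls = tissue_specific(mx, meta, expressed_threshold=0.1)
        assert calls.calls_at(2) == {}

    def test_nestedness_exact(self):
        from bodymap.synthetic import SimulationConfig, generate_dataset

        cfg = SimulationConfig(n_genes=1000, seed=17, frac_silent=0.1)
        matrix, _, meta, _ = generate_dataset(cfg)
        calls = tissue_specific(matrix, meta)
        sets = {f: set(calls.calls_at(f)) for f in (2, 4, 8, 16, 32)}
        assert sets[32] <= sets[16] <= sets[8] <= sets[4] <= sets[2]
        # brute-force recomputation of the 4-fold calls
        means = {
            t: matrix.values[meta.samples_of(t)].mean(axis=1) for t in meta.tissues
        }
        for g in matrix.gene_ids:
            best = None
            for t in meta.tissues:
                fold = min(
                    (means[t][g] + 0.01) / (means[o][g] + 0.01)
                    for o in meta.tissues
                    if o != t
                )
                if fold > 4 and means[t][g] >= 0.1:
                    best = t
            assert calls.calls_at(4).get(g) == best


class TestSexDominated:
    def test_fold_arithmetic(self):
        meta = _meta_ab(4, 4)
        mx = self._mx([[10.0, 4.0] * 4], meta)
        calls = sex_dominated(mx, meta, "A", fc=2.0)
        # female mean 10, male mean 4 -> fold (10.01)/(4.01) ~ 2.496 > 2
        assert calls.table.iloc[0]["fold_f_over_m"] == pytest.approx(10.01 / 4.01)
        assert "g0" in calls.female_dominated

    def _mx(self, rows, meta):
        return ExpressionMatrix(
            pd.DataFrame(
                np.asarray(rows, dtype=float),
                index=pd.Index([f"g{i}" for i in range(len(rows))], name="gene_id"),
                columns=meta.sample_ids,
            )
        )

    def test_equal_means_neither(self):
        meta = _meta_ab(4, 4)
        mx = self._mx([[3.0] * 8], meta)
        calls = sex_dominated(mx, meta, "A")
        assert calls.female_dominated == set() and calls.male_dominated == set()

    def test_sexual_tissue_rejected(self):
        tab = pd.DataFrame(
            {
                "tissue": ["testis"] * 2,
                "sex": ["male"] * 2,
                "individual": ["m1", "m2"],
                "sexual_tissue": [True] * 2,
            },
            index=pd.Index(["t1", "t2"], name="sample_id"),
        )
        meta = SampleMetadata(tab)
        mx = self._mx([[1.0, 1.0]], meta)
        with pytest.raises(ValueError, match="sexual tissue"):
            sex_dominated(mx, meta, "testis")

    def test_planted_recovery_and_disjointness(self):
        from bodymap.synthetic import SimulationConfig, generate_dataset

        cfg = SimulationConfig(
            n_genes=1000, seed=29, sex_fold=4.0, n_sex_dominated=6
        )
        matrix, _, meta, truth = generate_dataset(cfg)
        tp, total = 0, 0
        for tissue in meta.nonsexual_tissues():
            calls = sex_dominated(matrix, meta, tissue, fc=2.0)
            assert calls.female_dominated.isdisjoint(calls.male_dominated)
            sub = truth.table[
                (truth.table["class"] == "sex_dominated")
                & (truth.table["target_tissue"] == tissue)
            ]
            for g, row in sub.iterrows():
                total += 1
                hit = (
                    g in calls.female_dominated
                    if row["target_sex"] == "female"
                    else g in calls.male_dominated
                )
                tp += hit
        assert tp / total >= 0.9
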