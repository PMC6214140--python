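"""CPM normalization, sign-flip paired DE, BH FDR and 2^-ddCt."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from prdmscan.exceptions import (
    DomainInputError,
    NormalizationError,
    ValidationError,
)
from prdmscan.expression import (
    PairedCounts,
    bh_fdr,
    cpm_normalize,
    ddct,
    paired_de,
)


class TestCpm:
    def test_single_gene_unit_library(self):
        out = cpm_normalize(np.array([[10]]), pseudocount=0)
        assert out[0, 0] == pytest.approx(1e6)

    def test_scale_invariance_without_pseudocount(self):
        counts = np.array([[3, 6], [1, 2]])
        a = cpm_normalize(counts, pseudocount=0)
        b = cpm_normalize(counts * 2, pseudocount=0)
        assert np.allclose(a, b)

    def test_direct_arithmetic_with_pseudocount(self):
        out = cpm_normalize(np.array([[3], [1]]), pseudocount=0.5)
        assert out[:, 0] == pytest.approx([700000.0, 300000.0])

    def test_all_zero_column_names_sample(self):
        with pytest.raises(NormalizationError, match="S2"):
            cpm_normalize(np.array([[1, 0], [2, 0]]), sample_names=["S1", "S2"])


class TestBH:
    def test_single_p_passes_through(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_step_up_formula_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0, 1.0, 1.0])

    def test_rejects_out_of_range(self):
        for bad in ([0.0, 0.5], [0.5, 1.2], [np.nan]):
            with pytest.raises(ValidationError):
                bh_fdr(bad)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(1e-6, 1.0, allow_nan=False), min_size=1, max_size=30))
    def test_matches_step_up_oracle(self, p_list):
        def oracle(ps):
            m = len(ps)
            order = sorted(range(m), key=lambda i: ps[i])
            q = [0.0] * m
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, ps[i] * m / rank)
                q[i] = running
            return q

        assert bh_fdr(p_list) == pytest.approx(oracle(p_list))

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(1e-6, 1.0, allow_nan=False), min_size=2, max_size=15),
        st.data(),
    )
    def test_monotone_raising_a_p_never_lowers_any_q(self, p_list, data):
        idx = data.draw(st.integers(0, len(p_list) - 1))
        bumped = list(p_list)
        bumped[idx] = min(1.0, bumped[idx] * data.draw(st.floats(1.0, 5.0)))
        q0, q1 = bh_fdr(p_list), bh_fdr(bumped)
        assert (q1 >= q0 - 1e-12).all()


class TestDdct:
    @pytest.mark.parametrize(
        "cts, expected",
        [
            ((25, 20, 25, 20), 1.0),     # ddCt = 0
            ((24, 20, 25, 20), 2.0),     # one-cycle doubling
            ((25, 20, 22, 20), 0.125),   # ddCt = 3
        ],
    )
    def test_direct_arithmetic(self, cts, expected):
        assert ddct(*cts) == pytest.approx(expected)

    def test_nonfinite_ct_rejected(self):
        with pytest.raises(ValidationError):
            ddct(math.inf, 20, 25, 20)  # undetectable amplification


def _paired(tumor, normal, genes=None):
    tumor = np.atleast_2d(np.asarray(tumor))
    normal = np.atleast_2d(np.asarray(normal))
    genes = genes or tuple(f"G{i}" for i in range(tumor.shape[0]))
    pairs = tuple(f"P{i}" for i in range(tumor.shape[1]))
    return PairedCounts(genes, pairs, tumor, normal)


class TestPairedDE:
    def test_identical_tumor_normal_is_null(self, rng):
        counts = rng.poisson(100, size=(5, 6))
        de = paired_de(_paired(counts, counts), seed=0)
        assert np.allclose(de["logFC"], 0)
        assert (de["call"] == "NS").all()
        assert (de["zero_variance"]).all()
        assert np.allclose(de["p_value"], 1.0)

    def test_fewer_than_three_pairs_rejected(self, rng):
        counts = rng.poisson(100, size=(3, 2))
        with pytest.raises(DomainInputError):
            paired_de(_paired(counts, counts + 1))

    def test_exhaustive_enumeration_matches_brute_force_for_four_pairs(self, rng):
        tumor = rng.poisson(120, size=(6, 4))
        normal = rng.poisson(90, size=(6, 4))
        paired = _paired(tumor, normal)
        de = paired_de(paired, n_permutations=10_000, seed=1)

        # independent oracle: itertools over all 16 sign patterns
        cpm = lambda m: 1e6 * (m + 0.5) / (m.sum(axis=0) + m.shape[0] * 0.5)
        r = np.log2(cpm(tumor.astype(float)) / cpm(normal.astype(float)))
        n = 4
        for g in range(6):
            row = r[g]
            def tstat(x):
                return np.mean(x) / (np.std(x, ddof=1) / np.sqrt(n))
            t_obs = tstat(row)
            ts = [tstat(row * np.array(s)) for s in itertools.product([1, -1], repeat=n)]
            upper = np.mean([t >= t_obs for t in ts])
            lower = np.mean([t <= t_obs for t in ts])
            expected = min(1.0, 2 * min(upper, lower))
            assert de["p_value"][g] == pytest.approx(expected, abs=1e-12)

    def test_swapping_tumor_and_normal_negates_logfc(self, rng):
        tumor = rng.poisson(200, size=(8, 5))
        normal = rng.poisson(100, size=(8, 5))
        paired = _paired(tumor, normal)
        de = paired_de(paired, seed=2)
        de_swapped = paired_de(paired.swapped(), seed=2)
        assert np.allclose(de["logFC"], -de_swapped["logFC"])
        assert np.allclose(de["p_value"], de_swapped["p_value"])

    def test_calls_respect_thresholds(self, rng):
        # 14 pairs so the exhaustive sign-flip p can reach the FDR <= 0.01
        # threshold after BH across 31 genes (min two-sided p = 2/2^14)
        tumor = rng.poisson(100, size=(30, 14))
        normal = tumor.copy()
        tumor = np.vstack([tumor, rng.poisson(1600, size=(1, 14))])
        normal = np.vstack([normal, rng.poisson(100, size=(1, 14))])
        de = paired_de(_paired(tumor, normal), n_permutations=20_000, seed=3)
        strong = de.iloc[-1]
        assert strong["call"] == "UP"
        assert strong["logFC"] >= 1 and strong["fdr"] <= 0.01

    def test_pair_order_invariance(self, rng):
        tumor = rng.poisson(150, size=(5, 6))
        normal = rng.poisson(100, size=(5, 6))
        perm = rng.permutation(6)
        a = paired_de(_paired(tumor, normal), seed=4)
        b = paired_de(_paired(tumor[:, perm], normal[:, perm]), seed=4)
        assert np.allclose(a["p_value"], b["p_value"])
        assert np.allclose(a["logFC"], b["logFC"])


def test_paired_counts_validates_shape_and_sign():
    with pytest.raises(ValidationError):
        PairedCounts(("G1",), ("P1", "P2"), np.zeros((1, 1)), np.zeros((1, 2)))
    with pytest.raises(ValidationError):
        PairedCounts(("G1",), ("P1",), np.array([[-1]]), np.array([[1]]))
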