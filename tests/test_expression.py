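"""Normalization, dispersion, exact test, DEG calling, TPM, PCA."""
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from texpress.expression import (
    DEResult,
    call_degs,
    compute_tpm,
    corrected_cpm,
    estimate_common_dispersion,
    filter_low_expression,
    length_correct,
    nb_exact_test,
    pca_variance_explained,
    tmm_factors,
    _conditional_split_pvalue,
)
from texpress.models import OrthologPair


def _pairs_for(index, mean_len=1000):
    return [
        OrthologPair(g, g + "_b", mean_len, mean_len) for g in index
    ]


class TestLengthCorrect:
    def test_unit_scale(self):
        counts = pd.DataFrame({"s1": [100]}, index=["g1"])
        out = length_correct(counts, _pairs_for(["g1"], 1000))
        assert out.loc["g1", "s1"] == 100.0

    def test_half_scale(self):
        counts = pd.DataFrame({"s1": [100]}, index=["g1"])
        out = length_correct(counts, _pairs_for(["g1"], 2000))
        assert out.loc["g1", "s1"] == 50.0

    def test_zero_row(self):
        counts = pd.DataFrame({"s1": [0], "s2": [0]}, index=["g1"])
        out = length_correct(counts, _pairs_for(["g1"], 777))
        assert (out.values == 0).all()

    def test_linear(self, rng):
        counts = pd.DataFrame(
            rng.integers(0, 50, (20, 4)), index=[f"g{i}" for i in range(20)]
        )
        pairs = _pairs_for(counts.index, 1234)
        assert np.allclose(
            length_correct(counts * 2, pairs), length_correct(counts, pairs) * 2
        )

    def test_missing_pair_error(self):
        counts = pd.DataFrame({"s1": [1]}, index=["gX"])
        with pytest.raises(ValueError, match="gX"):
            length_correct(counts, [])


class TestFilter:
    def test_below_everywhere_dropped(self):
        corrected = pd.DataFrame(
            np.vstack([np.full(16, 0.5), np.full(16, 2e6)]),
            index=["low", "high"],
        )
        kept = filter_low_expression(corrected)
        assert kept == {"high"}

    def test_single_sample_above_keeps(self):
        x = np.full((2, 16), 1000.0)
        x[0] = 0.4
        x[0, 7] = 3000.0  # clears 1 CPM in that sample alone
        corrected = pd.DataFrame(x, index=["g1", "g2"])
        assert "g1" in filter_low_expression(corrected)

    def test_two_gene_toy(self):
        corrected = pd.DataFrame({"s1": [1.0, 999999.0]}, index=["g1", "g2"])
        cpm = corrected_cpm(corrected)
        assert cpm["s1"].tolist() == [1.0, 999999.0]
        assert filter_low_expression(corrected) == {"g1", "g2"}

    def test_cpm_columns_sum_to_million(self, rng):
        corrected = pd.DataFrame(rng.uniform(0.1, 10, (30, 5)))
        cpm = corrected_cpm(corrected)
        assert np.allclose(cpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_zero_column_error(self):
        corrected = pd.DataFrame({"s1": [0.0, 0.0]})
        with pytest.raises(ValueError):
            corrected_cpm(corrected)


class TestTMM:
    def test_identical_columns_unit(self, rng):
        col = rng.poisson(100, 500)
        mat = pd.DataFrame({"a": col, "b": col, "c": col})
        assert np.allclose(tmm_factors(mat), 1.0)

    def test_doubled_library_recovered(self, rng):
        base = rng.gamma(5, 20, 2000)
        a = rng.poisson(base)
        b = rng.poisson(2 * base)
        mat = pd.DataFrame({"a": a, "b": b, "c": rng.poisson(base)})
        f = tmm_factors(mat)
        assert f["b"] / f["a"] == pytest.approx(2.0, rel=0.01)

    def test_geometric_mean_is_one(self, rng):
        mat = pd.DataFrame(rng.poisson(50, (300, 4)))
        f = tmm_factors(mat)
        assert np.exp(np.log(f).mean()) == pytest.approx(1.0, abs=1e-12)

    def test_few_genes_unit_fallback(self):
        mat = pd.DataFrame(np.ones((3, 2)) * 5)
        f = tmm_factors(mat)
        assert np.allclose(f, 1.0)


class TestDispersion:
    GROUPS8 = {f"s{i}": ("A" if i < 4 else "B") for i in range(8)}

    def test_constant_counts_zero(self):
        mat = pd.DataFrame(
            np.full((10, 8), 33.0), columns=list(self.GROUPS8)
        )
        assert estimate_common_dispersion(mat, self.GROUPS8).phi == 0.0

    def test_poisson_small(self, rng):
        mat = pd.DataFrame(
            rng.poisson(100, (2000, 8)), columns=list(self.GROUPS8)
        )
        assert estimate_common_dispersion(mat, self.GROUPS8).phi <= 0.01

    def test_nb_phi_point_two(self, rng):
        r = 1 / 0.2
        lam = rng.gamma(r, 100 / r, size=(2000, 8))
        mat = pd.DataFrame(rng.poisson(lam), columns=list(self.GROUPS8))
        est = estimate_common_dispersion(mat, self.GROUPS8).phi
        assert 0.1 <= est <= 0.3

    def test_single_replicate_error(self):
        mat = pd.DataFrame(np.ones((5, 3)), columns=["s1", "s2", "s3"])
        with pytest.raises(ValueError):
            estimate_common_dispersion(
                mat, {"s1": "A", "s2": "A", "s3": "B"}
            )


class TestExactTest:
    def test_symmetric_mode_p_one(self):
        for phi in (0.0, 0.1, 0.5):
            assert nb_exact_test([5, 5], [5, 5], phi) == pytest.approx(1.0)

    def test_binomial_oracle_phi_zero(self):
        # totals (2, 18), equal libraries -> conditional binomial(20, 1/2)
        p = nb_exact_test([1, 1], [9, 9], 0.0)
        y = np.arange(21)
        pmf = stats.binom.pmf(y, 20, 0.5)
        want = pmf[pmf <= pmf[2] * (1 + 1e-7)].sum()
        assert p == pytest.approx(want, abs=1e-12)

    def test_enumeration_oracle_phi(self, rng):
        for _ in range(50):
            ta = int(rng.integers(0, 100))
            tb = int(rng.integers(0, 100))
            if ta + tb == 0:
                continue
            phi = 0.1
            t = ta + tb
            y = np.arange(t + 1)
            ra = rb = 2 / phi
            mu = t / 4
            pa = ra / (ra + 2 * mu)
            pmf = stats.nbinom.pmf(y, ra, pa) * stats.nbinom.pmf(t - y, rb, pa)
            pmf = pmf / pmf.sum()
            want = pmf[pmf <= pmf[ta] * (1 + 1e-7)].sum()
            got = _conditional_split_pvalue(ta, t, 2, 2, phi)
            assert got == pytest.approx(want, abs=1e-10)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            nb_exact_test([-1, 2], [3, 4], 0.1)

    def test_factor_adjustment(self):
        # doubling one library's factor halves its contribution
        p_eq = nb_exact_test([10, 10], [10, 10], 0.0, factors=[1, 1, 1, 1])
        assert p_eq == pytest.approx(1.0)


def _sim_counts(rng, n=300, mean=200.0, phi=0.05, lfc=0.0, deg_idx=()):
    cols = {}
    meta_rows = []
    for sp in ("A", "B"):
        for stage in ("L4", "YA"):
            for rep in range(1, 5):
                name = f"{sp}_{stage}_r{rep}"
                m = np.full(n, mean)
                if sp == "A" and len(deg_idx):
                    m[list(deg_idx)] *= 2.0 ** lfc
                if phi == 0:
                    cols[name] = rng.poisson(m)
                else:
                    r = 1 / phi
                    cols[name] = rng.poisson(rng.gamma(r, m / r))
                meta_rows.append((name, sp, stage, rep))
    counts = pd.DataFrame(cols, index=[f"g{i:04d}" for i in range(n)])
    meta = pd.DataFrame(
        [(sp, st, rep) for _, sp, st, rep in meta_rows],
        index=[name for name, *_ in meta_rows],
        columns=["species", "stage", "replicate"],
    )
    return counts, meta


class TestCallDegs:
    def test_null_no_calls(self, rng):
        counts, meta = _sim_counts(rng, n=400)
        pairs = _pairs_for(counts.index)
        res = call_degs(counts, meta, pairs, "L4")
        assert all(r.direction == "ns" for r in res)

    def test_planted_power(self, rng):
        deg_idx = range(40)
        counts, meta = _sim_counts(rng, n=400, lfc=2.0, deg_idx=deg_idx)
        pairs = _pairs_for(counts.index)
        res = {r.pair_id: r for r in call_degs(counts, meta, pairs, "L4")}
        hits = sum(
            res[f"g{i:04d}"].direction == "higher_in_A" for i in deg_idx
        )
        assert hits / len(list(deg_idx)) >= 0.7

    def test_direction_antisymmetry(self, rng):
        counts, meta = _sim_counts(rng, n=200, lfc=3.0, deg_idx=range(30))
        pairs = _pairs_for(counts.index)
        res1 = {r.pair_id: r for r in call_degs(counts, meta, pairs, "L4")}
        meta2 = meta.copy()
        meta2["species"] = meta2["species"].map({"A": "B", "B": "A"})
        res2 = {r.pair_id: r for r in call_degs(counts, meta2, pairs, "L4")}
        flip = {"higher_in_A": "higher_in_B", "higher_in_B": "higher_in_A", "ns": "ns"}
        for g in res1:
            assert res2[g].direction == flip[res1[g].direction]

    def test_permuted_labels_uniform_p(self, rng):
        counts, meta = _sim_counts(rng, n=1500, mean=300.0)
        # permute species labels within the stage
        meta2 = meta.copy()
        l4 = meta2.index[meta2["stage"] == "L4"]
        perm = rng.permutation(meta2.loc[l4, "species"].to_numpy())
        meta2.loc[l4, "species"] = perm
        if len(set(meta2.loc[l4, "species"])) < 2:
            pytest.skip("degenerate permutation")
        pairs = _pairs_for(counts.index)
        res = call_degs(counts, meta2, pairs, "L4")
        pvals = [r.p for r in res if not math.isnan(r.p)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_missing_stage_error(self, rng):
        counts, meta = _sim_counts(rng, n=20)
        with pytest.raises(ValueError):
            call_degs(counts, meta, _pairs_for(counts.index), "adult")

    def test_filtered_genes_appended_ns(self, rng):
        counts, meta = _sim_counts(rng, n=50)
        counts.iloc[0] = 0
        pairs = _pairs_for(counts.index)
        res = {r.pair_id: r for r in call_degs(counts, meta, pairs, "L4")}
        assert res["g0000"].direction == "ns"
        assert math.isnan(res["g0000"].p)
        assert len(res) == 50


class TestTPM:
    META = pd.DataFrame(
        {"species": ["A", "B"], "stage": ["L4", "L4"], "replicate": [1, 1]},
        index=["sA", "sB"],
    )

    def test_equal_rates(self):
        counts = pd.DataFrame({"sA": [100, 200], "sB": [100, 200]}, index=["g1", "g2"])
        pairs = [
            OrthologPair("g1", "b1", 1000, 1000),
            OrthologPair("g2", "b2", 2000, 2000),
        ]
        tpm = compute_tpm(counts, pairs, self.META)
        assert np.allclose(tpm["sA"], [500000, 500000])

    def test_single_gene(self):
        counts = pd.DataFrame({"sA": [7], "sB": [3]}, index=["g1"])
        pairs = [OrthologPair("g1", "b1", 500, 700)]
        tpm = compute_tpm(counts, pairs, self.META)
        assert np.allclose(tpm.values, 1e6)

    def test_columns_sum_to_million(self, rng):
        counts = pd.DataFrame(
            rng.integers(1, 500, (30, 2)), columns=["sA", "sB"],
            index=[f"g{i}" for i in range(30)],
        )
        pairs = [
            OrthologPair(f"g{i}", f"b{i}", int(rng.integers(200, 3000)), 500)
            for i in range(30)
        ]
        tpm = compute_tpm(counts, pairs, self.META)
        assert np.allclose(tpm.sum(axis=0), 1e6, rtol=1e-9)

    def test_species_specific_lengths_used(self):
        counts = pd.DataFrame({"sA": [10, 10], "sB": [10, 10]}, index=["g1", "g2"])
        pairs = [
            OrthologPair("g1", "b1", 100, 400),
            OrthologPair("g2", "b2", 100, 400),
        ]
        tpm = compute_tpm(counts, pairs, self.META)
        # within each sample rates are equal -> both 5e5 despite len_a != len_b
        assert np.allclose(tpm.values, 5e5)


class TestPCA:
    def test_rank_one(self):
        base = np.arange(10.0)
        mat = pd.DataFrame(
            {"s1": base, "s2": 2 * base, "s3": 3 * base}
        )
        fr, _ = pca_variance_explained(mat)
        assert fr[0] == pytest.approx(1.0)

    def test_two_sample_split(self):
        mat = pd.DataFrame({"s1": [1.0, 0.0], "s2": [0.0, 1.0]})
        fr, _ = pca_variance_explained(mat)
        assert fr[0] == pytest.approx(1.0)  # 2 samples, 1 centered dof

    def test_matches_eigsolver_oracle(self, rng):
        mat = pd.DataFrame(rng.normal(size=(40, 6)))
        fr, _ = pca_variance_explained(mat)
        x = mat.to_numpy() - mat.to_numpy().mean(axis=1, keepdims=True)
        evals = np.linalg.eigvalsh(x.T @ x)[::-1]
        want = evals[: len(fr)] / evals.sum()
        assert np.allclose(sorted(fr, reverse=True), want[want > -1e9][: len(fr)], atol=1e-10)

    def test_fractions_sum_to_one(self, rng):
        mat = pd.DataFrame(rng.normal(size=(30, 5)))
        fr, _ = pca_variance_explained(mat)
        assert fr.sum() == pytest.approx(1.0)

    def test_single_sample_error(self):
        with pytest.raises(ValueError):
            pca_variance_explained(pd.DataFrame({"s1": [1.0, 2.0]}))
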