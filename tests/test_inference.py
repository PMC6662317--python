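"""Permutation tests, one-sample t, Spearman, Moran's I, and the pipeline."""

import itertools
from math import comb

import numpy as np
import pytest
from scipy import stats

from traitdiv import (
    PipelineConfig,
    ScenarioConfig,
    ValidationError,
    generate_landscapes,
    morans_i,
    one_sample_t,
    permutation_t_test,
    run_pipeline,
    spearman,
)


def exhaustive_perm_p(x, y):
    """Enumerate every group relabeling; two-sided p on the mean difference."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    obs = abs(np.mean(x) - np.mean(y))
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        stat = abs(pooled[mask].mean() - pooled[~mask].mean())
        count += stat >= obs - 1e-12
        total += 1
    return count / total


class TestPermutationTTest:
    def test_identical_groups_give_p_one(self):
        r = permutation_t_test([3, 3, 3], [3, 3, 3])
        assert r.p_value == 1.0
        assert r.mean_diff == 0.0

    def test_complete_separation_exhaustive_p(self):
        r = permutation_t_test([1, 2, 3], [10, 11, 12])
        assert r.exhaustive
        assert r.p_value == pytest.approx(2 / comb(6, 3), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_exhaustive_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(0, 1, 4), rng.normal(0.8, 1, 4)
        r = permutation_t_test(x, y, n_iter=10_000)
        assert r.exhaustive
        assert r.p_value == pytest.approx(exhaustive_perm_p(x, y), abs=1e-12)

    def test_monte_carlo_within_binomial_error_of_exhaustive(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 8), rng.normal(1.0, 1, 8)  # C(16,8) = 12870
        p_ex = exhaustive_perm_p(x, y)
        n_iter = 5000
        r = permutation_t_test(x, y, n_iter=n_iter, seed=4)
        assert not r.exhaustive
        tol = 4 * np.sqrt(p_ex * (1 - p_ex) / n_iter) + 1 / n_iter
        assert abs(r.p_value - p_ex) < tol

    def test_symmetric_and_shift_invariant(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 5), rng.normal(1, 1, 5)
        a = permutation_t_test(x, y)
        b = permutation_t_test(y, x)
        c = permutation_t_test(x + 100.0, y + 100.0)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
        assert a.p_value == pytest.approx(c.p_value, abs=1e-12)
        assert a.mean_diff == pytest.approx(-b.mean_diff)


class TestOneSampleT:
    def test_symmetric_pair_gives_t_zero(self):
        t, p = one_sample_t([-1.0, 1.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_constant_vector_is_degenerate(self):
        t, p = one_sample_t([2.0] * 5)
        assert np.isnan(t) and np.isnan(p)

    def test_matches_reference_t_distribution(self):
        rng = np.random.default_rng(6)
        x = rng.normal(-1.0, 0.8, 12)
        t, p = one_sample_t(x)
        t_hand = x.mean() / (x.std(ddof=1) / np.sqrt(len(x)))
        p_hand = 2 * stats.t.sf(abs(t_hand), df=len(x) - 1)
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert p == pytest.approx(p_hand, abs=1e-12)


def midranks(v):
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        r = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = r
        i = j + 1
    return ranks


class TestSpearman:
    def test_monotone_relations(self):
        x = [1.0, 2.0, 5.0, 9.0]
        assert spearman(x, [2.0, 3.0, 8.0, 20.0])[0] == pytest.approx(1.0)
        assert spearman(x, [5.0, 4.0, 1.0, 0.0])[0] == pytest.approx(-1.0)

    def test_ties_use_midranks(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 4.0]
        y = [2.0, 1.0, 4.0, 4.0, 3.0, 5.0]
        rx, ry = np.array(midranks(x)), np.array(midranks(y))
        expected = np.corrcoef(rx, ry)[0, 1]
        assert spearman(x, y)[0] == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_undefined(self):
        rho, p = spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert np.isnan(rho) and np.isnan(p)


class TestMoransI:
    coords = np.array([[0, 0], [1, 2], [2, 1], [5, 4], [7, 0], [3, 6]], dtype=float)
    values = np.array([1.2, 3.4, 2.2, 5.1, 4.0, 0.5])

    def test_expectation_closed_form(self):
        rng = np.random.default_rng(0)
        res = morans_i(rng.normal(size=10), rng.random((10, 2)) * 10)
        assert res.expected == pytest.approx(-1 / 9)

    def test_matches_reference_implementation(self):
        # frozen from an independent inverse-distance row-normalized
        # computation on this exact fixture
        res = morans_i(self.values, self.coords)
        assert res.observed == pytest.approx(-0.2523034, abs=1e-6)
        assert res.sd == pytest.approx(0.105975, abs=1e-5)
        assert res.p_value == pytest.approx(0.6216279, abs=1e-5)

    def test_permuted_values_average_to_expectation(self):
        rng = np.random.default_rng(3)
        obs = []
        v = self.values.copy()
        for _ in range(400):
            rng.shuffle(v)
            obs.append(morans_i(v, self.coords).observed)
        assert np.mean(obs) == pytest.approx(-1 / 5, abs=0.03)

    def test_linear_gradient_is_positively_autocorrelated(self):
        x = np.arange(10, dtype=float)
        coords = np.column_stack([x, np.zeros(10)])
        res = morans_i(x, coords)
        assert res.observed > 0
        assert res.p_value < 0.05

    def test_coincident_sites_rejected(self):
        coords = np.array([[0, 0], [0, 0], [1, 1]], dtype=float)
        with pytest.raises(ValidationError, match="jitter"):
            morans_i([1.0, 2.0, 3.0], coords)


@pytest.fixture(scope="module")
def tiny_scenario():
    cfg = ScenarioConfig(
        n_species_pool=40,
        sites={"A": {"forest": 4, "agroforestry": 3}, "B": {"forest": 3, "agroforestry": 3}},
        richness_mean=12.0, richness_sd=2.0, seed=21,
    )
    return generate_landscapes(cfg)


class TestRunPipeline:
    def test_rerun_is_byte_identical(self, tiny_scenario, tmp_path):
        traits, comm, _ = tiny_scenario
        cfg = PipelineConfig(subgroups=("ALL", "FGr"), n_null=29, n_iter=2000, seed=11)
        for sub in ("one", "two"):
            run_pipeline(comm, traits, cfg).write(tmp_path / sub)
        for f in sorted((tmp_path / "one").iterdir()):
            assert f.read_bytes() == (tmp_path / "two" / f.name).read_bytes()

    def test_fifteen_ses_contrasts_per_landscape(self, tiny_scenario):
        traits, comm, _ = tiny_scenario
        cfg = PipelineConfig(n_null=9, n_iter=500, seed=1)
        res = run_pipeline(comm, traits, cfg)
        ses_rows = res.contrasts[res.contrasts["metric"].str.startswith("ses")]
        counts = ses_rows.groupby("landscape").size()
        assert (counts == 15).all()  # 5 subgroups x 3 indices

    def test_flags_consistent_with_p_values(self, tiny_scenario):
        traits, comm, _ = tiny_scenario
        cfg = PipelineConfig(subgroups=("ALL",), n_null=19, n_iter=1000, seed=2)
        res = run_pipeline(comm, traits, cfg)
        ok = res.contrasts.dropna(subset=["perm_p"])
        assert ((ok["perm_p"] >= 0) & (ok["perm_p"] <= 1)).all()
        assert (ok["significant"] == (ok["perm_p"] < 0.01)).all()
        assert (ok["suggestive_05"] == (ok["perm_p"] < 0.05)).all()
        assert res.assembly["metric"].str.startswith("ses").all()
        hab = set(res.assembly["habitat"])
        assert hab == {"forest", "agroforestry"}
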