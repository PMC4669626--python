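"""AMOVA PhiPT: oracle equivalence, conventions, subsampling, Welch t."""

import numpy as np
import pytest

from nannopop import (
    GenotypeMatrix,
    amova_distance,
    amova_phipt,
    colony_subsample_phipt,
    welch_t,
)
from nannopop.dist_clone import DistanceMatrix

from conftest import female_row, make_dataset


def brute_force_phipt(calls: np.ndarray, labels: list[str]) -> float:
    """First-principles PhiPT: explicit per-pair loops and variance components.

    Squared distance between two haploid 0/1 genotypes = number of differing
    loci over jointly called loci, rescaled to the full locus count.
    """
    n, L = calls.shape
    d2 = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            both = (calls[i] != -1) & (calls[j] != -1)
            m = int((calls[i][both] != calls[j][both]).sum())
            d2[i, j] = m * L / both.sum()
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d2[i, j]
    ss_total /= n
    groups = sorted(set(labels))
    ss_within = 0.0
    sizes = []
    for g in groups:
        idx = [i for i, lab in enumerate(labels) if lab == g]
        sizes.append(len(idx))
        s = 0.0
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                s += d2[idx[a], idx[b]]
        ss_within += s / len(idx)
    ss_among = ss_total - ss_within
    G = len(groups)
    ms_among = ss_among / (G - 1)
    ms_within = ss_within / (n - G)
    n0 = (n - sum(s**2 for s in sizes) / n) / (G - 1)
    s2a = (ms_among - ms_within) / n0
    s2w = ms_within
    return s2a / (s2a + s2w)


def random_instance(rng, max_n=12, max_l=8):
    n = int(rng.integers(6, max_n + 1))
    L = int(rng.integers(3, max_l + 1))
    calls = rng.integers(0, 2, size=(n, L)).astype(np.int8)
    calls[rng.random((n, L)) < 0.05] = -1
    # ensure every sample keeps at least one call and pairs stay comparable
    calls[:, 0] = rng.integers(0, 2, size=n)
    G = int(rng.integers(2, 4))
    labels = [f"g{i % G}" for i in range(n)]
    return calls, labels


def test_phipt_matches_brute_force_oracle():
    rng = np.random.default_rng(21)
    checked = 0
    while checked < 50:
        calls, labels = random_instance(rng)
        g = GenotypeMatrix(
            [f"s{i}" for i in range(len(labels))],
            [f"L{j}" for j in range(calls.shape[1])],
            calls,
        )
        d = amova_distance(g)
        if d.undefined_pairs().any():
            continue
        res = amova_phipt(d, dict(zip(g.sample_ids, labels)), n_perm=0)
        expect = brute_force_phipt(calls, labels)
        assert res.phi_pt == pytest.approx(expect, abs=1e-9)
        assert res.ss_total == pytest.approx(res.ss_among + res.ss_within, abs=1e-9)
        checked += 1


def test_fixed_complementary_groups_give_phi_one():
    calls = np.array([[0] * 6] * 5 + [[1] * 6] * 5, dtype=np.int8)
    g = GenotypeMatrix([f"s{i}" for i in range(10)], [f"L{j}" for j in range(6)], calls)
    groups = {f"s{i}": "a" if i < 5 else "b" for i in range(10)}
    res = amova_phipt(amova_distance(g), groups, n_perm=999, seed=0)
    assert res.phi_pt == pytest.approx(1.0)
    # only the 2/252 label permutations reproducing the split tie the observed
    assert res.p_value <= 0.05


def test_identical_genotypes_zero_variance_convention():
    calls = np.ones((6, 4), dtype=np.int8)
    g = GenotypeMatrix([f"s{i}" for i in range(6)], [f"L{j}" for j in range(4)], calls)
    groups = {f"s{i}": "a" if i % 2 else "b" for i in range(6)}
    res = amova_phipt(amova_distance(g), groups, n_perm=99, seed=0)
    assert res.phi_pt == 0.0
    assert res.p_value == 1.0


def test_negative_phipt_not_truncated():
    # within-group distances exceed between-group distances
    d = np.array(
        [
            [0, 4, 1, 4],
            [4, 0, 4, 1],
            [1, 4, 0, 4],
            [4, 1, 4, 0],
        ],
        dtype=float,
    )
    dm = DistanceMatrix(list("abcd"), d, "count")
    res = amova_phipt(dm, {"a": "g1", "b": "g1", "c": "g2", "d": "g2"}, n_perm=0)
    assert res.phi_pt < 0


def test_duplicating_every_individual_roughly_preserves_phi():
    # the variance ratio is df-corrected, so duplicating everyone shifts
    # PhiPT only through an O(G/N) finite-sample term that shrinks with N
    from nannopop import SimulationConfig, draw_population_frequencies

    rng = np.random.default_rng(22)
    cfg = SimulationConfig(
        n_populations=3,
        colonies_per_population=1,
        n_loci=100,
        fst_level=0.3,
        origin_weights=(1, 0, 0, 0),
        seed=8,
    )
    fr = draw_population_frequencies(cfg)
    shifts = []
    for n_per in (10, 40):
        calls = np.vstack(
            [
                (rng.random((n_per, 100)) < fr.by_population[p]).astype(np.int8)
                for p in range(3)
            ]
        )
        n = 3 * n_per
        ids = [f"s{i}" for i in range(n)]
        labels = [f"g{i // n_per}" for i in range(n)]
        g = GenotypeMatrix(ids, [f"L{j}" for j in range(100)], calls)
        res1 = amova_phipt(amova_distance(g), dict(zip(ids, labels)), n_perm=0)
        ids2 = ids + [f"t{i}" for i in range(n)]
        g2 = GenotypeMatrix(ids2, g.locus_ids, np.vstack([calls, calls]))
        res2 = amova_phipt(
            amova_distance(g2), dict(zip(ids2, labels + labels)), n_perm=0
        )
        shifts.append(abs(res2.phi_pt - res1.phi_pt))
    assert shifts[1] < 0.02
    assert shifts[1] < shifts[0]


def grid_dataset(rng, n_pops=2, n_colonies=3, n_females=3, L=20):
    rows, calls = [], []
    for p in range(n_pops):
        for c in range(n_colonies):
            colony = f"P{p}-C{c}"
            for i in range(n_females):
                rows.append(
                    female_row(f"{colony}-f{i}", colony=colony, pop=f"P{p}")
                )
                calls.append(rng.integers(0, 2, size=L))
    return make_dataset(np.array(calls, dtype=np.int8), rows)


class TestColonySubsample:
    def test_deterministic_under_seed(self, study_ds):
        ds, _ = study_ds
        a = colony_subsample_phipt(ds, "dwarf_male", seed=3)
        b = colony_subsample_phipt(ds, "dwarf_male", seed=3)
        assert np.array_equal(a.phi_values, b.phi_values)

    def test_identical_individuals_within_population_sd_zero(self):
        rows, calls = [], []
        for p in range(2):
            hap = [p] * 8
            for c in range(3):
                colony = f"P{p}-C{c}"
                for i in range(2):
                    rows.append(
                        female_row(f"{colony}-f{i}", colony=colony, pop=f"P{p}")
                    )
                    calls.append(hap)
        ds = make_dataset(np.array(calls, dtype=np.int8), rows)
        res = colony_subsample_phipt(ds, "female", n_subsamples=4, seed=0)
        assert res.sd == 0.0
        assert res.mean == pytest.approx(1.0)

    def test_subsample_mean_consistent_with_full_data(self, study_ds):
        # dwarf males are near-independent draws, so the one-per-colony
        # subsample mean should track the full-data PhiPT (for females the
        # clonal pseudo-replication the subsampling corrects biases the
        # full-data value, so no agreement is expected there)
        ds, _ = study_ds
        from nannopop import amova_distance as ad

        sset = colony_subsample_phipt(ds, "dwarf_male", seed=5)
        ids = ds.samples_where(category="dwarf_male")
        full = amova_phipt(
            ad(ds.genotypes.take(ids)),
            ds.metadata.loc[ids, "population"],
            n_perm=0,
        )
        assert abs(sset.mean - full.phi_pt) < 2 * max(sset.sd, 0.02)

    def test_subsamples_disjoint_when_pool_permits(self, study_ds):
        ds, _ = study_ds
        # every colony hosts ~10 dwarf males, so 5 subsamples can be disjoint
        sset = colony_subsample_phipt(ds, "dwarf_male", n_subsamples=5, seed=9)
        all_ids = [sid for sub in sset.subsample_ids for sid in sub]
        assert len(all_ids) == len(set(all_ids))
        # one individual per colony in each subsample
        n_colonies = ds.metadata["colony"].nunique()
        for sub in sset.subsample_ids:
            assert len(sub) == n_colonies
            assert ds.metadata.loc[sub, "colony"].nunique() == n_colonies


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_separated_samples(self):
        t, df, p = welch_t([1, 2, 3], [11, 12, 13])
        assert abs(t) > 5
        assert p < 0.01

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(6)
        x = rng.normal(0, 1, 12)
        y = rng.normal(0.5, 2, 9)
        t, df, p = welch_t(x, y)
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t_ref = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df_ref = (vx + vy) ** 2 / (
            vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1)
        )
        from scipy import stats

        p_ref = 2 * stats.t.sf(abs(t_ref), df_ref)
        assert t == pytest.approx(t_ref, rel=1e-12)
        assert df == pytest.approx(df_ref, rel=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-10)

    def test_degenerate_zero_variance(self):
        t, df, p = welch_t([2.0, 2.0], [2.0, 2.0])
        assert (t, p) == (0.0, 1.0)
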