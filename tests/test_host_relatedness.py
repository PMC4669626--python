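"""GD_HOST / GD_COL / GD_POP profiles, paired tests, and origin calls."""

import numpy as np
import pandas as pd
import pytest

from nannopop import (
    SimulationConfig,
    assign_origin,
    gd_compare,
    gd_profile,
    simulate_dataset,
)

from conftest import female_row, male_row, make_dataset


def crafted_two_colony_dataset():
    """10-locus dataset where the focal male's distances are hand-set.

    In colony C1 the male differs from its host at 1 locus (0.1) and from
    the four satellite females at 2, 2, 3 and 3 loci (mean 0.25); colony C2
    females differ at 5 loci each (gd_pop 0.5).
    """
    L = 10
    male = np.zeros(L, dtype=np.int8)

    def hap(k):
        h = male.copy()
        h[:k] = 1
        return h

    rows, calls = [], []
    rows.append(female_row("C1-f1", colony="C1"))
    calls.append(hap(1))
    for i, k in enumerate((2, 2, 3, 3), start=2):
        rows.append(female_row(f"C1-f{i}", colony="C1"))
        calls.append(hap(k))
    for i in range(1, 6):
        rows.append(female_row(f"C2-f{i}", colony="C2"))
        calls.append(hap(5))
    rows.append(male_row("C1-d1", "C1-f1", colony="C1"))
    calls.append(male)
    return make_dataset(np.array(calls, dtype=np.int8), rows)


class TestGdProfile:
    def test_crafted_distances(self):
        prof = gd_profile(crafted_two_colony_dataset())
        row = prof.loc["C1-d1"]
        assert row["gd_host"] == pytest.approx(0.1)
        assert row["gd_col"] == pytest.approx(0.25)
        assert row["gd_pop"] == pytest.approx(0.5)
        assert row["n_col_females"] == 4
        assert row["n_pop_females"] == 5

    def test_male_identical_to_host(self):
        ds = crafted_two_colony_dataset()
        # replace the male's genotype with the host haplotype
        i = ds.genotypes.sample_ids.index("C1-d1")
        j = ds.genotypes.sample_ids.index("C1-f1")
        ds.genotypes.calls[i] = ds.genotypes.calls[j]
        prof = gd_profile(ds)
        assert prof.loc["C1-d1", "gd_host"] == 0.0


class TestGdCompare:
    def test_equal_profiles_give_p_one(self):
        prof = pd.DataFrame(
            {
                "gd_host": [0.1, 0.2, 0.3, 0.1, 0.25, 0.12],
                "gd_col": [0.1, 0.2, 0.3, 0.1, 0.25, 0.12],
                "colony": ["C1"] * 6,
            }
        )
        res = gd_compare(prof, "host_vs_col", n_perm=999, seed=0)
        assert res.mean_difference == 0.0
        assert res.p_value == 1.0

    def test_exact_enumeration_for_few_pairs(self):
        prof = pd.DataFrame(
            {
                "gd_host": [0.0, 0.1, 0.05],
                "gd_col": [0.3, 0.4, 0.2],
                "colony": ["C1", "C2", "C3"],
            }
        )
        res = gd_compare(prof, "host_vs_col", seed=0)
        assert res.exact
        assert res.n_permutations == 8
        # all differences share a sign, so only the all-flip patterns tie
        assert res.p_value == pytest.approx(2 / 8)

    def test_swapping_pair_order_flips_sign_keeps_p(self):
        rng = np.random.default_rng(51)
        prof = pd.DataFrame(
            {
                "gd_host": rng.random(40) * 0.3,
                "gd_col": rng.random(40) * 0.3 + 0.05,
                "colony": [f"C{i % 5}" for i in range(40)],
            }
        )
        res = gd_compare(prof, "host_vs_col", n_perm=2999, seed=4)
        swapped = prof.rename(columns={"gd_host": "gd_col", "gd_col": "gd_host"})
        res2 = gd_compare(swapped, "host_vs_col", n_perm=2999, seed=4)
        assert res2.mean_difference == pytest.approx(-res.mean_difference)
        assert res2.p_value == res.p_value

    def test_power_on_host_biased_synthetic_data(self):
        cfg = SimulationConfig(
            origin_weights=(0.8, 0.2, 0.0, 0.0), missing_rate=0.0, seed=53
        )
        ds, _ = simulate_dataset(cfg)
        prof = gd_profile(ds)
        assert len(prof) >= 200
        res = gd_compare(prof, "host_vs_col", n_perm=999, seed=0)
        assert res.mean_difference < 0
        assert res.p_value <= 0.01

    def test_colony_stratified_variant(self, study_ds):
        ds, _ = study_ds
        prof = gd_profile(ds)
        res = gd_compare(
            prof, "host_vs_col", n_perm=999, seed=1, stratify_by_colony=True
        )
        assert res.mean_difference < 0
        assert res.p_value <= 0.05


class TestAssignOrigin:
    def test_foreign_male_called_other_population(self):
        rows, calls = [], []
        L = 8
        for i in range(1, 4):
            rows.append(female_row(f"A-f{i}", colony="A", pop="P1"))
            calls.append([0] * L)
        for i in range(1, 4):
            rows.append(female_row(f"B-f{i}", colony="B", pop="P1"))
            calls.append([0] * (L - 2) + [1, 1])
        for i in range(1, 4):
            rows.append(female_row(f"X-f{i}", colony="X", pop="P2"))
            calls.append([1] * L)
        rows.append(male_row("A-d1", "A-f1", colony="A", pop="P1"))
        calls.append([1] * L)  # identical to population P2 females
        ds = make_dataset(np.array(calls, dtype=np.int8), rows)
        call = assign_origin(ds).loc["A-d1"]
        assert call["call"] == "other_population"
        assert call["distance"] == 0.0
        assert not call["ambiguous"]

    def test_tie_resolved_to_host_and_flagged(self):
        rows, calls = [], []
        L = 6
        rows.append(female_row("C-f1", colony="C"))
        calls.append([0] * L)
        rows.append(female_row("C-f2", colony="C"))
        calls.append([0] * L)  # same haplotype as host
        rows.append(female_row("D-f1", colony="D"))
        calls.append([1] * L)
        rows.append(male_row("C-d1", "C-f1", colony="C"))
        calls.append([0] * L)
        ds = make_dataset(np.array(calls, dtype=np.int8), rows)
        call = assign_origin(ds, margin_threshold=0.0).loc["C-d1"]
        assert call["call"] == "host"
        assert call["margin"] == 0.0
        assert call["ambiguous"]

    def test_truth_recovery_on_differentiated_populations(self, study_ds):
        # the nearest sampled female is a relative of one of the spore's two
        # parents, so a correct call names the location category of the
        # mother or the father (an outbred spore is equally related to both)
        ds, truth = study_ds
        meta = ds.metadata
        calls = assign_origin(ds)
        merged = calls.join(truth.dwarf_males)

        def location_category(male, female):
            if female == meta.loc[male, "host_id"]:
                return "host"
            if meta.loc[female, "colony"] == meta.loc[male, "colony"]:
                return "own_colony"
            if meta.loc[female, "population"] == meta.loc[male, "population"]:
                return "own_population"
            return "other_population"

        matches = [
            row["call"]
            in {
                location_category(sid, row["mother_id"]),
                location_category(sid, row["father_id"]),
            }
            for sid, row in merged.iterrows()
        ]
        merged["parent_match"] = matches
        clear = merged[~merged["ambiguous"]]
        assert len(clear) >= 50
        assert clear["parent_match"].mean() >= 0.8

    def test_deterministic_and_order_invariant(self):
        ds = crafted_two_colony_dataset()
        a = assign_origin(ds)
        b = assign_origin(ds)
        assert a.equals(b)
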