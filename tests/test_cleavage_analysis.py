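import numpy as np
import pandas as pd
import pytest

import degradomics as dg

from conftest import make_table


def mapped_frame(toy, rows):
    """rows: (condition, sequence-by-coords (start, end), psm)."""
    table = make_table(
        [
            (f"{cond}_r1", cond, 1, toy.sequence[s - 1:e], n)
            for cond, (s, e), n in rows
        ]
    )
    mapped, _ = dg.map_table(table, toy)
    return mapped


class TestIntegrateSiteCounts:
    def test_internal_peptide_credits_both_sites(self, toy_substrate):
        mapped = mapped_frame(toy_substrate, [("20S", (3, 6), 10)])
        usage = dg.integrate_site_counts(mapped, "20S")
        assert usage.count_at(2) == 10 and usage.count_at(6) == 10

    def test_hand_summed_contributions(self, toy_substrate):
        # (1,4):5 touches the N-terminus (site 4 only); (5,8):7 bounds sites 4 and 8
        mapped = mapped_frame(toy_substrate, [("20S", (1, 4), 5), ("20S", (5, 8), 7)])
        usage = dg.integrate_site_counts(mapped, "20S")
        assert usage.count_at(4) == 12 and usage.count_at(8) == 7

    def test_empty_input_gives_empty_table(self, toy_substrate):
        mapped = mapped_frame(toy_substrate, [])
        assert dg.integrate_site_counts(mapped, "20S").counts.empty

    def test_nterm_credit_mode(self, toy_substrate):
        mapped = mapped_frame(toy_substrate, [("20S", (3, 6), 10)])
        usage = dg.integrate_site_counts(mapped, "20S", credit="nterm")
        assert usage.count_at(2) == 10 and usage.count_at(6) == 0

    def test_ambiguous_excluded_or_fractional(self):
        sub = dg.SubstrateRecord(id="a", sequence="CADWCADW")
        table = make_table([("s1", "c", 1, "CAD", 8)])
        mapped, _ = dg.map_table(table, sub)
        assert dg.integrate_site_counts(mapped, "c").counts.empty
        frac = dg.integrate_site_counts(mapped, "c", ambiguous="fractional")
        assert frac.count_at(3) == 4.0 and frac.count_at(7) == 4.0  # 8/2 per site

    def test_count_conservation(self, toy_substrate):
        rows = [("c", (1, 4), 5), ("c", (3, 6), 10), ("c", (5, 10), 2), ("c", (1, 10), 9)]
        mapped = mapped_frame(toy_substrate, rows)
        usage = dg.integrate_site_counts(mapped, "c")
        internal = 10  # (3,6) bounded on both sides
        one_terminus = 5 + 2  # (1,4) and (5,10); (1,10) touches both termini
        assert usage.counts.sum() == 2 * internal + one_terminus


class TestComputePreference:
    def usage(self, counts, cond="a"):
        return dg.SiteUsageTable("s", cond, pd.Series(counts, dtype=float))

    def test_equal_counts_no_preference(self):
        pref = dg.compute_preference(self.usage({5: 10}), self.usage({5: 10}))
        row = pref.iloc[0]
        assert row["log2_ratio"] == 0 and row["call"] == "none"

    def test_zero_substituted_with_pseudo_value(self):
        pref = dg.compute_preference(self.usage({5: 10}), self.usage({}))
        row = pref.set_index("site").loc[5]
        assert row["log2_ratio"] == pytest.approx(np.log2(10 / 0.1))
        assert row["log2_ratio"] == pytest.approx(6.6439, abs=1e-4)
        assert row["call"] == "prefer_a"

    def test_twofold_threshold_calls(self):
        pref = dg.compute_preference(self.usage({1: 3}), self.usage({1: 8}))
        row = pref.iloc[0]
        assert row["log2_ratio"] == pytest.approx(np.log2(3 / 8))
        assert row["log2_ratio"] == pytest.approx(-1.4150, abs=1e-4)
        assert row["call"] == "prefer_b"  # |ratio| > log2(2)

    def test_both_zero_is_na_not_zero(self):
        pref = dg.compute_preference(
            self.usage({2: 4}), self.usage({2: 4}), substrate_length=10
        )
        na_rows = pref[pref["call"] == "na"]
        assert len(na_rows) == 8  # sites 1..9 minus the observed site 2
        assert na_rows["log2_ratio"].isna().all()

    def test_antisymmetry_under_swap(self):
        rng = np.random.default_rng(3)
        a = self.usage({s: c for s, c in enumerate(rng.integers(0, 20, 9), 1) if c})
        b = self.usage({s: c for s, c in enumerate(rng.integers(0, 20, 9), 1) if c})
        ab = dg.compute_preference(a, b, substrate_length=10)
        ba = dg.compute_preference(b, a, substrate_length=10)
        np.testing.assert_allclose(
            ab["log2_ratio"].to_numpy(), -ba["log2_ratio"].to_numpy()
        )

    def test_scale_property_raw_mode(self):
        a = self.usage({1: 4, 3: 9, 7: 2})
        b = self.usage({1: 8, 3: 3, 7: 5})
        a4 = self.usage({1: 16, 3: 36, 7: 8})
        base = dg.compute_preference(a, b)["log2_ratio"]
        scaled = dg.compute_preference(a4, b)["log2_ratio"]
        np.testing.assert_allclose(scaled - base, 2.0)  # log2(4)

    def test_substrate_mismatch_rejected(self):
        a = dg.SiteUsageTable("s1", "a", pd.Series({1: 1.0}))
        b = dg.SiteUsageTable("s2", "b", pd.Series({1: 1.0}))
        with pytest.raises(dg.ValidationError):
            dg.compute_preference(a, b)

    def test_nonpositive_pseudo_rejected(self):
        a = self.usage({1: 1})
        with pytest.raises(dg.ValidationError):
            dg.compute_preference(a, a, pseudo_value=0.0)


def heatmap_inputs(toy):
    # three samples passing depth filter, one that fails, peptides with
    # shared and single-sample support
    rows = []
    for sample, rep, big, small in [
        ("s1", 1, 60, 40), ("s2", 2, 30, 25), ("s3", 3, 80, 10),
    ]:
        rows.append((sample, "c", rep, "TAYI", big))
        rows.append((sample, "c", rep, "MKTA", small))
    rows.append(("s4", "c", 1, "TAYI", 20))          # 20 < 50 PSMs: dropped
    rows.append(("s1", "c", 1, "AKQR", 5))           # single-sample peptide
    table = make_table(rows)
    mapped, _ = dg.map_table(table, toy)
    return table, mapped


class TestBuildHeatmap:
    def test_filters_and_rescaling(self, toy_substrate):
        table, mapped = heatmap_inputs(toy_substrate)
        hm = dg.build_heatmap(table, mapped, min_sample_psms=50)
        assert list(hm.values.index) == ["s1", "s2", "s3"]
        assert "AKQR" not in hm.values.columns
        # every retained peptide column has maximum exactly 1
        assert np.allclose(hm.values.max(axis=0), 1.0)
        # column order by N-terminal residue: MKTA (start 1) before TAYI (start 3)
        assert list(hm.values.columns) == ["MKTA", "TAYI"]

    def test_cpm_definition_and_maxima(self, toy_substrate):
        table, mapped = heatmap_inputs(toy_substrate)
        hm = dg.build_heatmap(table, mapped, min_sample_psms=50)
        # s1 total = 60 + 40 + 5 = 105 mapped PSMs
        assert hm.cpm.loc["s1", "TAYI"] == pytest.approx(60 * 1e6 / 105)
        assert hm.peptide_maxima["TAYI"] == pytest.approx(hm.cpm["TAYI"].max())

    def test_rescale_example_and_idempotence(self):
        cpm = pd.DataFrame({"pep": [100.0, 50.0]}, index=["s1", "s2"])
        scaled = dg.rescale_columns(cpm)
        assert list(scaled["pep"]) == [1.0, 0.5]
        pd.testing.assert_frame_equal(dg.rescale_columns(scaled), scaled)

    def test_all_samples_filtered_is_error(self, toy_substrate):
        table, mapped = heatmap_inputs(toy_substrate)
        with pytest.raises(dg.ValidationError):
            dg.build_heatmap(table, mapped, min_sample_psms=10_000)


class TestMdsWardCluster:
    def build(self, toy, rows):
        table = make_table(rows)
        mapped, _ = dg.map_table(table, toy)
        return dg.build_heatmap(table, mapped, min_sample_psms=1)

    def test_identical_samples_merge_at_zero(self, toy_substrate):
        rows = [
            ("s1", "c", 1, "TAYI", 10), ("s1", "c", 1, "MKTA", 5),
            ("s2", "c", 2, "TAYI", 10), ("s2", "c", 2, "MKTA", 5),
        ]
        hm = self.build(toy_substrate, rows)
        coords, z = dg.mds_ward_cluster(hm)
        assert np.allclose(coords.to_numpy(), 0.0)
        assert z[0, 2] == pytest.approx(0.0)

    def test_duplicate_samples_merge_first(self, toy_substrate):
        rows = [
            ("s1", "c", 1, "TAYI", 10), ("s1", "c", 1, "MKTA", 90),
            ("s2", "c", 2, "TAYI", 10), ("s2", "c", 2, "MKTA", 90),
            ("s3", "c", 3, "TAYI", 80), ("s3", "c", 3, "MKTA", 20),
        ]
        hm = self.build(toy_substrate, rows)
        coords, z = dg.mds_ward_cluster(hm)
        first = {int(z[0, 0]), int(z[0, 1])}
        assert first == {0, 1}  # the duplicated pair joins first
        assert z[0, 2] == pytest.approx(0.0, abs=1e-6)

    def test_top_n_clamped(self, toy_substrate):
        rows = [
            ("s1", "c", 1, "TAYI", 10), ("s2", "c", 2, "TAYI", 5),
            ("s1", "c", 1, "MKTA", 3), ("s2", "c", 2, "MKTA", 9),
        ]
        hm = self.build(toy_substrate, rows)
        coords, _ = dg.mds_ward_cluster(hm, top_n=1000)
        assert coords.shape == (2, 2)

    def test_single_sample_rejected(self):
        cpm = pd.DataFrame({"TAYI": [5.0], "MKTA": [3.0]}, index=["s1"])
        hm = dg.HeatmapMatrix(
            values=dg.rescale_columns(cpm), cpm=cpm, peptide_maxima=cpm.max(axis=0)
        )
        with pytest.raises(dg.ValidationError):
            dg.mds_ward_cluster(hm)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(5, 4))
        from scipy.spatial.distance import pdist, squareform
        d = squareform(pdist(x))
        c1 = dg.classical_mds(d)
        c2 = dg.classical_mds(d)
        np.testing.assert_array_equal(c1, c2)
        assert (c1[0] >= 0).all()
        # pairwise distances reproduced when the configuration is planar
        # (here rank > 2, so distances are only approximated)
        assert c1.shape == (5, 2)


class TestLinkageToNewick:
    def test_renders_all_labels(self):
        from scipy.cluster.hierarchy import linkage
        z = linkage(np.array([[0.0], [1.0], [5.0]]), method="ward")
        nwk = dg.linkage_to_newick(z, ["a", "b", "c"])
        assert nwk.endswith(";") and all(l in nwk for l in "abc")


class TestDiversity:
    def test_uniform_counts(self):
        table = make_table(
            [("s1", "c", 1, seq, 4) for seq in ("AA", "CC", "DD", "KK")]
        )
        summary = dg.diversity(table, "c")
        assert summary.richness == 4
        assert summary.shannon_entropy == pytest.approx(2.0)

    def test_single_peptide_zero_entropy(self):
        summary = dg.diversity(make_table([("s1", "c", 1, "AA", 9)]), "c")
        assert summary.richness == 1 and summary.shannon_entropy == 0.0

    def test_hand_computed_entropy(self):
        counts = {"AA": 8, "CC": 4, "DD": 2, "KK": 2}
        table = make_table([("s1", "c", 1, s, n) for s, n in counts.items()])
        summary = dg.diversity(table, "c")
        assert summary.shannon_entropy == pytest.approx(1.75)

    def test_empty_condition(self):
        summary = dg.diversity(make_table([("s1", "c", 1, "AA", 1)]), "other")
        assert summary.richness == 0 and summary.shannon_entropy == 0.0

    def test_entropy_bounded_by_log_richness(self):
        rng = np.random.default_rng(5)
        seqs = ["".join(rng.choice(list("ACDK"), 4)) for _ in range(12)]
        table = make_table(
            [("s1", "c", 1, s, int(n)) for s, n in
             zip(set(seqs), rng.integers(1, 50, len(set(seqs))))]
        )
        summary = dg.diversity(table, "c")
        assert 0 <= summary.shannon_entropy <= np.log2(summary.richness) + 1e-12
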