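"""Microbial response derivation: PLFA groups and ratios, taxonomy
filtering, rarefaction, dominant phyla, richness, Bray-Curtis, NMDS and
compositional transforms."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import procrustes
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from spectromicrobe.errors import DataError
from spectromicrobe.microbial_derive import (
    ALL_BIOMARKERS,
    bray_curtis,
    clr,
    dominant_phyla,
    filter_taxa,
    hellinger,
    nmds,
    plfa_groups,
    rarefy,
    richness,
)


def _lipid_table(concentrations: dict, sample="s1"):
    return pd.DataFrame(
        [
            {"sample_id": sample, "lipid": lip, "concentration_nmol_g": c}
            for lip, c in concentrations.items()
        ]
    )


class TestPLFAGroups:
    def test_unit_concentrations(self):
        table = _lipid_table({lip: 1.0 for lip in ALL_BIOMARKERS})
        out = plfa_groups(table)
        row = out.loc["s1"]
        assert row["gram_positive"] == 6
        assert row["gram_negative"] == 2
        assert row["actinomycetes"] == 3
        assert row["saprophytic_fungi"] == 3
        assert row["am_fungi"] == 1
        assert row["total_plfa"] == 15
        assert row["fb_ratio"] == pytest.approx(4 / 11)
        assert row["gp_gn_ratio"] == pytest.approx(3.0)

    def test_total_is_sum_of_groups_for_listed_biomarkers(self):
        rng = np.random.default_rng(5)
        conc = {lip: float(rng.uniform(0.1, 5)) for lip in ALL_BIOMARKERS}
        out = plfa_groups(_lipid_table(conc)).loc["s1"]
        groups = (
            out["gram_positive"] + out["gram_negative"] + out["actinomycetes"]
            + out["saprophytic_fungi"] + out["am_fungi"]
        )
        assert out["total_plfa"] == pytest.approx(groups, abs=1e-12)

    def test_missing_biomarker_error_lists_names(self):
        conc = {lip: 1.0 for lip in ALL_BIOMARKERS if lip != "cyclo19:0"}
        with pytest.raises(DataError, match="cyclo19:0"):
            plfa_groups(_lipid_table(conc))

    def test_zero_denominator_flags_nan_ratio(self):
        conc = {lip: 1.0 for lip in ALL_BIOMARKERS}
        conc["cyclo17:0"] = 0.0
        conc["cyclo19:0"] = 0.0
        out = plfa_groups(_lipid_table(conc))
        assert np.isnan(out.loc["s1", "gp_gn_ratio"])

    def test_negative_concentration_rejected(self):
        conc = {lip: 1.0 for lip in ALL_BIOMARKERS}
        conc["i15:0"] = -0.1
        with pytest.raises(DataError):
            plfa_groups(_lipid_table(conc))


class TestFilterTaxa:
    def _table(self):
        counts = pd.DataFrame(
            np.arange(12).reshape(2, 6) + 1,
            index=["s1", "s2"],
            columns=[f"a{i}" for i in range(6)],
        )
        taxonomy = pd.DataFrame(
            {
                "asv_id": [f"a{i}" for i in range(6)],
                "kingdom": ["Bacteria", "Archaea", "Bacteria", "Bacteria", "Archaea", "Bacteria"],
                "phylum": ["Proteo", "Cren", "", "Acido", "Cren", "unclassified"],
            }
        )
        return counts, taxonomy

    def test_archaea_and_undefined_removed(self):
        counts, tax = self._table()
        out, removed = filter_taxa(counts, tax)
        assert sorted(removed) == ["a1", "a2", "a4", "a5"]
        assert list(out.columns) == ["a0", "a3"]
        assert (out["a0"] == counts["a0"]).all()

    def test_all_bacteria_unchanged(self):
        counts, tax = self._table()
        tax["kingdom"] = "Bacteria"
        tax["phylum"] = "Proteo"
        out, removed = filter_taxa(counts, tax)
        assert removed == [] and out.equals(counts)


class TestRarefy:
    def test_below_depth_dropped_exact_depth_retained(self):
        counts = pd.DataFrame(
            {"a": [4999, 3000, 4000], "b": [0, 2000, 2000]},
            index=["low", "exact", "high"],
        )
        out, dropped = rarefy(counts, depth=5000, seed=0)
        assert dropped == ["low"]
        assert (out.loc["exact"] == counts.loc["exact"]).all()
        assert out.loc["high"].sum() == 5000

    def test_conservation_over_random_tables(self):
        rng = np.random.default_rng(1)
        for trial in range(100):
            counts = pd.DataFrame(rng.integers(0, 80, size=(4, 12)))
            depth = int(rng.integers(1, 120))
            out, _ = rarefy(counts, depth=depth, seed=trial)
            if len(out):
                assert (out.sum(axis=1) == depth).all()
                before = (counts.loc[out.index] > 0).sum(axis=1)
                after = (out > 0).sum(axis=1)
                assert (after <= before).all()

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(0, 500, size=(5, 30)))
        a, _ = rarefy(counts, depth=1000, seed=9)
        b, _ = rarefy(counts, depth=1000, seed=9)
        assert a.equals(b)


class TestDominantPhyla:
    def test_single_phylum_dataset(self):
        counts = pd.DataFrame({"a0": [10, 20], "a1": [5, 5]}, index=["s1", "s2"])
        tax = pd.DataFrame(
            {"asv_id": ["a0", "a1"], "kingdom": "Bacteria", "phylum": "Proteo"}
        )
        table, dominant = dominant_phyla(counts, tax)
        assert dominant == ["Proteo"]
        assert np.allclose(table["Proteo"], 1.0)
        assert np.allclose(table["Other"], 0.0)

    def test_ubiquitous_abundant_phylum_selected(self):
        # 10 phyla; A is ~50% everywhere, others rare and patchy
        rng = np.random.default_rng(3)
        n_samples, n_phyla = 8, 10
        cols, tax_rows = {}, []
        for p in range(n_phyla):
            name = chr(ord("A") + p)
            tax_rows.append({"asv_id": f"asv{p}", "kingdom": "Bacteria", "phylum": name})
            if p == 0:
                cols[f"asv{p}"] = np.full(n_samples, 100)
            else:
                vals = rng.integers(0, 12, size=n_samples)
                vals[rng.integers(0, n_samples)] = 0  # patchy
                cols[f"asv{p}"] = vals
        counts = pd.DataFrame(cols, index=[f"s{i}" for i in range(n_samples)])
        table, dominant = dominant_phyla(counts, pd.DataFrame(tax_rows))
        assert dominant == ["A"]
        assert np.allclose(table["Other"], 1.0 - table["A"])

    def test_fractions_sum_to_one(self, small_dataset):
        counts, _ = filter_taxa(small_dataset.asv_counts, small_dataset.taxonomy)
        table, _ = dominant_phyla(counts, small_dataset.taxonomy)
        assert np.abs(table.sum(axis=1) - 1.0).max() < 1e-9
        assert ((table >= -1e-12) & (table <= 1 + 1e-12)).all().all()


def test_richness_counts_nonzero_asvs():
    counts = pd.DataFrame({"a": [5, 0], "b": [0, 0], "c": [1, 0], "d": [2, 0]})
    assert list(richness(counts)) == [3, 0]


class TestBrayCurtis:
    def test_identical_and_disjoint_rows(self):
        counts = pd.DataFrame(
            [[1, 2, 0], [1, 2, 0], [0, 0, 5]], index=["a", "b", "c"]
        )
        dm = bray_curtis(counts)
        assert dm["a", "b"] == 0.0
        assert dm["a", "c"] == 1.0

    def test_hand_computed_value(self):
        counts = pd.DataFrame([[2, 0, 1], [1, 1, 1]], index=["x", "y"])
        dm = bray_curtis(counts)
        assert dm["x", "y"] == pytest.approx(2 / 6, abs=1e-12)

    def test_matches_brute_force_loop(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.integers(0, 50, size=(20, 15)) + 1)
        counts.index = counts.index.map(str)
        dm = bray_curtis(counts)
        mat = counts.to_numpy(float)
        for i in range(20):
            for j in range(20):
                expected = np.abs(mat[i] - mat[j]).sum() / (mat[i] + mat[j]).sum()
                assert abs(dm.data[i, j] - expected) < 1e-12

    def test_bounded_and_zero_column_invariant(self):
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(rng.integers(0, 30, size=(6, 8)) + 1)
        counts.index = counts.index.map(str)
        dm = bray_curtis(counts)
        assert (dm.data >= 0).all() and (dm.data <= 1).all()
        padded = counts.copy()
        padded["zero"] = 0
        assert np.allclose(bray_curtis(padded).data, dm.data)

    def test_zero_row_errors_naming_sample(self):
        counts = pd.DataFrame([[1, 1], [0, 0]], index=["ok", "empty"])
        with pytest.raises(DataError, match="empty"):
            bray_curtis(counts)


class TestNMDS:
    def test_three_equidistant_points_embed_exactly(self):
        d = DistanceMatrix(
            np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float), ids=list("abc")
        )
        res = nmds(d, k=2, seed=0, n_restarts=5)
        assert res.stress <= 1e-6

    def test_recovers_true_two_dimensional_configuration(self):
        rng = np.random.default_rng(6)
        true = rng.normal(size=(20, 2))
        d = DistanceMatrix(squareform(pdist(true)), ids=[str(i) for i in range(20)])
        res = nmds(d, k=2, seed=0, n_restarts=10, max_iter=500)
        assert res.stress <= 1e-3
        _, _, disparity = procrustes(true, res.scores.to_numpy())
        assert disparity <= 0.01

    def test_axes_centred_and_sign_fixed(self):
        rng = np.random.default_rng(7)
        pts = rng.normal(size=(12, 2))
        d = DistanceMatrix(squareform(pdist(pts)), ids=[str(i) for i in range(12)])
        res = nmds(d, k=2, seed=1, n_restarts=5)
        scores = res.scores.to_numpy()
        assert np.abs(scores.mean(axis=0)).max() < 1e-8
        for j in range(2):
            nz = np.nonzero(scores[:, j])[0]
            assert scores[nz[0], j] > 0


class TestTransforms:
    def test_hellinger_hand_values(self):
        out = hellinger(np.array([[4.0, 0.0], [1.0, 1.0]]))
        assert np.allclose(out[0], [1.0, 0.0])
        out2 = hellinger(np.array([[1.0, 1.0, 2.0]]))
        assert np.allclose(out2[0], [0.5, 0.5, np.sqrt(0.5)], atol=1e-12)

    def test_hellinger_rows_unit_norm(self):
        rng = np.random.default_rng(8)
        out = hellinger(rng.integers(1, 40, size=(10, 6)).astype(float))
        assert np.abs(np.linalg.norm(out, axis=1) - 1).max() < 1e-12

    def test_clr_uniform_row_is_zero(self):
        out = clr(np.array([[3.0, 3.0, 3.0]]))
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_clr_hand_values(self):
        out = clr(np.array([[1.0, 4.0]]))
        assert np.allclose(out[0], [-np.log(2), np.log(2)], atol=1e-10)

    def test_clr_rows_sum_to_zero_with_zero_replacement(self):
        rng = np.random.default_rng(9)
        mat = rng.integers(0, 20, size=(12, 7)).astype(float)
        mat[:, 0] += 1  # keep rows nonzero
        out = clr(mat)
        assert np.abs(np.asarray(out).sum(axis=1)).max() < 1e-9
        assert np.isfinite(np.asarray(out)).all()

    def test_zero_row_sum_rejected(self):
        with pytest.raises(DataError):
            hellinger(np.array([[0.0, 0.0]]))
        with pytest.raises(DataError):
            clr(np.array([[0.0, 0.0]]))
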