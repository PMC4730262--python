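"""Gapped-dipeptide composition features: formulas, layout, dataset assembly."""

import numpy as np
import pytest

from gapdpc import (
    AA_ORDER,
    PSSMProfile,
    decode_feature_index,
    dpc,
    extract_dataset,
    feature_names,
    feature_vector,
    gapdpc,
    read_dataset_tsv,
    write_dataset_tsv,
)
from conftest import naive_gapdpc, random_scaled_profile


def near_indicator_profile(columns, eps=1e-12):
    """Rows that put weight 1 - 19*eps on one column each (valid scaled profile)."""
    m = np.full((len(columns), 20), eps)
    for k, j in enumerate(columns):
        m[k, j] = 1 - 19 * eps
    return PSSMProfile("A" * len(columns), m, scaled=True)


class TestDpc:
    def test_single_dipeptide_indicator(self):
        i0, j0 = 4, 17
        vec = dpc(near_indicator_profile([i0, j0]))
        expected = np.zeros(400)
        expected[i0 * 20 + j0] = 1.0
        np.testing.assert_allclose(vec, expected, atol=1e-10)

    def test_constant_profile_closed_form(self):
        c, L = 0.3, 7
        prof = PSSMProfile("A" * L, np.full((L, 20), c), scaled=True)
        np.testing.assert_allclose(dpc(prof), (L - 1) * c * c, rtol=1e-12)

    def test_matches_naive_loop(self):
        prof = random_scaled_profile(np.random.default_rng(5), 5)
        np.testing.assert_allclose(dpc(prof), naive_gapdpc(prof.matrix, 0), rtol=1e-12)

    def test_requires_scaled_and_long_enough(self):
        with pytest.raises(ValueError, match="scaled"):
            dpc(PSSMProfile("MK", np.zeros((2, 20))))
        with pytest.raises(ValueError, match="too short"):
            dpc(random_scaled_profile(np.random.default_rng(0), 1))


class TestGapdpc:
    def test_gap_zero_equals_dpc_exactly(self):
        prof = random_scaled_profile(np.random.default_rng(6), 15)
        np.testing.assert_array_equal(gapdpc(prof, 0), dpc(prof))

    @pytest.mark.parametrize("g", range(1, 9))
    def test_matches_naive_loop(self, g):
        prof = random_scaled_profile(np.random.default_rng(100 + g), 12)
        np.testing.assert_allclose(gapdpc(prof, g), naive_gapdpc(prof.matrix, g), rtol=1e-10)

    def test_unit_row_sums_give_block_total(self):
        rng = np.random.default_rng(7)
        L = 11
        rows = rng.dirichlet(np.ones(20), size=L)
        prof = PSSMProfile("A" * L, np.clip(rows, 1e-12, None), scaled=True)
        for g in range(0, L - 1):
            assert gapdpc(prof, g).sum() == pytest.approx(L - g - 1, rel=1e-9)

    def test_bounds_from_scaled_profile(self):
        prof = random_scaled_profile(np.random.default_rng(8), 9)
        for g in range(0, 8):
            y = gapdpc(prof, g)
            assert (y >= 0).all() and (y <= prof.length - g - 1).all()

    def test_gap_exceeding_capacity_raises(self):
        prof = random_scaled_profile(np.random.default_rng(9), 4)
        with pytest.raises(ValueError, match="gap exceeds sequence capacity"):
            gapdpc(prof, 3)

    def test_permutation_equivariance(self):
        """Permuting profile columns permutes the 20x20 feature table consistently."""
        rng = np.random.default_rng(10)
        prof = random_scaled_profile(rng, 8)
        perm = rng.permutation(20)
        permuted = PSSMProfile(prof.sequence, prof.matrix[:, perm], scaled=True)
        for g in (0, 2):
            y = gapdpc(prof, g).reshape(20, 20)
            y_perm = gapdpc(permuted, g).reshape(20, 20)
            np.testing.assert_allclose(y_perm, y[np.ix_(perm, perm)], rtol=1e-12)


class TestFeatureVector:
    @pytest.mark.parametrize("max_gap, dim", [(8, 3600), (0, 400), (4, 2000)])
    def test_dimension(self, max_gap, dim):
        prof = random_scaled_profile(np.random.default_rng(11), max_gap + 5)
        fv = feature_vector(prof, max_gap)
        assert fv.values.shape == (dim,)

    def test_blocks_match_gapdpc(self):
        prof = random_scaled_profile(np.random.default_rng(12), 14)
        fv = feature_vector(prof, 5)
        for g in range(6):
            np.testing.assert_array_equal(fv.block(g), gapdpc(prof, g))

    def test_prefix_nesting_in_max_gap(self):
        prof = random_scaled_profile(np.random.default_rng(13), 14)
        small, big = feature_vector(prof, 3), feature_vector(prof, 4)
        np.testing.assert_array_equal(big.values[: small.values.size], small.values)

    def test_too_short_profile_names_minimum(self):
        prof = random_scaled_profile(np.random.default_rng(14), 5)
        with pytest.raises(ValueError, match="minimum admissible length is 10"):
            feature_vector(prof, 8)

    def test_length_normalization_flag(self):
        prof = random_scaled_profile(np.random.default_rng(15), 10)
        raw = feature_vector(prof, 2)
        norm = feature_vector(prof, 2, normalize_by_length=True)
        for g in range(3):
            np.testing.assert_allclose(norm.block(g), raw.block(g) / (10 - g - 1), rtol=1e-12)

    def test_naming_and_index_decoding(self):
        names = feature_names(8)
        assert len(names) == 3600
        assert names[0] == "g0_AA" and names[400] == "g1_AA"
        g, ai, aj = decode_feature_index(2 * 400 + 3 * 20 + 7, 8)
        assert (g, ai, aj) == (2, AA_ORDER[3], AA_ORDER[7])
        assert names[2 * 400 + 3 * 20 + 7] == f"g{g}_{ai}{aj}"


class TestExtractDataset:
    def _profiles(self, n=4, length=10, seed=20):
        rng = np.random.default_rng(seed)
        return [random_scaled_profile(rng, length, protein_id=f"p{i}") for i in range(n)]

    def test_rows_recompute_per_protein(self):
        profs = self._profiles()
        labels = {f"p{i}": cls for i, cls in enumerate(["all-α", "all-β", "α/β", "α+β"])}
        data = extract_dataset(profs, labels, max_gap=2)
        assert data.matrix.shape == (4, 1200)
        for row, pid in zip(data.matrix, data.ids):
            prof = next(p for p in profs if p.protein_id == pid)
            np.testing.assert_array_equal(row, feature_vector(prof, 2).values)

    def test_row_order_is_sorted_by_id(self):
        profs = self._profiles()[::-1]
        labels = {p.protein_id: "all-α" if int(p.protein_id[1]) % 2 else "all-β" for p in profs}
        data = extract_dataset(profs, labels, max_gap=1)
        assert list(data.ids) == sorted(labels)

    def test_empty_collection_raises(self):
        with pytest.raises(ValueError, match="no profiles"):
            extract_dataset([], {}, max_gap=1)

    def test_duplicate_id_raises(self):
        p = self._profiles(1)[0]
        with pytest.raises(ValueError, match="duplicate"):
            extract_dataset([p, p], {"p0": "all-α"}, max_gap=1)

    def test_missing_label_lists_ids(self):
        profs = self._profiles(3)
        with pytest.raises(ValueError, match="p1, p2"):
            extract_dataset(profs, {"p0": "all-α"}, max_gap=1)

    def test_too_short_profile_names_protein(self):
        profs = self._profiles(2, length=4)
        labels = {"p0": "all-α", "p1": "all-β"}
        with pytest.raises(ValueError, match="p0"):
            extract_dataset(profs, labels, max_gap=8)

    def test_tsv_round_trip(self, tmp_path):
        profs = self._profiles()
        labels = {p.protein_id: "all-α" for p in profs}
        data = extract_dataset(profs, labels, max_gap=1)
        path = tmp_path / "features.tsv"
        write_dataset_tsv(data, path)
        back = read_dataset_tsv(path)
        assert back.ids == data.ids
        assert list(back.labels) == list(data.labels)
        np.testing.assert_allclose(back.matrix, data.matrix, rtol=1e-15)


def test_oracle_equivalence_many_random_profiles():
    """Vectorized GapDPC equals the brute-force loop over many shapes and gaps."""
    rng = np.random.default_rng(2024)
    checked = 0
    for _ in range(100):
        L = int(rng.integers(3, 21))
        prof = random_scaled_profile(rng, L)
        g = int(rng.integers(0, L - 1))
        np.testing.assert_allclose(
            gapdpc(prof, g), naive_gapdpc(prof.matrix, g), rtol=1e-10
        )
        checked += 1
    assert checked == 100
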