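import numpy as np
import pandas as pd
import pytest

import treegenval as tg
from treegenval.io_prep import PedigreeCycleError

from conftest import random_pedigree


class TestRenumber:
    def test_founders_only_identity(self):
        raw = tg.RawPedigreeTable(pd.DataFrame({
            "id": ["A", "B"], "sire": [tg.UNKNOWN] * 2, "dam": [tg.UNKNOWN] * 2}))
        ped = tg.renumber(raw)
        assert list(ped.ids) == ["A", "B"]

    def test_child_before_parent_reordered(self):
        raw = tg.RawPedigreeTable(pd.DataFrame({
            "id": ["C", "A", "B"], "sire": ["A", tg.UNKNOWN, tg.UNKNOWN],
            "dam": ["B", tg.UNKNOWN, tg.UNKNOWN]}))
        ped = tg.renumber(raw)
        assert list(ped.ids).index("C") == 2
        assert ped.sire[2] < 2 and ped.dam[2] < 2

    def test_cycle_names_members(self):
        raw = tg.RawPedigreeTable(pd.DataFrame({
            "id": ["A", "B"], "sire": ["B", "A"], "dam": [tg.UNKNOWN] * 2}))
        with pytest.raises(PedigreeCycleError, match="A.*B"):
            tg.renumber(raw)

    def test_unlisted_parent_appended_as_founder(self):
        raw = tg.RawPedigreeTable(pd.DataFrame({
            "id": ["C"], "sire": ["A"], "dam": [tg.UNKNOWN]}))
        ped = tg.renumber(raw)
        assert set(ped.ids) == {"A", "C"}


class TestTabularA:
    def test_trio(self, trio):
        A = tg.tabular_A(tg.renumber(trio))
        assert A[0, 2] == A[1, 2] == 0.5
        assert A[2, 2] == 1.0

    def test_half_sib_inbreeding(self):
        # offspring of two half sibs (common sire P1): F = 0.125
        raw = tg.RawPedigreeTable(pd.DataFrame({
            "id": ["P1", "P2", "P3", "X", "Y", "O"],
            "sire": [tg.UNKNOWN] * 3 + ["P1", "P1", "X"],
            "dam": [tg.UNKNOWN] * 3 + ["P2", "P3", "Y"],
        }))
        ped = tg.renumber(raw)
        A = tg.tabular_A(ped)
        o = list(ped.ids).index("O")
        assert A[o, o] == pytest.approx(1.125)
        assert tg.inbreeding(ped)[o] == pytest.approx(0.125)

    def test_gene_dropping_oracle(self, rng):
        """A equals twice the kinship estimated by Monte Carlo gene dropping."""
        ped = random_pedigree(rng, 200)
        A = tg.tabular_A(ped)
        reps = 120_000
        # drop one biallelic locus: founder alleles unique per founder copy
        anc = np.empty((ped.n, 2, reps), dtype=np.int32)
        counter = 0
        for i in range(ped.n):
            for c, parent in enumerate((ped.sire[i], ped.dam[i])):
                if parent < 0:
                    anc[i, c] = counter
                    counter += 1
                else:
                    pick = rng.integers(0, 2, size=reps)
                    anc[i, c] = anc[parent, pick, np.arange(reps)]
        pairs = [(ped.n - 1, ped.n - 2), (ped.n - 1, ped.n - 5), (150, 199)]
        for i, j in pairs:
            ibd = np.zeros(reps)
            for a in range(2):
                for b in range(2):
                    ibd += anc[i, a] == anc[j, b]
            est = ibd.mean() / 2.0  # 2 * kinship
            se = ibd.std(ddof=1) / (2.0 * np.sqrt(reps))
            assert abs(est - A[i, j]) < 3 * max(se, 1e-4)


class TestInbreedingAndInverse:
    def test_founder_zero_and_fullsib_quarter(self):
        raw = tg.RawPedigreeTable(pd.DataFrame({
            "id": ["A", "B", "X", "Y", "O"],
            "sire": [tg.UNKNOWN] * 2 + ["A", "A", "X"],
            "dam": [tg.UNKNOWN] * 2 + ["B", "B", "Y"],
        }))
        ped = tg.renumber(raw)
        F = tg.inbreeding(ped)
        assert F[0] == 0.0
        assert F[list(ped.ids).index("O")] == pytest.approx(0.25)

    def test_f_matches_tabular_diagonal(self, rng):
        ped = random_pedigree(rng, 150)
        assert np.allclose(tg.inbreeding(ped), np.diag(tg.tabular_A(ped)) - 1)

    def test_single_founder_identity(self):
        ped = random_pedigree(np.random.default_rng(0), 1, n_founders=1)
        assert np.allclose(tg.a_inverse(ped).toarray(), [[1.0]])

    def test_trio_dense_inverse(self, trio):
        ped = tg.renumber(trio)
        Ainv = tg.a_inverse(ped).toarray()
        assert np.abs(Ainv - np.linalg.inv(tg.tabular_A(ped))).max() < 1e-10

    def test_product_is_identity(self, rng):
        ped = random_pedigree(rng, 500)
        prod = tg.a_inverse(ped) @ tg.tabular_A(ped)
        assert np.abs(prod - np.eye(ped.n)).max() < 1e-8


class TestSubsetA22:
    def test_all_genotyped(self, rng):
        ped = random_pedigree(rng, 40)
        A = tg.tabular_A(ped)
        A22, _ = tg.subset_A22(A, np.arange(40))
        assert np.array_equal(A22, A)

    def test_only_offspring(self, trio):
        A = tg.tabular_A(tg.renumber(trio))
        A22, A22i = tg.subset_A22(A, np.array([2]))
        assert np.allclose(A22, [[1.0]])

    def test_inverse_of_block_not_block_of_inverse(self, rng):
        ped = random_pedigree(rng, 200)
        A = tg.tabular_A(ped)
        rows = np.sort(rng.choice(200, 60, replace=False))
        A22, A22i = tg.subset_A22(A, rows)
        assert np.abs(A22i @ A22 - np.eye(60)).max() < 1e-8
        block_of_inv = np.linalg.inv(A)[np.ix_(rows, rows)]
        assert np.abs(block_of_inv - A22i).max() > 1e-3  # genuinely different

    def test_empty_set_rejected(self, trio):
        with pytest.raises(ValueError):
            tg.subset_A22(tg.tabular_A(tg.renumber(trio)), np.array([], dtype=int))


class TestMetafounders:
    def test_single_group_rewires_both_slots(self, trio):
        ped = tg.attach_metafounders(tg.renumber(trio))
        assert ped.n_mf == 1 and ped.n == 4
        assert ped.sire[1] == 0 and ped.dam[1] == 0  # founder A

    def test_four_groups_prepended(self, rng):
        ped = random_pedigree(rng, 60, groups=("a", "b", "c", "d"))
        mf = tg.attach_metafounders(ped)
        assert mf.n_mf == 4 and mf.mf_labels == ("a", "b", "c", "d")

    def test_partial_unknown_only_that_slot(self):
        raw = tg.RawPedigreeTable(pd.DataFrame({
            "id": ["S", "X"], "sire": [tg.UNKNOWN, "S"], "dam": [tg.UNKNOWN] * 2,
            "group": ["g1", "g1"]}))
        mf = tg.attach_metafounders(tg.renumber(raw))
        x = list(mf.ids).index("X")
        s = list(mf.ids).index("S")
        assert mf.sire[x] == s and mf.dam[x] == 0

    def test_unlabelled_unknown_rejected(self, trio):
        trio.df.loc[0, "group"] = ""
        with pytest.raises(ValueError, match="without a group label"):
            tg.attach_metafounders(tg.renumber(trio))


class TestTabularAGamma:
    def test_zero_gamma_equals_plain(self, trio):
        ped = tg.renumber(trio)
        mf = tg.attach_metafounders(ped)
        Ag = tg.tabular_A_gamma(mf, tg.GammaMatrix([[0.0]]))
        assert np.allclose(Ag[1:, 1:], tg.tabular_A(ped))

    def test_single_founder_hand_recursion(self):
        raw = tg.RawPedigreeTable(pd.DataFrame({
            "id": ["A"], "sire": [tg.UNKNOWN], "dam": [tg.UNKNOWN], "group": ["g"]}))
        mf = tg.attach_metafounders(tg.renumber(raw))
        Ag = tg.tabular_A_gamma(mf, tg.GammaMatrix([[0.2]]))
        assert Ag[1, 1] == pytest.approx(1.1)
        assert Ag[0, 1] == pytest.approx(0.2)

    def test_two_groups_cross_relationship(self):
        raw = tg.RawPedigreeTable(pd.DataFrame({
            "id": ["A", "B"], "sire": [tg.UNKNOWN] * 2, "dam": [tg.UNKNOWN] * 2,
            "group": ["g1", "g2"]}))
        mf = tg.attach_metafounders(tg.renumber(raw))
        gamma = tg.GammaMatrix([[0.5, 0.3], [0.3, 0.7]])
        Ag = tg.tabular_A_gamma(mf, gamma)
        a, b = list(mf.ids).index("A"), list(mf.ids).index("B")
        assert Ag[a, b] == pytest.approx(0.3)
        assert Ag[a, a] == pytest.approx(1.25)
        assert Ag[b, b] == pytest.approx(1.35)


class TestAGammaInverse:
    def test_dense_oracle_random(self, rng):
        for _ in range(5):
            ped = random_pedigree(rng, 100, groups=("a", "b", "c", "d"))
            mf = tg.attach_metafounders(ped)
            gamma = tg.GammaMatrix(np.array([
                [0.6, 0.25, 0.2, 0.2], [0.25, 0.5, 0.2, 0.25],
                [0.2, 0.2, 0.45, 0.3], [0.2, 0.25, 0.3, 0.4]]))
            Aginv = tg.a_gamma_inverse(mf, gamma).toarray()
            dense = np.linalg.inv(tg.tabular_A_gamma(mf, gamma))
            assert np.abs(Aginv - dense).max() < 1e-8

    def test_near_singular_gamma_raises(self, trio):
        mf = tg.attach_metafounders(tg.renumber(trio))
        with pytest.raises(Exception):
            tg.GammaMatrix([[0.0]]).inverse()

    def test_gamma_validation(self):
        with pytest.raises(ValueError):
            tg.GammaMatrix([[0.5, 0.9], [0.9, 0.5]])  # not PSD
        with pytest.raises(ValueError):
            tg.GammaMatrix([[2.5]])  # diagonal above 2


class TestProperties:
    def test_tabular_outputs_psd(self, rng):
        ped = random_pedigree(rng, 300, groups=("a", "b"))
        A = tg.tabular_A(ped)
        assert np.linalg.eigvalsh(A).min() > -1e-8
        mf = tg.attach_metafounders(ped)
        Ag = tg.tabular_A_gamma(mf, tg.GammaMatrix([[0.4, 0.2], [0.2, 0.5]]))
        assert np.linalg.eigvalsh(Ag).min() > -1e-8

    def test_monotone_information(self, rng):
        """Adding a generation never decreases an existing diagonal of A."""
        ped = random_pedigree(rng, 120)
        diag_before = np.diag(tg.tabular_A(ped))
        n_extra = 40
        sire = np.concatenate([ped.sire, rng.integers(0, 120, n_extra)])
        dam = np.concatenate([ped.dam, rng.integers(0, 120, n_extra)])
        ids = np.concatenate([ped.ids, [f"x{k}" for k in range(n_extra)]])
        groups = np.concatenate([ped.groups, [""] * n_extra])
        bigger = tg.Pedigree(ids, sire, dam, groups)
        diag_after = np.diag(tg.tabular_A(bigger))[:120]
        assert np.all(diag_after >= diag_before - 1e-12)

    def test_triplet_export(self, trio, tmp_path):
        ped = tg.renumber(trio)
        path = tmp_path / "ainv.txt"
        tg.export_triplets(tg.a_inverse(ped), path)
        rows = [line.split() for line in path.read_text().strip().splitlines()]
        assert all(int(i) <= int(j) for i, j, _ in rows)  # upper triangle, 1-based
        vals = {(int(i), int(j)): float(v) for i, j, v in rows}
        assert vals[(1, 1)] == pytest.approx(1.5)
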