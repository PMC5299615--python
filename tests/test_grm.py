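"""GRM construction, empirical Me, design utilities and text I/O."""

import numpy as np
import pytest

from gprelate.grm import (
    GenotypeMatrix,
    Grm,
    build_grm,
    me_from_grm,
    prune_relatedness,
    read_dosage_table,
    read_grm,
    target_variance_ranking,
    write_grm,
)

from conftest import make_hwe_genotypes, make_sib_families


class TestBuildGrm:
    def test_identical_individuals_have_equal_relationships(self, rng):
        row = rng.binomial(2, 0.4, size=50).astype(float)
        X = GenotypeMatrix(np.vstack([row, row, 1 - row % 2]), ["a", "b", "c"])
        G = build_grm(X)
        assert G.values[0, 1] == pytest.approx(G.values[0, 0])
        assert G.values[0, 1] == pytest.approx(G.values[1, 1])

    def test_single_snp_standardization_by_hand(self):
        # dosages {0,2} at p=0.5: Z = (d-1)/sqrt(0.5), so A_11 = 2
        X = GenotypeMatrix(np.array([[0.0], [2.0]]), ["a", "b"])
        G = build_grm(X)
        assert G.values[0, 0] == pytest.approx(2.0)
        assert G.values[0, 1] == pytest.approx(-2.0)

    def test_unrelated_hwe_off_diagonals(self, rng):
        X = make_hwe_genotypes(60, 10000, rng)
        G = build_grm(X)
        off = G.values[np.triu_indices(60, k=1)]
        # in-sample allele frequencies induce the usual -1/(n-1) offset
        assert off.mean() == pytest.approx(-1 / 59, abs=3e-3)
        assert off.var() == pytest.approx(1 / 10000, rel=0.25)
        assert np.diag(G.values).mean() == pytest.approx(1.0, abs=0.05)

    def test_variance_scales_inversely_with_snp_count(self, rng):
        ms = [500, 2000, 8000]
        vs = []
        for m in ms:
            G = build_grm(make_hwe_genotypes(80, m, rng))
            vs.append(G.values[np.triu_indices(80, k=1)].var())
        slope = np.polyfit(np.log(ms), np.log(vs), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.1)

    def test_monomorphic_snps_dropped_with_warning(self):
        dos = np.array([[0.0, 1.0], [0.0, 2.0], [0.0, 1.0]])
        with pytest.warns(RuntimeWarning):
            G = build_grm(GenotypeMatrix(dos, ["a", "b", "c"]))
        assert G.n_snps == 1

    def test_all_monomorphic_rejected(self):
        dos = np.zeros((3, 4))
        with pytest.raises(ValueError):
            build_grm(GenotypeMatrix(dos, ["a", "b", "c"]))

    def test_missing_dosages_mean_imputed(self, rng):
        X = make_hwe_genotypes(30, 200, rng)
        X.dosages[rng.random(X.dosages.shape) < 0.05] = np.nan
        G = build_grm(X)
        assert np.isfinite(G.values).all()


class TestMeFromGrm:
    def test_unrelated_individuals_recover_snp_count(self, rng):
        m = 5000
        X = make_hwe_genotypes(300, m, rng)
        G = build_grm(X)
        ids = X.individual_ids
        est, per_var = me_from_grm(G, ids[:200], ids[200:])
        assert est.value == pytest.approx(m, rel=0.15)
        assert per_var.shape == (100,)
        assert est.method == "grm_variance"

    def test_constant_block_is_undefined(self):
        G = Grm(np.ones((4, 4)) * 0.5, ["a", "b", "c", "d"])
        with pytest.raises(ValueError, match="undefined"):
            me_from_grm(G, ["a", "b"], ["c", "d"])

    def test_overlapping_sets_rejected(self, rng):
        G = build_grm(make_hwe_genotypes(10, 100, rng))
        with pytest.raises(ValueError):
            me_from_grm(G, G.individual_ids[:5], G.individual_ids[4:])

    def test_invariant_to_permutation_within_sets(self, rng):
        X = make_hwe_genotypes(40, 500, rng)
        G = build_grm(X)
        d, t = X.individual_ids[:25], X.individual_ids[25:]
        a, _ = me_from_grm(G, d, t)
        b, _ = me_from_grm(G, d[::-1], list(reversed(t)))
        assert a.value == pytest.approx(b.value, rel=1e-12)

    def test_per_target_mode_differs_from_pooled(self, rng):
        X, fams = make_sib_families(10, 4, 400, rng)
        G = build_grm(X)
        ids = X.individual_ids
        pooled, _ = me_from_grm(G, ids[:30], ids[30:], per_target=False)
        per_t, _ = me_from_grm(G, ids[:30], ids[30:], per_target=True)
        assert pooled.value > 0 and per_t.value > 0


class TestTargetVarianceRanking:
    def test_full_fraction_returns_everyone(self, rng):
        X = make_hwe_genotypes(20, 300, rng)
        G = build_grm(X)
        out = target_variance_ranking(G, X.individual_ids[:10], X.individual_ids[10:], 1.0)
        assert out == X.individual_ids[10:]

    def test_quarter_of_hundred_targets(self, rng):
        X = make_hwe_genotypes(140, 300, rng)
        G = build_grm(X)
        out = target_variance_ranking(G, X.individual_ids[:40], X.individual_ids[40:], 0.25)
        assert len(out) == 25

    def test_individual_with_sib_in_discovery_ranks_first(self, rng):
        freqs = rng.uniform(0.1, 0.9, 800)
        X, fams = make_sib_families(8, 2, 800, rng, freqs)
        ids = X.individual_ids
        # discovery: first sib of each family; targets: second sib of family 0
        # plus unrelated singletons (families 1.. second sibs removed)
        discovery = [ids[k] for k in range(0, 16, 2)]
        related_target = ids[1]  # full sib of discovery ids[0]
        unrelated = make_hwe_genotypes(5, 800, rng, freqs)
        joint = GenotypeMatrix(
            np.vstack([X.dosages, unrelated.dosages]),
            ids + [f"u{k}" for k in range(5)],
        )
        G = build_grm(joint)
        targets = [related_target] + [f"u{k}" for k in range(5)]
        top = target_variance_ranking(G, discovery, targets, 1 / 6)
        assert top == [related_target]


class TestPruneRelatedness:
    def test_nothing_above_threshold_keeps_all(self):
        A = np.eye(3) + 0.01
        G = Grm(A, ["a", "b", "c"])
        assert prune_relatedness(G, 0.5) == ["a", "b", "c"]

    def test_sib_pair_loses_one_member(self):
        G = Grm(np.array([[1.0, 0.5], [0.5, 1.0]]), ["a", "b"])
        kept = prune_relatedness(G, 0.025)
        assert len(kept) == 1

    def test_sib_pairs_among_unrelated_sample(self, rng):
        from conftest import make_hwe_genotypes

        freqs = rng.uniform(0.1, 0.9, 800)
        X, fams = make_sib_families(3, 2, 800, rng, freqs)
        U = make_hwe_genotypes(20, 800, rng, freqs)
        from gprelate.grm import GenotypeMatrix

        joint = GenotypeMatrix(
            np.vstack([X.dosages, U.dosages]),
            X.individual_ids + [f"u{k}" for k in range(20)],
        )
        G = build_grm(joint)
        kept = prune_relatedness(G, 0.2)  # well above the 1/sqrt(m) noise floor
        assert len(kept) == 23  # one member of each of the three sib pairs

    def test_three_clique_loses_two(self):
        A = np.full((4, 4), 0.0)
        np.fill_diagonal(A, 1.0)
        clique = np.ix_([0, 1, 2], [0, 1, 2])
        A[clique] = 0.3
        np.fill_diagonal(A, 1.0)
        G = Grm(A, ["a", "b", "c", "d"])
        kept = prune_relatedness(G, 0.025)
        assert len(kept) == 2 and "d" in kept


class TestGrmIO:
    def test_round_trip(self, rng, tmp_path):
        G = build_grm(make_hwe_genotypes(12, 100, rng))
        write_grm(G, tmp_path / "toy")
        back = read_grm(tmp_path / "toy")
        assert back.individual_ids == G.individual_ids
        assert back.n_snps == G.n_snps
        np.testing.assert_allclose(back.values, G.values, atol=1e-9)

    def test_two_individual_file_parses(self, tmp_path):
        (tmp_path / "t.grm").write_text("1\t1\t10\t1.0\n2\t1\t10\t0.25\n2\t2\t10\t1.0\n")
        (tmp_path / "t.grm.id").write_text("f1\ta\nf2\tb\n")
        G = read_grm(tmp_path / "t")
        assert G.values[0, 1] == pytest.approx(0.25)

    def test_malformed_row_names_line(self, tmp_path):
        (tmp_path / "t.grm").write_text("1\t1\t10\n")
        (tmp_path / "t.grm.id").write_text("f1\ta\n")
        with pytest.raises(ValueError, match="line 1"):
            read_grm(tmp_path / "t")

    def test_dosage_table_with_plink_header(self, tmp_path):
        (tmp_path / "d.raw").write_text(
            "FID IID PAT MAT SEX PHENOTYPE snp1_A snp2_C\n"
            "f1 a 0 0 1 -9 0 2\n"
            "f2 b 0 0 2 -9 1 1\n"
        )
        X = read_dosage_table(tmp_path / "d.raw")
        assert X.individual_ids == ["a", "b"]
        assert X.n_snps == 2
        np.testing.assert_array_equal(X.dosages, [[0, 2], [1, 1]])
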