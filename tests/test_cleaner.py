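import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pocketgrid.cleaner import (
    CleaningConfig,
    Cluster,
    FingerprintMatrix,
    cluster_by_uniprot,
    fingerprint_matrix,
    filter_distant_site,
    kmers,
    retain_site_chains,
    run_cleaning,
    select_representative,
    sliding_tanimoto,
    tanimoto_equal,
)
from pocketgrid.fixtures import FixtureConfig, make_cleaning_batch, make_toy_protein
from pocketgrid.structio import SiteCoords, structure_center

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestKmers:
    def test_paper_example_acdefg(self):
        assert kmers("ACDEFG") == ["ACD", "CDE", "DEF", "EFG"]

    def test_minimum_length_sequence(self):
        assert kmers("GGG") == ["GGG"]

    def test_too_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            kmers("GG")

    @settings(max_examples=60, deadline=None)
    @given(n=st.integers(min_value=3, max_value=500), seed=st.integers(0, 2**16))
    def test_count_is_n_minus_k_plus_1(self, n, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list(AA), n))
        assert len(kmers(seq)) == n - 2


class TestFingerprintMatrix:
    def test_shape_for_length_10(self):
        fp = fingerprint_matrix("ACDEFGHIKL")
        assert fp.bits.shape == (8, 167)

    @pytest.mark.parametrize("n", [3, 7, 50, 120])
    def test_row_count_tracks_sequence_length(self, n):
        rng = np.random.default_rng(n)
        seq = "".join(rng.choice(list("ACDG"), n))
        assert len(fingerprint_matrix(seq)) == n - 2

    def test_identical_sequences_bit_identical(self):
        a = fingerprint_matrix("ACDEFGIK")
        b = fingerprint_matrix("ACDEFGIK")
        assert np.array_equal(a.bits, b.bits)

    def test_ggg_row_matches_independent_tripeptide_build(self):
        """The sequence-derived fingerprint must equal the MACCS key of the
        same tripeptide assembled independently from SMILES."""
        from rdkit import Chem
        from rdkit.Chem import MACCSkeys

        fp = fingerprint_matrix("GGG")
        mol = Chem.MolFromSmiles("NCC(=O)NCC(=O)NCC(=O)O")  # Gly-Gly-Gly
        key = MACCSkeys.GenMACCSKeys(mol)
        expected = np.zeros(167, dtype=bool)
        for bit in key.GetOnBits():
            expected[bit] = True
        assert np.array_equal(fp.bits[0], expected)

    def test_unmappable_residue_names_offender(self):
        with pytest.raises(ValueError, match="AXA"):
            fingerprint_matrix("AXA")

    def test_column_count_is_fixed(self):
        with pytest.raises(ValueError):
            FingerprintMatrix(bits=np.zeros((4, 166), dtype=bool))


def _random_fp(rng, rows, density=0.25):
    return FingerprintMatrix(bits=rng.random((rows, 167)) < density)


def _brute_force_sliding(a1: FingerprintMatrix, a2: FingerprintMatrix) -> float:
    """Exhaustive-window oracle built from raw set arithmetic."""
    longer, shorter = (a1, a2) if len(a1) >= len(a2) else (a2, a1)
    w = len(shorter)
    short_bits = {
        (r, c)
        for r in range(w)
        for c in range(167)
        if shorter.bits[r, c]
    }
    best = 0.0
    for start in range(len(longer) - w + 1):
        win_bits = {
            (r, c)
            for r in range(w)
            for c in range(167)
            if longer.bits[start + r, c]
        }
        union = len(short_bits | win_bits)
        inter = len(short_bits & win_bits)
        best = max(best, 1.0 if union == 0 else inter / union)
    return best


class TestTanimoto:
    def test_self_similarity_is_one(self, rng):
        fp = _random_fp(rng, 9)
        assert tanimoto_equal(fp, fp) == 1.0
        assert sliding_tanimoto(fp, fp) == 1.0

    def test_disjoint_bits_give_zero(self):
        a = np.zeros((2, 167), dtype=bool)
        b = np.zeros((2, 167), dtype=bool)
        a[:, :10] = True
        b[:, 20:30] = True
        assert tanimoto_equal(FingerprintMatrix(a), FingerprintMatrix(b)) == 0.0

    def test_partial_overlap_set_arithmetic(self):
        a = np.zeros((1, 167), dtype=bool)
        b = np.zeros((1, 167), dtype=bool)
        a[0, [1, 2]] = True
        b[0, [2, 3]] = True
        assert tanimoto_equal(
            FingerprintMatrix(a), FingerprintMatrix(b)
        ) == pytest.approx(1 / 3)

    def test_both_empty_treated_as_identical(self):
        z = FingerprintMatrix(np.zeros((3, 167), dtype=bool))
        assert tanimoto_equal(z, z) == 1.0

    def test_unequal_lengths_rejected_by_equal_form(self, rng):
        with pytest.raises(ValueError):
            tanimoto_equal(_random_fp(rng, 3), _random_fp(rng, 5))

    def test_equal_lengths_reduce_to_equal_form(self, rng):
        a, b = _random_fp(rng, 6), _random_fp(rng, 6)
        assert sliding_tanimoto(a, b) == tanimoto_equal(a, b)

    def test_contiguous_slice_scores_one(self, rng):
        a = _random_fp(rng, 12)
        b = FingerprintMatrix(a.bits[4:9].copy())
        assert sliding_tanimoto(a, b) == 1.0

    def test_symmetry(self, rng):
        a, b = _random_fp(rng, 11), _random_fp(rng, 6)
        assert sliding_tanimoto(a, b) == sliding_tanimoto(b, a)

    def test_matches_exhaustive_window_oracle(self, rng):
        for _ in range(40):
            r1 = int(rng.integers(1, 20))
            r2 = int(rng.integers(1, 20))
            a, b = _random_fp(rng, r1), _random_fp(rng, r2)
            assert sliding_tanimoto(a, b) == pytest.approx(
                _brute_force_sliding(a, b)
            )


class TestClustering:
    def test_grouping_partition(self):
        clusters = cluster_by_uniprot(
            {"s1": "U1", "s2": "U1", "s3": "U2"},
            {"s1": "AAA", "s2": "AAAC", "s3": "GGG"},
        )
        sizes = sorted(len(c.members) for c in clusters)
        assert sizes == [1, 2]

    def test_all_distinct_ids_all_singletons(self):
        clusters = cluster_by_uniprot(
            {"a": "U1", "b": "U2", "c": "U3"},
            {"a": "AAA", "b": "CCC", "c": "GGG"},
        )
        assert all(len(c.members) == 1 for c in clusters)

    def test_tsv_mapping_file(self, tmp_path):
        tsv = tmp_path / "map.tsv"
        tsv.write_text("s1\tU9\ns2\tU9\n")
        clusters = cluster_by_uniprot(tsv, {"s1": "AAA", "s2": "AAC"})
        assert len(clusters) == 1 and clusters[0].uniprot_id == "U9"

    def test_unmapped_id_named_in_error(self):
        with pytest.raises(KeyError, match="orphan"):
            cluster_by_uniprot({"a": "U1"}, {"orphan": "AAA"})


class TestRepresentativeSelection:
    def test_singleton_cluster(self):
        rep, sim, below = select_representative(
            Cluster("U1", {"only": "ACDEF"})
        )
        assert rep == "only" and sim == 1.0 and not below

    def test_longest_sequence_wins_with_lexicographic_ties(self):
        cluster = Cluster(
            "U1",
            {"c": "G" * 50, "a": "A" * 80, "b": "C" * 80},
        )
        rep, _, _ = select_representative(cluster)
        assert rep == "a"

    def test_dissimilar_pair_sets_warning_flag(self):
        cluster = Cluster(
            "U1", {"x": "AAAAAAAAAA", "y": "WHWHWHWHWH"}
        )
        rep, sim, below = select_representative(cluster, similarity_threshold=0.8)
        assert below and sim < 0.8

    def test_near_duplicate_pair_is_similar(self):
        seq = "ACDEFGHIKLMNPQ"
        cluster = Cluster("U1", {"short": seq, "long": seq + "A"})
        _, sim, below = select_representative(cluster)
        assert sim > 0.8 and not below

    def test_order_independence(self):
        members = {"m1": "ACDAC", "m2": "ACDACG", "m3": "GGGGG"}
        r1 = select_representative(Cluster("U", dict(members)))
        r2 = select_representative(
            Cluster("U", dict(reversed(list(members.items()))))
        )
        assert r1 == r2


class TestGeometricFilters:
    def test_site_at_71_angstroms_dropped(self, toy):
        center = structure_center(toy.structure)
        site = SiteCoords(points=center[None, :] + [[71.000001, 0, 0]])
        assert filter_distant_site(toy.structure, site) == "drop"

    def test_site_at_exactly_70_kept(self, toy):
        center = structure_center(toy.structure)
        site = SiteCoords(points=center[None, :] + [[70.0, 0, 0]])
        assert filter_distant_site(toy.structure, site) == "keep"

    def test_site_at_center_kept(self, toy):
        center = structure_center(toy.structure)
        assert filter_distant_site(
            toy.structure, SiteCoords(points=center[None, :])
        ) == "keep"

    def test_contacting_chain_retained(self, toy_two_chain):
        kept = retain_site_chains(toy_two_chain.structure, toy_two_chain.site)
        assert kept.chain_ids == [toy_two_chain.site_chain]

    def test_site_touching_both_chains_keeps_both(self, toy_two_chain):
        s = toy_two_chain.structure
        a = next(a for a in s.atoms if a.chain_id == "A")
        b = next(x for x in s.atoms if x.chain_id == "B")
        site = SiteCoords(points=np.vstack([a.coords, b.coords]))
        assert retain_site_chains(s, site).chain_ids == ["A", "B"]

    def test_distant_site_flags_for_review(self, toy):
        far = SiteCoords(
            points=structure_center(toy.structure)[None, :] + [[50.0, 0, 0]]
        )
        with pytest.raises(ValueError, match="review"):
            retain_site_chains(toy.structure, far)


class TestRunCleaning:
    def test_batch_reproduces_constructed_dispositions(self, tmp_path):
        structures, sites, mapping, expected = make_cleaning_batch(
            tmp_path, seed=0
        )
        report, retained = run_cleaning(structures, sites, mapping)
        assert report.dispositions == expected
        assert set(retained) == {
            sid for sid, d in expected.items() if d == "kept"
        }

    def test_dispositions_partition_the_input(self, tmp_path):
        structures, sites, mapping, _ = make_cleaning_batch(tmp_path, seed=2)
        report, retained = run_cleaning(structures, sites, mapping)
        assert set(report.dispositions) == set(structures)
        assert set(retained) <= set(structures)

    def test_duplicate_pair_is_highly_similar(self, tmp_path):
        structures, sites, mapping, _ = make_cleaning_batch(tmp_path, seed=0)
        from pocketgrid.structio import read_structure

        seqs = {
            sid: "".join(read_structure(p).sequence.values())
            for sid, p in structures.items()
            if sid in ("dupA", "dupB")
        }
        sim = sliding_tanimoto(
            fingerprint_matrix(seqs["dupA"]), fingerprint_matrix(seqs["dupB"])
        )
        assert sim > 0.8

    def test_all_valid_singletons_all_kept(self, tmp_path):
        outdir = tmp_path / "solo"
        outdir.mkdir()
        from pocketgrid.fixtures import write_pdb
        from pocketgrid.structio import write_points_mol2

        structures, sites, mapping = {}, {}, {}
        for i in range(3):
            t = make_toy_protein(FixtureConfig(n_residues=15, seed=40 + i))
            sid = f"solo{i}"
            t.structure.id = sid
            write_pdb(t.structure, outdir / f"{sid}.pdb")
            write_points_mol2(t.site.points, outdir / f"{sid}_site.mol2")
            structures[sid] = outdir / f"{sid}.pdb"
            sites[sid] = outdir / f"{sid}_site.mol2"
            mapping[sid] = f"U{i}"
        report, retained = run_cleaning(structures, sites, mapping)
        assert all(d == "kept" for d in report.dispositions.values())
        assert len(retained) == 3

    def test_empty_input_empty_report(self):
        report, retained = run_cleaning({}, {}, {})
        assert report.dispositions == {} and retained == {}

    def test_report_dataframe_round_trip(self, tmp_path):
        structures, sites, mapping, _ = make_cleaning_batch(tmp_path, seed=1)
        report, _ = run_cleaning(structures, sites, mapping)
        df = report.to_dataframe()
        assert set(df.columns) >= {"structure_id", "disposition"}
        assert len(df) == len(structures)
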