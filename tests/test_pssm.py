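"""Matrix library I/O, PSSM synthesis and library structure analysis."""

import numpy as np
import pytest

from pocketpan import (
    POCKET_IDS,
    AlleleRecord,
    MatrixLibrary,
    PSSM,
    SimilarityConfig,
    count_unique_vectors,
    load_library,
    save_library,
    synthesize_pssm,
)
from pocketpan.pssm import DEFAULT_UNUSED_POCKETS, save_pssm_tsv


def make_library(n=3, seed=0, mask=frozenset()):
    rng = np.random.default_rng(seed)
    pssms = []
    for k in range(n):
        matrix = rng.normal(size=(9, 20))
        for pocket in mask:
            matrix[POCKET_IDS.index(pocket)] = 0.0
        pssms.append(PSSM(f"DRB1*92:{k + 1:02d}", matrix, mask))
    return MatrixLibrary(tuple(pssms), mask)


class TestLibraryIO:
    def test_round_trip(self, tmp_path):
        library = make_library(mask=DEFAULT_UNUSED_POCKETS)
        path = tmp_path / "library.tsv"
        save_library(library, path)
        loaded = load_library(path)
        assert loaded.alleles == library.alleles
        assert loaded.unused_pockets == DEFAULT_UNUSED_POCKETS
        for a, b in zip(loaded.pssms, library.pssms):
            np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_round_trip_without_mask(self, tmp_path):
        library = make_library(mask=frozenset())
        path = tmp_path / "library.tsv"
        save_library(library, path)
        assert load_library(path).unused_pockets == frozenset()

    def test_single_zero_allele(self, tmp_path):
        library = MatrixLibrary(
            (PSSM("DRB1*92:01", np.zeros((9, 20)), frozenset()),), frozenset()
        )
        path = tmp_path / "zeros.tsv"
        save_library(library, path)
        loaded = load_library(path)
        assert len(loaded) == 1
        np.testing.assert_array_equal(loaded.pssms[0].matrix, 0.0)

    def test_eleven_allele_library_reports_eleven(self, tmp_path):
        path = tmp_path / "eleven.tsv"
        save_library(make_library(11), path)
        assert len(load_library(path)) == 11

    def test_wrong_arity_rejected_with_line_number(self, tmp_path):
        library = make_library(1)
        path = tmp_path / "bad.tsv"
        save_library(library, path)
        lines = path.read_text().splitlines()
        lines[1] = "\t".join(lines[1].split("\t")[:-1])  # drop one value
        path.write_text("\n".join(lines))
        with pytest.raises(ValueError, match=":2"):
            load_library(path)

    def test_malformed_number_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        save_library(make_library(1), path)
        path.write_text(path.read_text().replace("\t", "\tnot_a_number\t", 1))
        with pytest.raises(ValueError):
            load_library(path)

    def test_duplicate_pocket_rejected(self, tmp_path):
        path = tmp_path / "dup.tsv"
        save_library(make_library(1), path)
        lines = path.read_text().splitlines()
        lines.append(lines[1])
        path.write_text("\n".join(lines))
        with pytest.raises(ValueError, match="duplicate"):
            load_library(path)

    def test_pssm_tsv_export(self, tmp_path):
        pssm = make_library(1).pssms[0]
        path = tmp_path / "one.tsv"
        save_pssm_tsv(pssm, path)
        lines = path.read_text().splitlines()
        assert len(lines) == 10 and lines[1].startswith("P1\t")


class TestLibraryInvariants:
    def test_duplicate_allele_rejected(self):
        pssm = PSSM("DRB1*92:01", np.zeros((9, 20)), frozenset())
        with pytest.raises(ValueError, match="duplicate"):
            MatrixLibrary((pssm, pssm), frozenset())

    def test_mask_mismatch_rejected(self):
        a = PSSM("DRB1*92:01", np.zeros((9, 20)), frozenset())
        b = PSSM("DRB1*92:02", np.zeros((9, 20)), DEFAULT_UNUSED_POCKETS)
        with pytest.raises(ValueError, match="mask"):
            MatrixLibrary((a, b), frozenset())

    def test_masked_pocket_must_be_zero(self):
        with pytest.raises(ValueError, match="P[58]"):
            PSSM("DRB1*92:01", np.ones((9, 20)), DEFAULT_UNUSED_POCKETS)


class TestSynthesizePssm:
    def test_single_allele_library_is_copied(self, distinct_library):
        library, records, pseqs = distinct_library
        one = MatrixLibrary((library.pssms[0],), frozenset())
        for alpha in (1.0, 9.0, 100.0):
            query = AlleleRecord("DRB1*93:01", records[1].sequence)
            pssm, _ = synthesize_pssm(
                query, one, pseqs, SimilarityConfig(alpha=alpha)
            )
            np.testing.assert_allclose(pssm.matrix, library.pssms[0].matrix)

    def test_equal_weights_give_arithmetic_mean(self, blosum62):
        """A query equidistant from two alleles averages their matrices."""
        from .conftest import make_allele

        rng = np.random.default_rng(3)
        a = PSSM("DRB1*92:01", rng.normal(size=(9, 20)), frozenset())
        b = PSSM("DRB1*92:02", rng.normal(size=(9, 20)), frozenset())
        library = MatrixLibrary((a, b), frozenset())
        from pocketpan import extract_pseudosequences

        pseqs = {
            "DRB1*92:01": extract_pseudosequences(make_allele("DRB1*92:01", "C")),
            "DRB1*92:02": extract_pseudosequences(make_allele("DRB1*92:02", "C")),
        }
        query = make_allele("DRB1*93:01", "A")
        pssm, profile = synthesize_pssm(query, library, pseqs)
        assert np.allclose(profile.weight.to_numpy(), 0.5)
        np.testing.assert_allclose(pssm.matrix, (a.matrix + b.matrix) / 2)

    def test_knn_limit_copies_most_similar_matrix(self, distinct_library):
        """Query identical in pseudosequence to one allele, huge alpha:
        the synthesized PSSM equals that allele's matrix to 1e-6."""
        library, records, pseqs = distinct_library
        target = records[2]
        query = AlleleRecord("DRB1*93:01", target.sequence)
        pssm, _ = synthesize_pssm(
            query, library, pseqs, SimilarityConfig(alpha=1000.0)
        )
        np.testing.assert_allclose(
            pssm.matrix, library.get(target.name).matrix, atol=1e-6
        )

    def test_explicit_knn_mode_matches_limit(self, distinct_library):
        library, records, pseqs = distinct_library
        query = AlleleRecord("DRB1*93:01", records[2].sequence)
        limit, _ = synthesize_pssm(
            query, library, pseqs, SimilarityConfig(alpha=1000.0)
        )
        knn, _ = synthesize_pssm(query, library, pseqs, mode="1-knn")
        np.testing.assert_allclose(knn.matrix, limit.matrix, atol=1e-6)

    def test_convexity(self, distinct_library):
        """Synthesized entries stay within the library's per-entry range."""
        library, records, pseqs = distinct_library
        query = AlleleRecord("DRB1*93:01", records[0].sequence)
        for alpha in (1.0, 9.0):
            pssm, _ = synthesize_pssm(
                query, library, pseqs, SimilarityConfig(alpha=alpha)
            )
            stack = np.stack([p.matrix for p in library.pssms])
            assert np.all(pssm.matrix >= stack.min(axis=0) - 1e-12)
            assert np.all(pssm.matrix <= stack.max(axis=0) + 1e-12)

    def test_linearity_in_library_scale(self, distinct_library):
        library, records, pseqs = distinct_library
        query = AlleleRecord("DRB1*93:01", records[1].sequence)
        base, _ = synthesize_pssm(query, library, pseqs)
        scaled_lib = MatrixLibrary(
            tuple(
                PSSM(p.allele, 3.0 * p.matrix, p.unused_pockets)
                for p in library.pssms
            ),
            library.unused_pockets,
        )
        scaled, _ = synthesize_pssm(query, scaled_lib, pseqs)
        np.testing.assert_allclose(scaled.matrix, 3.0 * base.matrix, rtol=1e-10)

    def test_continuity_in_alpha(self, distinct_library):
        library, records, pseqs = distinct_library
        query = AlleleRecord("DRB1*93:01", records[3].sequence)

        def max_step(grid):
            matrices = [
                synthesize_pssm(
                    query, library, pseqs, SimilarityConfig(alpha=a)
                )[0].matrix
                for a in grid
            ]
            return max(np.abs(b - a).max() for a, b in zip(matrices, matrices[1:]))

        # refining the alpha grid shrinks the largest jump roughly in
        # proportion -- the synthesis is continuous in alpha, not stepped
        coarse = max_step(np.linspace(1.0, 20.0, 20))
        fine = max_step(np.linspace(1.0, 20.0, 77))
        assert fine < 0.5 * coarse

    def test_masked_pockets_stay_zero(self, tmp_path):
        from .conftest import make_allele
        from pocketpan import extract_pseudosequences

        library = make_library(3, mask=DEFAULT_UNUSED_POCKETS)
        pseqs = {
            name: extract_pseudosequences(make_allele(name, "C"))
            for name in library.alleles
        }
        pssm, _ = synthesize_pssm(make_allele("DRB1*93:01", "A"), library, pseqs)
        assert pssm.unused_pockets == DEFAULT_UNUSED_POCKETS
        for pocket in DEFAULT_UNUSED_POCKETS:
            assert np.all(pssm.matrix[POCKET_IDS.index(pocket)] == 0.0)


class TestCountUniqueVectors:
    def test_distinct_vectors_unmasked(self):
        count, _ = count_unique_vectors(make_library(1))
        assert count == 9

    def test_identical_alleles_fully_share(self):
        base = make_library(1)
        twin = MatrixLibrary(
            (base.pssms[0], PSSM("DRB1*92:99", base.pssms[0].matrix, frozenset())),
            frozenset(),
        )
        count, sharing = count_unique_vectors(twin)
        assert count == 9
        assert all(len(owners) == 2 for owners in sharing.values())

    def test_mask_excludes_pockets(self):
        count, _ = count_unique_vectors(make_library(2, mask=DEFAULT_UNUSED_POCKETS))
        assert count == 2 * 7  # nine pockets minus the two masked, per allele

    def test_partial_sharing_counted_once(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=(9, 20))
        b = a.copy()
        b[3] = rng.normal(size=20)  # alleles share all pockets except P4
        library = MatrixLibrary(
            (
                PSSM("DRB1*92:01", a, frozenset()),
                PSSM("DRB1*92:02", b, frozenset()),
            ),
            frozenset(),
        )
        count, _ = count_unique_vectors(library)
        assert count == 10
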