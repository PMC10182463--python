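"""Co-occurrence counting, log normalization and SVD space construction."""

import math

import numpy as np
import pytest
import scipy.linalg
from hypothesis import given, settings, strategies as st

from semscale.space import (
    CooccurrenceMatrix,
    NGramParseError,
    NGramRecord,
    SemanticSpace,
    SpaceConfig,
    build_space,
    count_cooccurrences,
    normalize_counts,
    read_ngram_counts,
    write_ngram_counts,
)


def gram(text, count=1):
    return NGramRecord(tokens=tuple(text.split()), count=count)


def brute_force_cooccurrence(records, window):
    """Independent oracle: iterate every (gram, i, j) position pair."""
    cells = {}
    for rec in records:
        if rec.count == 0:
            continue
        n = len(rec.tokens)
        for i in range(n):
            for j in range(n):
                if i != j and abs(i - j) <= window:
                    key = (rec.tokens[i], rec.tokens[j])
                    cells[key] = cells.get(key, 0) + rec.count
    return cells


def as_dict(matrix):
    out = {}
    for i, rw in enumerate(matrix.row_vocab):
        for j, cw in enumerate(matrix.col_vocab):
            if matrix.cells[i, j]:
                out[(rw, cw)] = matrix.cells[i, j]
    return out


class TestReadNgramCounts:
    def test_parses_tokens_and_count(self, tmp_path):
        path = tmp_path / "c.ngrams"
        path.write_text("a b c d e\t3\n")
        (rec,) = list(read_ngram_counts(path, n=5))
        assert rec.tokens == ("a", "b", "c", "d", "e")
        assert rec.count == 3

    def test_empty_file_yields_empty_stream(self, tmp_path):
        path = tmp_path / "c.ngrams"
        path.write_text("")
        assert list(read_ngram_counts(path, n=5)) == []

    @pytest.mark.parametrize(
        "line",
        ["a b c d\t1", "a b c d e 1", "a b c d e\tx", "a b c d e\t-2"],
        ids=["short", "no-tab", "bad-count", "negative"],
    )
    def test_malformed_line_names_line_number(self, tmp_path, line):
        path = tmp_path / "c.ngrams"
        path.write_text("a b c d e\t1\n" + line + "\n")
        with pytest.raises(NGramParseError, match=":2"):
            list(read_ngram_counts(path, n=5))

    def test_lowercases_tokens(self, tmp_path):
        path = tmp_path / "c.ngrams"
        path.write_text("A b C d E\t1\n")
        (rec,) = list(read_ngram_counts(path, n=5))
        assert rec.tokens == ("a", "b", "c", "d", "e")

    def test_round_trip(self, tmp_path):
        records = [gram("a b c d e", 2), gram("f g h i j", 5)]
        path = write_ngram_counts(records, tmp_path / "out.ngrams")
        assert list(read_ngram_counts(path, n=5)) == records


class TestCountCooccurrences:
    def test_single_gram_full_window(self):
        m = count_cooccurrences([gram("a b c d e")], SpaceConfig(window=4))
        assert m.cell("a", "b") == 1
        assert m.cell("a", "e") == 1
        assert m.cell("a", "a") == 0
        assert not m.normalized

    def test_single_gram_window_one(self):
        m = count_cooccurrences([gram("a b c d e")], SpaceConfig(window=1))
        assert m.cell("a", "c") == 0
        assert m.cell("a", "b") == 1

    def test_three_grams_match_brute_force(self):
        records = [gram("a b c a e", 1), gram("b b d e a", 2), gram("c a a b d", 1)]
        config = SpaceConfig(window=3)
        assert as_dict(count_cooccurrences(records, config)) == pytest.approx(
            brute_force_cooccurrence(records, window=3)
        )

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        grams=st.lists(
            st.tuples(
                st.lists(st.sampled_from("abcdefgh"), min_size=5, max_size=5),
                st.integers(min_value=0, max_value=3),
            ),
            min_size=1,
            max_size=50,
        ),
        window=st.integers(min_value=1, max_value=4),
    )
    def test_equals_brute_force_oracle(self, grams, window):
        records = [NGramRecord(tokens=tuple(t), count=c) for t, c in grams]
        config = SpaceConfig(window=window)
        assert as_dict(count_cooccurrences(records, config)) == pytest.approx(
            brute_force_cooccurrence(records, window)
        )

    def test_counting_is_additive_over_corpora(self):
        rng = np.random.default_rng(7)
        alphabet = list("abcdef")
        corpus_a = [
            NGramRecord(tuple(rng.choice(alphabet, 5)), int(rng.integers(1, 4)))
            for _ in range(12)
        ]
        corpus_b = [
            NGramRecord(tuple(rng.choice(alphabet, 5)), int(rng.integers(1, 4)))
            for _ in range(9)
        ]
        config = SpaceConfig(window=4)
        union = as_dict(count_cooccurrences(corpus_a + corpus_b, config))
        part_a = as_dict(count_cooccurrences(corpus_a, config))
        part_b = as_dict(count_cooccurrences(corpus_b, config))
        summed = {k: part_a.get(k, 0) + part_b.get(k, 0) for k in set(part_a) | set(part_b)}
        assert union == pytest.approx(summed)

    def test_vocabulary_ranked_by_frequency_then_lexical(self):
        records = [gram("b b b a a", 1), gram("c c c a a", 1)]
        m = count_cooccurrences(records, SpaceConfig(window=4, n_row_words=2, n_dims=2))
        # a appears 4x; b and c 3x each, tie broken lexicographically
        assert m.row_vocab == ["a", "b"]

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            count_cooccurrences([], SpaceConfig())


class TestNormalizeCounts:
    def test_log1p_closed_forms(self):
        m = CooccurrenceMatrix(["a"], ["b", "c"], np.array([[0.0, math.e - 1]]))
        out = normalize_counts(m, SpaceConfig())
        assert out.cells[0, 0] == 0.0
        assert out.cells[0, 1] == pytest.approx(1.0)
        assert out.normalized

    def test_matches_scalar_log_oracle(self):
        rng = np.random.default_rng(1)
        cells = rng.integers(0, 20, size=(4, 4)).astype(float)
        m = CooccurrenceMatrix(list("abcd"), list("wxyz"), cells)
        out = normalize_counts(m, SpaceConfig())
        for i in range(4):
            for j in range(4):
                assert out.cells[i, j] == pytest.approx(math.log(cells[i, j] + 1))

    def test_base10_option(self):
        m = CooccurrenceMatrix(["a"], ["b"], np.array([[9.0]]))
        out = normalize_counts(m, SpaceConfig(log_base="base10"))
        assert out.cells[0, 0] == pytest.approx(1.0)

    def test_double_normalization_rejected(self):
        m = CooccurrenceMatrix(["a"], ["b"], np.array([[2.0]]))
        out = normalize_counts(m, SpaceConfig())
        with pytest.raises(ValueError, match="already"):
            normalize_counts(out, SpaceConfig())


class TestBuildSpace:
    def test_identity_input_gives_orthonormal_rows(self):
        m = CooccurrenceMatrix(
            list("abcd"), list("wxyz"), np.eye(4), normalized=True
        )
        space = build_space(m, SpaceConfig(n_dims=4))
        assert np.allclose(space.embeddings @ space.embeddings.T, np.eye(4), atol=1e-9)

    def test_unit_row_norms(self):
        rng = np.random.default_rng(3)
        m = CooccurrenceMatrix(
            [f"w{i}" for i in range(6)],
            [f"c{j}" for j in range(5)],
            rng.random((6, 5)),
            normalized=True,
        )
        space = build_space(m, SpaceConfig(n_dims=3))
        assert np.allclose(np.linalg.norm(space.embeddings, axis=1), 1.0, atol=1e-9)
        assert np.all(np.diff(space.singular_values) <= 1e-12)

    def test_rank2_truncation_is_optimal(self):
        rng = np.random.default_rng(5)
        cells = rng.random((6, 4))
        m = CooccurrenceMatrix(
            [f"w{i}" for i in range(6)], [f"c{j}" for j in range(4)], cells,
            normalized=True,
        )
        # oracle: full dense SVD; the embedding rows must equal the
        # row-normalized optimal rank-2 factor U S (Eckart-Young), up to
        # the per-column sign indeterminacy of singular vectors
        u, s, vt = scipy.linalg.svd(cells, full_matrices=False)
        space = build_space(m, SpaceConfig(n_dims=2))
        assert space.singular_values == pytest.approx(s[:2])
        us = u[:, :2] * s[:2]
        us /= np.linalg.norm(us, axis=1, keepdims=True)
        assert np.abs(space.embeddings) == pytest.approx(np.abs(us), abs=1e-9)

    def test_truncation_error_non_increasing_in_k(self):
        rng = np.random.default_rng(11)
        cells = rng.random((8, 6))
        u, s, vt = scipy.linalg.svd(cells, full_matrices=False)
        errors = [
            np.linalg.norm(cells - (u[:, :k] * s[:k]) @ vt[:k]) for k in range(1, 7)
        ]
        spaces = [
            build_space(
                CooccurrenceMatrix(
                    [f"w{i}" for i in range(8)],
                    [f"c{j}" for j in range(6)],
                    cells,
                    normalized=True,
                ),
                SpaceConfig(n_dims=k),
            )
            for k in range(1, 7)
        ]
        assert all(e2 <= e1 + 1e-12 for e1, e2 in zip(errors, errors[1:]))
        # retained singular values are prefixes of the same spectrum
        for k, space in enumerate(spaces, start=1):
            assert space.singular_values == pytest.approx(s[:k])

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(9)
        cells = rng.random((7, 7))
        m = lambda: CooccurrenceMatrix(
            [f"w{i}" for i in range(7)], [f"c{j}" for j in range(7)], cells.copy(),
            normalized=True,
        )
        s1 = build_space(m(), SpaceConfig(n_dims=4))
        s2 = build_space(m(), SpaceConfig(n_dims=4))
        assert np.array_equal(s1.embeddings, s2.embeddings)
        # the documented rule (largest-magnitude entry of each singular
        # vector made positive, then rows normalized) reproduces the output
        u, s, _vt = scipy.linalg.svd(cells, full_matrices=False)
        u = u[:, :4]
        flip = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(4)])
        us = (u * flip) * s[:4]
        us /= np.linalg.norm(us, axis=1, keepdims=True)
        assert s1.embeddings == pytest.approx(us, abs=1e-12)

    def test_unnormalized_input_rejected(self):
        m = CooccurrenceMatrix(["a"], ["b"], np.array([[2.0]]), normalized=False)
        with pytest.raises(ValueError, match="normalized"):
            build_space(m, SpaceConfig(n_dims=1))

    def test_n_dims_beyond_rank_errors_with_rank(self):
        cells = np.outer(np.ones(4), np.arange(1.0, 5.0))  # rank 1
        m = CooccurrenceMatrix(
            list("abcd"), list("wxyz"), cells, normalized=True
        )
        with pytest.raises(ValueError, match="rank 1"):
            build_space(m, SpaceConfig(n_dims=3))

    def test_default_config_keeps_512_dimensions(self):
        assert SpaceConfig().n_dims == 512
        assert SpaceConfig().window == 4


class TestPersistence:
    def test_space_round_trip_is_exact(self, tmp_path):
        rng = np.random.default_rng(13)
        m = CooccurrenceMatrix(
            [f"w{i}" for i in range(5)],
            [f"c{j}" for j in range(5)],
            rng.random((5, 5)),
            normalized=True,
        )
        config = SpaceConfig(n_dims=3, window=2)
        space = build_space(m, config)
        space.save(tmp_path / "space", config)
        loaded = SemanticSpace.load(tmp_path / "space")
        assert loaded.vocab == space.vocab
        assert np.array_equal(loaded.embeddings, space.embeddings)
        assert np.array_equal(loaded.singular_values, space.singular_values)
        assert SemanticSpace.load_config(tmp_path / "space") == config
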