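"""Contact-matrix operations against brute-force oracles."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fivec.matrix import (
    ContactMatrix,
    bin_matrix,
    build,
    differential,
    normalize,
    read_matrix_tsv,
    replicate_agreement,
    smooth,
    write_matrix_tsv,
)
from fivec.reads import InteractionRecord
from fivec.regions import GenomicInterval


def random_matrix(rng, n_rows=6, n_cols=6, frag_len=5_000, missing=0.1,
                  state="normalized"):
    """Random matrix on irregular genomic axes, with missing cells."""
    def axis(n):
        starts = np.sort(rng.integers(0, 200_000, size=n))
        return [GenomicInterval("chrS", int(s) + 3 * i, int(s) + 3 * i + frag_len + int(rng.integers(0, 2_000)))
                for i, s in enumerate(starts)]

    rows = axis(n_rows)
    cols = axis(n_cols)
    values = rng.uniform(0, 5, size=(n_rows, n_cols))
    values[rng.random((n_rows, n_cols)) < missing] = np.nan
    return ContactMatrix(rows, cols, [f"r{i}" for i in range(n_rows)],
                         [f"c{j}" for j in range(n_cols)], values, state)


def brute_force_bin(matrix, bin_size):
    """Oracle: exhaustive midpoint assignment and per-bin-pair mean."""
    ivs = matrix.row_intervals + matrix.col_intervals
    origin = min(iv.start for iv in ivs)
    end = max(iv.end for iv in ivs)
    n_bins = max(1, -(-(end - origin) // bin_size))

    def bin_of(iv):
        return min(n_bins - 1, int((iv.midpoint - origin) // bin_size))

    out = np.full((n_bins, n_bins), np.nan)
    for bi in range(n_bins):
        for bj in range(n_bins):
            cells = []
            for i, riv in enumerate(matrix.row_intervals):
                for j, civ in enumerate(matrix.col_intervals):
                    if bin_of(riv) == bi and bin_of(civ) == bj:
                        v = matrix.values[i, j]
                        if not np.isnan(v):
                            cells.append(v)
            if cells:
                total = 0.0
                for v in cells:
                    total += v
                out[bi, bj] = total / len(cells)
    return out


def brute_force_smooth(matrix, window):
    """Oracle: direct double loop over neighbourhood means."""
    rmid = [iv.midpoint for iv in matrix.row_intervals]
    cmid = [iv.midpoint for iv in matrix.col_intervals]
    half = window / 2.0
    n, m = matrix.values.shape
    out = np.full((n, m), np.nan)
    for i in range(n):
        for j in range(m):
            cells = []
            for a in range(n):
                for b in range(m):
                    if abs(rmid[a] - rmid[i]) <= half and abs(cmid[b] - cmid[j]) <= half:
                        v = matrix.values[a, b]
                        if not np.isnan(v):
                            cells.append(v)
            if cells:
                total = 0.0
                for v in cells:
                    total += v
                out[i, j] = total / len(cells)
    return out


@pytest.fixture()
def small_design():
    """2 forward x 2 reverse design over four 1 kb fragments."""
    from fivec.design import design_primers
    from fivec.regions import ECORI_SITE, digest, filter_fragments

    body = "ACGTGGCCTTAACCGGTTGGCCAATTGGCC"
    unit = ECORI_SITE + (body * 40)[: 994]
    seq = ("ACGT" + (unit * 4)[4:])
    frags = filter_fragments(digest(seq, seq_name="chrS"))
    design = design_primers(frags, seq, "alternating")
    return design, frags


class TestBuild:
    def test_empty_records_give_zero_matrix(self, small_design):
        design, frags = small_design
        m = build([], design, frags)
        assert m.state == "raw"
        assert m.shape == (2, 2)
        assert np.all(m.values == 0)

    def test_counts_land_in_cells(self, small_design):
        design, frags = small_design
        fwd = design.forward_primers[0].primer_id
        rev = design.reverse_primers[0].primer_id
        m = build([InteractionRecord(fwd, rev, 3)], design, frags)
        assert m.values.sum() == 3

    def test_unknown_primer_is_error(self, small_design):
        design, frags = small_design
        with pytest.raises(KeyError):
            build([InteractionRecord("F999", "R999", 1)], design, frags)

    def test_primerless_fragments_have_no_axis_entry(self, small_design):
        design, frags = small_design
        m = build([], design, frags)
        covered = {p.fragment_index for p in design.primers}
        assert len(m.row_ids) + len(m.col_ids) == len(covered)


class TestNormalize:
    def test_per_thousand_formula(self, small_design):
        design, frags = small_design
        fwd = design.forward_primers[0].primer_id
        rev = design.reverse_primers[0].primer_id
        m = build([InteractionRecord(fwd, rev, 5)], design, frags)
        norm = normalize(m, 10_000)
        assert norm.values.max() == pytest.approx(0.5)
        assert norm.state == "normalized"

    def test_scale_invariance(self, small_design):
        design, frags = small_design
        fwd = design.forward_primers[0].primer_id
        rev = design.reverse_primers[0].primer_id
        a = normalize(build([InteractionRecord(fwd, rev, 5)], design, frags), 1_000)
        b = normalize(build([InteractionRecord(fwd, rev, 10)], design, frags), 2_000)
        np.testing.assert_array_equal(a.values, b.values)

    @given(st.integers(1, 10**7))
    def test_conservation(self, total):
        g = np.random.default_rng(total)
        raw = ContactMatrix(
            [GenomicInterval("c", 0, 10)], [GenomicInterval("c", 20, 30)],
            ["r0"], ["c0"],
            g.integers(0, 1000, size=(1, 1)).astype(float), "raw",
        )
        norm = normalize(raw, total)
        assert norm.values.sum() * total / 1000.0 == pytest.approx(raw.values.sum(), rel=1e-9)

    def test_zero_total_is_error(self, small_design):
        design, frags = small_design
        with pytest.raises(ValueError):
            normalize(build([], design, frags), 0)


class TestBinAndSmooth:
    def test_two_pairs_in_one_bin_average(self, rng):
        m = ContactMatrix(
            [GenomicInterval("c", 0, 1_000), GenomicInterval("c", 1_000, 2_000)],
            [GenomicInterval("c", 2_000, 3_000)],
            ["r0", "r1"], ["c0"],
            np.array([[1.0], [3.0]]), "normalized",
        )
        binned = bin_matrix(m, 20_000)
        assert binned.values[0, 0] == pytest.approx(2.0)

    def test_bin_matches_oracle_on_random_matrices(self, rng):
        for k in range(50):
            m = random_matrix(rng, n_rows=int(rng.integers(2, 10)),
                              n_cols=int(rng.integers(2, 10)))
            got = bin_matrix(m, 20_000).values
            want = brute_force_bin(m, 20_000)
            np.testing.assert_allclose(got, want, rtol=1e-12, equal_nan=True)

    def test_smooth_matches_oracle_on_random_matrices(self, rng):
        for k in range(50):
            m = random_matrix(rng, n_rows=6, n_cols=6)
            got = smooth(m, 8_000).values
            want = brute_force_smooth(m, 8_000)
            np.testing.assert_allclose(got, want, rtol=1e-12, equal_nan=True)

    def test_constant_matrix_unchanged_by_smoothing(self, rng):
        m = random_matrix(rng, missing=0.0)
        m.values[:] = 2.5
        np.testing.assert_allclose(smooth(m, 50_000).values, 2.5)

    def test_tiny_window_is_identity(self, rng):
        m = random_matrix(rng, missing=0.0)
        np.testing.assert_array_equal(smooth(m, 1).values, m.values)

    def test_means_stay_in_input_range(self, rng):
        m = random_matrix(rng, missing=0.2)
        lo, hi = np.nanmin(m.values), np.nanmax(m.values)
        for out in (bin_matrix(m, 15_000).values, smooth(m, 30_000).values):
            vals = out[~np.isnan(out)]
            assert vals.min() >= lo - 1e-12 and vals.max() <= hi + 1e-12

    def test_bad_sizes_are_errors(self, rng):
        m = random_matrix(rng)
        with pytest.raises(ValueError):
            bin_matrix(m, 0)
        with pytest.raises(ValueError):
            smooth(m, -5)


class TestDifferential:
    def test_self_difference_is_zero(self, rng):
        a = random_matrix(rng)
        d = differential(a, a)
        assert d.state == "differential"
        vals = d.values[~np.isnan(d.values)]
        np.testing.assert_array_equal(vals, 0.0)

    def test_antisymmetry(self, rng):
        a = random_matrix(rng)
        b = a.copy_with(np.asarray(random_matrix(rng).values), "normalized")
        ab = differential(a, b).values
        ba = differential(b, a).values
        np.testing.assert_allclose(ab, -ba, equal_nan=True)

    def test_missing_propagates(self, rng):
        a = random_matrix(rng, missing=0.3)
        b = a.copy_with(np.nan_to_num(a.values), "normalized")
        d = differential(a, b)
        assert np.isnan(d.values).sum() == np.isnan(a.values).sum()

    def test_axis_and_state_mismatch_are_errors(self, rng):
        a = random_matrix(rng, n_rows=4)
        b = random_matrix(rng, n_rows=5)
        with pytest.raises(ValueError):
            differential(a, b)
        raw = a.copy_with(a.values, "raw")
        with pytest.raises(ValueError):
            differential(raw, raw)


class TestReplicateAgreement:
    def test_identity_correlates_perfectly(self, rng):
        a = random_matrix(rng, missing=0.0)
        assert replicate_agreement(a, a) == pytest.approx(1.0)

    def test_permuted_replicate_decorrelates(self, rng):
        a = random_matrix(rng, n_rows=20, n_cols=20, missing=0.0)
        shuffled = a.values.ravel().copy()
        rng.shuffle(shuffled)
        b = a.copy_with(shuffled.reshape(a.values.shape), "normalized")
        assert abs(replicate_agreement(a, b)) < 0.25

    def test_multinomial_resamples_agree(self, rng):
        p = rng.dirichlet(np.ones(400))
        rows = [GenomicInterval("c", 1000 * i, 1000 * i + 900) for i in range(20)]
        reps = []
        for seed in (5, 6):
            counts = np.random.default_rng(seed).multinomial(100_000, p)
            m = ContactMatrix(rows, list(rows), [f"r{i}" for i in range(20)],
                              [f"r{i}" for i in range(20)],
                              counts.reshape(20, 20) * 1000.0 / 100_000, "normalized")
            reps.append(m)
        assert replicate_agreement(*reps) > 0.9

    def test_too_few_shared_cells_is_error(self, rng):
        a = random_matrix(rng, n_rows=2, n_cols=1, missing=0.0)
        b = a.copy_with(a.values.copy(), "normalized")
        with pytest.raises(ValueError):
            replicate_agreement(a, b)


def test_matrix_tsv_round_trip(tmp_path, rng):
    m = random_matrix(rng, missing=0.15)
    m.total_run_reads = 123_456
    path = tmp_path / "matrix.tsv"
    write_matrix_tsv(m, path)
    back = read_matrix_tsv(path)
    assert back.state == m.state
    assert back.total_run_reads == m.total_run_reads
    assert back.row_ids == m.row_ids and back.col_ids == m.col_ids
    assert back.row_intervals == m.row_intervals
    np.testing.assert_allclose(back.values, m.values, rtol=1e-5, equal_nan=True)
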