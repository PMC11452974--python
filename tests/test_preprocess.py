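"""Quality filters and the total-abundance / IRS / TMM normalization stack."""

import math

import numpy as np
import pytest

from itsakit import (
    apply_factors,
    apply_normalization_pipeline,
    filter_proteins,
    irs_normalize,
    tmm_factors,
    total_abundance_normalize,
)
from itsakit.design import ChannelDesign

from conftest import make_table, small_design


def reference_tmm(mat, labels, trim_m=0.30, trim_a=0.05):
    """Independent plain-Python trimmed-mean-of-M re-implementation.

    Same conventions (upper-quartile reference, double trim, precision
    weights, geometric-mean-1 rescaling) coded from the definition with
    sorting loops instead of array operations.
    """
    n_chan = len(labels)
    uqs = [float(np.percentile(mat[:, j], 75)) for j in range(n_chan)]
    mean_uq = sum(uqs) / n_chan
    ref = min(range(n_chan), key=lambda j: (abs(uqs[j] - mean_uq), j))
    raw = []
    for j in range(n_chan):
        if j == ref:
            raw.append(1.0)
            continue
        ms, as_, ws = [], [], []
        for i in range(mat.shape[0]):
            x, r = mat[i, j], mat[i, ref]
            ms.append(math.log2(x / r))
            as_.append(0.5 * math.log2(x * r))
            ws.append(1.0 / (1.0 / x + 1.0 / r))
        n = len(ms)

        def keep_indices(values, trim):
            cut = int(math.floor(n * trim))
            order = sorted(range(n), key=lambda i: values[i])
            return set(order[cut : n - cut])

        keep = keep_indices(ms, trim_m) & keep_indices(as_, trim_a)
        num = sum(ws[i] * ms[i] for i in keep)
        den = sum(ws[i] for i in keep)
        raw.append(2.0 ** (num / den))
    log_gm = sum(math.log(f) for f in raw) / n_chan
    return [f / math.exp(log_gm) for f in raw]


class TestFilter:
    def test_pep_boundary_is_inclusive(self):
        table = make_table(
            np.full((2, 4), 10.0), pep=np.array([4.9, 5.0])
        )
        out, report = filter_proteins(table)
        assert list(out.accessions) == ["P0001"]
        assert report.dropped == (("P0000", "pep"),)

    def test_empty_table_all_counts_zero(self):
        table = make_table(np.empty((0, 4)))
        out, report = filter_proteins(table)
        assert len(out) == 0
        assert (report.n_input, report.n_after_missing) == (0, 0)

    def test_missing_value_rows_deleted(self):
        mat = np.full((3, 4), 5.0)
        mat[1, 2] = np.nan
        out, report = filter_proteins(make_table(mat))
        assert list(out.accessions) == ["P0000", "P0002"]
        assert ("P0001", "missing") in report.dropped

    def test_random_table_matches_row_by_row_recheck(self, rng):
        n = 50
        mat = rng.lognormal(3, 1, size=(n, 4))
        mat[rng.random((n, 4)) < 0.1] = np.nan
        pep = rng.uniform(0, 15, n)
        uniq = rng.integers(0, 4, n)
        table = make_table(mat, pep=pep, unique=uniq)
        out, report = filter_proteins(table, min_sum_pep=5, min_unique=1)
        expected = [
            f"P{i:04d}"
            for i in range(n)
            if pep[i] >= 5 and uniq[i] >= 1 and not np.isnan(mat[i]).any()
        ]
        assert list(out.accessions) == expected
        assert report.n_after_missing == len(expected)
        assert report.n_input - len(report.dropped) == len(expected)

    def test_output_is_ordered_subset(self, rng):
        mat = rng.lognormal(3, 1, size=(30, 4))
        pep = rng.uniform(0, 10, 30)
        table = make_table(mat, pep=pep)
        out, _ = filter_proteins(table)
        idx = [list(table.accessions).index(a) for a in out.accessions]
        assert idx == sorted(idx)


class TestTotalAbundance:
    def test_equal_sums_is_identity(self):
        mat = np.array([[1.0, 2.0, 3.0, 2.0], [3.0, 2.0, 1.0, 2.0]])
        out, factors = total_abundance_normalize(make_table(mat))
        np.testing.assert_allclose(list(factors.factors.values()), 1.0)
        np.testing.assert_allclose(out.abundance_matrix(), mat)

    def test_doubled_channel_scaled_back(self):
        base = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        mat = base.copy()
        mat[:, 1] *= 2.0
        design = ChannelDesign.from_pairs(
            "p", [("C0", "control"), ("C1", "control"), ("T0", "treated"), ("T1", "treated")]
        )
        mat4 = np.hstack([mat, base])
        out, factors = total_abundance_normalize(make_table(mat4, design=design))
        sums = out.abundance_matrix().sum(axis=0)
        np.testing.assert_allclose(sums, sums[0], rtol=1e-12)
        # doubled channel's factor is mean-sum / its-sum
        expected = mat4.sum(axis=0).mean() / mat4[:, 1].sum()
        assert factors.factors["C1"] == pytest.approx(expected)

    def test_random_matrix_sums_equal_and_grand_total_conserved(self, rng):
        mat = rng.lognormal(2, 1, size=(40, 6))
        out, _ = total_abundance_normalize(make_table(mat))
        norm = out.abundance_matrix()
        sums = norm.sum(axis=0)
        np.testing.assert_allclose(sums, sums.mean(), rtol=1e-9)
        assert norm.sum() == pytest.approx(mat.sum(), rel=1e-9)

    def test_zero_channel_errors_with_name(self):
        mat = np.array([[0.0, 1.0, 1.0, 1.0]])
        with pytest.raises(ValueError, match="C0"):
            total_abundance_normalize(make_table(mat))


class TestIRS:
    def test_single_plex_identity(self, rng):
        mat = rng.lognormal(3, 1, size=(10, 4))
        table = make_table(mat)
        out, factors = irs_normalize([table])
        np.testing.assert_allclose(out[0].abundance_matrix(), mat)
        assert list(factors[0].factors.values()) == [1.0]

    def test_scaled_plexes_align(self, rng):
        mat = rng.lognormal(3, 0.5, size=(12, 4))
        d1 = ChannelDesign.from_pairs(
            "plexA", [("C0", "control"), ("C1", "control"), ("T0", "treated"), ("T1", "treated")]
        )
        d2 = ChannelDesign.from_pairs(
            "plexB", [("C0", "control"), ("C1", "control"), ("T0", "treated"), ("T1", "treated")]
        )
        t1 = make_table(mat, design=d1)
        t2 = make_table(mat * 3.0, design=d2)
        out, _ = irs_normalize([t1, t2])
        m1 = np.exp(np.log(out[0].abundance_matrix()).mean(axis=1))
        m2 = np.exp(np.log(out[1].abundance_matrix()).mean(axis=1))
        np.testing.assert_allclose(m1, m2, rtol=1e-9)

    def test_random_two_plex_per_protein_means_agree(self, rng):
        d1 = small_design()
        d2 = ChannelDesign.from_pairs(
            "plex2", [("C0", "control"), ("C1", "control"), ("T0", "treated"), ("T1", "treated")]
        )
        t1 = make_table(rng.lognormal(3, 1, size=(15, 4)), design=d1)
        t2 = make_table(rng.lognormal(4, 1, size=(15, 4)), design=d2)
        out, _ = irs_normalize([t1, t2])
        g1 = np.log(out[0].abundance_matrix()).mean(axis=1)
        g2 = np.log(out[1].abundance_matrix()).mean(axis=1)
        np.testing.assert_allclose(g1, g2, rtol=1e-9)


class TestTMM:
    def test_identical_channels_all_factors_one(self):
        col = np.array([[1.0], [5.0], [10.0], [2.0]])
        mat = np.repeat(col, 4, axis=1)
        factors = tmm_factors(make_table(mat))
        np.testing.assert_allclose(list(factors.factors.values()), 1.0, rtol=1e-12)

    def test_two_channel_doubling_closed_form(self):
        design = ChannelDesign.from_pairs(
            "p", [("A", "control"), ("A2", "control"), ("B", "treated"), ("B2", "treated")]
        )
        base = np.array([1.0, 2.0, 4.0, 8.0, 16.0])[:, None]
        mat = np.hstack([base, base, 2 * base, 2 * base])
        factors = tmm_factors(make_table(mat, design=design))
        # all M = 1 against the reference pair: factors 2^(+-1/2) after rescale
        vals = np.array(list(factors.factors.values()))
        np.testing.assert_allclose(sorted(vals), [2**-0.5, 2**-0.5, 2**0.5, 2**0.5], rtol=1e-9)

    def test_matches_independent_reimplementation(self, rng):
        mat = rng.lognormal(4, 1, size=(200, 6))
        mat[:, 2] *= 1.7
        mat[:, 5] *= 0.6
        table = make_table(mat)
        ours = np.array(list(tmm_factors(table).factors.values()))
        theirs = np.array(reference_tmm(mat, table.design.labels))
        np.testing.assert_allclose(ours, theirs, rtol=1e-6)

    def test_product_one_and_positive(self, rng):
        mat = rng.lognormal(4, 1, size=(100, 5)) * rng.uniform(0.5, 2.0, 5)
        f = np.array(list(tmm_factors(make_table(mat)).factors.values()))
        assert (f > 0).all()
        assert np.prod(f) == pytest.approx(1.0, abs=1e-9)

    def test_relabeling_invariance(self, rng):
        mat = rng.lognormal(4, 1, size=(80, 4))
        table = make_table(mat)
        f = tmm_factors(make_table(mat))
        perm = [2, 0, 3, 1]
        table_p = make_table(mat[:, perm])
        f_p = tmm_factors(table_p)
        orig = list(f.factors.values())
        permuted = list(f_p.factors.values())
        np.testing.assert_allclose(permuted, [orig[j] for j in perm], rtol=1e-9)

    def test_applying_factors_divides(self, rng):
        mat = rng.lognormal(4, 1, size=(50, 4))
        table = make_table(mat)
        f = tmm_factors(table)
        out = apply_factors(table, f)
        np.testing.assert_allclose(
            out.abundance_matrix(),
            mat / np.array(list(f.factors.values())),
            rtol=1e-12,
        )

    def test_single_channel_rejected(self, rng):
        design = ChannelDesign.from_pairs(
            "p", [("A", "control"), ("B", "control"), ("C", "treated"), ("D", "treated")]
        )
        table = make_table(rng.lognormal(1, 1, size=(10, 4)), design=design)
        sub = table  # full design fine; now a 1-channel design is unconstructible,
        # so exercise the guard directly on trims that erase everything
        with pytest.raises(ValueError, match="trim"):
            tmm_factors(sub, trim_m=0.5, trim_a=0.5)


class TestPipeline:
    def test_balanced_input_unchanged(self):
        col = np.array([[1.0], [2.0], [8.0], [3.0]])
        mat = np.repeat(col, 4, axis=1)
        out, factors = apply_normalization_pipeline(make_table(mat))
        np.testing.assert_allclose(out.abundance_matrix(), mat, rtol=1e-9)

    def test_provenance_lists_stages_in_order(self, rng):
        out, _ = apply_normalization_pipeline(make_table(rng.lognormal(3, 1, (20, 4))))
        assert out.provenance[-3:] == ["total_abundance", "irs", "tmm"]

    def test_uniformly_doubled_channel_composed_factor_near_half(self, rng):
        # balanced base (all channels identical), then one channel doubled
        col = rng.lognormal(4, 1, size=(100, 1))
        doubled = np.repeat(col, 10, axis=1)
        doubled[:, 3] *= 2.0
        out, _ = apply_normalization_pipeline(make_table(doubled))
        composed = out.abundance_matrix() / doubled
        # per-channel scaling: constant within channel, ~0.5 for the doubled one
        np.testing.assert_allclose(composed.std(axis=0) / composed.mean(axis=0), 0, atol=1e-9)
        assert composed[:, 3].mean() == pytest.approx(11 / 10 / 2, rel=1e-9)  # mean-sum / 2x-sum
        assert composed[:, 3].mean() == pytest.approx(0.5, abs=0.1)

    def test_within_channel_rank_order_preserved(self, rng):
        mat = rng.lognormal(4, 1, size=(60, 4))
        out, _ = apply_normalization_pipeline(make_table(mat))
        norm = out.abundance_matrix()
        for j in range(4):
            assert (np.argsort(mat[:, j]) == np.argsort(norm[:, j])).all()
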