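import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from caft import (
    CountTable,
    EmptyTableError,
    filter_samples,
    filter_taxa,
    to_censored,
    zero_fraction,
)


def make_table(counts, library_sizes=None):
    counts = np.asarray(counts)
    n, j = counts.shape
    return CountTable(
        counts=counts,
        sample_ids=np.array([f"s{i}" for i in range(n)]),
        taxon_ids=np.array([f"t{k}" for k in range(j)]),
        library_sizes=library_sizes,
    )


class TestCensoringTransform:
    def test_direct_formula(self):
        table = make_table([[9, 1], [1, 9], [0, 10]])
        ct = to_censored(table, "t0")
        np.testing.assert_allclose(ct.tau, [-np.log(0.9), -np.log(0.1), np.log(10)])
        np.testing.assert_array_equal(ct.delta, [1, 1, 0])

    def test_taxon_occupying_whole_sample_has_tau_zero(self):
        table = make_table([[10, 0]], library_sizes=[10])
        ct = to_censored(table, "t0")
        assert ct.tau[0] == 0.0 and ct.delta[0] == 1

    def test_all_zero_taxon_is_fully_censored(self):
        table = make_table([[0, 5], [0, 7]])
        ct = to_censored(table, "t0")
        assert np.all(ct.delta == 0)
        np.testing.assert_allclose(ct.tau, np.log(table.library_sizes))

    def test_unknown_taxon_rejected(self):
        with pytest.raises(KeyError):
            to_censored(make_table([[1, 2]]), "nope")

    def test_no_zero_table_is_all_uncensored(self, rng):
        counts = rng.integers(1, 50, size=(6, 5))
        table = make_table(counts)
        for t in table.taxon_ids:
            ct = to_censored(table, t)
            assert np.all(ct.delta == 1)
            assert np.all(np.isfinite(ct.tau))
            # tau < log N except where the taxon is the entire sample
            full = counts[:, table.taxon_index(t)] == table.library_sizes
            assert np.all(ct.tau[~full] > 0)
            assert np.all(ct.tau[full] == 0)


class TestFilters:
    def test_library_filter_boundary(self):
        table = make_table([[2999, 0], [3000, 0]], library_sizes=[2999, 3000])
        kept = filter_samples(table, 3000)
        assert list(kept.sample_ids) == ["s1"]

    def test_library_filter_inclusive_mode(self):
        table = make_table([[2999, 1], [3000, 1], [3001, 1]],
                           library_sizes=[3000, 3001, 3002])
        kept = filter_samples(table, 3000, exclude_at_threshold=True)
        assert list(kept.library_sizes) == [3001, 3002]

    def test_library_filter_identity_when_all_deep(self):
        table = make_table([[10, 5], [8, 9]])
        kept = filter_samples(table, 5)
        np.testing.assert_array_equal(kept.counts, table.counts)

    def test_library_filter_empty_error(self):
        with pytest.raises(EmptyTableError):
            filter_samples(make_table([[1, 1]]), 100)

    def test_presence_below_threshold_removed(self):
        counts = np.zeros((100, 2), dtype=int)
        counts[:5, 0] = 1  # present in 5% of samples
        counts[:, 1] = 1
        kept = filter_taxa(make_table(counts), 0.06)
        assert list(kept.taxon_ids) == ["t1"]

    def test_presence_exactly_at_threshold_kept(self):
        counts = np.zeros((100, 2), dtype=int)
        counts[:6, 0] = 1
        counts[:, 1] = 1
        kept = filter_taxa(make_table(counts), 0.06)
        assert list(kept.taxon_ids) == ["t0", "t1"]

    def test_absent_taxa_always_removed(self):
        kept = filter_taxa(make_table([[1, 0], [2, 0]]), 0.0)
        assert list(kept.taxon_ids) == ["t0"]

    def test_library_sizes_frozen_across_taxon_filter(self):
        # t1 present in half the samples -> dropped at 60%; depths keep the
        # full row sums unless recomputation is requested
        table = make_table([[5, 3], [1, 0]])
        frozen = filter_taxa(table, 0.6)
        assert list(frozen.taxon_ids) == ["t0"]
        np.testing.assert_array_equal(frozen.library_sizes, [8, 1])
        recomputed = filter_taxa(table, 0.6, recompute_library_sizes=True)
        np.testing.assert_array_equal(recomputed.library_sizes, [5, 1])

    def test_filters_idempotent(self, rng):
        counts = rng.integers(0, 5, size=(12, 8))
        counts[:, 0] = 1  # keep at least one taxon everywhere
        table = make_table(counts)
        once = filter_taxa(filter_samples(table, 3), 0.25)
        twice = filter_taxa(filter_samples(once, 3), 0.25)
        np.testing.assert_array_equal(once.counts, twice.counts)
        np.testing.assert_array_equal(once.library_sizes, twice.library_sizes)

    def test_both_filter_orders_available(self):
        counts = np.array([[0, 9], [5, 5], [6, 0]])
        table = make_table(counts)
        a = filter_taxa(filter_samples(table, 9), 0.5)
        b = filter_samples(filter_taxa(table, 0.5), 9)
        # orders can differ; both must be valid tables
        assert a.n_samples >= 1 and b.n_samples >= 1


class TestZeroFraction:
    def test_quarter(self):
        assert zero_fraction(make_table([[1, 0], [2, 3]])) == 0.25

    @settings(max_examples=25, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_bounds_and_censoring_consistency(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 4, size=(5, 4))
        counts[0, :] = np.maximum(counts[0, :], 1)  # keep every sample nonempty
        table = make_table(counts.T)
        zf = zero_fraction(table)
        assert 0.0 <= zf <= 1.0
        deltas = np.column_stack([to_censored(table, t).delta for t in table.taxon_ids])
        assert np.isclose(zf, 1 - deltas.mean())
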