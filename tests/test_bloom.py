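"""Unit and property tests for the Bloom / counting-Bloom primitives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ppdedup.bloom import (
    BloomFilter,
    BloomParams,
    CountingBloomFilter,
    KeyedHasher,
    add,
    count,
    fp_probability,
    intersect,
    random_cbf,
    size_parameters,
    sub,
    to_bloom_filter,
)


# ---------------------------------------------------------------------------
# position derivation
# ---------------------------------------------------------------------------


class TestPositions:
    def test_deterministic_and_in_range(self):
        hasher = KeyedHasher(b"k1", k=3, m=16)
        for x in ["10000000001", "abc", b"\x00\x01"]:
            p1 = hasher.positions(x)
            p2 = hasher.positions(x)
            assert np.array_equal(p1, p2)
            assert len(p1) == 3
            assert ((p1 >= 0) & (p1 <= 15)).all()

    def test_empty_element_rejected(self):
        hasher = KeyedHasher(b"k1", k=3, m=16)
        with pytest.raises(ValueError, match="empty"):
            hasher.positions("")

    def test_key_changes_positions(self):
        a = KeyedHasher(b"key-a", k=4, m=1024)
        b = KeyedHasher(b"key-b", k=4, m=1024)
        assert not np.array_equal(a.positions("x"), b.positions("x"))

    def test_cross_key_collision_rate_matches_uniform_tuples(self):
        """Position tuples under random keys collide like uniform k-tuples:
        the number of coinciding pairs among many keys matches the
        birthday expectation n(n-1)/2 / m^k within 3 Poisson sigma."""
        m, k, n_keys = 16, 3, 1000
        rng = np.random.default_rng(7)
        tuples = []
        for _ in range(n_keys):
            h = KeyedHasher(rng.bytes(16), k=k, m=m)
            tuples.append(tuple(h.positions("patient-42")))
        seen: dict = {}
        pairs = 0
        for t in tuples:
            pairs += seen.get(t, 0)
            seen[t] = seen.get(t, 0) + 1
        expected = n_keys * (n_keys - 1) / 2 / m**k
        assert abs(pairs - expected) <= 3 * math.sqrt(expected)


# ---------------------------------------------------------------------------
# plain Bloom filter
# ---------------------------------------------------------------------------


class TestBloomFilter:
    def test_no_false_negatives(self, toy_params, toy_hasher):
        bf = BloomFilter.zeros(toy_params)
        for x in ["a", "b", "c"]:
            bf.insert(x, toy_hasher)
        for x in ["a", "b", "c"]:
            assert bf.query(x, toy_hasher)

    def test_empty_filter_rejects_everything(self, toy_params, toy_hasher):
        bf = BloomFilter.zeros(toy_params)
        assert not bf.query("anything", toy_hasher)

    def test_empirical_fp_rate_matches_formula(self):
        """FP rate after n insertions within 3 binomial SE of
        (1 - e^(-kn/m))^k."""
        n, p_target, trials = 300, 0.05, 20000
        params = size_parameters(n, p_target, c=8)
        hasher = KeyedHasher(b"fp-test-key", params.k, params.m)
        bf = BloomFilter.zeros(params)
        for i in range(n):
            bf.insert(f"member-{i}", hasher)
        hits = sum(bf.query(f"fresh-{j}", hasher) for j in range(trials))
        rate = hits / trials
        p = fp_probability(n, params.m, params.k)
        se = math.sqrt(p * (1 - p) / trials)
        assert abs(rate - p) <= 3 * se


# ---------------------------------------------------------------------------
# counting Bloom filter: insert/delete/count vs a brute-force tracker
# ---------------------------------------------------------------------------


class TestCountingBloomFilter:
    def test_insert_then_delete_is_identity(self, toy_params, toy_hasher):
        cbf = CountingBloomFilter.zeros(toy_params)
        cbf.insert("x", toy_hasher).delete("x", toy_hasher)
        assert not cbf.counters.any()

    def test_double_insert_counts_two(self, toy_params, toy_hasher):
        # pick an element whose k positions are distinct so counters are
        # exactly the multiplicity
        x = next(
            s for s in (f"e{i}" for i in range(100))
            if len(set(toy_hasher.positions(s))) == toy_params.k
        )
        cbf = CountingBloomFilter.zeros(toy_params)
        cbf.insert(x, toy_hasher).insert(x, toy_hasher)
        assert (cbf.counters[toy_hasher.positions(x)] == 2).all()

    def test_random_ops_match_position_tracker(self, toy_params, toy_hasher, rng):
        """Any insert/delete sequence leaves counters equal to a brute-force
        position->count tracker (mod 2^c)."""
        cbf = CountingBloomFilter.zeros(toy_params)
        tracker = np.zeros(toy_params.m, dtype=np.int64)
        elems = [f"p{i}" for i in range(20)]
        inserted: list[str] = []
        for _ in range(300):
            if inserted and rng.random() < 0.4:
                x = inserted.pop(int(rng.integers(len(inserted))))
                cbf.delete(x, toy_hasher)
                tracker[toy_hasher.positions(x)] -= 1
            else:
                x = elems[int(rng.integers(len(elems)))]
                cbf.insert(x, toy_hasher)
                tracker[toy_hasher.positions(x)] += 1
                inserted.append(x)
        assert np.array_equal(
            cbf.counters, tracker % toy_params.modulus
        )

    def test_count_never_underestimates(self, toy_params, toy_hasher, rng):
        cbf = CountingBloomFilter.zeros(toy_params)
        truth: dict[str, int] = {}
        for _ in range(200):
            x = f"q{int(rng.integers(30))}"
            cbf.insert(x, toy_hasher)
            truth[x] = truth.get(x, 0) + 1
        for x, mult in truth.items():
            assert count(cbf, toy_hasher.positions(x)) >= mult

    def test_count_exact_on_collision_free_instance(self, toy_params, toy_hasher):
        x = next(
            s for s in (f"e{i}" for i in range(100))
            if len(set(toy_hasher.positions(s))) == toy_params.k
        )
        cbf = CountingBloomFilter.zeros(toy_params)
        for _ in range(5):
            cbf.insert(x, toy_hasher)
        assert count(cbf, toy_hasher.positions(x)) == 5
        assert count(CountingBloomFilter.zeros(toy_params),
                     toy_hasher.positions(x)) == 0


# ---------------------------------------------------------------------------
# modular multiset algebra
# ---------------------------------------------------------------------------


def _cbf_from(params, values):
    counters = np.zeros(params.m, dtype=np.uint64)
    counters[: len(values)] = values
    return CountingBloomFilter(params=params, counters=counters)


class TestAlgebra:
    def test_add_modular_wrap(self, toy_params):
        M = toy_params.modulus
        a = _cbf_from(toy_params, [3, M - 1])
        b = _cbf_from(toy_params, [4, 1])
        out = add(a, b)
        assert list(out.counters[:2]) == [7, 0]

    def test_sub_modular_wrap(self, toy_params):
        M = toy_params.modulus
        a = _cbf_from(toy_params, [0, 5])
        b = _cbf_from(toy_params, [1, 2])
        out = sub(a, b)
        assert list(out.counters[:2]) == [M - 1, 3]

    def test_param_mismatch_rejected(self, toy_params):
        other = BloomParams(m=32, k=3, c=8, n=10, p_target=0.1)
        with pytest.raises(ValueError, match="mismatch"):
            add(CountingBloomFilter.zeros(toy_params),
                CountingBloomFilter.zeros(other))
        with pytest.raises(ValueError, match="mismatch"):
            sub(CountingBloomFilter.zeros(toy_params),
                CountingBloomFilter.zeros(other))
        with pytest.raises(ValueError, match="mismatch"):
            intersect(CountingBloomFilter.zeros(toy_params),
                      BloomFilter.zeros(other))

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_add_commutes_and_sub_inverts(self, seed):
        params = BloomParams(m=64, k=3, c=8, n=10, p_target=0.1)
        rng = np.random.default_rng(seed)
        x = random_cbf(params, rng)
        r = random_cbf(params, rng)
        assert np.array_equal(add(x, r).counters, add(r, x).counters)
        assert np.array_equal(sub(add(x, r), r).counters, x.counters)
        zero = CountingBloomFilter.zeros(params)
        assert np.array_equal(add(x, zero).counters, x.counters)
        assert np.array_equal(sub(x, zero).counters, x.counters)

    @settings(max_examples=30, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_intersect_identity_annihilator_and_oracle(self, seed):
        params = BloomParams(m=64, k=3, c=8, n=10, p_target=0.1)
        rng = np.random.default_rng(seed)
        x = random_cbf(params, rng)
        ones = BloomFilter(params=params, bits=np.ones(params.m, dtype=np.uint8))
        zeros = BloomFilter.zeros(params)
        assert np.array_equal(intersect(x, ones).counters, x.counters)
        assert not intersect(x, zeros).counters.any()
        bits = rng.integers(0, 2, size=params.m).astype(np.uint8)
        bf = BloomFilter(params=params, bits=bits)
        assert np.array_equal(
            intersect(x, bf).counters, x.counters * bits
        )
        # projection law: masking x by its own footprint changes nothing
        assert np.array_equal(
            intersect(x, to_bloom_filter(x)).counters, x.counters
        )

    def test_to_bloom_filter_is_positivity_indicator(self, toy_params, rng):
        x = random_cbf(toy_params, rng)
        bf = to_bloom_filter(x)
        assert np.array_equal(bf.bits, (x.counters > 0).astype(np.uint8))
        assert not to_bloom_filter(
            CountingBloomFilter.zeros(toy_params)
        ).bits.any()


# ---------------------------------------------------------------------------
# parameter sizing
# ---------------------------------------------------------------------------


class TestSizing:
    def test_small_instance(self):
        p = size_parameters(1, 0.5)
        assert p.m >= 2
        assert p.k == 1
        assert fp_probability(p.n, p.m, p.k) <= 0.5

    def test_target_respected(self):
        p = size_parameters(1000, 0.01)
        assert fp_probability(1000, p.m, p.k) <= 0.01

    @pytest.mark.parametrize("n", [100, 1000, 20000])
    def test_sizing_monotone_in_n(self, n):
        # m scales as n * C(k): doubling n doubles m up to ceiling slack
        m1 = size_parameters(n, 0.01).m
        m2 = size_parameters(2 * n, 0.01).m
        assert m2 >= 2 * m1 - 2
        assert m2 > m1

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            size_parameters(100, 0.0)
        with pytest.raises(ValueError):
            size_parameters(100, 1.5)


# ---------------------------------------------------------------------------
# random masks
# ---------------------------------------------------------------------------


class TestRandomMask:
    def test_reproducible_under_seed(self, toy_params):
        a = random_cbf(toy_params, np.random.default_rng(9))
        b = random_cbf(toy_params, np.random.default_rng(9))
        c = random_cbf(toy_params, np.random.default_rng(10))
        assert np.array_equal(a.counters, b.counters)
        assert not np.array_equal(a.counters, c.counters)

    def test_counters_uniform_chi_square(self):
        params = BloomParams(m=10000, k=3, c=8, n=10, p_target=0.1)
        x = random_cbf(params, np.random.default_rng(31))
        freq = np.bincount(x.counters.astype(int), minlength=256)
        assert stats.chisquare(freq).pvalue > 0.01

    def test_masked_fixed_filter_is_uniform(self, rng):
        """add(x, r) over uniform r is uniform for any fixed x — the
        one-time-pad property that hides a custodian's input."""
        params = BloomParams(m=16, k=3, c=8, n=10, p_target=0.1)
        x = _cbf_from(params, [200, 1, 17, 255])  # arbitrary fixed filter
        samples = []
        for _ in range(1000):
            samples.append(add(x, random_cbf(params, rng)).counters)
        pooled = np.concatenate(samples).astype(int)
        freq = np.bincount(pooled, minlength=256)
        assert stats.chisquare(freq).pvalue > 0.01


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------


class TestSerialization:
    @pytest.mark.parametrize("compress", [False, True])
    def test_round_trip_bit_exact(self, toy_params, rng, compress):
        x = random_cbf(toy_params, rng)
        text = x.to_text(compress=compress)
        y = CountingBloomFilter.from_text(text)
        assert y.params == x.params
        assert np.array_equal(y.counters, x.counters)

    def test_wrong_length_rejected(self, toy_params, rng):
        x = random_cbf(toy_params, rng)
        text = x.to_text().replace('"m": 64', '"m": 32')
        with pytest.raises(ValueError):
            CountingBloomFilter.from_text(text)
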