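"""Keyed-hash Bloom filter and counting Bloom filter primitives.

A Bloom filter (BF) is an ``m``-bit array encoding a set: inserting an
element sets the ``k`` array positions derived from keyed hashes of the
element; a membership query reports "member" iff all ``k`` positions are
set. A counting Bloom filter (CBF) replaces bits with ``c``-bit counters,
so it encodes a *multiset*: insertion increments, deletion decrements, and
the minimum counter over an element's positions bounds its multiplicity
from above never from below (no false negatives).

All counter arithmetic is modulo ``2^c``. This makes subtraction the exact
inverse of addition and — crucially for the surrounding protocol — makes a
CBF masked with independently uniform random counters information-
theoretically hiding: ``add(x, r)`` is itself uniform for any fixed ``x``.

Position derivation uses a single keyed cryptographic hash (BLAKE2b with
the shared secret key) indexed by the hash-function number, reduced mod
``m``; positions are 0-based in ``[0, m - 1]``.
"""

from __future__ import annotations

import base64
import hashlib
import json
import math
import zlib
from dataclasses import dataclass

import numpy as np

__all__ = [
    "BloomParams",
    "KeyedHasher",
    "BloomFilter",
    "CountingBloomFilter",
    "fp_probability",
    "size_parameters",
    "add",
    "sub",
    "intersect",
    "count",
    "to_bloom_filter",
    "random_cbf",
    "keyed_digest",
]


def fp_probability(n: int, m: int, k: int) -> float:
    """False-positive probability of a membership query, (1 - e^(-kn/m))^k.

    ``n`` elements inserted into an ``m``-position filter with ``k`` hash
    functions.
    """
    return float((1.0 - math.exp(-k * n / m)) ** k)


@dataclass(frozen=True)
class BloomParams:
    """Shared filter parameters agreed by all parties of a session.

    Attributes
    ----------
    m : int
        Array size (number of positions), >= 8.
    k : int
        Number of keyed hash functions, >= 1.
    c : int
        Counter bit-width; counters live in ``[0, 2^c - 1]`` and all
        arithmetic is mod ``2^c``. Must be >= 2 and <= 63 (counters are
        held in uint64 arrays).
    n : int
        Expected number of distinct elements, >= 1.
    p_target : float
        Target false-positive probability in (0, 1).
    """

    m: int
    k: int
    c: int
    n: int
    p_target: float

    def __post_init__(self) -> None:
        if self.m < 8:
            raise ValueError(f"array size m must be >= 8, got {self.m}")
        if self.k < 1:
            raise ValueError(f"hash count k must be >= 1, got {self.k}")
        if not (2 <= self.c <= 63):
            raise ValueError(f"counter width c must be in [2, 63], got {self.c}")
        if self.n < 1:
            raise ValueError(f"expected element count n must be >= 1, got {self.n}")
        if not (0.0 < self.p_target < 1.0):
            raise ValueError(f"p_target must be in (0, 1), got {self.p_target}")

    @property
    def modulus(self) -> int:
        """Counter modulus M = 2^c."""
        return 1 << self.c

    @property
    def counter_mask(self) -> np.uint64:
        return np.uint64((1 << self.c) - 1)

    def fp_probability(self) -> float:
        """False-positive probability at these parameters."""
        return fp_probability(self.n, self.m, self.k)


def size_parameters(n: int, p_target: float, c: int = 32) -> BloomParams:
    """Size a filter for ``n`` expected elements at a target FP probability.

    Chooses the smallest array satisfying the guarantee: for each integer
    k, the minimal m with (1 - e^(-kn/m))^k <= p is
    ceil(kn / -ln(1 - p^(1/k))); the best k is taken. The result tracks
    the classical optimum m = -n ln p / (ln 2)^2, k = (m/n) ln 2, with
    ``fp_probability(n, m, k) <= p_target`` holding exactly.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not (0.0 < p_target < 1.0):
        raise ValueError(f"p_target must be in (0, 1), got {p_target}")
    best_m, best_k = None, None
    for k in range(1, 65):
        rate_bound = -math.log(1.0 - p_target ** (1.0 / k))
        m_k = math.ceil(k * n / rate_bound)
        if best_m is None or m_k < best_m:
            best_m, best_k = m_k, k
    m = max(best_m, 8)
    return BloomParams(m=m, k=best_k, c=c, n=n, p_target=p_target)


def _as_bytes(x: bytes | str) -> bytes:
    if isinstance(x, str):
        x = x.encode("utf-8")
    if not isinstance(x, (bytes, bytearray)):
        raise TypeError(f"element must be str or bytes, got {type(x).__name__}")
    if len(x) == 0:
        raise ValueError("cannot hash an empty element")
    return bytes(x)


def keyed_digest(key: bytes, x: bytes | str, digest_size: int = 16) -> str:
    """Keyed cryptographic hash H_0 of an element, as a hex string.

    Used for the sorted-neighborhood stage: parties holding the secret key
    agree on digests while the digest reveals nothing about the element to
    anyone without the key.
    """
    return hashlib.blake2b(_as_bytes(x), key=key, digest_size=digest_size).hexdigest()


class KeyedHasher:
    """Family of ``k`` keyed position functions b_h(x) = H_h(x) mod m.

    The k functions are derived from a single BLAKE2b keyed hash by
    prefixing the function index h to the element bytes, so all parties
    sharing the secret key compute identical positions.
    """

    def __init__(self, key: bytes, k: int, m: int):
        if not key:
            raise ValueError("hasher requires a non-empty secret key")
        if k < 1 or m < 1:
            raise ValueError("k and m must be positive")
        self.key = bytes(key)
        self.k = k
        self.m = m

    def positions(self, x: bytes | str) -> np.ndarray:
        """The k array positions of ``x``, each in [0, m - 1]."""
        data = _as_bytes(x)
        out = np.empty(self.k, dtype=np.int64)
        for h in range(self.k):
            d = hashlib.blake2b(
                h.to_bytes(4, "big") + data, key=self.key, digest_size=8
            ).digest()
            out[h] = int.from_bytes(d, "big") % self.m
        return out

    def positions_many(self, xs) -> np.ndarray:
        """Positions for a sequence of elements, shape (len(xs), k)."""
        return np.array([self.positions(x) for x in xs], dtype=np.int64).reshape(
            len(xs), self.k
        )


def _check_same_params(a, b) -> None:
    if a.params != b.params:
        raise ValueError(
            f"filter parameter mismatch: {a.params} vs {b.params}"
        )


@dataclass
class BloomFilter:
    """Presence bit-array of length m."""

    params: BloomParams
    bits: np.ndarray  # uint8 in {0, 1}, length m

    @classmethod
    def zeros(cls, params: BloomParams) -> "BloomFilter":
        return cls(params=params, bits=np.zeros(params.m, dtype=np.uint8))

    def insert(self, x: bytes | str, hasher: KeyedHasher) -> "BloomFilter":
        self.bits[hasher.positions(x)] = 1
        return self

    def query(self, x: bytes | str, hasher: KeyedHasher) -> bool:
        """Membership: True iff all k positions of x are set."""
        return bool(self.bits[hasher.positions(x)].all())

    def copy(self) -> "BloomFilter":
        return BloomFilter(params=self.params, bits=self.bits.copy())


@dataclass
class CountingBloomFilter:
    """Counter array of length m encoding a multiset; arithmetic mod 2^c."""

    params: BloomParams
    counters: np.ndarray  # uint64 in [0, 2^c - 1], length m

    @classmethod
    def zeros(cls, params: BloomParams) -> "CountingBloomFilter":
        return cls(params=params, counters=np.zeros(params.m, dtype=np.uint64))

    def insert(self, x: bytes | str, hasher: KeyedHasher) -> "CountingBloomFilter":
        """Increment the k counters of x (mod 2^c)."""
        pos = hasher.positions(x)
        self.counters[pos] = (self.counters[pos] + np.uint64(1)) & self.params.counter_mask
        return self

    def insert_positions(self, positions: np.ndarray) -> "CountingBloomFilter":
        """Increment at precomputed positions; ``positions`` is (n, k) or (k,).

        Repeated positions within one row accumulate, matching repeated
        single insertions.
        """
        flat = np.asarray(positions, dtype=np.int64).ravel()
        if flat.size:
            inc = np.bincount(flat, minlength=self.params.m).astype(np.uint64)
            self.counters = (self.counters + inc) & self.params.counter_mask
        return self

    def delete(self, x: bytes | str, hasher: KeyedHasher) -> "CountingBloomFilter":
        """Decrement the k counters of x (mod 2^c; wrap is defined)."""
        pos = hasher.positions(x)
        self.counters[pos] = (self.counters[pos] - np.uint64(1)) & self.params.counter_mask
        return self

    def copy(self) -> "CountingBloomFilter":
        return CountingBloomFilter(params=self.params, counters=self.counters.copy())

    # -- serialization: params block + base64-packed payload ---------------

    def to_text(self, compress: bool = False) -> str:
        return _filter_to_text("cbf", self.params, self.counters, compress)

    @classmethod
    def from_text(cls, text: str) -> "CountingBloomFilter":
        kind, params, arr = _filter_from_text(text)
        if kind != "cbf":
            raise ValueError(f"expected a cbf record, got {kind!r}")
        return cls(params=params, counters=arr.astype(np.uint64))


def _filter_to_text(kind: str, params: BloomParams, arr: np.ndarray, compress: bool) -> str:
    payload = arr.astype(np.uint64).tobytes()
    if compress:
        payload = zlib.compress(payload, level=6)
    doc = {
        "kind": kind,
        "params": {
            "m": params.m,
            "k": params.k,
            "c": params.c,
            "n": params.n,
            "p_target": params.p_target,
        },
        "compressed": compress,
        "payload": base64.b64encode(payload).decode("ascii"),
    }
    return json.dumps(doc)


def _filter_from_text(text: str):
    doc = json.loads(text)
    params = BloomParams(**doc["params"])
    payload = base64.b64decode(doc["payload"])
    if doc.get("compressed"):
        payload = zlib.decompress(payload)
    arr = np.frombuffer(payload, dtype=np.uint64).copy()
    if arr.size != params.m:
        raise ValueError(f"payload length {arr.size} does not match m={params.m}")
    return doc["kind"], params, arr


# -- the five multiset operations ------------------------------------------


def add(a: CountingBloomFilter, b: CountingBloomFilter) -> CountingBloomFilter:
    """Elementwise counter sum mod 2^c (multiset union / masking)."""
    _check_same_params(a, b)
    return CountingBloomFilter(
        params=a.params, counters=(a.counters + b.counters) & a.params.counter_mask
    )


def sub(a: CountingBloomFilter, b: CountingBloomFilter) -> CountingBloomFilter:
    """Elementwise counter difference mod 2^c; exact inverse of add."""
    _check_same_params(a, b)
    return CountingBloomFilter(
        params=a.params, counters=(a.counters - b.counters) & a.params.counter_mask
    )


def intersect(cbf: CountingBloomFilter, bf: BloomFilter) -> CountingBloomFilter:
    """Keep counters where the mask bit is 1, zero elsewhere."""
    if cbf.params.m != bf.params.m:
        raise ValueError(
            f"array size mismatch: cbf m={cbf.params.m}, bf m={bf.params.m}"
        )
    return CountingBloomFilter(
        params=cbf.params, counters=cbf.counters * bf.bits.astype(np.uint64)
    )


def count(cbf: CountingBloomFilter, positions: np.ndarray) -> int:
    """Multiplicity estimate of the element with these positions.

    Returns the minimum counter over the k positions: never below the true
    multiplicity of the element in the encoded multiset, possibly above it
    when other elements collide on all k positions.
    """
    return int(cbf.counters[np.asarray(positions, dtype=np.int64)].min())


def to_bloom_filter(cbf: CountingBloomFilter) -> BloomFilter:
    """Presence projection: bit j = 1 iff counter j > 0."""
    return BloomFilter(
        params=cbf.params, bits=(cbf.counters > 0).astype(np.uint8)
    )


def random_cbf(params: BloomParams, rng: np.random.Generator) -> CountingBloomFilter:
    """Random mask: each counter i.i.d. uniform on [0, 2^c - 1].

    Uniformity over the full counter ring is what makes ``add(x, mask)``
    uniform for any fixed x, hence a one-time-pad-style hiding of x.
    """
    counters = rng.integers(0, params.modulus, size=params.m, dtype=np.uint64)
    return CountingBloomFilter(params=params, counters=counters)
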