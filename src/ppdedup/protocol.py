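"""Secure deduplication protocol: setup, duplicate identifier, DSN, audit.

The protocol lets N >= 3 data custodians, holding horizontal partitions of
a virtual dataset (VD), find and remove records duplicated across
custodians while keeping exactly one occurrence — without any party
learning another custodian's patient identifiers or record count. A
semi-trusted coordinator aggregates masked filters and resolves duplicate
candidates; it participates without input and holds no secret keys.

Phases
------
1. **Setup**: agree on ring order (leader first), filter parameters sized
   from the expected element count and a target false-positive
   probability, and two secret keys — k1 for Bloom positions, k0 for the
   sorted-neighborhood hashes. The coordinator receives neither key.
2. **Secure duplicate identifier**: each custodian encodes its unique IDs
   into CBF_I^i, draws a uniform random mask CBF_r^i; the masks are
   summed over the ring (secure sum) into CBF_R; each custodian sends the
   masked add(CBF_r^i, CBF_I^i) to the coordinator, who aggregates them
   into CBF_{R u S} and returns to each custodian the slice
   intersect(CBF_{R u S}, BF_{r u I}^i). Locally subtracting the matching
   slice of CBF_R exposes CBF_S ∩ BF_I^i, from which each custodian reads
   the global multiplicity of each of its own IDs: the candidate list L_i
   holds those with multiplicity >= 2 (all true duplicates, plus Bloom
   false positives at a bounded rate).
3. **Distributed sorted neighborhood (DSN)**: candidates are re-hashed
   with k0, locally sorted, and merged at the coordinator; runs of equal
   hashes spanning >= 2 custodians are confirmed duplicates. One keeper
   per group (lowest ring index) retains the record; the others receive
   its hash in their removal list DL_i and delete locally. False-positive
   candidates appear at a single custodian only and are discarded.

The whole exchange is captured in an auditable transcript;
:func:`audit_transcript` checks the closed-form message accounting
(total 6N - 1) and the structural privacy contract (the coordinator only
ever receives masked filters and keyed hash lists).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bloom import (
    BloomParams,
    CountingBloomFilter,
    KeyedHasher,
    add,
    count,
    intersect,
    keyed_digest,
    random_cbf,
    size_parameters,
    sub,
    to_bloom_filter,
)
from .messages import COORDINATOR_SAFE_PAYLOADS, Channel, Transcript
from .secure_sum import RingOrder, run_secure_sum

__all__ = [
    "Record",
    "VirtualDataset",
    "ProtocolConfig",
    "ProtocolSession",
    "CandidateList",
    "SortedHashList",
    "RemovalList",
    "DedupReport",
    "setup",
    "run_duplicate_identifier",
    "run_dsn",
    "deduplicate",
    "audit_transcript",
    "COORDINATOR_ID",
    "EXTRACT_COLUMNS",
]

COORDINATOR_ID = "coordinator"

#: Column order of a per-custodian record extract (delimited text).
EXTRACT_COLUMNS = [
    "custodian_id",
    "record_id",
    "patient_id",
    "agent",
    "result",
    "sex",
    "age",
    "area",
    "date",
    "first_name",
    "last_name",
    "dob",
]


# ---------------------------------------------------------------------------
# Records and the virtual dataset
# ---------------------------------------------------------------------------


@dataclass
class Record:
    """One test-result record held by a custodian."""

    custodian_id: str
    record_id: str
    patient_id: str
    attributes: dict[str, str] = field(default_factory=dict)

    def get(self, name: str) -> str | None:
        if name == "patient_id":
            return self.patient_id
        if name == "record_id":
            return self.record_id
        if name == "custodian_id":
            return self.custodian_id
        return self.attributes.get(name)


class VirtualDataset:
    """Per-custodian record lists forming the distributed query result."""

    def __init__(self, custodians: Mapping[str, Sequence[Record]]):
        self.custodians: dict[str, list[Record]] = {
            cid: list(records) for cid, records in custodians.items()
        }
        for cid, records in self.custodians.items():
            rids = [r.record_id for r in records]
            if len(set(rids)) != len(rids):
                raise ValueError(f"duplicate record ids within custodian {cid}")

    @property
    def custodian_ids(self) -> list[str]:
        return sorted(self.custodians)

    @property
    def n_custodians(self) -> int:
        return len(self.custodians)

    @property
    def total_records(self) -> int:
        return sum(len(v) for v in self.custodians.values())

    def unique_ids(self, cid: str) -> list[str]:
        """Sorted set I_i of (trimmed) patient IDs at a custodian."""
        return sorted({r.patient_id.strip() for r in self.custodians[cid]})

    def remove(self, removals: Mapping[str, Iterable[str]]) -> "VirtualDataset":
        """New VD with the listed record ids deleted per custodian."""
        out = {}
        for cid, records in self.custodians.items():
            drop = set(removals.get(cid, ()))
            out[cid] = [r for r in records if r.record_id not in drop]
        return VirtualDataset(out)

    def copy(self) -> "VirtualDataset":
        return VirtualDataset(
            {cid: [Record(r.custodian_id, r.record_id, r.patient_id, dict(r.attributes))
                   for r in recs]
             for cid, recs in self.custodians.items()}
        )

    # -- delimited-text extracts -------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cid in self.custodian_ids:
            for r in self.custodians[cid]:
                row = {"custodian_id": cid, "record_id": r.record_id,
                       "patient_id": r.patient_id}
                row.update(r.attributes)
                rows.append(row)
        df = pd.DataFrame(rows)
        cols = [c for c in EXTRACT_COLUMNS if c in df.columns] + [
            c for c in df.columns if c not in EXTRACT_COLUMNS
        ]
        return df.reindex(columns=cols)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "VirtualDataset":
        required = {"custodian_id", "record_id", "patient_id"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"extract missing required columns: {sorted(missing)}")
        custodians: dict[str, list[Record]] = {}
        attr_cols = [c for c in df.columns if c not in required]
        for row in df.itertuples(index=False):
            d = row._asdict()
            rec = Record(
                custodian_id=str(d["custodian_id"]),
                record_id=str(d["record_id"]),
                patient_id=str(d["patient_id"]),
                attributes={c: "" if pd.isna(d[c]) else str(d[c]) for c in attr_cols},
            )
            custodians.setdefault(rec.custodian_id, []).append(rec)
        return cls(custodians)

    def write_extracts(self, outdir: str | Path) -> list[Path]:
        """One tab-separated extract file per custodian."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = []
        df = self.to_frame()
        for cid in self.custodian_ids:
            p = outdir / f"extract_{cid}.tsv"
            df[df["custodian_id"] == cid].to_csv(p, sep="\t", index=False)
            paths.append(p)
        return paths

    @classmethod
    def read_extracts(cls, paths: Sequence[str | Path]) -> "VirtualDataset":
        frames = [pd.read_csv(p, sep="\t", dtype=str) for p in paths]
        return cls.from_frame(pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# Session setup
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ProtocolConfig:
    """Run-level knobs shared by all parties.

    ``n_expected`` is the jointly agreed expected number of distinct IDs
    used to size the filters; when None, the orchestrator uses the total
    extract size. ``window`` is the DSN sliding-window size kept for
    forward compatibility — confirmed duplicates are exact hash
    equalities, so any window >= 2 is equivalent to run-scanning.
    """

    p_target: float = 1e-4
    c: int = 32
    n_expected: int | None = None
    window: int = 2
    compress: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.p_target < 1.0):
            raise ValueError(f"p_target must be in (0, 1), got {self.p_target}")
        if self.window < 2:
            raise ValueError(f"window must be >= 2, got {self.window}")


@dataclass
class ProtocolSession:
    """State of one protocol instance (one linkage key).

    Custodian secret keys live in ``custodian_keys``; the coordinator has
    no entry there, by the trust assumption.
    """

    session_id: str
    ring: RingOrder
    params: BloomParams
    config: ProtocolConfig
    coordinator_id: str
    custodian_keys: dict[str, tuple[bytes, bytes]]  # cid -> (k0, k1)
    mask_seeds: dict[str, int]  # per-party seeds for the random masks
    channel: Channel = field(init=False)

    def __post_init__(self) -> None:
        self.channel = Channel(session_id=self.session_id)

    @property
    def transcript(self) -> Transcript:
        return self.channel.transcript

    def keys_of(self, cid: str) -> tuple[bytes, bytes]:
        return self.custodian_keys[cid]

    @property
    def coordinator_key_store(self) -> dict:
        """Always empty: the coordinator holds no secrets."""
        return {}


def setup(
    custodian_ids: Sequence[str],
    config: ProtocolConfig,
    n_expected: int,
    master_seed: int,
    instance_index: int = 0,
    coordinator_key: bytes | None = None,
) -> ProtocolSession:
    """Establish a session: ring, sized parameters, secret keys, seeds.

    The leader is the lowest custodian id (a deterministic stand-in for
    joint leader election); the ring is the sorted id order. Keys and
    per-party mask seeds derive from ``(master_seed, instance_index)`` so
    a run is fully reproducible.
    """
    ids = sorted(custodian_ids)
    if len(ids) < 3:
        raise ValueError(
            f"protocol requires at least 3 custodians, got {len(ids)}; "
            "with fewer the ring degenerates and masking is vacuous"
        )
    if coordinator_key is not None:
        raise ValueError(
            "the coordinator must not hold a secret key (trust assumption)"
        )
    ring = RingOrder.of(ids)
    params = size_parameters(n_expected, config.p_target, c=config.c)
    if n_expected * len(ids) >= params.modulus:
        raise ValueError(
            f"n*N = {n_expected * len(ids)} >= 2^c = {params.modulus}: true "
            "aggregate counts could wrap; increase the counter width c"
        )
    ss = np.random.SeedSequence([int(master_seed), int(instance_index)])
    rng = np.random.default_rng(ss)
    k1 = rng.bytes(32)  # Bloom position key
    k0 = rng.bytes(32)  # DSN hash key
    # one mask stream per custodian plus one for the leader's initial mask
    seeds = rng.integers(0, 2**31 - 1, size=len(ids) + 1)
    mask_seeds = {cid: int(s) for cid, s in zip(ids, seeds[:-1])}
    mask_seeds["__leader_initial__"] = int(seeds[-1])
    return ProtocolSession(
        session_id=f"s{master_seed}-i{instance_index}",
        ring=ring,
        params=params,
        config=config,
        coordinator_id=COORDINATOR_ID,
        custodian_keys={cid: (k0, k1) for cid in ids},
        mask_seeds=mask_seeds,
    )


# ---------------------------------------------------------------------------
# Stage results
# ---------------------------------------------------------------------------


@dataclass
class CandidateList:
    """L_i: a custodian's IDs whose estimated global multiplicity is >= 2."""

    custodian_id: str
    members: list[str]  # sorted key strings, subset of the custodian's I_i


@dataclass
class SortedHashList:
    """SL_i: lexicographically sorted keyed hashes of L_i members."""

    custodian_id: str
    hashes: list[str]


@dataclass
class RemovalList:
    """DL_i: hash ids a custodian must remove, with the local resolution."""

    custodian_id: str
    hashes: list[str]
    record_ids: list[str]  # resolved locally by the custodian


@dataclass
class InstanceResult:
    """Everything one protocol instance produced (one linkage key)."""

    session: ProtocolSession
    criterion_name: str
    candidates: dict[str, CandidateList]
    groups: list[dict]  # [{"key_hash", "members": [(cid, record_id), ...], "keeper"}]
    removals: dict[str, RemovalList]
    keeper_map: dict[str, str]  # key hash -> keeper custodian
    key_elements: dict[str, dict[str, list[str]]]  # cid -> key -> record ids
    plaintext_ids: set[str]


# ---------------------------------------------------------------------------
# Stage 2: secure duplicate identifier
# ---------------------------------------------------------------------------


def _custodian_elements(
    vd: VirtualDataset, key_func: Callable[[Record], str | None]
) -> dict[str, dict[str, list[str]]]:
    """Per custodian: linkage key -> record ids carrying it.

    Records for which ``key_func`` returns None (missing/empty fields) are
    excluded from this instance.
    """
    out: dict[str, dict[str, list[str]]] = {}
    for cid in vd.custodian_ids:
        keymap: dict[str, list[str]] = {}
        for rec in vd.custodians[cid]:
            key = key_func(rec)
            if key:
                keymap.setdefault(key, []).append(rec.record_id)
        out[cid] = keymap
    return out


def run_duplicate_identifier(
    session: ProtocolSession,
    vd: VirtualDataset,
    key_func: Callable[[Record], str | None] | None = None,
) -> dict[str, CandidateList]:
    """Steps 1-7: each custodian learns which of its IDs recur in the VD.

    Returns per-custodian candidate lists L_i containing every ID truly
    present at >= 2 custodians (no false negatives) plus possible Bloom
    false positives at a rate bounded by the sized parameters.
    """
    if key_func is None:
        key_func = lambda r: r.patient_id.strip() or None  # noqa: E731
    elements = _custodian_elements(vd, key_func)
    candidates, _ = _identify_candidates(session, elements)
    return candidates


def _identify_candidates(
    session: ProtocolSession,
    elements: Mapping[str, Mapping[str, list[str]]],
) -> tuple[dict[str, CandidateList], dict[str, dict[str, np.ndarray]]]:
    ring = session.ring
    params = session.params
    missing = [cid for cid in ring.members if cid not in elements]
    if missing:
        raise ValueError(f"no extract for custodians in the ring: {missing}")

    # Step 1: each custodian encodes I_i and draws its random mask.
    hashers: dict[str, KeyedHasher] = {}
    positions: dict[str, dict[str, np.ndarray]] = {}
    cbf_I: dict[str, CountingBloomFilter] = {}
    cbf_r: dict[str, CountingBloomFilter] = {}
    for cid in ring.members:
        _, k1 = session.keys_of(cid)
        hasher = KeyedHasher(k1, params.k, params.m)
        hashers[cid] = hasher
        pos = {x: hasher.positions(x) for x in sorted(elements[cid])}
        positions[cid] = pos
        filt = CountingBloomFilter.zeros(params)
        if pos:
            filt.insert_positions(np.stack(list(pos.values())))
        cbf_I[cid] = filt
        cbf_r[cid] = random_cbf(
            params, np.random.default_rng(session.mask_seeds[cid])
        )

    # Step 2: the leader's initial mask CBF_r^0.
    leader_mask = random_cbf(
        params, np.random.default_rng(session.mask_seeds["__leader_initial__"])
    )

    # Step 3: secure sum of the random masks over the ring.
    cbf_R = run_secure_sum(ring, cbf_r, leader_mask, session.channel)

    # Step 4: each custodian sends its masked input to the coordinator.
    masked: dict[str, CountingBloomFilter] = {}
    for rnd, cid in enumerate(ring.members, start=1):
        m = add(cbf_r[cid], cbf_I[cid])
        masked[cid] = m
        session.channel.send(
            "dup_identifier", rnd, cid, session.coordinator_id,
            "masked-cbf", m.to_text(compress=session.config.compress),
        )

    # Step 5: the coordinator aggregates CBF_{R u S}. It sees only
    # uniformly masked filters; no key, no plaintext.
    received = {
        msg.sender: CountingBloomFilter.from_text(msg.payload)
        for msg in session.transcript
        if msg.receiver == session.coordinator_id and msg.payload_type == "masked-cbf"
    }
    cbf_RS = CountingBloomFilter.zeros(params)
    for cid in ring.members:
        cbf_RS = add(cbf_RS, received[cid])

    # Step 6: per custodian, mask the aggregate down to its own footprint
    # and return it.
    for rnd, cid in enumerate(ring.members, start=1):
        bf_rI = to_bloom_filter(received[cid])
        reply = intersect(cbf_RS, bf_rI)
        session.channel.send(
            "dup_identifier", ring.n + rnd, session.coordinator_id, cid,
            "intersected-cbf", reply.to_text(compress=session.config.compress),
        )

    # Step 7: each custodian exposes CBF_{S ∩ I}^i and thresholds counts.
    candidates: dict[str, CandidateList] = {}
    replies = {
        msg.receiver: CountingBloomFilter.from_text(msg.payload)
        for msg in session.transcript
        if msg.sender == session.coordinator_id
        and msg.payload_type == "intersected-cbf"
    }
    for cid in ring.members:
        bf_I = to_bloom_filter(cbf_I[cid])
        bf_rI = to_bloom_filter(add(cbf_r[cid], cbf_I[cid]))
        masked_R = intersect(cbf_R, bf_rI)
        cbf_S_slice = sub(replies[cid], masked_R)  # = CBF_S ∩ BF_{r u I}^i
        cbf_SI = intersect(cbf_S_slice, bf_I)
        members = [
            x for x, pos in positions[cid].items() if count(cbf_SI, pos) >= 2
        ]
        candidates[cid] = CandidateList(custodian_id=cid, members=sorted(members))
    return candidates, positions


# ---------------------------------------------------------------------------
# Stage 3: distributed sorted neighborhood
# ---------------------------------------------------------------------------


def _require_sorted(cid: str, hashes: Sequence[str]) -> None:
    """Coordinator-side contract check on a received SL_i."""
    if list(hashes) != sorted(hashes):
        raise ValueError(f"SL from {cid} is not lexicographically sorted")


def run_dsn(
    session: ProtocolSession,
    candidates: Mapping[str, CandidateList],
    key_elements: Mapping[str, Mapping[str, list[str]]] | None = None,
    with_handles: bool = False,
    handle_key: bytes | None = None,
    finalize: bool = True,
) -> tuple[list[dict], dict[str, str], dict[str, RemovalList]]:
    """Resolve candidates into confirmed duplicate groups and removals.

    Each custodian hashes its L_i with the k0 key, sorts, and sends SL_i;
    the coordinator merges the sorted lists and scans maximal runs of
    equal hashes. A run spanning >= 2 custodians is a confirmed group;
    the lowest-ring-index holder keeps the record, the rest get its hash
    in DL_i. Candidates seen at one custodian only (Bloom false
    positives) never enter any DL_i.

    With ``with_handles`` (multi-criterion runs) each SL_i entry pairs the
    linkage-key hash with a keyed record-handle hash, and — unless
    ``finalize`` — the coordinator returns confirmed match groups instead
    of removal decisions, leaving the keeper rule to the combined stage.
    """
    ring = session.ring
    hash_to_key: dict[str, dict[str, str]] = {}
    sls: dict[str, list] = {}
    for rnd, cid in enumerate(ring.members, start=1):
        k0, _ = session.keys_of(cid)
        lst = candidates[cid].members
        mapping = {keyed_digest(k0, x): x for x in lst}
        hash_to_key[cid] = mapping
        if with_handles:
            if handle_key is None:
                raise ValueError("with_handles requires a handle key")
            entries = []
            for h, key in mapping.items():
                rids = list(key_elements[cid][key]) if key_elements else []
                handles = [
                    keyed_digest(handle_key, f"{cid}|{rid}") for rid in rids
                ]
                entries.append((h, handles))
            entries.sort(key=lambda e: e[0])
            payload = entries
            hashes_sorted = [e[0] for e in entries]
        else:
            hashes_sorted = sorted(mapping)
            payload = hashes_sorted
        sls[cid] = payload
        session.channel.send(
            "dsn", rnd, cid, session.coordinator_id, "sorted-hash-list", payload
        )

    # Coordinator: contract check, merge, run-scan for equal-hash groups.
    occurrences: dict[str, list[str]] = {}
    for cid in ring.members:
        payload = sls[cid]
        hs = [e[0] for e in payload] if with_handles else list(payload)
        _require_sorted(cid, hs)
        for h in hs:
            occurrences.setdefault(h, []).append(cid)

    confirmed = {
        h: cids for h, cids in sorted(occurrences.items()) if len(cids) >= 2
    }
    keeper_map = {
        h: min(cids, key=ring.members.index) for h, cids in confirmed.items()
    }

    dl: dict[str, list[str]] = {cid: [] for cid in ring.members}
    for h, cids in confirmed.items():
        for cid in cids:
            if cid != keeper_map[h]:
                dl[cid].append(h)

    if finalize:
        payload_type = "removal-list"
        payloads = {cid: sorted(dl[cid]) for cid in ring.members}
    else:
        # Multi-criterion: report this instance's confirmed matches; the
        # keeper decision is deferred to the combined stage.
        payload_type = "match-groups"
        payloads = {
            cid: sorted(h for h in confirmed if cid in confirmed[h])
            for cid in ring.members
        }
    for rnd, cid in enumerate(ring.members, start=1):
        session.channel.send(
            "dsn", ring.n + rnd, session.coordinator_id, cid,
            payload_type, payloads[cid],
        )

    # Custodians resolve hashes locally to record ids.
    removals: dict[str, RemovalList] = {}
    for cid in ring.members:
        hashes = sorted(dl[cid])
        rids: list[str] = []
        for h in hashes:
            key = hash_to_key[cid][h]
            if key_elements is not None:
                rids.extend(key_elements[cid][key])
            else:
                rids.append(key)
        removals[cid] = RemovalList(
            custodian_id=cid, hashes=hashes, record_ids=sorted(rids)
        )

    groups = []
    for h, cids in confirmed.items():
        members = []
        for cid in cids:
            key = hash_to_key[cid][h]
            if key_elements is not None:
                members.extend((cid, rid) for rid in key_elements[cid][key])
            else:
                members.append((cid, key))
        groups.append(
            {"key_hash": h, "members": sorted(members), "keeper": keeper_map[h]}
        )

    return groups, keeper_map, removals


# ---------------------------------------------------------------------------
# Transcript audit
# ---------------------------------------------------------------------------


@dataclass
class AuditReport:
    """Message-count and structural-privacy summary of one instance.

    Receive tallies follow the protocol's accounting convention: the
    leader's CBF_R broadcast fan-out is counted on the send side (the
    leader sends N + 2 messages) but excluded from per-party receive
    counts, which is the only reading under which the closed forms
    (non-leader 3/3, coordinator 2N/2N, total 6N - 1) are simultaneously
    exact. Broadcast deliveries are reported separately.
    """

    n_custodians: int
    sent: dict[str, int]
    received: dict[str, int]
    broadcast_received: dict[str, int]
    total_messages: int
    passed: bool
    failures: list[str]
    coordinator_payload_types: list[str]
    privacy_ok: bool

    def to_dict(self) -> dict:
        return {
            "n_custodians": self.n_custodians,
            "sent": dict(sorted(self.sent.items())),
            "received": dict(sorted(self.received.items())),
            "broadcast_received": dict(sorted(self.broadcast_received.items())),
            "total_messages": self.total_messages,
            "passed": self.passed,
            "failures": list(self.failures),
            "coordinator_payload_types": sorted(set(self.coordinator_payload_types)),
            "privacy_ok": self.privacy_ok,
        }


def _payload_tokens(payload) -> Iterable[str]:
    """All strings inside a (possibly nested) list payload."""
    if isinstance(payload, str):
        yield payload
    elif isinstance(payload, (list, tuple)):
        for item in payload:
            yield from _payload_tokens(item)


def audit_transcript(
    session: ProtocolSession,
    secret_strings: Iterable[str] = (),
) -> AuditReport:
    """Check the transcript against the closed-form message accounting.

    Expected for N custodians: each non-leader sends 3 and receives 3;
    the leader sends N + 2 (including the N - 1 broadcast fan-out) and
    receives 3; the coordinator sends and receives 2N; the grand total is
    6N - 1 messages. Also asserts the coordinator only ever received
    masked filters or sorted hash lists, and that no secret key material
    or plaintext identifier appears in any coordinator-bound payload.
    """
    ring = session.ring
    transcript = session.transcript
    n = ring.n
    parties = list(ring.members) + [session.coordinator_id]
    sent = {p: len(transcript.sent_by(p)) for p in parties}
    received = {
        p: len(transcript.received_by(p, include_broadcast=False)) for p in parties
    }
    bcast = {
        p: len(transcript.received_by(p)) - received[p] for p in parties
    }
    total = len(transcript)

    failures: list[str] = []
    for cid in ring.members[1:]:
        if sent[cid] != 3:
            failures.append(f"{cid} sent {sent[cid]} messages, expected 3")
        if received[cid] != 3:
            failures.append(f"{cid} received {received[cid]} messages, expected 3")
    if sent[ring.leader] != n + 2:
        failures.append(
            f"leader {ring.leader} sent {sent[ring.leader]}, expected N+2={n + 2}"
        )
    coord = session.coordinator_id
    if sent[coord] != 2 * n:
        failures.append(f"coordinator sent {sent[coord]}, expected 2N={2 * n}")
    if received[coord] != 2 * n:
        failures.append(f"coordinator received {received[coord]}, expected 2N={2 * n}")
    if total != 6 * n - 1:
        failures.append(f"total {total} messages, expected 6N-1={6 * n - 1}")

    coord_msgs = transcript.received_by(coord)
    payload_types = [m.payload_type for m in coord_msgs]
    bad_types = [t for t in payload_types if t not in COORDINATOR_SAFE_PAYLOADS]
    if bad_types:
        failures.append(f"coordinator received unsafe payload types: {sorted(set(bad_types))}")

    # Structural privacy: nothing the coordinator saw may carry secret key
    # material or a plaintext identifier. Key bytes are scanned against
    # every payload; list payloads (hash lists) must contain only keyed
    # hashes, so their tokens are matched exactly against the plaintext
    # identifiers. Filter payloads are base64-packed masked counters — a
    # plaintext string cannot occur there by construction — and are
    # checked to parse as well-formed filters of the session's parameters.
    key_hexes = set()
    for k0, k1 in session.custodian_keys.values():
        key_hexes.add(k0.hex())
        key_hexes.add(k1.hex())
    secrets = {s for s in secret_strings if s}
    privacy_ok = True
    for m in coord_msgs:
        is_text = isinstance(m.payload, str)
        text = m.payload if is_text else json.dumps(m.payload)
        leaked = any(kh in text for kh in key_hexes)
        if not leaked and m.payload_type == "masked-cbf":
            try:
                filt = CountingBloomFilter.from_text(text)
                if filt.params != session.params:
                    raise ValueError("parameter mismatch")
            except (ValueError, KeyError):
                failures.append(
                    f"coordinator payload from {m.sender} is not a "
                    "well-formed session filter"
                )
        elif not leaked:
            # list payloads: every token must be a keyed hash, never a
            # plaintext identifier (exact-match check, linear in payload)
            leaked = any(tok in secrets for tok in _payload_tokens(m.payload))
        if leaked:
            privacy_ok = False
            failures.append(
                f"coordinator payload from {m.sender} leaks a secret string"
            )

    return AuditReport(
        n_custodians=n,
        sent=sent,
        received=received,
        broadcast_received=bcast,
        total_messages=total,
        passed=not failures,
        failures=failures,
        coordinator_payload_types=payload_types,
        privacy_ok=privacy_ok,
    )


# ---------------------------------------------------------------------------
# Full composition
# ---------------------------------------------------------------------------


@dataclass
class DedupReport:
    """Final report: candidates, removals, keepers, audit, deduplicated VD."""

    config: ProtocolConfig
    master_seed: int
    instances: list[dict]  # per criterion: name, params, candidates, audit
    groups: list[dict]  # combined duplicate groups with keepers
    removals: dict[str, list[str]]  # cid -> record ids removed
    keeper_map: dict[str, str]  # group id -> keeper custodian
    vd_after: VirtualDataset | None = None

    def to_dict(self) -> dict:
        return {
            "config": {
                "p_target": self.config.p_target,
                "c": self.config.c,
                "window": self.config.window,
            },
            "master_seed": self.master_seed,
            "instances": self.instances,
            "groups": self.groups,
            "removals": {k: list(v) for k, v in sorted(self.removals.items())},
            "keeper_map": dict(sorted(self.keeper_map.items())),
        }

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json() + "\n")
        return path


def run_instance(
    vd: VirtualDataset,
    config: ProtocolConfig,
    master_seed: int,
    key_func: Callable[[Record], str | None] | None = None,
    criterion_name: str = "unique_id",
    instance_index: int = 0,
    with_handles: bool = False,
    handle_key: bytes | None = None,
    finalize: bool = True,
) -> InstanceResult:
    """One full protocol instance under a single linkage key."""
    if key_func is None:
        key_func = lambda r: r.patient_id.strip() or None  # noqa: E731
    elements = _custodian_elements(vd, key_func)
    n_expected = config.n_expected or max(
        1, sum(len(v) for v in elements.values())
    )
    session = setup(
        vd.custodian_ids, config, n_expected, master_seed,
        instance_index=instance_index,
    )
    candidates, _ = _identify_candidates(session, elements)
    groups, keeper_map, removals = run_dsn(
        session, candidates, key_elements=elements,
        with_handles=with_handles, handle_key=handle_key, finalize=finalize,
    )
    plaintext = {x for cid in elements for x in elements[cid]}
    plaintext |= {rid for cid in vd.custodian_ids
                  for rid in (r.record_id for r in vd.custodians[cid])}
    return InstanceResult(
        session=session,
        criterion_name=criterion_name,
        candidates=candidates,
        groups=groups,
        removals=removals,
        keeper_map=keeper_map,
        key_elements={cid: dict(m) for cid, m in elements.items()},
        plaintext_ids=plaintext,
    )


def _instance_block(res: InstanceResult) -> dict:
    audit = audit_transcript(res.session, secret_strings=res.plaintext_ids)
    return {
        "criterion": res.criterion_name,
        "params": {
            "m": res.session.params.m,
            "k": res.session.params.k,
            "c": res.session.params.c,
            "n": res.session.params.n,
            "p_target": res.session.params.p_target,
        },
        "candidates": {
            cid: list(cl.members) for cid, cl in sorted(res.candidates.items())
        },
        "audit": audit.to_dict(),
    }


def report_from_groups(
    config: ProtocolConfig,
    master_seed: int,
    instance_blocks: list[dict],
    groups: list[dict],
    ring: RingOrder,
    vd: VirtualDataset,
) -> DedupReport:
    """Assemble the final report from combined duplicate groups."""
    keeper_map: dict[str, str] = {}
    removals: dict[str, list[str]] = {cid: [] for cid in vd.custodian_ids}
    out_groups = []
    for gi, g in enumerate(sorted(groups, key=lambda g: g["members"])):
        members = sorted(set(map(tuple, g["members"])))
        keeper = min({cid for cid, _ in members}, key=ring.members.index)
        gid = f"g{gi:05d}"
        keeper_map[gid] = keeper
        for cid, rid in members:
            if cid != keeper:
                removals[cid].append(rid)
        out_groups.append(
            {"group_id": gid, "members": [list(m) for m in members], "keeper": keeper}
        )
    removals = {cid: sorted(v) for cid, v in removals.items()}
    return DedupReport(
        config=config,
        master_seed=master_seed,
        instances=instance_blocks,
        groups=out_groups,
        removals=removals,
        keeper_map=keeper_map,
        vd_after=vd.remove(removals),
    )


def deduplicate(
    vd: VirtualDataset, config: ProtocolConfig, master_seed: int
) -> DedupReport:
    """Full pipeline on unique patient IDs: setup -> secure sum ->
    duplicate identifier -> DSN -> local deletion.

    The deduplicated VD equals plaintext union-deduplication exactly
    unless the keyed DSN hash collides (probability ~2^-128).
    """
    res = run_instance(vd, config, master_seed)
    return report_from_groups(
        config, master_seed, [_instance_block(res)], res.groups, res.session.ring, vd
    )
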