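"""Deterministic record linkage over quasi-identifiers.

When no reliable unique patient ID exists, a linkage key — a normalized
concatenation of quasi-identifiers such as last name, sex, date of birth
and postal area — stands in for it. A deterministic linkage scheme defines
p match criteria; the deduplication protocol runs one independent
instance per criterion (fresh secret keys each), and a pair of records is
a duplicate iff it matches under at least one criterion. Matched pairs
are merged transitively into groups so that a single keeper per group can
be designated consistently, SEER/Medicare-style.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from datetime import datetime
from typing import Callable, Sequence

import numpy as np

from .protocol import (
    DedupReport,
    ProtocolConfig,
    Record,
    VirtualDataset,
    _instance_block,
    keyed_digest,
    report_from_groups,
    run_instance,
)

__all__ = [
    "MatchCriterion",
    "LinkageKey",
    "UNIQUE_ID_CRITERION",
    "make_linkage_key",
    "run_multikey_dedup",
    "UnionFind",
]

#: Reserved field separator inside a linkage key (ASCII unit separator),
#: never produced by normalization.
KEY_SEPARATOR = "\x1f"

_DATE_FORMATS = ("%Y-%m-%d", "%d.%m.%Y", "%d/%m/%Y", "%Y%m%d", "%d-%m-%Y")
_WS = re.compile(r"\s+")


def _norm_text(value: str) -> str:
    return _WS.sub(" ", value.strip()).casefold()


def _norm_date(value: str) -> str:
    """Canonicalize a date string to ISO yyyy-mm-dd."""
    v = value.strip()
    for fmt in _DATE_FORMATS:
        try:
            return datetime.strptime(v, fmt).strftime("%Y-%m-%d")
        except ValueError:
            continue
    raise ValueError(f"unrecognized date format: {value!r}")

_NORMALIZERS: dict[str, Callable[[str], str]] = {
    "strip": str.strip,
    "casefold": str.casefold,
    "collapse_ws": lambda v: _WS.sub(" ", v),
    "text": _norm_text,
    "date_iso": _norm_date,
}


def _default_recipe(field_name: str) -> tuple[str, ...]:
    if field_name in ("patient_id", "record_id"):
        return ("strip",)  # unique IDs: trimmed, case preserved
    if "date" in field_name or field_name == "dob":
        return ("date_iso",)
    return ("text",)


@dataclass(frozen=True)
class MatchCriterion:
    """One deterministic match criterion: an ordered quasi-identifier list.

    ``normalizers`` maps a field to the names of normalization steps
    applied in order; unlisted fields get a sensible default (dates to
    ISO, free text trimmed/case-folded/whitespace-collapsed, unique IDs
    trimmed only). A pluggable hook (e.g. phonetic encoding) can be
    registered as an extra normalizer name.
    """

    name: str
    fields: tuple[str, ...]
    normalizers: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.fields:
            raise ValueError("a match criterion needs at least one field")

    def recipe(self, field_name: str) -> tuple[str, ...]:
        return self.normalizers.get(field_name, _default_recipe(field_name))

    def __hash__(self) -> int:
        return hash((self.name, self.fields))


UNIQUE_ID_CRITERION = MatchCriterion(name="unique_id", fields=("patient_id",))


@dataclass(frozen=True)
class LinkageKey:
    """Normalized concatenation of a record's criterion fields."""

    criterion: str
    value: str


def make_linkage_key(record: Record, criterion: MatchCriterion) -> LinkageKey | None:
    """Build the linkage key of a record under a criterion.

    Returns None when any criterion field is missing or empty — the
    record is excluded from that criterion's protocol instance rather
    than matched on an empty string.
    """
    parts = []
    for fname in criterion.fields:
        raw = record.get(fname)
        if raw is None or not str(raw).strip():
            return None
        value = str(raw)
        for step in criterion.recipe(fname):
            value = _NORMALIZERS[step](value)
        if not value:
            return None
        parts.append(value)
    return LinkageKey(criterion=criterion.name, value=KEY_SEPARATOR.join(parts))


def _key_func(criterion: MatchCriterion) -> Callable[[Record], str | None]:
    def f(record: Record) -> str | None:
        key = make_linkage_key(record, criterion)
        return key.value if key else None

    return f


class UnionFind:
    """Disjoint sets over hashable items (for transitive group merging)."""

    def __init__(self) -> None:
        self._parent: dict = {}

    def find(self, x):
        p = self._parent.setdefault(x, x)
        while p != x:
            self._parent[x] = p = self._parent[p]
            x = p
            p = self._parent[x]
        return x

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self._parent[max(ra, rb)] = min(ra, rb)

    def groups(self) -> list[list]:
        out: dict = {}
        for x in self._parent:
            out.setdefault(self.find(x), []).append(x)
        return [sorted(v) for v in out.values() if len(v) >= 2]


def run_multikey_dedup(
    vd: VirtualDataset,
    criteria: Sequence[MatchCriterion],
    config: ProtocolConfig,
    master_seed: int,
) -> DedupReport:
    """Run one protocol instance per criterion and combine the results.

    Instances use fresh secret keys derived from (master_seed, instance
    index); a shared record-handle key, held by custodians only, lets the
    combined stage merge matched groups across criteria transitively.
    The keeper rule is applied once on the merged groups. With a single
    criterion the result is identical to the base protocol run — for the
    unique-ID criterion, bit for bit.
    """
    if not criteria:
        raise ValueError("at least one match criterion is required")
    names = [c.name for c in criteria]
    if len(set(names)) != len(names):
        raise ValueError("criterion names must be distinct")

    p = len(criteria)
    handle_rng = np.random.default_rng(
        np.random.SeedSequence([int(master_seed), 1048576])
    )
    handle_key = handle_rng.bytes(32)

    results = []
    for idx, crit in enumerate(criteria):
        res = run_instance(
            vd,
            config,
            master_seed,
            key_func=_key_func(crit),
            criterion_name=crit.name,
            instance_index=idx,
            with_handles=p > 1,
            handle_key=handle_key if p > 1 else None,
            finalize=p == 1,
        )
        results.append(res)

    ring = results[0].session.ring
    blocks = [_instance_block(r) for r in results]

    if p == 1:
        return report_from_groups(
            config, master_seed, blocks, results[0].groups, ring, vd
        )

    # Combine: transitive closure over (custodian, record) members of every
    # per-criterion confirmed group; one keeper per merged group.
    uf = UnionFind()
    for res in results:
        for g in res.groups:
            members = [tuple(m) for m in g["members"]]
            for other in members[1:]:
                uf.union(members[0], other)
    merged = [
        {"members": grp} for grp in uf.groups()
        if len({cid for cid, _ in grp}) >= 2
    ]
    report = report_from_groups(config, master_seed, blocks, merged, ring, vd)

    # The coordinator notifies each custodian of its combined removals as
    # record handles (one extra round of N messages beyond the per-instance
    # transcripts); custodians resolve handles locally.
    combine_channel = results[-1].session.channel.__class__(
        session_id=f"s{master_seed}-combine"
    )
    for rnd, cid in enumerate(ring.members, start=1):
        handles = sorted(
            keyed_digest(handle_key, f"{cid}|{rid}")
            for rid in report.removals.get(cid, [])
        )
        combine_channel.send(
            "combine", rnd, "coordinator", cid, "removal-list", handles
        )
    report.instances.append(
        {
            "criterion": "__combined__",
            "messages": len(combine_channel.transcript),
            "n_groups": len(report.groups),
        }
    )
    return report
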