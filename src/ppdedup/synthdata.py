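"""Synthetic microbiology virtual datasets with planted duplicates.

The generator emulates the study setting of distributed laboratory-based
disease surveillance: N custodians (microbiology laboratories) each hold
an extract of test-result records — infectious agent, result, sex, age,
geographic area, test date — plus the patient's unique ID and the
quasi-identifiers (name, sex, date of birth, area) used for deterministic
linkage when no unique ID is available.

Records are distributed equally among the custodians (±1). A configurable
fraction of each custodian's records are *copies* of records held at
other custodians (the transferred-sample scenario): the copy keeps the
patient ID and quasi-identifiers — optionally with case/whitespace
perturbations that exercise linkage-key normalization — so every planted
duplicate group spans at least two custodians. Ground truth records the
groups and the canonical keeper under the protocol's keeper rule.

Patient IDs are 11-digit strings shaped like Norwegian personal numbers
but without valid check digits (purely synthetic; no real-format
identifiers are generated).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Sequence

import numpy as np

from .linkage import MatchCriterion, UnionFind, make_linkage_key
from .protocol import Record, VirtualDataset

__all__ = ["GeneratorSpec", "GroundTruth", "OracleResult", "generate_vd", "plaintext_oracle"]

_FIRST_NAMES = [
    "Anna", "Bjorn", "Cecilie", "David", "Elin", "Fredrik", "Grete", "Hans",
    "Ingrid", "Jon", "Kari", "Lars", "Maria", "Nils", "Oda", "Per", "Randi",
    "Stein", "Tone", "Ulf", "Vera", "Wenche", "Yngve", "Aase",
]
_LAST_NAMES = [
    "Andersen", "Berg", "Christensen", "Dahl", "Eriksen", "Fossum", "Gundersen",
    "Hansen", "Iversen", "Johansen", "Karlsen", "Larsen", "Moen", "Nilsen",
    "Olsen", "Pedersen", "Ruud", "Solberg", "Thomassen", "Vik",
]
_AGENTS = [
    "influenza A", "influenza B", "RSV", "rhinovirus", "adenovirus",
    "Mycoplasma pneumoniae", "Bordetella pertussis", "norovirus",
]
_AREAS = [f"{code:04d}" for code in range(9000, 9060)]  # postal-style area codes


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one synthetic virtual dataset.

    ``duplicate_rate`` is the fraction of each custodian's records that
    are copies of records at other custodians (exact:
    floor(rate * records-per-custodian) copies are planted).
    ``triple_fraction`` is the probability that a copy extends an
    existing group to a third custodian instead of starting a new pair.
    ``perturb_quasi_ids`` applies case/whitespace noise to the copied
    name fields (normalization-invariant).
    """

    n_custodians: int
    total_records: int
    duplicate_rate: float = 0.05
    triple_fraction: float = 0.0
    perturb_quasi_ids: bool = True
    seed: int = 0
    date_range: tuple[str, str] = ("2015-01-01", "2016-04-30")

    def __post_init__(self) -> None:
        if self.n_custodians < 3:
            raise ValueError(
                f"need at least 3 custodians, got {self.n_custodians}"
            )
        if not (0.0 <= self.duplicate_rate < 1.0):
            raise ValueError(
                f"duplicate_rate must be in [0, 1), got {self.duplicate_rate}"
            )
        if self.total_records < self.n_custodians:
            raise ValueError("need at least one record per custodian")
        if not (0.0 <= self.triple_fraction <= 1.0):
            raise ValueError("triple_fraction must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted duplicate groups and their canonical keepers."""

    groups: list[dict] = field(default_factory=list)
    # each: {"members": [(cid, record_id), ...] sorted, "keeper": cid}
    copies: dict[str, int] = field(default_factory=dict)
    # per custodian: number of records that are copies of records elsewhere

    @property
    def member_sets(self) -> set[frozenset]:
        return {frozenset(map(tuple, g["members"])) for g in self.groups}

    def removals(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for g in self.groups:
            for cid, rid in g["members"]:
                if cid != g["keeper"]:
                    out.setdefault(cid, []).append(rid)
        return {cid: sorted(v) for cid, v in out.items()}


def _unique_pids(rng: np.random.Generator, n: int) -> list[str]:
    """n distinct 11-digit synthetic personal numbers."""
    seen: set[int] = set()
    while len(seen) < n:
        draw = rng.integers(10**10, 10**11, size=n - len(seen))
        seen.update(int(v) for v in draw)
    return [str(v) for v in sorted(seen, key=lambda _: rng.random())][:n]


def _perturb(rng: np.random.Generator, value: str) -> str:
    """Case/whitespace noise that normalization must undo."""
    choice = rng.integers(0, 4)
    if choice == 0:
        return value.upper()
    if choice == 1:
        return value.lower()
    if choice == 2:
        return f"  {value}"
    return value + " "


def generate_vd(spec: GeneratorSpec) -> tuple[VirtualDataset, GroundTruth]:
    """Generate a virtual dataset with planted cross-custodian duplicates.

    Fully reproducible from ``spec.seed``. Raises when the duplicate rate
    is infeasible: every copy needs a distinct original at another
    custodian, which requires rate <= (N-1)/N under equal allocation.
    """
    rng = np.random.default_rng(spec.seed)
    N = spec.n_custodians
    cids = [f"D{i + 1:02d}" for i in range(N)]

    base, extra = divmod(spec.total_records, N)
    n_per = {cid: base + (1 if i < extra else 0) for i, cid in enumerate(cids)}
    d_per = {cid: int(spec.duplicate_rate * n_per[cid]) for cid in cids}
    for cid in cids:
        host_capacity = sum(n_per[o] - d_per[o] for o in cids if o != cid)
        if d_per[cid] > host_capacity:
            raise ValueError(
                f"duplicate_rate {spec.duplicate_rate} infeasible for "
                f"N={N}: custodian {cid} needs {d_per[cid]} originals at "
                f"other custodians but only {host_capacity} are available"
            )

    start = date.fromisoformat(spec.date_range[0])
    span = (date.fromisoformat(spec.date_range[1]) - start).days

    pids = _unique_pids(rng, spec.total_records)
    records: dict[str, list[Record]] = {}
    pid_iter = iter(pids)
    for cid in cids:
        recs = []
        for j in range(n_per[cid]):
            pid = next(pid_iter)
            dob_year = int(rng.integers(1920, 2015))
            dob = date(dob_year, int(rng.integers(1, 13)), int(rng.integers(1, 29)))
            test_date = start + timedelta(days=int(rng.integers(0, span + 1)))
            recs.append(
                Record(
                    custodian_id=cid,
                    record_id=f"{cid}-r{j:06d}",
                    patient_id=pid,
                    attributes={
                        "agent": str(rng.choice(_AGENTS)),
                        "result": "positive" if rng.random() < 0.8 else "negative",
                        "sex": "F" if rng.random() < 0.5 else "M",
                        "age": str(test_date.year - dob.year),
                        "area": str(rng.choice(_AREAS)),
                        "date": test_date.isoformat(),
                        "first_name": str(rng.choice(_FIRST_NAMES)),
                        "last_name": str(rng.choice(_LAST_NAMES)),
                        "dob": dob.isoformat(),
                    },
                )
            )
        records[cid] = recs

    # Plant copies: per custodian, the chosen records are overwritten with
    # copies of originals held elsewhere.
    originals_free: dict[str, list[int]] = {}
    copy_slots: list[tuple[str, int]] = []
    for cid in cids:
        idx = rng.permutation(n_per[cid])
        copies = [int(i) for i in idx[: d_per[cid]]]
        originals_free[cid] = [int(i) for i in idx[d_per[cid]:]]
        copy_slots.extend((cid, i) for i in copies)
    order = rng.permutation(len(copy_slots))
    copy_slots = [copy_slots[int(i)] for i in order]

    groups: dict[tuple[str, int], list[tuple[str, int]]] = {}
    for cid, slot in copy_slots:
        attached = False
        if spec.triple_fraction > 0 and groups and rng.random() < spec.triple_fraction:
            open_groups = [
                okey for okey, members in groups.items()
                if len(members) < 3 and cid not in {c for c, _ in members}
                and okey[0] != cid
            ]
            if open_groups:
                okey = open_groups[int(rng.integers(0, len(open_groups)))]
                groups[okey].append((cid, slot))
                attached = True
        if not attached:
            donors = [o for o in cids if o != cid and originals_free[o]]
            if not donors:
                raise ValueError(
                    "could not place a duplicate copy: no free original "
                    "record at another custodian"
                )
            donor = max(donors, key=lambda o: (len(originals_free[o]), o))
            oslot = originals_free[donor].pop()
            groups[(donor, oslot)] = [(cid, slot)]

    for (ocid, oslot), members in groups.items():
        orig = records[ocid][oslot]
        for cid, slot in members:
            tgt = records[cid][slot]
            attrs = dict(orig.attributes)
            if spec.perturb_quasi_ids:
                attrs["first_name"] = _perturb(rng, attrs["first_name"])
                attrs["last_name"] = _perturb(rng, attrs["last_name"])
            records[cid][slot] = Record(
                custodian_id=cid,
                record_id=tgt.record_id,
                patient_id=orig.patient_id,
                attributes=attrs,
            )

    gt = GroundTruth(copies={cid: d_per[cid] for cid in cids})
    for (ocid, oslot), members in sorted(groups.items()):
        all_members = sorted(
            [(ocid, records[ocid][oslot].record_id)]
            + [(cid, records[cid][slot].record_id) for cid, slot in members]
        )
        keeper = min(cid for cid, _ in all_members)
        gt.groups.append({"members": all_members, "keeper": keeper})
    gt.groups.sort(key=lambda g: g["members"])

    return VirtualDataset(records), gt


@dataclass
class OracleResult:
    """Reference deduplication computed in the clear."""

    groups: list[dict]
    removals: dict[str, list[str]]
    vd_after: VirtualDataset

    @property
    def member_sets(self) -> set[frozenset]:
        return {frozenset(map(tuple, g["members"])) for g in self.groups}


def plaintext_oracle(
    vd: VirtualDataset,
    criteria: Sequence[MatchCriterion] | None = None,
) -> OracleResult:
    """Brute-force deduplication reference, same keeper rule as the protocol.

    Without criteria, records are grouped by exact (trimmed) unique
    patient ID; with criteria, by linkage-key equality under any
    criterion, transitively closed. Only groups spanning >= 2 custodians
    count — within-custodian repeats are out of the protocol's scope.
    """
    uf = UnionFind()
    if criteria is None:
        by_key: dict[str, list[tuple[str, str]]] = {}
        for cid in vd.custodian_ids:
            for r in vd.custodians[cid]:
                by_key.setdefault(r.patient_id.strip(), []).append((cid, r.record_id))
        for members in by_key.values():
            for other in members[1:]:
                uf.union(members[0], other)
    else:
        for crit in criteria:
            by_key = {}
            for cid in vd.custodian_ids:
                for r in vd.custodians[cid]:
                    key = make_linkage_key(r, crit)
                    if key:
                        by_key.setdefault(key.value, []).append((cid, r.record_id))
            for members in by_key.values():
                for other in members[1:]:
                    uf.union(members[0], other)

    groups = []
    removals: dict[str, list[str]] = {cid: [] for cid in vd.custodian_ids}
    for grp in uf.groups():
        custodians = {cid for cid, _ in grp}
        if len(custodians) < 2:
            continue
        keeper = min(custodians)
        for cid, rid in grp:
            if cid != keeper:
                removals[cid].append(rid)
        groups.append({"members": sorted(grp), "keeper": keeper})
    groups.sort(key=lambda g: g["members"])
    removals = {cid: sorted(v) for cid, v in removals.items()}
    return OracleResult(
        groups=groups, removals=removals, vd_after=vd.remove(removals)
    )
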