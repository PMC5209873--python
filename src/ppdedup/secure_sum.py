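"""Ring-based secure summation of counting Bloom filters.

The N custodians form a ring with the leader first. The leader adds its
input to an initial random mask CBF_r^0 and passes the partial sum around
the ring; each custodian adds its own input in turn. The last custodian
returns the final partial sum to the leader, who strips the mask and
broadcasts the true sum CBF_R to everyone. Because counter arithmetic is
modulo 2^c and the mask is uniform, every intermediate partial sum is
itself uniform: no single party learns another party's input (though the
two ring neighbours of a custodian can jointly reconstruct it — the
protocol's stated collusion limit).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .bloom import CountingBloomFilter, add, sub
from .messages import Channel

__all__ = ["RingOrder", "PartialSum", "run_secure_sum"]


@dataclass(frozen=True)
class RingOrder:
    """Custodian identities in ring order, leader first."""

    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 3:
            raise ValueError(
                f"ring requires at least 3 custodians, got {len(self.members)}"
            )
        if len(set(self.members)) != len(self.members):
            raise ValueError("ring members must be distinct")

    @property
    def leader(self) -> str:
        return self.members[0]

    @property
    def n(self) -> int:
        return len(self.members)

    def successor(self, party: str) -> str:
        i = self.members.index(party)
        return self.members[(i + 1) % len(self.members)]

    @classmethod
    def of(cls, members: Sequence[str]) -> "RingOrder":
        return cls(members=tuple(members))


@dataclass(frozen=True)
class PartialSum:
    """Masked running sum CBF_R^i held after custodian i added its input."""

    holder_index: int  # 1-based position in the ring
    value: CountingBloomFilter


def run_secure_sum(
    ring: RingOrder,
    inputs: Mapping[str, CountingBloomFilter],
    leader_mask: CountingBloomFilter,
    channel: Channel,
    phase: str = "secure_sum",
) -> CountingBloomFilter:
    """Compute the elementwise modular sum of the custodians' filters.

    Parameters
    ----------
    ring : RingOrder
        Ring topology, leader first.
    inputs : mapping custodian id -> CountingBloomFilter
        Each custodian's secret input (its random mask CBF_r^i in the
        deduplication protocol; any filter in general).
    leader_mask : CountingBloomFilter
        The leader's initial random mask CBF_r^0, never revealed.
    channel : Channel
        Transport; records N ring messages plus N-1 broadcast messages.

    Returns
    -------
    CountingBloomFilter
        CBF_R = sum of the inputs, mask removed — independent of the mask
        and of the ring order.
    """
    missing = [p for p in ring.members if p not in inputs]
    if missing:
        raise ValueError(f"no input filter for custodians: {missing}")
    params = leader_mask.params
    for party in ring.members:
        if inputs[party].params != params:
            raise ValueError(
                f"parameter mismatch for {party}: {inputs[party].params} != {params}"
            )

    # Leader masks its own input and starts the ring.
    partial = add(inputs[ring.leader], leader_mask)
    channel.send(
        phase, 1, ring.leader, ring.members[1], "partial-sum-cbf", partial.to_text()
    )

    # Each custodian in turn adds its input and forwards.
    for i in range(1, ring.n):
        party = ring.members[i]
        partial = add(inputs[party], partial)
        receiver = ring.members[(i + 1) % ring.n]  # D_N closes the ring to D_L
        channel.send(
            phase, i + 1, party, receiver, "partial-sum-cbf", partial.to_text()
        )

    # Leader strips the initial mask from the final partial sum CBF_R^N.
    total = sub(partial, leader_mask)

    # Broadcast the true sum to the other custodians.
    for j, party in enumerate(ring.members[1:], start=1):
        channel.send(
            phase, ring.n + j, ring.leader, party, "broadcast-sum-cbf", total.to_text()
        )
    return total
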