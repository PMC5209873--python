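"""Message envelopes and the append-only protocol transcript.

Every exchange between parties is recorded as a :class:`Message` in a
:class:`Transcript`. The transcript is the auditable ground truth for the
message-complexity accounting and for the structural privacy checks (what
the coordinator ever received).

Payload-type tags
-----------------
``partial-sum-cbf``   ring message of the secure sum (CBF_R^i)
``broadcast-sum-cbf`` the leader's broadcast of the unmasked sum CBF_R
``masked-cbf``        custodian -> coordinator masked input (CBF_{r u I}^i)
``intersected-cbf``   coordinator -> custodian reply (CBF_{R u S} ∩ BF_{r u I}^i)
``sorted-hash-list``  custodian -> coordinator sorted keyed hashes SL_i
``removal-list``      coordinator -> custodian hash IDs to delete (DL_i)
``match-groups``      coordinator -> custodian per-instance confirmed matches
                      (multi-criterion runs only)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterator

__all__ = ["Message", "Transcript", "COORDINATOR_SAFE_PAYLOADS"]

#: Payload types a coordinator may legitimately receive: masked filters and
#: keyed hash lists only — never raw identifiers, never secret keys.
COORDINATOR_SAFE_PAYLOADS = frozenset({"masked-cbf", "sorted-hash-list"})


@dataclass(frozen=True)
class Message:
    """One delivered protocol message."""

    session_id: str
    phase: str  # "secure_sum" | "dup_identifier" | "dsn" | "combine"
    round: int
    sender: str
    receiver: str
    payload_type: str
    payload: Any

    @property
    def is_broadcast(self) -> bool:
        return self.payload_type == "broadcast-sum-cbf"


class Transcript:
    """Append-only ordered log of every message of a session."""

    def __init__(self) -> None:
        self._messages: list[Message] = []

    def record(self, msg: Message) -> Message:
        self._messages.append(msg)
        return msg

    def __len__(self) -> int:
        return len(self._messages)

    def __iter__(self) -> Iterator[Message]:
        return iter(self._messages)

    @property
    def messages(self) -> tuple[Message, ...]:
        return tuple(self._messages)

    def sent_by(self, party: str) -> list[Message]:
        return [m for m in self._messages if m.sender == party]

    def received_by(self, party: str, include_broadcast: bool = True) -> list[Message]:
        return [
            m
            for m in self._messages
            if m.receiver == party and (include_broadcast or not m.is_broadcast)
        ]


@dataclass
class Channel:
    """In-process transport: delivery is a transcript append.

    A stand-in for the point-to-point secure channels the protocol assumes;
    the simulation delivers synchronously and records everything.
    """

    session_id: str
    transcript: Transcript = field(default_factory=Transcript)

    def send(
        self,
        phase: str,
        round: int,
        sender: str,
        receiver: str,
        payload_type: str,
        payload: Any,
    ) -> Message:
        return self.transcript.record(
            Message(
                session_id=self.session_id,
                phase=phase,
                round=round,
                sender=sender,
                receiver=receiver,
                payload_type=payload_type,
                payload=payload,
            )
        )
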