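"""Round-Robin participant scheduling and communication accounting.

A message is one model vector of (d+1) float64 entries, i.e. 8*(d+1) bytes;
dual variables stay local and are never transmitted. In peer topologies one
round is every agent sending its primal to every neighbour (2|E| messages);
in star/Round-Robin mode one round is the k scheduled clients' upload plus
download (2k messages). Volume converts at 2**30 bytes per gigabyte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

__all__ = ["RoundRobinState", "CommLog", "next_participants",
           "record_round", "volume_gigabytes", "BYTES_PER_FLOAT"]

BYTES_PER_FLOAT = 8


@dataclass(frozen=True)
class RoundRobinState:
    """Cyclic pointer over an ordered participant list."""

    nodes: tuple
    pointer: int = 0
    aggregators: tuple = ()

    def __post_init__(self) -> None:
        if len(self.nodes) == 0:
            raise ValueError("node list must be nonempty")
        if not (0 <= self.pointer < len(self.nodes)):
            raise ValueError("pointer out of range")


def next_participants(state: RoundRobinState, k: int
                      ) -> tuple[list, RoundRobinState]:
    """Next k nodes in cyclic order starting at the pointer.

    Wraps to the first node when the list is exhausted; the pointer advances
    by k modulo |V|.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(state.nodes)
    chosen = [state.nodes[(state.pointer + i) % n] for i in range(k)]
    return chosen, replace(state, pointer=(state.pointer + k) % n)


@dataclass(frozen=True)
class CommLog:
    rounds: int = 0
    messages: int = 0
    bytes: int = 0
    per_node_sends: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.rounds, self.messages, self.bytes) < 0:
            raise ValueError("counts must be nonnegative")


def record_round(log: CommLog, n_messages: int, vector_length: int,
                 senders: Optional[Sequence] = None) -> CommLog:
    """Account one communication round of fixed-size model-vector messages."""
    if n_messages < 0 or vector_length < 0:
        raise ValueError("inputs must be nonnegative")
    sends = dict(log.per_node_sends)
    for node in senders or ():
        sends[node] = sends.get(node, 0) + 1
    return CommLog(
        rounds=log.rounds + 1,
        messages=log.messages + n_messages,
        bytes=log.bytes + n_messages * vector_length * BYTES_PER_FLOAT,
        per_node_sends=sends,
    )


def volume_gigabytes(log: CommLog) -> float:
    return log.bytes / 2**30
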