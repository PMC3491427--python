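"""Construction of the temporal sequence of binary functional networks.

Two channels are functionally connected at pattern time ``t`` exactly when
their order-pattern symbols at ``t`` are identical.  Every network is
therefore a disjoint union of cliques: the channels sharing one symbol form
a complete subgraph, disconnected from everything else.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import realign_times
from .symbolize import SymbolSequence

__all__ = ["NetworkSequence", "adjacency_at", "build_network_sequence"]


def adjacency_at(symbols_at_t) -> np.ndarray:
    """N x N symmetric 0/1 adjacency from one time slice of symbols:
    ``A[i, j] = 1`` iff ``i != j`` and the symbols are equal."""
    s = np.asarray(symbols_at_t)
    if s.ndim != 1 or s.size < 2:
        raise ValueError("need a 1-D vector of at least 2 symbols")
    a = (s[:, None] == s[None, :]).astype(np.uint8)
    np.fill_diagonal(a, 0)
    return a


@dataclass
class NetworkSequence:
    """Ordered stack of binary functional networks.

    Internally only the ``N x L`` symbol matrix is stored (channels sharing
    a symbol at a column form that network's cliques); dense adjacency
    matrices are materialized on demand and are guaranteed identical to the
    all-pairs comparison of the symbols.
    """

    symbols: np.ndarray          # N x L integer matrix
    times: np.ndarray            # L realigned timestamps
    labels: list[str]
    d: int
    tau: int

    def __post_init__(self) -> None:
        self.symbols = np.asarray(self.symbols, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        if self.symbols.ndim != 2:
            raise ValueError("symbols must be an N x L matrix")
        if self.times.size != self.symbols.shape[1]:
            raise ValueError("one timestamp per network required")
        if len(self.labels) != self.symbols.shape[0]:
            raise ValueError("one label per channel required")

    def __len__(self) -> int:
        return self.symbols.shape[1]

    @property
    def n_channels(self) -> int:
        return self.symbols.shape[0]

    def adjacency(self, k: int) -> np.ndarray:
        """Dense adjacency of the ``k``-th network."""
        return adjacency_at(self.symbols[:, k])

    def iter_adjacency(self):
        for k in range(len(self)):
            yield self.adjacency(k)

    def edges(self, k: int) -> list[tuple[int, int]]:
        """Undirected edges of the k-th network as (i, j) index pairs, i < j."""
        s = self.symbols[:, k]
        out: list[tuple[int, int]] = []
        order = np.argsort(s, kind="stable")
        grouped: dict[int, list[int]] = {}
        for i in order:
            grouped.setdefault(int(s[i]), []).append(int(i))
        for members in grouped.values():
            members.sort()
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    out.append((members[a], members[b]))
        out.sort()
        return out

    def to_graph(self, k: int):
        """The k-th network as a networkx Graph (nodes = channel labels)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.labels)
        for i, j in self.edges(k):
            g.add_edge(self.labels[i], self.labels[j])
        return g


def build_network_sequence(
    symbol_sequences: list[SymbolSequence],
    sampling_rate: float | None = None,
) -> NetworkSequence:
    """Stack per-channel symbol sequences into a network sequence.

    All sequences must share ``d``, ``tau``, ``start_index`` and length.
    Timestamps are realigned to the pattern-window centres
    (``t* = t + (d-1)*tau/2``), in samples, or milliseconds when a
    sampling rate is given.
    """
    if not symbol_sequences:
        raise ValueError("no symbol sequences given")
    first = symbol_sequences[0]
    for seq in symbol_sequences[1:]:
        if (seq.d, seq.tau, seq.start_index, len(seq)) != (
            first.d,
            first.tau,
            first.start_index,
            len(first),
        ):
            raise ValueError(
                f"channel {seq.label!r}: embedding parameters or length differ "
                "from the first channel's"
            )
    mat = np.stack([seq.symbols for seq in symbol_sequences])
    anchors = first.start_index + np.arange(len(first))
    times = realign_times(anchors, first.d, first.tau, sampling_rate)
    labels = [
        seq.label if seq.label is not None else f"ch{idx}"
        for idx, seq in enumerate(symbol_sequences)
    ]
    return NetworkSequence(mat, times, labels, d=first.d, tau=first.tau)
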