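"""Per-group consensus sequence construction.

The consensus is the per-column plurality character among {A, C, G, T, -};
N and IUPAC ambiguity codes never vote and never appear in a consensus.
Ties are broken deterministically by the fixed order A < C < G < T < -.
Downstream statistics only use match/mismatch against the consensus, so any
deterministic tie rule yields a valid contract; this one is the package's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment_io import Alignment

__all__ = ["ConsensusResult", "build_consensus"]

_VOTING = np.frombuffer(b"ACGT-", dtype=np.uint8)


@dataclass(frozen=True)
class ConsensusResult:
    """A consensus sequence plus per-column support.

    ``support[j]`` is the fraction of voting (non-missing) characters in
    column *j* that equal the consensus character; 0.0 for columns where
    nothing votes (consensus '-').
    """

    seq: str
    support: np.ndarray

    def __post_init__(self) -> None:
        if len(self.seq) != self.support.size:
            raise ValueError("support length must equal consensus length")


def build_consensus(aln: Alignment) -> ConsensusResult:
    """Build the plurality consensus of *aln*.

    Per column the plurality character among {A,C,G,T,-} wins; ties break
    by the order A<C<G<T<-; columns with no voting character yield '-'
    with support 0.
    """
    mat = np.frombuffer(
        "".join(aln.sequences).encode("ascii"), dtype=np.uint8
    ).reshape(len(aln), aln.length)
    # counts[c, j]: occurrences of voting character c in column j
    counts = (mat[None, :, :] == _VOTING[:, None, None]).sum(axis=1)
    totals = counts.sum(axis=0)
    winner = counts.argmax(axis=0)  # first max -> tie order A<C<G<T<-
    chars = _VOTING[winner]
    chars = np.where(totals == 0, np.uint8(ord("-")), chars)
    with np.errstate(invalid="ignore"):
        support = np.where(
            totals > 0, counts.max(axis=0) / np.maximum(totals, 1), 0.0
        )
    return ConsensusResult(seq=chars.tobytes().decode("ascii"), support=support)
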