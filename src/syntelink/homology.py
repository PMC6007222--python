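"""Greedy incremental homolog clustering at a sequence-identity cutoff.

Re-implements the CD-HIT-style stage that groups genes across genomes:
sequences are sorted longest-first and scanned in order; each sequence
joins the first (oldest) existing cluster whose representative it matches
at or above the identity cutoff, otherwise it founds a new cluster with
itself as representative. A short-word (k-mer) count filter prunes
candidate representatives without ever rejecting a pair that could reach
the cutoff, so results with and without the filter are identical.

Identity between two sequences is the number of matched columns of an
optimal global alignment (match +1 / mismatch -1 / gap open -2 / extend -1)
divided by either the shorter sequence length (the CD-HIT convention,
default) or the alignment length.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from ._align import global_alignment_stats
from .models import ResolutionError

logger = logging.getLogger(__name__)

DEFAULT_IDENTITY_CUTOFF = 0.95  # "at least 95%" read as identity >= 0.95
DEFAULT_WORD_SIZE = 8


@dataclass(frozen=True)
class ClusteringParams:
    """Knobs of the greedy clustering stage.

    identity_cutoff
        Minimum identity of a member to its cluster representative,
        inclusive; fraction in (0, 1], default 0.95.
    word_size
        k-mer length of the candidate prefilter (>= 4).
    identity_denominator
        ``"shorter_sequence"`` (CD-HIT convention, default) or
        ``"alignment_length"``.
    """

    identity_cutoff: float = DEFAULT_IDENTITY_CUTOFF
    word_size: int = DEFAULT_WORD_SIZE
    identity_denominator: str = "shorter_sequence"

    def __post_init__(self) -> None:
        if not (0.0 < self.identity_cutoff <= 1.0):
            raise ValueError("identity_cutoff must be in (0, 1]")
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.identity_denominator not in ("shorter_sequence", "alignment_length"):
            raise ValueError(
                "identity_denominator must be 'shorter_sequence' or 'alignment_length'"
            )


@dataclass
class HomologGroup:
    """A cluster of homologous genes, possibly spanning genomes."""

    group_id: int
    representative_id: str
    #: (genome label, gene_id, identity to the representative)
    members: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def genomes(self) -> set[str]:
        return {genome for genome, _, _ in self.members}

    def members_of(self, genome: str) -> list[tuple[str, float]]:
        return [(gid, ident) for g, gid, ident in self.members if g == genome]


def pairwise_identity(
    seq_a: str, seq_b: str, denominator: str = "shorter_sequence"
) -> float:
    """Fraction of matched columns of an optimal global alignment.

    Symmetric in its arguments; denominator is the shorter input length or
    the total alignment length. Empty sequences are a hard error.
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    _, matches, aligned = global_alignment_stats(seq_a, seq_b)
    if denominator == "shorter_sequence":
        denom = min(len(seq_a), len(seq_b))
    elif denominator == "alignment_length":
        # columns = substitution columns + gapped columns
        denom = len(seq_a) + len(seq_b) - aligned
    else:
        raise ValueError(f"unknown identity denominator {denominator!r}")
    return matches / denom


def _kmer_counts(seq: str, k: int) -> dict[str, int]:
    counts: dict[str, int] = defaultdict(int)
    for i in range(len(seq) - k + 1):
        counts[seq[i : i + k]] += 1
    return counts


def min_shared_words(l_short: int, word_size: int, identity_cutoff: float) -> float:
    """Minimum k-mer sharing forced by the cutoff, floored at 0.

    A pair at identity p over the shorter length L has at most (1-p)*L
    mismatching positions, each destroying at most ``word_size`` of the
    L - word_size + 1 words of the shorter sequence, so at least
    L - word_size*(1-p)*L - word_size + 1 words survive intact.
    """
    bound = (
        l_short
        - word_size * (1.0 - identity_cutoff) * l_short
        - word_size
        + 1.0
    )
    return max(0.0, bound)


def kmer_prefilter(
    seq_a: str,
    seq_b: str,
    word_size: int = DEFAULT_WORD_SIZE,
    identity_cutoff: float = DEFAULT_IDENTITY_CUTOFF,
) -> bool:
    """True if the pair could reach the cutoff (candidate), False if the
    shared-word count rules it out. Never falsely rejects: rejection only
    when the count falls below the bound of :func:`min_shared_words`."""
    if len(seq_a) > len(seq_b):
        seq_a, seq_b = seq_b, seq_a
    l_short = len(seq_a)
    if l_short < word_size:
        return True
    needed = min_shared_words(l_short, word_size, identity_cutoff)
    if needed <= 0:
        return True
    other = set()
    for i in range(len(seq_b) - word_size + 1):
        other.add(seq_b[i : i + word_size])
    shared = 0
    for i in range(l_short - word_size + 1):
        if seq_a[i : i + word_size] in other:
            shared += 1
    return shared >= needed


class _RepIndex:
    """Inverted k-mer index over cluster representatives for fast candidate
    lookup during the greedy scan."""

    def __init__(self, word_size: int) -> None:
        self.word_size = word_size
        self._index: dict[str, list[int]] = defaultdict(list)
        self._lengths: list[int] = []

    def add(self, rep_id: int, seq: str) -> None:
        k = self.word_size
        self._lengths.append(len(seq))
        words = {seq[i : i + k] for i in range(len(seq) - k + 1)}
        for word in words:
            self._index[word].append(rep_id)

    def candidates(self, seq: str, identity_cutoff: float) -> list[int]:
        """Representatives (in creation order) passing the shared-word bound."""
        k = self.word_size
        shared: dict[int, int] = defaultdict(int)
        for i in range(len(seq) - k + 1):
            for rep in self._index.get(seq[i : i + k], ()):
                shared[rep] += 1
        out = []
        for rep in range(len(self._lengths)):
            l_short = min(len(seq), self._lengths[rep])
            if l_short < k:
                out.append(rep)
                continue
            needed = min_shared_words(l_short, k, identity_cutoff)
            if shared.get(rep, 0) >= needed:
                out.append(rep)
        return out


def cluster_greedy(
    sequences: Mapping[str, str],
    genome_of: Mapping[str, str],
    params: ClusteringParams | None = None,
    use_prefilter: bool = True,
) -> list[HomologGroup]:
    """Greedy incremental clustering of gene sequences across genomes.

    Sequences are visited longest-first (ties: identifier ascending); each
    joins the first existing representative at identity >= cutoff, else
    founds a new group. Deterministic for fixed input. ``genome_of`` maps
    every sequence identifier to its genome label.
    """
    params = params or ClusteringParams()
    for name in sequences:
        if name not in genome_of:
            raise ResolutionError(f"sequence {name!r} has no genome label")
        if not sequences[name]:
            raise ValueError(f"empty sequence {name!r}")

    order = sorted(sequences, key=lambda n: (-len(sequences[n]), n))
    groups: list[HomologGroup] = []
    reps: list[str] = []
    index = _RepIndex(params.word_size)

    for name in order:
        seq = sequences[name]
        if use_prefilter:
            candidate_ids = index.candidates(seq, params.identity_cutoff)
        else:
            candidate_ids = list(range(len(reps)))
        placed = False
        for rep_idx in candidate_ids:
            identity = pairwise_identity(
                seq, sequences[reps[rep_idx]], params.identity_denominator
            )
            if identity >= params.identity_cutoff:
                groups[rep_idx].members.append((genome_of[name], name, identity))
                placed = True
                break
        if not placed:
            group = HomologGroup(
                group_id=len(groups),
                representative_id=name,
                members=[(genome_of[name], name, 1.0)],
            )
            groups.append(group)
            reps.append(name)
            index.add(len(reps) - 1, seq)
    logger.info(
        "clustered %d sequences into %d groups (cutoff %.3f)",
        len(sequences),
        len(groups),
        params.identity_cutoff,
    )
    return groups


def cross_genome_groups(
    groups: Iterable[HomologGroup], genome_a: str, genome_b: str
) -> list[HomologGroup]:
    """Groups with at least one member in each of the two genomes, order
    preserved. Unknown genome labels are a hard error."""
    groups = list(groups)
    known = {g for grp in groups for g in grp.genomes}
    for label in (genome_a, genome_b):
        if label not in known:
            raise ResolutionError(f"genome label {label!r} absent from groups")
    return [g for g in groups if genome_a in g.genomes and genome_b in g.genomes]


def groups_to_rows(groups: Iterable[HomologGroup]) -> list[dict]:
    """Flatten groups for the TSV output (group_id, representative_id,
    genome, gene_id, identity)."""
    rows = []
    for group in groups:
        for genome, gene_id, identity in group.members:
            rows.append(
                {
                    "group_id": group.group_id,
                    "representative_id": group.representative_id,
                    "genome": genome,
                    "gene_id": gene_id,
                    "identity": round(identity, 6),
                }
            )
    return rows


def groups_from_rows(rows) -> list[HomologGroup]:
    """Inverse of :func:`groups_to_rows` (accepts an iterable of dicts or a
    DataFrame)."""
    import pandas as pd

    if isinstance(rows, pd.DataFrame):
        rows = rows.to_dict(orient="records")
    by_id: dict[int, HomologGroup] = {}
    for row in rows:
        gid = int(row["group_id"])
        if gid not in by_id:
            by_id[gid] = HomologGroup(
                group_id=gid, representative_id=str(row["representative_id"])
            )
        by_id[gid].members.append(
            (str(row["genome"]), str(row["gene_id"]), float(row["identity"]))
        )
    return [by_id[gid] for gid in sorted(by_id)]
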