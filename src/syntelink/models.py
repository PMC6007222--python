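"""Core domain types shared across the pipeline.

All genomic coordinates are 1-based and inclusive at both ends, matching the
GFF3 and VCF conventions of the input formats; no half-open coordinate is
ever stored or serialized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping


class SyntelinkError(Exception):
    """Base class for all package errors."""


class FormatError(SyntelinkError):
    """Malformed or invariant-violating input data."""


class ResolutionError(SyntelinkError):
    """An identifier could not be resolved against a catalog or sequence set."""


@dataclass(frozen=True)
class GeneModel:
    """A single gene: identity, location and free-text description.

    ``aliases`` holds alternative identifiers (transcript and protein IDs)
    that resolve to this gene; important for annotations such as potato's,
    where gene, transcript and protein identifiers differ.
    """

    gene_id: str
    genome: str
    chromosome: str
    start: int
    end: int
    strand: str
    aliases: frozenset[str] = frozenset()
    description: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise FormatError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, start: int, end: int) -> bool:
        """Closed-interval overlap with [start, end]."""
        return self.start <= end and start <= self.end


class SequenceSet(Mapping[str, str]):
    """An identifier -> nucleotide sequence mapping (uppercase A/C/G/T/N).

    Identifiers are unique and sequences non-empty; both are enforced on
    insertion.
    """

    def __init__(self, sequences: Mapping[str, str] | None = None) -> None:
        self._seqs: dict[str, str] = {}
        if sequences:
            for name, seq in sequences.items():
                self.add(name, seq)

    def add(self, name: str, seq: str) -> None:
        if name in self._seqs:
            raise FormatError(f"duplicate sequence identifier: {name!r}")
        if not seq:
            raise FormatError(f"empty sequence for identifier {name!r}")
        self._seqs[name] = seq.upper()

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._seqs)

    def __len__(self) -> int:
        return len(self._seqs)

    def __repr__(self) -> str:  # pragma: no cover
        return f"SequenceSet({len(self)} sequences)"


class GeneCatalog:
    """All gene models of one genome, ordered by position within chromosomes.

    Maintains a per-chromosome list sorted by ``start`` plus identifier
    indexes so genes can be looked up by gene ID or by any alias,
    case-insensitively. The positional ordinal of a gene along its chromosome
    (0-based rank by start) is the coordinate system used by synteny
    chaining.
    """

    def __init__(
        self,
        genome: str,
        genes: Iterable[GeneModel] = (),
        chromosome_lengths: Mapping[str, int] | None = None,
    ) -> None:
        self.genome = genome
        self.chromosome_lengths: dict[str, int] = dict(chromosome_lengths or {})
        self._by_chrom: dict[str, list[GeneModel]] = {}
        self._by_id: dict[str, GeneModel] = {}
        self._by_alias: dict[str, str] = {}  # lowercased alias -> gene_id
        self._ordinal: dict[str, int] = {}
        for gene in genes:
            self._insert(gene)
        self._reindex()

    # -- construction ------------------------------------------------------

    def _insert(self, gene: GeneModel) -> None:
        if gene.genome != self.genome:
            raise FormatError(
                f"gene {gene.gene_id} labelled {gene.genome!r}, catalog is {self.genome!r}"
            )
        if gene.gene_id in self._by_id:
            raise FormatError(f"duplicate gene_id {gene.gene_id!r} in {self.genome}")
        length = self.chromosome_lengths.get(gene.chromosome)
        if length is not None and gene.end > length:
            raise FormatError(
                f"gene {gene.gene_id} ends at {gene.end}, beyond "
                f"{gene.chromosome} length {length}"
            )
        self._by_id[gene.gene_id] = gene
        key = gene.gene_id.lower()
        self._by_alias[key] = gene.gene_id
        for alias in gene.aliases:
            akey = alias.lower()
            owner = self._by_alias.get(akey)
            if owner is not None and owner != gene.gene_id:
                raise FormatError(
                    f"alias {alias!r} maps to both {owner!r} and {gene.gene_id!r}"
                )
            self._by_alias[akey] = gene.gene_id
        self._by_chrom.setdefault(gene.chromosome, []).append(gene)

    def _reindex(self) -> None:
        self._ordinal.clear()
        for chrom in self._by_chrom:
            self._by_chrom[chrom].sort(key=lambda g: (g.start, g.end, g.gene_id))
            for rank, gene in enumerate(self._by_chrom[chrom]):
                self._ordinal[gene.gene_id] = rank

    # -- access ------------------------------------------------------------

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom)

    def genes(self) -> Iterator[GeneModel]:
        for chrom in self.chromosomes:
            yield from self._by_chrom[chrom]

    def genes_on(self, chromosome: str) -> list[GeneModel]:
        if chromosome not in self._by_chrom:
            raise ResolutionError(
                f"unknown chromosome {chromosome!r} in genome {self.genome}"
            )
        return list(self._by_chrom[chromosome])

    def get(self, gene_id: str) -> GeneModel:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise ResolutionError(
                f"gene {gene_id!r} not found in genome {self.genome}"
            ) from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __len__(self) -> int:
        return len(self._by_id)

    def resolve(self, identifier: str) -> GeneModel | None:
        """Resolve a gene ID *or any alias*, case-insensitively; None if absent."""
        gene_id = self._by_alias.get(identifier.lower())
        return self._by_id[gene_id] if gene_id is not None else None

    def ordinal(self, gene_id: str) -> int:
        """0-based rank of the gene along its chromosome, ordered by start."""
        self.get(gene_id)  # raise if absent
        return self._ordinal[gene_id]

    def chromosome_length(self, chromosome: str) -> int:
        """Declared length, or the last gene end if no length was provided."""
        if chromosome in self.chromosome_lengths:
            return self.chromosome_lengths[chromosome]
        genes = self.genes_on(chromosome)
        return max(g.end for g in genes)

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GeneCatalog({self.genome!r}, {len(self)} genes, "
            f"{len(self._by_chrom)} chromosomes)"
        )
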