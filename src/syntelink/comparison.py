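"""Cross-genome ortholog table, per-gene homology classification and the
three target-gene search modes (ID, description, position).

Classification follows the chromosome-comparison colour logic: for each
gene of the query genome, *same_chromosome* (pink) if any homolog lies on
the paired chromosome of the other genome, *different_chromosome* (navy)
if homologs exist only elsewhere, *no_homology* (mint) otherwise. The
chromosome pairing itself is derived from the synteny blocks by a
majority-anchor rule (and can be overridden by the caller).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .homology import HomologGroup
from .models import GeneCatalog, GeneModel, ResolutionError
from .synteny import SyntenyBlock

logger = logging.getLogger(__name__)

SAME_CHROMOSOME = "same_chromosome"
DIFFERENT_CHROMOSOME = "different_chromosome"
NO_HOMOLOGY = "no_homology"

CATEGORIES = (SAME_CHROMOSOME, DIFFERENT_CHROMOSOME, NO_HOMOLOGY)


@dataclass
class OrthologRecord:
    """Classification of one genome-A gene against genome B."""

    gene: GeneModel
    partners: list[GeneModel] = field(default_factory=list)
    group_id: int | None = None
    category: str = NO_HOMOLOGY
    in_synteny: bool = False


def default_pairing(
    blocks: Iterable[SyntenyBlock],
    catalog_a: GeneCatalog | None = None,
) -> dict[str, str | None]:
    """Map each A-chromosome to the B-chromosome sharing the most anchors.

    Ties break to the lexicographically smaller B name. If a catalog is
    supplied, its anchor-free chromosomes are mapped to None and logged.
    """
    votes: dict[str, Counter] = {}
    for block in blocks:
        votes.setdefault(block.chrom_a, Counter())[block.chrom_b] += block.score
    pairing: dict[str, str | None] = {}
    for chrom_a, counter in votes.items():
        top = max(counter.values())
        pairing[chrom_a] = min(c for c, n in counter.items() if n == top)
    if catalog_a is not None:
        for chrom in catalog_a.chromosomes:
            if chrom not in pairing:
                pairing[chrom] = None
                logger.warning(
                    "chromosome %s of %s has no anchors; no paired chromosome",
                    chrom,
                    catalog_a.genome,
                )
    return pairing


def classify_genes(
    catalog_a: GeneCatalog,
    catalog_b: GeneCatalog,
    groups: Iterable[HomologGroup],
    pairing: dict[str, str | None],
    blocks: Iterable[SyntenyBlock],
) -> list[OrthologRecord]:
    """One record per genome-A gene, in catalog order.

    The three categories partition the gene set: a gene is
    ``same_chromosome`` iff at least one partner lies on the chromosome its
    own chromosome is paired with, ``different_chromosome`` iff it has
    partners but none on the paired chromosome, and ``no_homology`` iff it
    has no partner in genome B at all. ``in_synteny`` flags membership in
    any synteny block.
    """
    partner_map: dict[str, tuple[int, list[str]]] = {}
    for group in groups:
        ids_b = [gid for gid, _ in group.members_of(catalog_b.genome)]
        if not ids_b:
            continue
        for gid_a, _ in group.members_of(catalog_a.genome):
            partner_map[gid_a] = (group.group_id, ids_b)

    in_block: set[str] = set()
    for block in blocks:
        in_block.update(block.gene_ids())

    records: list[OrthologRecord] = []
    for gene in catalog_a.genes():
        record = OrthologRecord(gene=gene, in_synteny=gene.gene_id in in_block)
        entry = partner_map.get(gene.gene_id)
        if entry is not None:
            group_id, ids_b = entry
            record.group_id = group_id
            record.partners = [catalog_b.get(gid) for gid in ids_b]
            paired_chrom = pairing.get(gene.chromosome)
            if paired_chrom is not None and any(
                p.chromosome == paired_chrom for p in record.partners
            ):
                record.category = SAME_CHROMOSOME
            else:
                record.category = DIFFERENT_CHROMOSOME
        records.append(record)
    return records


def records_to_rows(records: Sequence[OrthologRecord]) -> list[dict]:
    """Flatten ortholog records for the classification TSV."""
    return [
        {
            "gene_id": r.gene.gene_id,
            "chromosome": r.gene.chromosome,
            "start": r.gene.start,
            "end": r.gene.end,
            "category": r.category,
            "partner_ids": ",".join(p.gene_id for p in r.partners),
            "group_id": r.group_id if r.group_id is not None else "",
            "in_synteny": r.in_synteny,
        }
        for r in records
    ]


# -- search modes ----------------------------------------------------------


def search_by_id(
    query: str, catalogs: Sequence[GeneCatalog]
) -> list[GeneModel]:
    """Exact, case-insensitive match on gene ID or any alias, so e.g. a
    potato transcript or protein identifier resolves to its parent gene.
    No match is an empty result, not an error."""
    out: list[GeneModel] = []
    for catalog in catalogs:
        gene = catalog.resolve(query)
        if gene is not None:
            out.append(gene)
    return out


def search_by_description(
    query: str, catalogs: Sequence[GeneCatalog]
) -> list[GeneModel]:
    """Case-insensitive substring match on gene descriptions, sorted by
    (genome, chromosome, start)."""
    if not query:
        raise ValueError("description query must be non-empty")
    needle = query.lower()
    hits = [
        gene
        for catalog in catalogs
        for gene in catalog.genes()
        if needle in gene.description.lower()
    ]
    hits.sort(key=lambda g: (g.genome, g.chromosome, g.start))
    return hits


def search_by_position(
    chromosome: str, start: int, end: int, catalog: GeneCatalog
) -> list[GeneModel]:
    """Genes whose closed interval overlaps [start, end], sorted by start.
    An unknown chromosome is a hard error."""
    if start > end:
        raise ValueError(f"search interval has start {start} > end {end}")
    if chromosome not in catalog.chromosomes:
        raise ResolutionError(
            f"unknown chromosome {chromosome!r} in genome {catalog.genome}"
        )
    return [g for g in catalog.genes_on(chromosome) if g.overlaps(start, end)]
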