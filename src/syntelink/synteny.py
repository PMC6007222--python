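"""Collinear anchor chaining into synteny blocks.

Anchors are cross-genome ortholog pairs placed in gene-ordinal space (the
0-based rank of each gene along its chromosome). Blocks are extracted
greedily: the longest strictly monotone chain (rising in both genomes, or
rising in A while falling in B for an inverted block) is found by
longest-increasing-subsequence dynamic programming under a gene-count gap
cap, removed, and the process repeats until no chain reaches the minimum
anchor count. Chain length ties are broken by smaller starting ordinal in
genome A, then forward orientation before inverted — every output is
byte-deterministic for a fixed input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .homology import HomologGroup
from .models import GeneCatalog, GeneModel, ResolutionError

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_BP = 200_000  # the 0.2 Mbp sliding window of the block view

FORWARD = "forward"
INVERTED = "inverted"


@dataclass(frozen=True)
class Anchor:
    """One putative ortholog pair, positioned on a chromosome pair."""

    gene_a: str
    gene_b: str
    ord_a: int
    ord_b: int
    identity: float = 1.0
    e_value: float | None = None
    coverage: float | None = None
    # bp intervals of the two genes, used for block spans
    start_a: int = 0
    end_a: int = 0
    start_b: int = 0
    end_b: int = 0


@dataclass(frozen=True)
class AnchorFilters:
    """Quality filters applied to anchors: e-value ceiling, identity floor,
    alignment-coverage floor. An unset filter passes everything; an anchor
    missing the attribute of a *set* filter is dropped."""

    e_value_max: float | None = None
    identity_min: float | None = None
    coverage_min: float | None = None


@dataclass(frozen=True)
class ChainParams:
    """Chaining knobs: maximum ordinal step between consecutive anchors on
    either genome (max_gap_genes, i.e. at most max_gap_genes - 1 intervening
    genes) and the minimum anchors per reported block."""

    max_gap_genes: int = 10
    min_block_anchors: int = 3
    filters: AnchorFilters = field(default_factory=AnchorFilters)

    def __post_init__(self) -> None:
        if self.max_gap_genes < 1:
            raise ValueError("max_gap_genes must be >= 1")
        if self.min_block_anchors < 1:
            raise ValueError("min_block_anchors must be >= 1")


@dataclass
class SyntenyBlock:
    """An ordered collinear chain of anchors on one chromosome pair."""

    chrom_a: str
    chrom_b: str
    orientation: str
    anchors: list[Anchor]
    block_id: int = -1

    @property
    def score(self) -> int:
        return len(self.anchors)

    @property
    def span_a(self) -> tuple[int, int]:
        return (
            min(a.start_a for a in self.anchors),
            max(a.end_a for a in self.anchors),
        )

    @property
    def span_b(self) -> tuple[int, int]:
        return (
            min(a.start_b for a in self.anchors),
            max(a.end_b for a in self.anchors),
        )

    def gene_ids(self) -> set[str]:
        out: set[str] = set()
        for a in self.anchors:
            out.add(a.gene_a)
            out.add(a.gene_b)
        return out


def make_anchors(
    groups: Iterable[HomologGroup],
    catalog_a: GeneCatalog,
    catalog_b: GeneCatalog,
) -> dict[tuple[str, str], list[Anchor]]:
    """Turn cross-genome homolog groups into anchors keyed by chromosome pair.

    A group linking one gene of genome A to k genes of genome B fans out
    into k anchors (and symmetrically); chaining later decides which copy
    is the syntenic one. A member gene absent from its catalog is a hard
    error. Anchor identity is the smaller of the two members' identities to
    the group representative (a lower-bound proxy for the pair identity).
    """
    anchors: dict[tuple[str, str], list[Anchor]] = {}
    for group in groups:
        members_a = group.members_of(catalog_a.genome)
        members_b = group.members_of(catalog_b.genome)
        for gid_a, ident_a in members_a:
            if gid_a not in catalog_a:
                raise ResolutionError(
                    f"group {group.group_id}: gene {gid_a!r} not in catalog "
                    f"{catalog_a.genome}"
                )
            gene_a = catalog_a.get(gid_a)
            for gid_b, ident_b in members_b:
                if gid_b not in catalog_b:
                    raise ResolutionError(
                        f"group {group.group_id}: gene {gid_b!r} not in catalog "
                        f"{catalog_b.genome}"
                    )
                gene_b = catalog_b.get(gid_b)
                anchor = Anchor(
                    gene_a=gid_a,
                    gene_b=gid_b,
                    ord_a=catalog_a.ordinal(gid_a),
                    ord_b=catalog_b.ordinal(gid_b),
                    identity=min(ident_a, ident_b),
                    start_a=gene_a.start,
                    end_a=gene_a.end,
                    start_b=gene_b.start,
                    end_b=gene_b.end,
                )
                key = (gene_a.chromosome, gene_b.chromosome)
                anchors.setdefault(key, []).append(anchor)
    for key in anchors:
        anchors[key].sort(key=lambda a: (a.ord_a, a.ord_b))
    return anchors


def anchors_from_hits(
    hits,
    catalog_a: GeneCatalog,
    catalog_b: GeneCatalog,
) -> dict[tuple[str, str], list[Anchor]]:
    """Build anchors from a precomputed pairwise-hit table (query_id,
    subject_id, identity 0-100, alignment_length, e_value, query_coverage
    0-100). Hits whose query or subject is not a known gene/alias are
    skipped with a logged count."""
    anchors: dict[tuple[str, str], list[Anchor]] = {}
    skipped = 0
    for row in hits.itertuples(index=False):
        gene_a = catalog_a.resolve(str(row.query_id))
        gene_b = catalog_b.resolve(str(row.subject_id))
        if gene_a is None or gene_b is None:
            skipped += 1
            continue
        anchor = Anchor(
            gene_a=gene_a.gene_id,
            gene_b=gene_b.gene_id,
            ord_a=catalog_a.ordinal(gene_a.gene_id),
            ord_b=catalog_b.ordinal(gene_b.gene_id),
            identity=float(row.identity) / 100.0,
            e_value=float(row.e_value),
            coverage=float(row.query_coverage) / 100.0,
            start_a=gene_a.start,
            end_a=gene_a.end,
            start_b=gene_b.start,
            end_b=gene_b.end,
        )
        key = (gene_a.chromosome, gene_b.chromosome)
        anchors.setdefault(key, []).append(anchor)
    if skipped:
        logger.warning("anchors_from_hits: skipped %d unresolvable hits", skipped)
    for key in anchors:
        anchors[key].sort(key=lambda a: (a.ord_a, a.ord_b))
    return anchors


def filter_anchors(
    anchors: Sequence[Anchor], filters: AnchorFilters
) -> list[Anchor]:
    """Apply the syntenic quality filters (e-value, identity, coverage).

    An anchor lacking the attribute of a set filter fails that filter; the
    count of such drops is logged.
    """
    kept: list[Anchor] = []
    missing_drops = 0
    for anchor in anchors:
        ok = True
        if filters.e_value_max is not None:
            if anchor.e_value is None:
                ok = False
                missing_drops += 1
            elif anchor.e_value > filters.e_value_max:
                ok = False
        if ok and filters.identity_min is not None:
            if anchor.identity is None:
                ok = False
                missing_drops += 1
            elif anchor.identity < filters.identity_min:
                ok = False
        if ok and filters.coverage_min is not None:
            if anchor.coverage is None:
                ok = False
                missing_drops += 1
            elif anchor.coverage < filters.coverage_min:
                ok = False
        if ok:
            kept.append(anchor)
    if missing_drops:
        logger.info(
            "filter_anchors: %d anchors dropped for missing attributes",
            missing_drops,
        )
    return kept


def _longest_chain(
    anchors: list[Anchor], max_gap: int, orientation: str
) -> list[int]:
    """Longest strictly monotone chain (as indexes into ``anchors``) under
    the gap cap; among equal-length chains, the one with lexicographically
    smallest (ord_a, oriented ord_b) anchor sequence, which in particular
    starts at the smallest ord_a."""
    n = len(anchors)
    if n == 0:
        return []
    sign = 1 if orientation == FORWARD else -1
    keys = sorted(
        range(n), key=lambda i: (anchors[i].ord_a, sign * anchors[i].ord_b)
    )

    def step_ok(i: int, j: int) -> bool:
        ai, aj = anchors[i], anchors[j]
        if aj.ord_a <= ai.ord_a:
            return False
        if sign * aj.ord_b <= sign * ai.ord_b:
            return False
        if aj.ord_a - ai.ord_a > max_gap:
            return False
        if abs(aj.ord_b - ai.ord_b) > max_gap:
            return False
        return True

    # chain length starting at each anchor, computed right-to-left
    length_from = [1] * n
    for pos in range(n - 1, -1, -1):
        i = keys[pos]
        best = 1
        for nxt in range(pos + 1, n):
            j = keys[nxt]
            if step_ok(i, j) and 1 + length_from[nxt] > best:
                best = 1 + length_from[nxt]
        length_from[pos] = best

    total = max(length_from)
    # greedy reconstruction: smallest (ord_a, oriented ord_b) at each step
    chain: list[int] = []
    current = None
    remaining = total
    for pos in range(n):
        if length_from[pos] == remaining and (
            current is None or step_ok(keys[current], keys[pos])
        ):
            chain.append(keys[pos])
            current = pos
            remaining -= 1
            if remaining == 0:
                break
    return chain


def chain_anchors(
    anchors: Sequence[Anchor],
    params: ChainParams | None = None,
    chrom_a: str = "",
    chrom_b: str = "",
) -> list[SyntenyBlock]:
    """Greedy best-chain-first decomposition of one chromosome pair's anchors.

    Anchors are de-duplicated on (ord_a, ord_b) (highest identity kept),
    then quality-filtered per ``params.filters``. Repeatedly the longest
    monotone chain over both orientations is extracted as one block until
    no chain reaches ``min_block_anchors``. Length ties prefer the chain
    with the smaller starting ordinal in A, then forward over inverted.
    """
    params = params or ChainParams()
    filtered = filter_anchors(list(anchors), params.filters)
    dedup: dict[tuple[int, int], Anchor] = {}
    for anchor in filtered:
        key = (anchor.ord_a, anchor.ord_b)
        prior = dedup.get(key)
        if prior is None or anchor.identity > prior.identity:
            dedup[key] = anchor
    pool = [dedup[k] for k in sorted(dedup)]

    blocks: list[SyntenyBlock] = []
    while pool:
        forward = _longest_chain(pool, params.max_gap_genes, FORWARD)
        inverted = _longest_chain(pool, params.max_gap_genes, INVERTED)
        candidates: list[tuple[int, int, int, str, list[int]]] = []
        if forward:
            candidates.append(
                (-len(forward), pool[forward[0]].ord_a, 0, FORWARD, forward)
            )
        if inverted:
            candidates.append(
                (-len(inverted), pool[inverted[0]].ord_a, 1, INVERTED, inverted)
            )
        if not candidates:
            break
        candidates.sort(key=lambda c: c[:3])
        neg_len, _, _, orientation, chain = candidates[0]
        if -neg_len < params.min_block_anchors:
            break
        chain_set = set(chain)
        blocks.append(
            SyntenyBlock(
                chrom_a=chrom_a,
                chrom_b=chrom_b,
                orientation=orientation,
                anchors=[pool[i] for i in chain],
            )
        )
        pool = [a for i, a in enumerate(pool) if i not in chain_set]
    return blocks


def build_blocks(
    anchor_map: dict[tuple[str, str], list[Anchor]],
    params: ChainParams | None = None,
) -> list[SyntenyBlock]:
    """Chain every chromosome pair and assign sequential block IDs
    (chromosome pairs visited in sorted order)."""
    params = params or ChainParams()
    blocks: list[SyntenyBlock] = []
    for chrom_a, chrom_b in sorted(anchor_map):
        for block in chain_anchors(
            anchor_map[(chrom_a, chrom_b)], params, chrom_a, chrom_b
        ):
            blocks.append(replace_block_id(block, len(blocks)))
    return blocks


def replace_block_id(block: SyntenyBlock, block_id: int) -> SyntenyBlock:
    block.block_id = block_id
    return block


def block_for_gene(gene_id: str, blocks: Iterable[SyntenyBlock]) -> list[SyntenyBlock]:
    """All blocks whose anchor list contains the gene (either genome); an
    empty result means the gene is not in synteny."""
    return [b for b in blocks if gene_id in b.gene_ids()]


@dataclass
class WindowGene:
    """One gene row of a window report, with its signed offset from the
    centered gene (the centered gene itself is 0)."""

    gene: GeneModel
    rel_index: int
    in_anchor: bool


@dataclass
class WindowReport:
    """Genes of both genomes around a centered gene, with anchor links."""

    center_gene: str
    window_a: tuple[str, int, int]  # chromosome, start, end (bp, clipped)
    window_b: tuple[str, int, int] | None
    genes_a: list[WindowGene]
    genes_b: list[WindowGene]
    #: (gene_a, gene_b) pairs with both ends inside the window
    anchor_links: list[tuple[str, str]]
    block: SyntenyBlock | None


def window_view(
    catalog_a: GeneCatalog,
    catalog_b: GeneCatalog,
    blocks: Iterable[SyntenyBlock],
    center_gene: str,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> WindowReport:
    """Region report for the synteny-block view around one gene.

    The genome-A window is ``window_bp`` wide, centered on the gene's
    midpoint and clipped to [1, chromosome length]; the partner region on
    genome B is taken from the span of the block containing the gene (the
    highest-scoring one if several). Genes overlapping each window are
    listed with relative indices ..., -2, -1, 0, +1, +2, ... by gene order;
    on genome B the zero point is the centered gene's anchor partner.
    """
    if center_gene not in catalog_a:
        raise ResolutionError(
            f"center gene {center_gene!r} not found in genome {catalog_a.genome}"
        )
    gene = catalog_a.get(center_gene)
    half = window_bp // 2
    mid = int(gene.midpoint)
    chrom_len = catalog_a.chromosome_length(gene.chromosome)
    win_start = max(1, mid - half)
    win_end = min(chrom_len, mid + half)

    containing = sorted(
        block_for_gene(center_gene, blocks),
        key=lambda b: (-b.score, b.block_id),
    )
    block = containing[0] if containing else None

    partner_of_center: str | None = None
    if block is not None:
        for anchor in block.anchors:
            if anchor.gene_a == center_gene:
                partner_of_center = anchor.gene_b
                break

    genes_a_raw = [
        g
        for g in catalog_a.genes_on(gene.chromosome)
        if g.overlaps(win_start, win_end)
    ]
    anchored_a: dict[str, str] = {}
    if block is not None:
        for anchor in block.anchors:
            anchored_a[anchor.gene_a] = anchor.gene_b
    center_pos = next(
        i for i, g in enumerate(genes_a_raw) if g.gene_id == center_gene
    )
    genes_a = [
        WindowGene(g, i - center_pos, g.gene_id in anchored_a)
        for i, g in enumerate(genes_a_raw)
    ]

    genes_b: list[WindowGene] = []
    window_b: tuple[str, int, int] | None = None
    anchor_links: list[tuple[str, str]] = []
    if block is not None:
        b_start, b_end = block.span_b
        window_b = (block.chrom_b, b_start, b_end)
        genes_b_raw = [
            g
            for g in catalog_b.genes_on(block.chrom_b)
            if g.overlaps(b_start, b_end)
        ]
        anchored_b = {a.gene_b for a in block.anchors}
        zero_pos = 0
        if partner_of_center is not None:
            for i, g in enumerate(genes_b_raw):
                if g.gene_id == partner_of_center:
                    zero_pos = i
                    break
        genes_b = [
            WindowGene(g, i - zero_pos, g.gene_id in anchored_b)
            for i, g in enumerate(genes_b_raw)
        ]
        ids_a = {g.gene.gene_id for g in genes_a}
        ids_b = {g.gene.gene_id for g in genes_b}
        anchor_links = [
            (a.gene_a, a.gene_b)
            for a in block.anchors
            if a.gene_a in ids_a and a.gene_b in ids_b
        ]
    return WindowReport(
        center_gene=center_gene,
        window_a=(gene.chromosome, win_start, win_end),
        window_b=window_b,
        genes_a=genes_a,
        genes_b=genes_b,
        anchor_links=anchor_links,
        block=block,
    )


def blocks_to_rows(blocks: Iterable[SyntenyBlock]) -> list[dict]:
    rows = []
    for b in blocks:
        (a0, a1), (b0, b1) = b.span_a, b.span_b
        rows.append(
            {
                "block_id": b.block_id,
                "chrom_a": b.chrom_a,
                "chrom_b": b.chrom_b,
                "orientation": b.orientation,
                "n_anchors": b.score,
                "span_a_start": a0,
                "span_a_end": a1,
                "span_b_start": b0,
                "span_b_end": b1,
            }
        )
    return rows


def anchors_to_rows(blocks: Iterable[SyntenyBlock]) -> list[dict]:
    rows = []
    for b in blocks:
        for a in b.anchors:
            rows.append(
                {
                    "block_id": b.block_id,
                    "gene_a": a.gene_a,
                    "gene_b": a.gene_b,
                    "ord_a": a.ord_a,
                    "ord_b": a.ord_b,
                    "identity": round(a.identity, 6),
                    "e_value": a.e_value if a.e_value is not None else "",
                    "coverage": a.coverage if a.coverage is not None else "",
                }
            )
    return rows
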