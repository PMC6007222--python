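"""End-to-end convenience: cluster -> anchors -> blocks -> classification.

Each step is an independent module function; this wrapper wires them
together for the common two-genome case and is what the CLI and the
planted-truth evaluations drive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .comparison import OrthologRecord, classify_genes, default_pairing
from .homology import (
    ClusteringParams,
    HomologGroup,
    cluster_greedy,
    cross_genome_groups,
)
from .models import GeneCatalog
from .synteny import Anchor, ChainParams, SyntenyBlock, build_blocks, make_anchors


@dataclass
class PipelineResult:
    groups: list[HomologGroup]
    cross_groups: list[HomologGroup]
    anchors: dict[tuple[str, str], list[Anchor]]
    blocks: list[SyntenyBlock]
    pairing: dict[str, str | None]
    records: list[OrthologRecord] = field(default_factory=list)


def run_pipeline(
    sequences_a: Mapping[str, str],
    sequences_b: Mapping[str, str],
    catalog_a: GeneCatalog,
    catalog_b: GeneCatalog,
    clustering: ClusteringParams | None = None,
    chaining: ChainParams | None = None,
) -> PipelineResult:
    """Cluster the two genomes' gene sequences, chain ortholog anchors into
    synteny blocks, derive the chromosome pairing and classify every
    genome-A gene."""
    sequences = dict(sequences_a)
    genome_of = {name: catalog_a.genome for name in sequences_a}
    for name, seq in sequences_b.items():
        sequences[name] = seq
        genome_of[name] = catalog_b.genome
    groups = cluster_greedy(sequences, genome_of, clustering)
    cross = cross_genome_groups(groups, catalog_a.genome, catalog_b.genome)
    anchors = make_anchors(cross, catalog_a, catalog_b)
    blocks = build_blocks(anchors, chaining)
    pairing = default_pairing(blocks, catalog_a)
    records = classify_genes(catalog_a, catalog_b, groups, pairing, blocks)
    return PipelineResult(
        groups=groups,
        cross_groups=cross,
        anchors=anchors,
        blocks=blocks,
        pairing=pairing,
        records=records,
    )
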