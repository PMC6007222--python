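"""Static SVG exports of the three comparison views, plus their backing
tables.

Level 1: whole-genome ideograms of the query genome with target genes
marked. Level 2: per-chromosome columns with every classified gene drawn
in its category colour (pink = homology on the paired chromosome,
navy = homology elsewhere, mint = no homology) and targets as red lines.
Level 3: two parallel gene tracks around a centered gene (labelled "0")
with anchor connector lines; an inverted block shows crossing connectors.

Rendering is deterministic: identical inputs give byte-identical SVG.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .comparison import (
    DIFFERENT_CHROMOSOME,
    NO_HOMOLOGY,
    SAME_CHROMOSOME,
    OrthologRecord,
)
from .models import GeneCatalog
from .synteny import SyntenyBlock, WindowReport

DEFAULT_COLORS = {
    SAME_CHROMOSOME: "#ffc0cb",  # pink
    DIFFERENT_CHROMOSOME: "#000080",  # navy
    NO_HOMOLOGY: "#aaf0d1",  # mint
}
TARGET_COLOR = "#ff0000"

WHOLE_GENOME = "whole_genome"
CHROMOSOME_COMPARISON = "chromosome_comparison"
SYNTENY_BLOCK = "synteny_block"


@dataclass(frozen=True)
class ViewSpec:
    """Which view to render, for which genome pair, at which focus."""

    level: str
    genome_a: str = ""
    genome_b: str = ""
    focus: str | None = None
    colors: dict = field(default_factory=lambda: dict(DEFAULT_COLORS))

    def __post_init__(self) -> None:
        if self.level not in (WHOLE_GENOME, CHROMOSOME_COMPARISON, SYNTENY_BLOCK):
            raise ValueError(f"unknown view level {self.level!r}")
        if self.level == SYNTENY_BLOCK and not self.focus:
            raise ValueError("synteny_block view requires a focus gene")


def _svg_root(width: int, height: int) -> ET.Element:
    return ET.Element(
        "svg",
        {
            "xmlns": "http://www.w3.org/2000/svg",
            "width": str(width),
            "height": str(height),
            "viewBox": f"0 0 {width} {height}",
        },
    )


def _to_string(root: ET.Element) -> str:
    return ET.tostring(root, encoding="unicode") + "\n"


def render_whole_genome(
    records: Sequence[OrthologRecord],
    catalog: GeneCatalog,
    targets: Iterable[str] = (),
    colors: dict | None = None,
) -> tuple[str, pd.DataFrame]:
    """Whole-genome ideogram: one to-scale chromosome glyph per chromosome,
    target genes marked with their IDs; companion table lists the homologs
    of every target."""
    colors = colors or DEFAULT_COLORS
    targets = set(targets)
    chroms = catalog.chromosomes
    max_len = max(catalog.chromosome_length(c) for c in chroms)
    col_w, gap, top, bottom, height_px = 40, 60, 40, 20, 400
    width = gap + len(chroms) * (col_w + gap)
    root = _svg_root(width, top + height_px + bottom)

    by_id = {r.gene.gene_id: r for r in records}
    for i, chrom in enumerate(chroms):
        x = gap + i * (col_w + gap)
        h = height_px * catalog.chromosome_length(chrom) / max_len
        ET.SubElement(
            root,
            "rect",
            {
                "class": "chromosome",
                "id": f"chrom-{chrom}",
                "x": str(x),
                "y": str(top),
                "width": str(col_w),
                "height": f"{h:.1f}",
                "fill": "#e8e8e8",
                "stroke": "#555555",
                "rx": "8",
            },
        )
        label = ET.SubElement(
            root,
            "text",
            {"x": str(x), "y": str(top - 8), "font-size": "12"},
        )
        label.text = chrom
        for gene in catalog.genes_on(chrom):
            if gene.gene_id in targets:
                y = top + height_px * gene.midpoint / max_len
                ET.SubElement(
                    root,
                    "line",
                    {
                        "class": "target",
                        "x1": str(x - 6),
                        "x2": str(x + col_w + 6),
                        "y1": f"{y:.1f}",
                        "y2": f"{y:.1f}",
                        "stroke": TARGET_COLOR,
                        "stroke-width": "2",
                    },
                )
                text = ET.SubElement(
                    root,
                    "text",
                    {
                        "class": "target-label",
                        "x": str(x + col_w + 8),
                        "y": f"{y + 4:.1f}",
                        "font-size": "10",
                        "fill": TARGET_COLOR,
                    },
                )
                text.text = gene.gene_id

    rows = []
    for gene_id in sorted(targets):
        record = by_id.get(gene_id)
        if record is None:
            continue
        rows.append(
            {
                "gene_id": gene_id,
                "chromosome": record.gene.chromosome,
                "start": record.gene.start,
                "end": record.gene.end,
                "category": record.category,
                "homologs": ",".join(p.gene_id for p in record.partners),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["gene_id", "chromosome", "start", "end", "category", "homologs"],
    )
    return _to_string(root), table


def render_chromosome_comparison(
    records: Sequence[OrthologRecord],
    pairing: dict[str, str | None],
    targets: Iterable[str] = (),
    colors: dict | None = None,
) -> str:
    """Chromosome comparison view: one column per query chromosome with a
    coloured glyph per gene (pink/navy/mint by category) and red target
    lines; a legend names the three categories."""
    colors = colors or DEFAULT_COLORS
    targets = set(targets)
    by_chrom: dict[str, list[OrthologRecord]] = {}
    for record in records:
        by_chrom.setdefault(record.gene.chromosome, []).append(record)
    chroms = sorted(by_chrom)
    max_end = max(r.gene.end for r in records)
    col_w, gap, top, height_px = 50, 70, 60, 420
    width = gap + len(chroms) * (col_w + gap)
    root = _svg_root(width, top + height_px + 40)

    legend = ET.SubElement(root, "g", {"class": "legend"})
    for i, category in enumerate((SAME_CHROMOSOME, DIFFERENT_CHROMOSOME, NO_HOMOLOGY)):
        ET.SubElement(
            legend,
            "rect",
            {
                "x": str(10 + i * 170),
                "y": "8",
                "width": "12",
                "height": "12",
                "fill": colors[category],
            },
        )
        text = ET.SubElement(
            legend,
            "text",
            {"x": str(26 + i * 170), "y": "18", "font-size": "11"},
        )
        text.text = category
    for i, chrom in enumerate(chroms):
        x = gap + i * (col_w + gap)
        ET.SubElement(
            root,
            "rect",
            {
                "class": "chromosome",
                "id": f"chrom-{chrom}",
                "x": str(x),
                "y": str(top),
                "width": str(col_w),
                "height": str(height_px),
                "fill": "none",
                "stroke": "#555555",
            },
        )
        title = ET.SubElement(
            root,
            "text",
            {"x": str(x), "y": str(top - 8), "font-size": "12"},
        )
        paired = pairing.get(chrom)
        title.text = f"{chrom} | {paired}" if paired else chrom
        for record in by_chrom[chrom]:
            y = top + height_px * record.gene.midpoint / max_end
            ET.SubElement(
                root,
                "rect",
                {
                    "class": f"gene {record.category}",
                    "x": str(x + 4),
                    "y": f"{y:.1f}",
                    "width": str(col_w - 8),
                    "height": "2",
                    "fill": colors[record.category],
                },
            )
            if record.gene.gene_id in targets:
                ET.SubElement(
                    root,
                    "line",
                    {
                        "class": "target",
                        "x1": str(x - 6),
                        "x2": str(x + col_w + 6),
                        "y1": f"{y:.1f}",
                        "y2": f"{y:.1f}",
                        "stroke": TARGET_COLOR,
                        "stroke-width": "2",
                    },
                )
    return _to_string(root)


def render_synteny_block(
    window: WindowReport,
    blocks: Iterable[SyntenyBlock] = (),
) -> tuple[str, pd.DataFrame]:
    """Synteny-block view around a centered gene: two parallel gene tracks
    with strand arrows, relative indices (centered gene labelled "0") and
    one connector line per anchor inside the window. The companion table
    mirrors the figure row-for-row."""
    track_y = {"a": 80, "b": 220}
    gene_w, gene_h, margin = 46, 16, 30
    n_cols = max(len(window.genes_a), len(window.genes_b), 1)
    width = margin * 2 + n_cols * (gene_w + 8)
    root = _svg_root(width, 300)

    positions: dict[str, tuple[float, float]] = {}

    def draw_track(genes, y: float, track: str) -> None:
        for i, wg in enumerate(genes):
            x = margin + i * (gene_w + 8)
            is_center = track == "a" and wg.rel_index == 0
            # strand arrow: a pentagon pointing along the gene's strand
            if wg.gene.strand == "+":
                points = (
                    f"{x},{y} {x + gene_w - 8},{y} {x + gene_w},{y + gene_h / 2} "
                    f"{x + gene_w - 8},{y + gene_h} {x},{y + gene_h}"
                )
            else:
                points = (
                    f"{x + 8},{y} {x + gene_w},{y} {x + gene_w},{y + gene_h} "
                    f"{x + 8},{y + gene_h} {x},{y + gene_h / 2}"
                )
            ET.SubElement(
                root,
                "polygon",
                {
                    "class": ("gene center" if is_center else "gene"),
                    "id": f"gene-{wg.gene.gene_id}",
                    "points": points,
                    "fill": TARGET_COLOR if is_center else "#cfd8ff",
                    "stroke": "#333333",
                },
            )
            label = ET.SubElement(
                root,
                "text",
                {
                    "class": "rel-index",
                    "x": f"{x + gene_w / 2:.1f}",
                    "y": f"{y - 6:.1f}",
                    "font-size": "10",
                    "text-anchor": "middle",
                },
            )
            label.text = (
                "0" if wg.rel_index == 0 else f"{wg.rel_index:+d}"
            )
            positions[wg.gene.gene_id] = (x + gene_w / 2, y)

    draw_track(window.genes_a, track_y["a"], "a")
    draw_track(window.genes_b, track_y["b"], "b")

    for gene_a, gene_b in window.anchor_links:
        xa, ya = positions[gene_a]
        xb, yb = positions[gene_b]
        ET.SubElement(
            root,
            "line",
            {
                "class": "connector",
                "x1": f"{xa:.1f}",
                "y1": f"{ya + gene_h:.1f}",
                "x2": f"{xb:.1f}",
                "y2": f"{yb:.1f}",
                "stroke": "#888888",
            },
        )

    rows = []
    for track, genes in (("a", window.genes_a), ("b", window.genes_b)):
        for wg in genes:
            rows.append(
                {
                    "track": track,
                    "rel_index": wg.rel_index,
                    "gene_id": wg.gene.gene_id,
                    "chromosome": wg.gene.chromosome,
                    "start": wg.gene.start,
                    "end": wg.gene.end,
                    "strand": wg.gene.strand,
                    "in_anchor": wg.in_anchor,
                    "description": wg.gene.description,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "track",
            "rel_index",
            "gene_id",
            "chromosome",
            "start",
            "end",
            "strand",
            "in_anchor",
            "description",
        ],
    )
    return _to_string(root), table
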