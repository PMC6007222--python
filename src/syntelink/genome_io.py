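"""Readers and writers for the standard formats the pipeline touches.

FASTA is parsed with Biopython, GFF3 with gffutils (in-memory database),
VCF with cyvcf2. Tabular outputs are TSV or JSON with lossless round-trip.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .models import FormatError, GeneCatalog, GeneModel, SequenceSet

logger = logging.getLogger(__name__)

HIT_TABLE_COLUMNS = [
    "query_id",
    "subject_id",
    "identity",
    "alignment_length",
    "e_value",
    "query_coverage",
]


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    The header token before the first whitespace is the identifier;
    sequences are uppercased. Duplicate identifiers and empty files are
    hard errors.
    """
    seqs = SequenceSet()
    for record in SeqIO.parse(str(path), "fasta"):
        seqs.add(record.id, str(record.seq))
    if len(seqs) == 0:
        raise FormatError(f"no FASTA records in {path}")
    return seqs


def write_fasta(seqs: SequenceSet, path: str | Path, width: int = 60) -> None:
    """Write sequences in deterministic insertion order, wrapped at ``width``."""
    with open(path, "w") as handle:
        for name in seqs:
            handle.write(f">{name}\n")
            seq = seqs[name]
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


_DESCRIPTION_ATTRS = ("Note", "description", "product")


def read_gff3(
    path: str | Path,
    genome: str,
    feature_type: str = "gene",
    chromosome_lengths: dict[str, int] | None = None,
) -> GeneCatalog:
    """Read a GFF3 file into a :class:`GeneCatalog` of one feature type.

    The ``ID`` attribute becomes the gene ID; ``Alias``/``Name`` attributes
    and the IDs of child mRNA/CDS features become aliases; the description
    is taken from ``Note``, falling back to ``description`` then ``product``.
    Features without an ID are skipped with a logged warning. A feature with
    end < start is a hard error.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    genes: list[GeneModel] = []
    skipped = 0
    for feat in db.features_of_type(feature_type):
        if feat.end < feat.start:
            raise FormatError(
                f"{path}: feature at {feat.seqid}:{feat.start} has end < start"
            )
        ids = feat.attributes.get("ID", [])
        if not ids:
            skipped += 1
            logger.warning(
                "skipping %s feature at %s:%d-%d with no ID attribute",
                feature_type,
                feat.seqid,
                feat.start,
                feat.end,
            )
            continue
        gene_id = ids[0]
        aliases: set[str] = set()
        for key in ("Alias", "Name"):
            for value in feat.attributes.get(key, []):
                if value != gene_id:
                    aliases.add(value)
        for child in db.children(gene_id):
            if child.featuretype in ("mRNA", "CDS", "transcript"):
                for cid in child.attributes.get("ID", []):
                    if cid != gene_id:
                        aliases.add(cid)
        description = ""
        for key in _DESCRIPTION_ATTRS:
            values = feat.attributes.get(key, [])
            if values:
                description = values[0]
                break
        strand = feat.strand if feat.strand in ("+", "-") else "+"
        genes.append(
            GeneModel(
                gene_id=gene_id,
                genome=genome,
                chromosome=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=strand,
                aliases=frozenset(aliases),
                description=description,
            )
        )
    if skipped:
        logger.warning("%s: skipped %d %s feature(s) without ID", path, skipped, feature_type)
    return GeneCatalog(genome, genes, chromosome_lengths=chromosome_lengths)


def write_gff3(catalog: GeneCatalog, path: str | Path) -> None:
    """Serialize a catalog as GFF3 gene features (plus one mRNA child per alias
    that looks like a transcript, i.e. ``<gene_id>.<n>``)."""
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for chrom in catalog.chromosomes:
            if chrom in catalog.chromosome_lengths:
                handle.write(
                    f"##sequence-region {chrom} 1 {catalog.chromosome_lengths[chrom]}\n"
                )
        for gene in catalog.genes():
            attrs = [f"ID={gene.gene_id}"]
            if gene.description:
                attrs.append(f"Note={gene.description}")
            plain_aliases = sorted(
                a for a in gene.aliases if not a.startswith(gene.gene_id + ".")
            )
            if plain_aliases:
                attrs.append("Alias=" + ",".join(plain_aliases))
            handle.write(
                "\t".join(
                    [
                        gene.chromosome,
                        "syntelink",
                        "gene",
                        str(gene.start),
                        str(gene.end),
                        ".",
                        gene.strand,
                        ".",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )
            for alias in sorted(a for a in gene.aliases if a.startswith(gene.gene_id + ".")):
                handle.write(
                    "\t".join(
                        [
                            gene.chromosome,
                            "syntelink",
                            "mRNA",
                            str(gene.start),
                            str(gene.end),
                            ".",
                            gene.strand,
                            ".",
                            f"ID={alias};Parent={gene.gene_id}",
                        ]
                    )
                    + "\n"
                )


def read_vcf(path: str | Path):
    """Read a VCF 4.x file with diploid GT calls into a GenotypeMatrix.

    Biallelic and multiallelic records are loaded; missing calls ("./.")
    are preserved as missing. A record whose ALT equals REF, or a file with
    no samples, is a hard error.
    """
    from cyvcf2 import VCF

    from .markers import GenotypeMatrix, SnpRecord

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise FormatError(f"{path}: VCF has no sample columns")
    sites: list[SnpRecord] = []
    rows: list[np.ndarray] = []
    for variant in vcf:
        alts = tuple(variant.ALT)
        if not alts or variant.REF in alts:
            raise FormatError(
                f"{path}: record at {variant.CHROM}:{variant.POS} has "
                f"ALT identical to REF (or no ALT)"
            )
        sites.append(
            SnpRecord(
                chromosome=variant.CHROM,
                position=variant.POS,
                ref=variant.REF,
                alts=alts,
                id=variant.ID,
            )
        )
        gts = np.asarray(variant.genotypes, dtype=np.int16)[:, :2]
        rows.append(gts.astype(np.int8))
    calls = (
        np.stack(rows) if rows else np.empty((0, len(samples), 2), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, sites=sites, calls=calls)


def write_table(
    rows: Sequence[dict] | pd.DataFrame,
    path: str | Path,
    format: str = "TSV",
    columns: Sequence[str] | None = None,
) -> None:
    """Write rows sharing a column schema as TSV (header + rows) or JSON
    (list of records). TSV preserves column order; both round-trip through
    :func:`read_table`."""
    if isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = pd.DataFrame(list(rows), columns=columns)
        if columns is None and not len(df.columns) and rows:
            raise FormatError("rows have no columns")
    fmt = format.upper()
    if fmt == "TSV":
        df.to_csv(path, sep="\t", index=False)
    elif fmt == "JSON":
        with open(path, "w") as handle:
            json.dump(df.to_dict(orient="records"), handle, indent=1)
            handle.write("\n")
    else:
        raise ValueError(f"unsupported table format: {format!r}")


def read_table(path: str | Path, format: str = "TSV") -> pd.DataFrame:
    fmt = format.upper()
    if fmt == "TSV":
        return pd.read_csv(path, sep="\t")
    if fmt == "JSON":
        with open(path) as handle:
            return pd.DataFrame(json.load(handle))
    raise ValueError(f"unsupported table format: {format!r}")


def read_hit_table(path: str | Path) -> pd.DataFrame:
    """Read an optional precomputed pairwise-hit table.

    Expected TSV columns: query_id, subject_id, identity (0-100),
    alignment_length, e_value, query_coverage (0-100).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in HIT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: hit table missing columns {missing}")
    return df[HIT_TABLE_COLUMNS]


def catalog_to_frame(catalog: GeneCatalog) -> pd.DataFrame:
    """Flatten a catalog to a DataFrame (one row per gene, catalog order)."""
    return pd.DataFrame(
        [
            {
                "gene_id": g.gene_id,
                "genome": g.genome,
                "chromosome": g.chromosome,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "description": g.description,
                "aliases": ",".join(sorted(g.aliases)),
            }
            for g in catalog.genes()
        ]
    )


def iter_fasta_lengths(seqs: SequenceSet) -> dict[str, int]:
    return {name: len(seqs[name]) for name in seqs}
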