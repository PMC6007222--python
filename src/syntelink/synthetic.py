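"""Synthetic genome pairs and genotype matrices with planted ground truth.

The generator emulates the comparative setting the pipeline targets: two
closely related genomes with near-identical gene content and order (the
Solanaceae premise), differing by point divergence plus a configurable
number of inversions, translocations, gene losses and tandem duplications.
Genotype matrices are drawn at planted allele frequencies under
Hardy-Weinberg sampling (or an inbred, RIL-like homozygous mode). Every
run is fully determined by its seed, and the emitted FASTA/GFF3/VCF files
are byte-identical across repeated runs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .genome_io import write_fasta, write_gff3
from .markers import GenotypeMatrix, SnpRecord
from .models import GeneCatalog, GeneModel, SequenceSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_DESCRIPTION_VOCAB = [
    "receptor-like kinase",
    "ABC transporter",
    "MYB transcription factor",
    "heat shock protein",
    "disease resistance protein",
    "cytochrome P450",
    "pectin lyase",
    "auxin response factor",
]


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions of a simulated genome pair.

    Defaults describe a pair of 2-chromosome genomes with 200 genes of
    1 kb per chromosome, 2% per-base divergence, two 8-gene inversions and
    one 5-gene translocation — a compact stand-in for the low-rearrangement
    regime of closely related crop genomes.
    """

    n_chromosomes: int = 2
    genes_per_chromosome: int = 200
    gene_length_bp: int = 1000
    intergenic_bp: int = 500
    divergence: float = 0.02
    inversion_count: int = 2
    inversion_length_genes: int = 8
    translocation_count: int = 1
    translocation_length_genes: int = 5
    gene_loss_fraction: float = 0.0
    duplication_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("divergence", "gene_loss_fraction", "duplication_fraction"):
            value = getattr(self, name)
            if not (0.0 <= value <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        for name in (
            "n_chromosomes",
            "genes_per_chromosome",
            "gene_length_bp",
            "intergenic_bp",
        ):
            if getattr(self, name) < 1 and name != "intergenic_bp":
                raise ValueError(f"{name} must be >= 1")
        if self.inversion_count and (
            self.inversion_length_genes > self.genes_per_chromosome
        ):
            raise ValueError("inversion longer than a chromosome")
        if self.translocation_count and (
            self.translocation_length_genes > self.genes_per_chromosome
        ):
            raise ValueError("translocation longer than a chromosome")


@dataclass
class PlantedInversion:
    chromosome: str
    start_index: int  # 0-based ordinal of the first inverted gene (genome A)
    length_genes: int
    gene_ids_a: list[str]
    gene_ids_b: list[str]


@dataclass
class PlantedTranslocation:
    source_chromosome: str
    dest_chromosome: str
    gene_ids_a: list[str]
    gene_ids_b: list[str]


@dataclass
class SyntheticTruth:
    """Planted ground truth of one simulated genome pair."""

    #: A-gene id -> B-gene id, or None where the B copy was lost
    ortholog_map: dict[str, str | None] = field(default_factory=dict)
    #: duplicated B-gene id -> source A-gene id
    duplications: dict[str, str] = field(default_factory=dict)
    inversions: list[PlantedInversion] = field(default_factory=list)
    translocations: list[PlantedTranslocation] = field(default_factory=list)
    #: A-chromosome -> B-chromosome correspondence
    chromosome_map: dict[str, str] = field(default_factory=dict)

    def lost_genes(self) -> set[str]:
        return {a for a, b in self.ortholog_map.items() if b is None}

    def translocated_genes_a(self) -> set[str]:
        out: set[str] = set()
        for event in self.translocations:
            out.update(event.gene_ids_a)
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "ortholog_map": self.ortholog_map,
                "duplications": self.duplications,
                "inversions": [asdict(i) for i in self.inversions],
                "translocations": [asdict(t) for t in self.translocations],
                "chromosome_map": self.chromosome_map,
            },
            indent=1,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        data = json.loads(text)
        return cls(
            ortholog_map=data["ortholog_map"],
            duplications=data["duplications"],
            inversions=[PlantedInversion(**i) for i in data["inversions"]],
            translocations=[PlantedTranslocation(**t) for t in data["translocations"]],
            chromosome_map=data["chromosome_map"],
        )


@dataclass
class _Slot:
    """One gene copy on genome B before coordinate layout."""

    b_id: str
    a_id: str | None  # None only for duplicate copies' bookkeeping clarity
    seq: str
    strand: str
    description: str


@dataclass
class SimulatedPair:
    """In-memory result of :func:`generate_genome_pair`."""

    params: SimulationParams
    catalog_a: GeneCatalog
    catalog_b: GeneCatalog
    genes_a: SequenceSet
    genes_b: SequenceSet
    chromosomes_a: SequenceSet
    chromosomes_b: SequenceSet
    truth: SyntheticTruth

    def gene_sequences(self) -> tuple[SequenceSet, SequenceSet]:
        return self.genes_a, self.genes_b

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Emit FASTA (genes + chromosomes), GFF3 and truth JSON; returns
        the path of each artifact. Byte-identical for identical params."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes_a": outdir / "genomeA.genes.fasta",
            "genes_b": outdir / "genomeB.genes.fasta",
            "chromosomes_a": outdir / "genomeA.fasta",
            "chromosomes_b": outdir / "genomeB.fasta",
            "gff_a": outdir / "genomeA.gff3",
            "gff_b": outdir / "genomeB.gff3",
            "truth": outdir / "truth.json",
        }
        write_fasta(self.genes_a, paths["genes_a"])
        write_fasta(self.genes_b, paths["genes_b"])
        write_fasta(self.chromosomes_a, paths["chromosomes_a"])
        write_fasta(self.chromosomes_b, paths["chromosomes_b"])
        write_gff3(self.catalog_a, paths["gff_a"])
        write_gff3(self.catalog_b, paths["gff_b"])
        paths["truth"].write_text(self.truth.to_json() + "\n")
        return paths


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0.0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    n_hits = int(hit.sum())
    if n_hits:
        # shift each hit base by 1..3 positions around the A/C/G/T wheel,
        # so a substitution never reproduces the original base
        lut = np.zeros(256, dtype=np.uint8)
        for i, b in enumerate(_BASES):
            lut[b] = i
        idx = (lut[arr[hit]] + rng.integers(1, 4, size=n_hits)) % 4
        arr[hit] = _BASES[idx]
    return arr.tobytes().decode("ascii")


_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.encode("ascii").translate(_COMP)[::-1].decode("ascii")


def _pick_windows(
    rng: np.random.Generator,
    n_chrom: int,
    genes_per_chrom: int,
    counts_lengths: list[tuple[int, int]],
) -> list[tuple[int, int, int]]:
    """Choose non-overlapping (chrom_index, start, length) gene windows for
    the planted events; hard error if they cannot be placed."""
    taken: dict[int, list[tuple[int, int]]] = {c: [] for c in range(n_chrom)}
    windows: list[tuple[int, int, int]] = []
    for count, length in counts_lengths:
        for _ in range(count):
            placed = False
            for _attempt in range(1000):
                chrom = int(rng.integers(0, n_chrom))
                if genes_per_chrom < length:
                    continue
                start = int(rng.integers(0, genes_per_chrom - length + 1))
                if all(
                    start + length <= s or start >= s + l
                    for s, l in taken[chrom]
                ):
                    taken[chrom].append((start, length))
                    windows.append((chrom, start, length))
                    placed = True
                    break
            if not placed:
                raise ValueError(
                    "could not place planted rearrangement windows; "
                    "chromosomes too small for the requested events"
                )
    return windows


def generate_genome_pair(params: SimulationParams | None = None) -> SimulatedPair:
    """Build genome A from seeded random sequence and derive genome B by
    divergence, inversions, translocations, loss and tandem duplication,
    recording every event in the truth."""
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    chrom_names = [f"chr{c + 1:02d}" for c in range(params.n_chromosomes)]

    # -- genome A gene content --------------------------------------------
    genes_a_by_chrom: list[list[tuple[str, str, str, str]]] = []
    for c in range(params.n_chromosomes):
        chrom_genes = []
        for j in range(params.genes_per_chromosome):
            a_id = f"gA{c + 1:02d}_{j + 1:04d}"
            seq = _random_seq(rng, params.gene_length_bp)
            strand = "+" if rng.random() < 0.5 else "-"
            description = (
                f"{_DESCRIPTION_VOCAB[j % len(_DESCRIPTION_VOCAB)]} {j + 1}"
            )
            chrom_genes.append((a_id, seq, strand, description))
        genes_a_by_chrom.append(chrom_genes)

    # -- genome B: diverged copies in A's order ---------------------------
    truth = SyntheticTruth(
        chromosome_map={name: name for name in chrom_names}
    )
    slots_by_chrom: list[list[_Slot]] = []
    for c in range(params.n_chromosomes):
        slots = []
        for a_id, seq, strand, description in genes_a_by_chrom[c]:
            b_id = "gB" + a_id[2:]
            slots.append(
                _Slot(
                    b_id=b_id,
                    a_id=a_id,
                    seq=_mutate(rng, seq, params.divergence),
                    strand=strand,
                    description=description,
                )
            )
            truth.ortholog_map[a_id] = b_id
        slots_by_chrom.append(slots)

    # -- planted rearrangements -------------------------------------------
    windows = _pick_windows(
        rng,
        params.n_chromosomes,
        params.genes_per_chromosome,
        [
            (params.inversion_count, params.inversion_length_genes),
            (params.translocation_count, params.translocation_length_genes),
        ],
    )
    inversion_windows = windows[: params.inversion_count]
    translocation_windows = windows[params.inversion_count :]

    for chrom, start, length in inversion_windows:
        segment = slots_by_chrom[chrom][start : start + length]
        inverted = [
            _Slot(
                b_id=s.b_id,
                a_id=s.a_id,
                seq=s.seq,
                strand="-" if s.strand == "+" else "+",
                description=s.description,
            )
            for s in reversed(segment)
        ]
        slots_by_chrom[chrom][start : start + length] = inverted
        truth.inversions.append(
            PlantedInversion(
                chromosome=chrom_names[chrom],
                start_index=start,
                length_genes=length,
                gene_ids_a=[s.a_id for s in segment],
                gene_ids_b=[s.b_id for s in segment],
            )
        )

    # translocations move a segment to a different chromosome; positions of
    # the planted windows were chosen disjoint, but the ordinal shifts from
    # removal mean we process them from the highest start index down
    for chrom, start, length in sorted(
        translocation_windows, key=lambda w: -w[1]
    ):
        if params.n_chromosomes < 2:
            raise ValueError("translocations need at least 2 chromosomes")
        segment = slots_by_chrom[chrom][start : start + length]
        del slots_by_chrom[chrom][start : start + length]
        dest_choices = [c for c in range(params.n_chromosomes) if c != chrom]
        dest = int(rng.choice(np.asarray(dest_choices)))
        # never split a planted inversion on the destination chromosome
        forbidden = [
            (s, s + l)
            for (c2, s, l) in inversion_windows
            if c2 == dest
        ]
        while True:
            insert_at = int(rng.integers(0, len(slots_by_chrom[dest]) + 1))
            if all(not (lo < insert_at < hi) for lo, hi in forbidden):
                break
        slots_by_chrom[dest][insert_at:insert_at] = segment
        truth.translocations.append(
            PlantedTranslocation(
                source_chromosome=chrom_names[chrom],
                dest_chromosome=chrom_names[dest],
                gene_ids_a=[s.a_id for s in segment],
                gene_ids_b=[s.b_id for s in segment],
            )
        )

    # -- gene loss and tandem duplication ---------------------------------
    if params.gene_loss_fraction > 0.0:
        for slots in slots_by_chrom:
            kept = []
            for slot in slots:
                if rng.random() < params.gene_loss_fraction:
                    truth.ortholog_map[slot.a_id] = None
                else:
                    kept.append(slot)
            slots[:] = kept
    if params.duplication_fraction > 0.0:
        for slots in slots_by_chrom:
            augmented: list[_Slot] = []
            for slot in slots:
                augmented.append(slot)
                if rng.random() < params.duplication_fraction:
                    dup = _Slot(
                        b_id=slot.b_id + "d",
                        a_id=slot.a_id,
                        seq=slot.seq,
                        strand=slot.strand,
                        description=slot.description,
                    )
                    augmented.append(dup)
                    truth.duplications[dup.b_id] = slot.a_id
            slots[:] = augmented

    # -- coordinate layout and sequence assembly --------------------------
    def layout(
        genome: str,
        per_chrom: list[list[tuple[str, str, str, str]]],
    ) -> tuple[GeneCatalog, SequenceSet, SequenceSet]:
        gene_seqs = SequenceSet()
        chrom_seqs = SequenceSet()
        models: list[GeneModel] = []
        lengths: dict[str, int] = {}
        for c, chrom_genes in enumerate(per_chrom):
            parts: list[str] = []
            cursor = 0
            chrom = chrom_names[c]
            for gene_id, seq, strand, description in chrom_genes:
                spacer = _random_seq(rng, params.intergenic_bp)
                parts.append(spacer)
                start = cursor + params.intergenic_bp + 1
                end = start + len(seq) - 1
                cursor = end
                parts.append(seq if strand == "+" else reverse_complement(seq))
                gene_seqs.add(gene_id, seq)
                models.append(
                    GeneModel(
                        gene_id=gene_id,
                        genome=genome,
                        chromosome=chrom,
                        start=start,
                        end=end,
                        strand=strand,
                        aliases=frozenset({f"{gene_id}.1"}),
                        description=description,
                    )
                )
            parts.append(_random_seq(rng, params.intergenic_bp))
            chrom_seq = "".join(parts)
            lengths[chrom] = len(chrom_seq)
            chrom_seqs.add(chrom, chrom_seq)
        catalog = GeneCatalog(genome, models, chromosome_lengths=lengths)
        return catalog, gene_seqs, chrom_seqs

    catalog_a, genes_a, chrom_a = layout("genomeA", genes_a_by_chrom)
    catalog_b, genes_b, chrom_b = layout(
        "genomeB",
        [
            [(s.b_id, s.seq, s.strand, s.description) for s in slots]
            for slots in slots_by_chrom
        ],
    )
    return SimulatedPair(
        params=params,
        catalog_a=catalog_a,
        catalog_b=catalog_b,
        genes_a=genes_a,
        genes_b=genes_b,
        chromosomes_a=chrom_a,
        chromosomes_b=chrom_b,
        truth=truth,
    )


# -- genotype simulation ---------------------------------------------------


@dataclass(frozen=True)
class PlantedSite:
    """A variant site with its planted alternate-allele frequency."""

    chromosome: str
    position: int
    ref: str
    alt: str
    frequency: float

    @property
    def planted_maf(self) -> float:
        return min(self.frequency, 1.0 - self.frequency)


def sites_from_reference(
    reference: SequenceSet,
    n_sites: int,
    seed: int,
    freq_low: float = 0.0,
    freq_high: float = 1.0,
) -> list[PlantedSite]:
    """Plant ``n_sites`` biallelic SNPs on a reference sequence set with
    alternate-allele frequencies uniform on [freq_low, freq_high]; REF is
    read off the reference so flank extraction validates."""
    rng = np.random.default_rng(seed)
    chroms = sorted(reference)
    sites: list[PlantedSite] = []
    used: set[tuple[str, int]] = set()
    while len(sites) < n_sites:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(1, len(reference[chrom]) + 1))
        if (chrom, pos) in used:
            continue
        ref = reference[chrom][pos - 1]
        if ref not in "ACGT":
            continue
        alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
        freq = float(rng.uniform(freq_low, freq_high))
        sites.append(
            PlantedSite(
                chromosome=chrom, position=pos, ref=ref, alt=alt, frequency=freq
            )
        )
        used.add((chrom, pos))
    sites.sort(key=lambda s: (s.chromosome, s.position))
    return sites


def generate_genotypes(
    n_samples: int,
    sites: Sequence[PlantedSite],
    missing_rate: float = 0.0,
    seed: int = 0,
    inbred: bool = False,
    exact: bool = False,
) -> GenotypeMatrix:
    """Draw a diploid genotype matrix at the planted frequencies.

    Hardy-Weinberg sampling by default (each allele an independent
    Bernoulli draw at the site frequency); ``inbred`` draws one allele per
    sample and doubles it (RIL-like homozygosity); ``exact`` plants exactly
    ``round(freq * 2 * n_samples)`` alternate alleles so the realized
    frequency matches the planted one to rounding. Whole genotypes are
    masked missing at ``missing_rate``.
    """
    if not (0.0 <= missing_rate <= 1.0):
        raise ValueError("missing_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_sites = len(sites)
    calls = np.zeros((n_sites, n_samples, 2), dtype=np.int8)
    for i, site in enumerate(sites):
        if not (0.0 <= site.frequency <= 1.0):
            raise ValueError(
                f"site {site.chromosome}:{site.position}: frequency outside [0, 1]"
            )
        if exact:
            n_alleles = 2 * n_samples
            n_alt = int(round(site.frequency * n_alleles))
            flat = np.zeros(n_alleles, dtype=np.int8)
            flat[:n_alt] = 1
            rng.shuffle(flat)
            calls[i] = flat.reshape(n_samples, 2)
        elif inbred:
            allele = (rng.random(n_samples) < site.frequency).astype(np.int8)
            calls[i, :, 0] = allele
            calls[i, :, 1] = allele
        else:
            calls[i] = (rng.random((n_samples, 2)) < site.frequency).astype(
                np.int8
            )
    if missing_rate > 0.0:
        mask = rng.random((n_sites, n_samples)) < missing_rate
        calls[mask] = -1
    records = [
        SnpRecord(
            chromosome=s.chromosome,
            position=s.position,
            ref=s.ref,
            alts=(s.alt,),
            id=f"snp{i + 1:06d}",
        )
        for i, s in enumerate(sites)
    ]
    samples = [f"sample{j + 1:04d}" for j in range(n_samples)]
    return GenotypeMatrix(samples=samples, sites=records, calls=calls)


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal deterministic VCF 4.2 with GT-only genotypes."""
    with open(path, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        handle.write("##source=syntelink-simulator\n")
        handle.write(
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
        )
        seen: list[str] = []
        for site in matrix.sites:
            if site.chromosome not in seen:
                seen.append(site.chromosome)
        for chrom in seen:
            handle.write(f"##contig=<ID={chrom}>\n")
        handle.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.samples)
            + "\n"
        )
        for i, site in enumerate(matrix.sites):
            cells = []
            for j in range(matrix.n_samples):
                a, b = matrix.calls[i, j]
                cells.append("./." if a < 0 or b < 0 else f"{a}/{b}")
            handle.write(
                "\t".join(
                    [
                        site.chromosome,
                        str(site.position),
                        site.id or ".",
                        site.ref,
                        ",".join(site.alts),
                        ".",
                        "PASS",
                        ".",
                        "GT",
                    ]
                    + cells
                )
                + "\n"
            )
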