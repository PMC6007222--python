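"""Minor-allele-frequency computation and filtering, gene-to-SNP linking,
and primer-ready flanking-sequence extraction.

MAF is computed per site over non-missing alleles only (each diploid call
contributes two); it is the frequency of the second-most-frequent allele,
so it is 0 for monomorphic sites and <= 0.5 for biallelic ones. The marker
pool filter keeps sites with MAF strictly greater than the threshold
(default 0.2). Flanking sequences are emitted as LEFT[REF/ALT]RIGHT text
blocks with up to 1 kbp of reference sequence on each side, ready to paste
into a primer-design tool.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .models import FormatError, GeneModel, ResolutionError, SequenceSet

logger = logging.getLogger(__name__)

DEFAULT_MAF_MIN = 0.2  # marker pool keeps sites with MAF strictly > 0.2
DEFAULT_FLANK_BP = 1000  # 1 kbp flanking sequence per side

MISSING = -1  # allele code for a missing call


class UndefinedMafError(FormatError):
    """Raised when every call at a site is missing."""


@dataclass(frozen=True)
class SnpRecord:
    """One variant site (1-based position). Indels are carried through but
    flagged; multiallelic sites keep all alternate alleles."""

    chromosome: str
    position: int
    ref: str
    alts: tuple[str, ...]
    id: str | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError(
                f"site {self.chromosome}:{self.position}: position must be >= 1"
            )
        if self.ref in self.alts:
            raise FormatError(
                f"site {self.chromosome}:{self.position}: REF equals an ALT"
            )

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def is_multiallelic(self) -> bool:
        return len(self.alts) > 1

    @property
    def alleles(self) -> tuple[str, ...]:
        return (self.ref,) + self.alts


class GenotypeMatrix:
    """Sample-by-site diploid call table.

    ``calls`` is an int8 array of shape (n_sites, n_samples, 2) holding
    allele indexes into each site's (REF, ALT1, ...) list, with -1 for a
    missing call.
    """

    def __init__(
        self,
        samples: Sequence[str],
        sites: Sequence[SnpRecord],
        calls: np.ndarray,
    ) -> None:
        calls = np.asarray(calls, dtype=np.int8)
        if calls.shape != (len(sites), len(samples), 2):
            raise FormatError(
                f"calls shape {calls.shape} does not match "
                f"{len(sites)} sites x {len(samples)} samples x 2"
            )
        for i, site in enumerate(sites):
            if calls[i].max(initial=MISSING) >= len(site.alleles):
                raise FormatError(
                    f"site {site.chromosome}:{site.position}: allele index "
                    f"out of range"
                )
        self.samples = list(samples)
        self.sites = list(sites)
        self.calls = calls

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def site_calls(self, index: int) -> np.ndarray:
        """(n_samples, 2) allele indexes for one site."""
        return self.calls[index]

    def subset(
        self,
        samples: Sequence[str] | None = None,
        site_indexes: Sequence[int] | None = None,
    ) -> "GenotypeMatrix":
        if samples is None:
            sample_idx = list(range(self.n_samples))
        else:
            if len(samples) == 0:
                raise ValueError("sample selection must be non-empty")
            pos = {s: i for i, s in enumerate(self.samples)}
            missing = [s for s in samples if s not in pos]
            if missing:
                raise ResolutionError(f"unknown samples: {missing}")
            sample_idx = [pos[s] for s in samples]
        if site_indexes is None:
            site_indexes = list(range(self.n_sites))
        sites = [self.sites[i] for i in site_indexes]
        calls = self.calls[np.ix_(site_indexes, sample_idx)]
        return GenotypeMatrix(
            [self.samples[i] for i in sample_idx], sites, calls
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"GenotypeMatrix({self.n_sites} sites x {self.n_samples} samples)"


@dataclass
class MarkerReport:
    """A SNP with its MAF and primer-ready flanking text."""

    snp: SnpRecord
    maf: float
    flank_left: str
    flank_right: str
    formatted: str


def compute_maf(calls: np.ndarray) -> float:
    """Minor allele frequency of one site from its (n_samples, 2) calls.

    Frequencies are over non-missing alleles; the MAF is the largest
    non-major allele frequency (for a biallelic site, the second allele's
    frequency, hence <= 0.5). All-missing input raises
    :class:`UndefinedMafError`.
    """
    flat = np.asarray(calls).reshape(-1)
    observed = flat[flat != MISSING]
    if observed.size == 0:
        raise UndefinedMafError("all calls missing; MAF undefined")
    counts = np.bincount(observed)
    if np.count_nonzero(counts) < 2:
        return 0.0
    ordered = np.sort(counts)[::-1]
    return float(ordered[1]) / float(observed.size)


def maf_table(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-site MAF table (NaN where every call is missing)."""
    rows = []
    for i, site in enumerate(matrix.sites):
        try:
            maf = compute_maf(matrix.site_calls(i))
        except UndefinedMafError:
            maf = float("nan")
        rows.append(
            {
                "chromosome": site.chromosome,
                "position": site.position,
                "ref": site.ref,
                "alt": ",".join(site.alts),
                "is_snp": site.is_snp,
                "multiallelic": site.is_multiallelic,
                "maf": maf,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chromosome",
            "position",
            "ref",
            "alt",
            "is_snp",
            "multiallelic",
            "maf",
        ],
    )


def filter_snps(
    matrix: GenotypeMatrix, maf_min: float = DEFAULT_MAF_MIN
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Restrict to sites with MAF strictly greater than ``maf_min``.

    Returns the filtered matrix plus the per-site MAF table with a ``kept``
    column; site order is preserved. Sites whose MAF is undefined (all
    calls missing) never pass.
    """
    table = maf_table(matrix)
    kept_mask = table["maf"] > maf_min  # NaN compares False
    table = table.assign(kept=kept_mask)
    kept_idx = [i for i, keep in enumerate(kept_mask) if keep]
    logger.info(
        "MAF filter (> %.3f): kept %d of %d sites",
        maf_min,
        len(kept_idx),
        matrix.n_sites,
    )
    return matrix.subset(site_indexes=kept_idx), table


def snps_in_gene(
    gene: GeneModel, matrix: GenotypeMatrix, flank_bp: int = 0
) -> list[SnpRecord]:
    """Sites inside the gene (closed interval, optionally widened by
    ``flank_bp`` on each side), sorted by position."""
    lo = gene.start - flank_bp
    hi = gene.end + flank_bp
    hits = [
        site
        for site in matrix.sites
        if site.chromosome == gene.chromosome and lo <= site.position <= hi
    ]
    hits.sort(key=lambda s: s.position)
    return hits


def flanking_sequence(
    snp: SnpRecord,
    reference: SequenceSet,
    flank_bp: int = DEFAULT_FLANK_BP,
    maf: float = float("nan"),
) -> MarkerReport:
    """Extract up to ``flank_bp`` reference bases on each side of a SNP.

    The reference base at the site must equal the REF allele (validated);
    flanks are truncated at chromosome edges; the formatted string is
    ``LEFT[REF/ALT1(/ALT2...)]RIGHT`` in uppercase.
    """
    if snp.chromosome not in reference:
        raise ResolutionError(
            f"chromosome {snp.chromosome!r} absent from reference sequences"
        )
    chrom_seq = reference[snp.chromosome]
    pos0 = snp.position - 1
    ref_len = len(snp.ref)
    if pos0 + ref_len > len(chrom_seq):
        raise FormatError(
            f"site {snp.chromosome}:{snp.position} beyond chromosome end"
        )
    observed = chrom_seq[pos0 : pos0 + ref_len]
    if observed != snp.ref.upper():
        raise FormatError(
            f"reference mismatch at {snp.chromosome}:{snp.position}: "
            f"VCF REF {snp.ref!r}, sequence has {observed!r}"
        )
    flank_left = chrom_seq[max(0, pos0 - flank_bp) : pos0]
    flank_right = chrom_seq[pos0 + ref_len : pos0 + ref_len + flank_bp]
    bracket = "[" + "/".join((snp.ref.upper(),) + tuple(a.upper() for a in snp.alts)) + "]"
    return MarkerReport(
        snp=snp,
        maf=maf,
        flank_left=flank_left,
        flank_right=flank_right,
        formatted=flank_left + bracket + flank_right,
    )


def marker_matrix_view(
    matrix: GenotypeMatrix,
    samples: Sequence[str] | None = None,
    site_indexes: Sequence[int] | None = None,
) -> tuple[GenotypeMatrix, pd.DataFrame, str]:
    """Row/column-restricted genotype table with MAF recomputed on the
    selected samples only.

    Returns the sub-matrix, its per-site MAF table and a TSV-style text
    rendering (sites as rows, samples as columns, calls as ``a/b`` with
    ``./.`` for missing). An empty sample selection is a hard error.
    """
    if samples is not None and len(samples) == 0:
        raise ValueError("sample selection must be non-empty")
    sub = matrix.subset(samples=samples, site_indexes=site_indexes)
    table = maf_table(sub)
    lines = ["\t".join(["chromosome", "position", "ref", "alt"] + sub.samples)]
    for i, site in enumerate(sub.sites):
        cells = []
        for j in range(sub.n_samples):
            a, b = sub.calls[i, j]
            cells.append("./." if a == MISSING or b == MISSING else f"{a}/{b}")
        lines.append(
            "\t".join(
                [site.chromosome, str(site.position), site.ref, ",".join(site.alts)]
                + cells
            )
        )
    return sub, table, "\n".join(lines) + "\n"


def write_marker_text(
    reports: Sequence[MarkerReport], path, flank_bp: int = DEFAULT_FLANK_BP
) -> None:
    """Plain-text marker output: one block per SNP, ready for primer design."""
    with open(path, "w") as handle:
        for report in reports:
            snp = report.snp
            name = snp.id or f"{snp.chromosome}_{snp.position}"
            handle.write(f"# {name} {snp.chromosome}:{snp.position} ")
            handle.write(f"{snp.ref}>{','.join(snp.alts)}")
            if report.maf == report.maf:  # not NaN
                handle.write(f" MAF={report.maf:.4f}")
            handle.write(f" flank={flank_bp}bp\n")
            handle.write(report.formatted + "\n\n")
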