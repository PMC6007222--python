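"""MAF computation, the strict marker-pool filter, gene-SNP linking and
flanking-sequence extraction."""

import random

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from syntelink.markers import (
    GenotypeMatrix,
    SnpRecord,
    UndefinedMafError,
    compute_maf,
    filter_snps,
    flanking_sequence,
    marker_matrix_view,
    snps_in_gene,
)
from syntelink.models import FormatError, GeneModel, SequenceSet
from syntelink.synthetic import PlantedSite, generate_genotypes


def calls(*genotypes):
    """Build a one-site calls array from '0/1'-style strings."""
    out = []
    for gt in genotypes:
        a, b = gt.split("/")
        out.append(
            [-1 if a == "." else int(a), -1 if b == "." else int(b)]
        )
    return np.array(out, dtype=np.int8)


def matrix_from(sites_calls, positions=None, chrom="chr1"):
    sites = [
        SnpRecord(chrom, (positions or range(1, len(sites_calls) + 1))[i], "A", ("G",))
        for i in range(len(sites_calls))
    ]
    n_samples = sites_calls[0].shape[0]
    samples = [f"s{j}" for j in range(n_samples)]
    return GenotypeMatrix(samples, sites, np.stack(sites_calls))


# -- compute_maf -----------------------------------------------------------


def test_monomorphic_site_has_zero_maf():
    assert compute_maf(calls("0/0", "0/0", "0/0")) == 0.0


def test_maf_two_alt_alleles_of_eight():
    assert compute_maf(calls("0/1", "0/0", "0/1", "0/0")) == pytest.approx(0.25)


def test_maf_with_missing_call_uses_complete_case_denominator():
    # (0/1, ./., 1/1): 3 alt of 4 observed alleles -> minor allele is ref
    assert compute_maf(calls("0/1", "./.", "1/1")) == pytest.approx(0.25)


def test_all_missing_site_raises_undefined_maf():
    with pytest.raises(UndefinedMafError):
        compute_maf(calls("./.", "./."))


def test_multiallelic_maf_is_largest_non_major_frequency():
    # alleles 0,0,0,1,1,2 -> freqs 3/6, 2/6, 1/6 -> MAF = 2/6
    row = np.array([[0, 0], [0, 1], [1, 2]], dtype=np.int8)
    assert compute_maf(row) == pytest.approx(2 / 6)


@given(
    st.lists(
        st.tuples(st.integers(0, 1), st.integers(0, 1)),
        min_size=1,
        max_size=50,
    )
)
def test_biallelic_maf_is_bounded_by_half(genotypes):
    row = np.array(genotypes, dtype=np.int8)
    assert 0.0 <= compute_maf(row) <= 0.5


# -- filter_snps -----------------------------------------------------------


def test_filter_is_strictly_greater_than_threshold():
    """A site at exactly the 0.2 threshold is dropped (strict >)."""
    exactly_02 = calls("0/1", "0/1", "0/0", "0/0", "0/0")  # 2/10
    above = calls("0/1", "0/1", "0/1", "0/0", "0/0")  # 3/10
    matrix = matrix_from([exactly_02, above])
    kept, table = filter_snps(matrix, 0.2)
    assert table["maf"].tolist() == pytest.approx([0.2, 0.3])
    assert table["kept"].tolist() == [False, True]
    assert [s.position for s in kept.sites] == [2]


def test_filter_is_idempotent():
    sites = [PlantedSite("chr1", p, "A", "G", f) for p, f in
             [(10, 0.05), (20, 0.3), (30, 0.45), (40, 0.15)]]
    matrix = generate_genotypes(50, sites, seed=8)
    once, _ = filter_snps(matrix, 0.2)
    twice, _ = filter_snps(once, 0.2)
    assert [s.position for s in twice.sites] == [s.position for s in once.sites]
    assert np.array_equal(twice.calls, once.calls)


def test_filter_threshold_monotonicity():
    sites = [PlantedSite("chr1", 10 * (i + 1), "A", "G", i / 40.0) for i in range(40)]
    matrix = generate_genotypes(60, sites, seed=12)
    kept_sets = {}
    for threshold in (0.05, 0.2, 0.35):
        kept, _ = filter_snps(matrix, threshold)
        kept_sets[threshold] = {s.position for s in kept.sites}
    assert kept_sets[0.35] <= kept_sets[0.2] <= kept_sets[0.05]


def test_filter_exact_generation_matches_planted_count():
    """With calls planted at exact allele counts, the kept sites are
    exactly those whose planted MAF exceeds the threshold."""
    rng = random.Random(30)
    sites = [
        PlantedSite("chr1", i + 1, "A", "G", rng.random())
        for i in range(500)
    ]
    n_samples = 100
    matrix = generate_genotypes(n_samples, sites, seed=14, exact=True)
    kept, _ = filter_snps(matrix, 0.2)
    expected = {
        s.position
        for s in sites
        if min(round(s.frequency * 2 * n_samples), 2 * n_samples - round(s.frequency * 2 * n_samples))
        / (2 * n_samples)
        > 0.2
    }
    assert {s.position for s in kept.sites} == expected


# -- snps_in_gene ----------------------------------------------------------


@pytest.fixture()
def gene_and_sites():
    gene = GeneModel("g1", "tomato", "chr1", 1000, 2000, "+")
    positions = [999, 1000, 1500, 2000, 2001]
    rows = [calls("0/1", "0/0") for _ in positions]
    return gene, matrix_from(rows, positions=positions)


def test_snp_at_gene_boundaries_included(gene_and_sites):
    gene, matrix = gene_and_sites
    hits = snps_in_gene(gene, matrix)
    assert [s.position for s in hits] == [1000, 1500, 2000]


def test_flank_widens_the_interval(gene_and_sites):
    gene, matrix = gene_and_sites
    hits = snps_in_gene(gene, matrix, flank_bp=1)
    assert [s.position for s in hits] == [999, 1000, 1500, 2000, 2001]


def test_snps_in_gene_matches_interval_scan_oracle():
    rng = random.Random(19)
    positions = sorted(rng.sample(range(1, 100_000), 200))
    rows = [calls("0/1", "1/1") for _ in positions]
    matrix = matrix_from(rows, positions=positions)
    for i in range(20):
        start = rng.randint(1, 90_000)
        gene = GeneModel(f"g{i}", "t", "chr1", start, start + rng.randint(100, 8000), "+")
        expected = [p for p in positions if gene.start <= p <= gene.end]
        got = [s.position for s in snps_in_gene(gene, matrix)]
        assert got == expected


# -- flanking_sequence -----------------------------------------------------


def toy_reference():
    # 30 bp ACGT-patterned chromosome; position 13 is an A
    return SequenceSet({"chr1": "ACGTACGTACGTACGTACGTACGTACGTAC"})


def test_flank_formatted_string_matches_hand_slicing():
    """SNP at position 13 (A>G) with 5 bp flanks on the patterned toy
    chromosome: left = positions 8-12 'TACGT', right = positions 14-18
    'CGTAC', hand-checked character by character."""
    snp = SnpRecord("chr1", 13, "A", ("G",))
    report = flanking_sequence(snp, toy_reference(), flank_bp=5)
    assert report.flank_left == "TACGT"
    assert report.flank_right == "CGTAC"
    assert report.formatted == "TACGT[A/G]CGTAC"


def test_flank_truncates_at_chromosome_start():
    snp = SnpRecord("chr1", 3, "G", ("A",))
    report = flanking_sequence(snp, toy_reference(), flank_bp=5)
    assert report.flank_left == "AC"  # only 2 bases exist upstream
    assert len(report.flank_left) == 2


def test_flank_default_is_one_kilobase():
    import inspect

    from syntelink.markers import DEFAULT_FLANK_BP

    assert DEFAULT_FLANK_BP == 1000
    signature = inspect.signature(flanking_sequence)
    assert signature.parameters["flank_bp"].default == 1000


def test_flank_reference_mismatch_is_hard_error():
    snp = SnpRecord("chr1", 13, "C", ("G",))  # position 13 is really A
    with pytest.raises(FormatError, match="chr1:13"):
        flanking_sequence(snp, toy_reference(), flank_bp=5)


def test_flank_unknown_chromosome_is_hard_error():
    snp = SnpRecord("chrZ", 5, "A", ("G",))
    from syntelink.models import ResolutionError

    with pytest.raises(ResolutionError):
        flanking_sequence(snp, toy_reference(), flank_bp=5)


def test_flank_round_trip_reconstructs_reference():
    """Stripping the bracket and substituting REF reproduces the reference
    substring around every site."""
    rng = random.Random(23)
    seq = "".join(rng.choice("ACGT") for _ in range(500))
    reference = SequenceSet({"chr1": seq})
    for _ in range(25):
        pos = rng.randint(1, 500)
        ref = seq[pos - 1]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        report = flanking_sequence(
            SnpRecord("chr1", pos, ref, (alt,)), reference, flank_bp=30
        )
        rebuilt = report.flank_left + ref + report.flank_right
        lo = max(0, pos - 1 - 30)
        assert rebuilt == seq[lo : pos + 30]


def test_multiallelic_bracket_lists_all_alleles():
    snp = SnpRecord("chr1", 13, "A", ("G", "T"))
    report = flanking_sequence(snp, toy_reference(), flank_bp=3)
    assert "[A/G/T]" in report.formatted
    assert report.formatted.count("[") == 1


# -- marker_matrix_view ----------------------------------------------------


def test_selecting_all_samples_keeps_mafs():
    sites = [PlantedSite("chr1", 10 * (i + 1), "A", "G", 0.3) for i in range(5)]
    matrix = generate_genotypes(20, sites, seed=3)
    sub, table, _ = marker_matrix_view(matrix, samples=list(matrix.samples))
    from syntelink.markers import maf_table

    assert table["maf"].tolist() == maf_table(matrix)["maf"].tolist()


def test_submatrix_of_homozygous_alt_samples_has_zero_maf():
    rows = [calls("1/1", "1/1", "0/0", "0/1")]
    matrix = matrix_from(rows)
    sub, table, _ = marker_matrix_view(matrix, samples=["s0", "s1"])
    # alt is now the only observed allele, so the minor frequency is 0
    assert table["maf"].tolist() == [0.0]


def test_submatrix_maf_equals_recomputation_oracle():
    rng = random.Random(11)
    sites = [PlantedSite("chr1", i + 1, "A", "G", rng.random()) for i in range(30)]
    matrix = generate_genotypes(40, sites, missing_rate=0.1, seed=6)
    for _ in range(10):
        chosen = rng.sample(matrix.samples, rng.randint(1, 40))
        sub, table, _ = marker_matrix_view(matrix, samples=chosen)
        for i in range(sub.n_sites):
            observed = sub.site_calls(i)
            if (observed != -1).sum() == 0:
                assert np.isnan(table["maf"].iloc[i])
            else:
                assert table["maf"].iloc[i] == pytest.approx(
                    compute_maf(observed)
                )


def test_empty_sample_selection_is_hard_error():
    rows = [calls("0/1", "0/0")]
    with pytest.raises(ValueError):
        marker_matrix_view(matrix_from(rows), samples=[])


def test_matrix_text_rendering_shows_missing_as_dots():
    rows = [calls("0/1", "./.")]
    _, _, text = marker_matrix_view(matrix_from(rows))
    lines = text.strip().splitlines()
    assert lines[0].split("\t")[4:] == ["s0", "s1"]
    assert lines[1].split("\t")[4:] == ["0/1", "./."]
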