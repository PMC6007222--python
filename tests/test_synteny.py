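"""Anchor construction, quality filtering, collinear chaining and the
window view."""

import itertools
import random

import pytest

from syntelink.models import GeneCatalog, GeneModel, ResolutionError
from syntelink.synteny import (
    FORWARD,
    INVERTED,
    Anchor,
    AnchorFilters,
    ChainParams,
    block_for_gene,
    build_blocks,
    chain_anchors,
    filter_anchors,
    make_anchors,
    window_view,
)


def A(ord_a, ord_b, **kw):
    defaults = dict(
        gene_a=f"a{ord_a}",
        gene_b=f"b{ord_b}",
        start_a=ord_a * 100 + 1,
        end_a=ord_a * 100 + 50,
        start_b=ord_b * 100 + 1,
        end_b=ord_b * 100 + 50,
    )
    defaults.update(kw)
    return Anchor(ord_a=ord_a, ord_b=ord_b, **defaults)


def catalog(genome, chrom, n, spacing=1000, length=400):
    genes = [
        GeneModel(
            gene_id=f"{genome}_{i}",
            genome=genome,
            chromosome=chrom,
            start=i * spacing + 1,
            end=i * spacing + length,
            strand="+",
            description=f"gene {i}",
        )
        for i in range(n)
    ]
    return GeneCatalog(genome, genes)


# -- exhaustive chain oracle ----------------------------------------------


def oracle_best_chain_length(anchors, max_gap):
    """Maximum chain size over every subset of <= 10 anchors that is
    strictly monotone in both genomes (either orientation) under the gap
    cap — brute force, independent of the DP."""
    best = 0
    idx = range(len(anchors))
    for r in range(1, len(anchors) + 1):
        for combo in itertools.combinations(idx, r):
            chosen = sorted(
                (anchors[i] for i in combo), key=lambda a: a.ord_a
            )
            for sign in (1, -1):
                ok = True
                for prev, nxt in zip(chosen, chosen[1:]):
                    if nxt.ord_a <= prev.ord_a:
                        ok = False
                        break
                    if sign * nxt.ord_b <= sign * prev.ord_b:
                        ok = False
                        break
                    if (
                        nxt.ord_a - prev.ord_a > max_gap
                        or abs(nxt.ord_b - prev.ord_b) > max_gap
                    ):
                        ok = False
                        break
                if ok:
                    best = max(best, r)
                    break
    return best


# -- chaining --------------------------------------------------------------


def test_diagonal_chains_into_one_forward_block():
    anchors = [A(i, i) for i in range(5)]
    blocks = chain_anchors(anchors)
    assert len(blocks) == 1
    assert blocks[0].orientation == FORWARD
    assert blocks[0].score == 5


def test_antidiagonal_chains_into_one_inverted_block():
    anchors = [A(i, 4 - i) for i in range(5)]
    blocks = chain_anchors(anchors)
    assert len(blocks) == 1
    assert blocks[0].orientation == INVERTED
    assert blocks[0].score == 5


def test_displaced_anchor_excluded_from_main_block():
    """A 6-gene diagonal with one anchor displaced to (2, 9): the main
    block keeps the 5 collinear anchors and the displaced one cannot
    extend it (hand enumeration of monotone chains)."""
    anchors = [A(i, i) for i in (0, 1, 3, 4, 5)] + [A(2, 9)]
    blocks = chain_anchors(anchors, ChainParams(max_gap_genes=10))
    assert blocks[0].score == 5
    assert all(a.ord_b != 9 for a in blocks[0].anchors)


def test_first_chain_matches_exhaustive_subset_oracle():
    """Random <= 10-anchor instances: the first extracted chain has the
    brute-force maximum length over all monotone subsets."""
    rng = random.Random(17)
    for trial in range(60):
        n = rng.randint(1, 10)
        max_gap = rng.choice([2, 3, 10])
        seen = set()
        anchors = []
        while len(anchors) < n:
            pt = (rng.randint(0, 12), rng.randint(0, 12))
            if pt not in seen:
                seen.add(pt)
                anchors.append(A(*pt))
        blocks = chain_anchors(
            anchors, ChainParams(max_gap_genes=max_gap, min_block_anchors=1)
        )
        expected = oracle_best_chain_length(anchors, max_gap)
        assert blocks[0].score == expected, (trial, anchors)


def test_blocks_are_anchor_disjoint():
    rng = random.Random(23)
    anchors = [
        A(a, b)
        for a, b in {(rng.randint(0, 30), rng.randint(0, 30)) for _ in range(40)}
    ]
    blocks = chain_anchors(anchors, ChainParams(min_block_anchors=1))
    seen = set()
    for block in blocks:
        for anchor in block.anchors:
            key = (anchor.ord_a, anchor.ord_b)
            assert key not in seen
            seen.add(key)


def test_adding_anchors_never_shortens_best_chain():
    rng = random.Random(29)
    for _ in range(20):
        pts = list({(rng.randint(0, 15), rng.randint(0, 15)) for _ in range(12)})
        subset = pts[: len(pts) // 2]
        params = ChainParams(min_block_anchors=1)
        best_subset = chain_anchors([A(*p) for p in subset], params)
        best_full = chain_anchors([A(*p) for p in pts], params)
        len_subset = best_subset[0].score if best_subset else 0
        len_full = best_full[0].score if best_full else 0
        assert len_full >= len_subset


def test_reversing_b_order_swaps_orientation():
    """Mirroring genome B's gene order turns forward blocks inverted (and
    vice versa) with the same anchor multiset, on instances whose chains
    are unambiguous (no equal-length forward/inverted tie, where the
    forward-first tie-break is deliberately not mirror-symmetric)."""
    forward_run = [A(i, i) for i in range(6)]
    inverted_run = [A(10 + i, 30 - i) for i in range(5)]
    pts = forward_run + inverted_run
    max_b = 30
    params = ChainParams(min_block_anchors=1)
    blocks = chain_anchors(pts, params)
    mirrored = chain_anchors(
        [A(a.ord_a, max_b - a.ord_b, gene_a=a.gene_a, gene_b=a.gene_b) for a in pts],
        params,
    )

    def signature(blocks, flip):
        out = []
        for block in blocks:
            pairs = frozenset(
                (a.ord_a, max_b - a.ord_b if flip else a.ord_b)
                for a in block.anchors
            )
            orientation = block.orientation
            if flip and len(pairs) > 1:
                orientation = INVERTED if orientation == FORWARD else FORWARD
            out.append((pairs, orientation))
        return sorted(out, key=lambda x: sorted(x[0]))

    assert signature(blocks, False) == signature(mirrored, True)


def test_first_chain_length_is_mirror_invariant():
    """The best chain length is unchanged by mirroring B's gene order even
    on arbitrary instances (orientation search covers both directions)."""
    rng = random.Random(31)
    params = ChainParams(min_block_anchors=1)
    for _ in range(20):
        pts = list({(rng.randint(0, 20), rng.randint(0, 20)) for _ in range(18)})
        max_b = max(b for _, b in pts)
        blocks = chain_anchors([A(a, b) for a, b in pts], params)
        mirrored = chain_anchors([A(a, max_b - b) for a, b in pts], params)
        assert blocks[0].score == mirrored[0].score


def test_duplicate_ordinal_pairs_are_deduplicated():
    anchors = [A(i, i) for i in range(4)] + [A(2, 2, identity=0.99)]
    blocks = chain_anchors(anchors, ChainParams(min_block_anchors=1))
    assert sum(b.score for b in blocks) == 4


# -- filters ---------------------------------------------------------------


def test_identity_filter_drops_low_identity():
    anchors = [A(0, 0, identity=0.90), A(1, 1, identity=0.97)]
    kept = filter_anchors(anchors, AnchorFilters(identity_min=0.95))
    assert [a.ord_a for a in kept] == [1]


def test_unset_filters_are_identity_function():
    anchors = [A(i, i, identity=0.5) for i in range(3)]
    assert filter_anchors(anchors, AnchorFilters()) == anchors


def test_mixed_filter_fixture_matches_hand_enumeration():
    """10 anchors with mixed attributes against all three filters; the
    survivor set was enumerated by hand: an absent attribute fails a set
    filter."""
    anchors = [
        A(0, 0, identity=0.99, e_value=1e-30, coverage=0.9),  # keep
        A(1, 1, identity=0.90, e_value=1e-30, coverage=0.9),  # identity low
        A(2, 2, identity=0.99, e_value=1e-2, coverage=0.9),  # e-value high
        A(3, 3, identity=0.99, e_value=1e-30, coverage=0.5),  # coverage low
        A(4, 4, identity=0.99, e_value=None, coverage=0.9),  # missing e-value
        A(5, 5, identity=0.99, e_value=1e-30, coverage=None),  # missing cov
        A(6, 6, identity=0.95, e_value=1e-10, coverage=0.8),  # keep (boundary)
        A(7, 7, identity=0.951, e_value=1e-9, coverage=0.81),  # keep
        A(8, 8, identity=0.80, e_value=1e-2, coverage=0.1),  # all fail
        A(9, 9, identity=0.99, e_value=1e-10, coverage=0.79),  # coverage low
    ]
    kept = filter_anchors(
        anchors,
        AnchorFilters(e_value_max=1e-9, identity_min=0.95, coverage_min=0.8),
    )
    assert [a.ord_a for a in kept] == [0, 6, 7]


# -- make_anchors ----------------------------------------------------------


def test_make_anchors_uses_catalog_ordinals():
    from syntelink.homology import HomologGroup

    cat_a = catalog("ga", "chr1", 3)
    cat_b = catalog("gb", "chr1", 5)
    group = HomologGroup(0, "ga_0", [("ga", "ga_0", 1.0), ("gb", "gb_4", 0.97)])
    anchors = make_anchors([group], cat_a, cat_b)
    (anchor,) = anchors[("chr1", "chr1")]
    assert (anchor.ord_a, anchor.ord_b) == (0, 4)
    assert anchor.identity == pytest.approx(0.97)


def test_one_to_many_group_fans_out():
    from syntelink.homology import HomologGroup

    cat_a = catalog("ga", "chr1", 2)
    cat_b = catalog("gb", "chr1", 3)
    group = HomologGroup(
        0,
        "ga_0",
        [("ga", "ga_0", 1.0), ("gb", "gb_0", 0.98), ("gb", "gb_2", 0.96)],
    )
    anchors = make_anchors([group], cat_a, cat_b)
    assert len(anchors[("chr1", "chr1")]) == 2


def test_make_anchors_unresolvable_gene_is_hard_error():
    from syntelink.homology import HomologGroup

    cat_a = catalog("ga", "chr1", 2)
    cat_b = catalog("gb", "chr1", 2)
    group = HomologGroup(0, "ga_0", [("ga", "ga_0", 1.0), ("gb", "ghost", 0.98)])
    with pytest.raises(ResolutionError, match="ghost"):
        make_anchors([group], cat_a, cat_b)


def test_simulated_anchor_count_matches_planted_orthologs(
    small_pair, small_pipeline
):
    planted = sum(1 for b in small_pair.truth.ortholog_map.values() if b)
    total = sum(len(v) for v in small_pipeline.anchors.values())
    assert total == planted


# -- block_for_gene and window_view ---------------------------------------


def test_block_for_gene_finds_containing_block():
    anchors = [A(i, i) for i in range(5)]
    blocks = chain_anchors(anchors)
    assert block_for_gene("a2", blocks) == blocks
    assert block_for_gene("b3", blocks) == blocks
    assert block_for_gene("nope", blocks) == []


def test_every_non_lost_gene_is_in_a_block(small_pair, small_pipeline):
    """Simulator genes with a surviving diverged ortholog land in a block."""
    truth = small_pair.truth
    for a_id, b_id in truth.ortholog_map.items():
        if b_id is None:
            continue
        assert block_for_gene(a_id, small_pipeline.blocks), a_id


def test_window_view_default_width_and_center_tag(small_pair, small_pipeline):
    gene = next(iter(small_pair.truth.ortholog_map))
    report = window_view(
        small_pair.catalog_a,
        small_pair.catalog_b,
        small_pipeline.blocks,
        gene,
    )
    chrom, start, end = report.window_a
    assert end - start <= 200_000  # 0.2 Mbp default, clipped at bounds
    center = [g for g in report.genes_a if g.rel_index == 0]
    assert len(center) == 1 and center[0].gene.gene_id == gene


def test_window_clips_at_chromosome_start():
    cat_a = catalog("ga", "chr1", 30)
    cat_b = catalog("gb", "chr1", 30)
    report = window_view(cat_a, cat_b, [], "ga_0", window_bp=10_000)
    assert report.window_a[1] == 1


def test_window_gene_set_matches_interval_arithmetic():
    """30 genes spaced 1 kb apart, 400 bp long: a 5 kb window centered on
    gene 10 (midpoint 10 201) spans [7 701, 12 701] and must contain the
    genes overlapping it — genes 8..12 by hand interval arithmetic."""
    cat_a = catalog("ga", "chr1", 30)
    cat_b = catalog("gb", "chr1", 30)
    report = window_view(cat_a, cat_b, [], "ga_10", window_bp=5000)
    ids = [g.gene.gene_id for g in report.genes_a]
    assert ids == [f"ga_{i}" for i in range(8, 13)]
    rels = [g.rel_index for g in report.genes_a]
    assert rels == [-2, -1, 0, 1, 2]


def test_window_view_missing_center_gene_is_hard_error():
    cat = catalog("ga", "chr1", 5)
    with pytest.raises(ResolutionError):
        window_view(cat, cat, [], "absent")


def test_build_blocks_assigns_sequential_ids(small_pipeline):
    ids = [b.block_id for b in small_pipeline.blocks]
    assert ids == list(range(len(ids)))
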