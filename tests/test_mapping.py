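"""Adapter trimming, mismatch-budget matching, and exclusive assignment.

The matching oracle here is an independent, literal re-statement of the
budget rule: slide the read's internal colors over every offset of both
genome strands and count mismatches in the seed and tail directly.
"""

import numpy as np
import pytest

from mirsolid.catalog import (
    NON_ANNOTATED,
    UNMAPPED,
    AnnotationCatalog,
    Feature,
    build_color_index,
)
from mirsolid.colorspace import (
    FROM_3P,
    ColorRead,
    encode_colorspace,
    internal_colors,
    reverse_complement,
)
from mirsolid.mapping import (
    MatchParams,
    assign_all,
    assign_read,
    match_read,
    trim_adapter,
)

ADAPTER = "CGCCTTGGCCGTACAGCAGCCTCTT"


def make_read(insert, read_id="r", direction="from_5p", n_colors=None, primer="T"):
    """Simulate library construction: insert (+ adapter read-through)."""
    src = reverse_complement(insert) if direction == FROM_3P else insert
    s = src + ADAPTER
    n = n_colors if n_colors is not None else min(35, len(s))
    rec = encode_colorspace(s[:n], primer)
    return ColorRead(read_id, rec[0], rec[1:], direction=direction)


def brute_force_hits(genome, colors, params):
    """Oracle: literal scan of every offset and strand of one contig.

    Returns {(start, strand, mm_seed, mm_tail)} over base coordinates.
    """
    out = set()
    m = len(colors)
    s = min(params.seed_len, m)
    for strand in "+-":
        ref = internal_colors(genome if strand == "+" else reverse_complement(genome))
        for off in range(len(ref) - m + 1):
            win = ref[off : off + m]
            mm_seed = sum(a != b for a, b in zip(win[:s], colors[:s]))
            mm_tail = sum(a != b for a, b in zip(win[s:], colors[s:]))
            if mm_seed <= params.seed_mismatch_max and mm_tail <= params.tail_mismatch_max:
                start = off if strand == "+" else len(genome) - off - m - 1
                out.add((start, strand, mm_seed, mm_tail))
    return out


# ---------------------------------------------------------------------------
# trimming
# ---------------------------------------------------------------------------

def test_trim_exact_readthrough():
    r = make_read("A" * 0 + "ACGTTGCA" * 3)  # 24-base insert + adapter tail
    t = trim_adapter(r, ADAPTER)
    assert len(t.colors) == 24


def test_trim_no_adapter_returns_unchanged():
    insert = "ACGTTGCAACGTTGCAACGTTGCAACGTTGCAACG"  # 35 bases, no adapter
    r = make_read(insert)
    assert trim_adapter(r, ADAPTER).colors == r.colors


def test_trim_tolerates_one_mismatch_in_long_overlap():
    r = make_read("ACGTTGCAACGTTGCAACGT")  # 20-base insert, 14 adapter colors
    colors = list(r.colors)
    colors[26] = str((int(colors[26]) + 1) % 4)  # corrupt one adapter color
    r2 = ColorRead("r", r.primer, "".join(colors))
    assert len(trim_adapter(r2, ADAPTER).colors) == 20


def test_trimmed_too_short_flagged_downstream(toy_catalog):
    r = make_read(toy_catalog.contigs["chr1"][100:110])  # 10-base insert
    table, _ = assign_all({"s": [r]}, toy_catalog, MatchParams(), adapter=ADAPTER)
    assert list(table["category"]) == ["too_short"]


def test_trim_truncates_qualities():
    r = make_read("ACGTTGCAACGTTGCAACGT")
    r.quals = list(range(len(r.colors)))
    t = trim_adapter(r, ADAPTER)
    assert t.quals == list(range(len(t.colors)))


# ---------------------------------------------------------------------------
# matching
# ---------------------------------------------------------------------------

def test_exact_read_matches_with_zero_mismatches(toy_catalog):
    insert = toy_catalog.contigs["chr1"][100:122]
    r = make_read(insert, n_colors=len(insert))
    hits = match_read(toy_catalog, r)
    assert any(
        h.contig == "chr1" and h.start == 100 and h.strand == "+" and h.mismatches == 0
        for h in hits
    )


def test_one_seed_mismatch_still_matches(toy_catalog):
    insert = toy_catalog.contigs["chr1"][100:122]
    r = make_read(insert, n_colors=len(insert))
    colors = list(r.colors)
    colors[5] = str((int(colors[5]) + 2) % 4)
    r2 = ColorRead("r", r.primer, "".join(colors))
    hits = match_read(toy_catalog, r2)
    assert any(h.start == 100 and h.mm_seed == 1 for h in hits)


def test_two_seed_mismatches_rejected(toy_catalog):
    insert = toy_catalog.contigs["chr1"][100:122]
    r = make_read(insert, n_colors=len(insert))
    colors = list(r.colors)
    for pos in (3, 9):
        colors[pos] = str((int(colors[pos]) + 1) % 4)
    r2 = ColorRead("r", r.primer, "".join(colors))
    hits = match_read(toy_catalog, r2)
    assert not any(h.contig == "chr1" and h.start == 100 for h in hits)


def test_3p_direction_reads_map_to_same_locus(toy_catalog):
    insert = toy_catalog.contigs["chr1"][138:160]
    r = make_read(insert, direction=FROM_3P, n_colors=len(insert))
    hits = match_read(toy_catalog, r)
    assert any(h.start == 138 and h.strand == "+" for h in hits)


def test_minus_strand_feature_reads(toy_catalog):
    f = toy_catalog.feature("pirna-1")
    insert = reverse_complement(toy_catalog.contigs["chr1"][f.start : f.end])
    r = make_read(insert, n_colors=len(insert))
    hits = match_read(toy_catalog, r)
    best = min(hits, key=lambda h: h.mismatches)
    assert (best.start, best.strand) == (f.start, "-")
    a = assign_read(hits, toy_catalog, "r")
    assert a.category == "piRNA" and a.feature_id == "pirna-1"


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_matcher_agrees_with_brute_force_oracle(seed):
    """Seed-and-extend hits equal the literal budget scan on toy genomes."""
    rng = np.random.default_rng(seed)
    genome = "".join("ACGT"[i] for i in rng.integers(0, 4, 1500))
    cat = AnnotationCatalog(contigs={"g": genome}, features=[])
    build_color_index(cat, 8)
    params = MatchParams()
    for _ in range(40):
        pos = int(rng.integers(0, len(genome) - 35))
        insert_len = int(rng.integers(16, 32))
        insert = genome[pos : pos + insert_len]
        if rng.random() < 0.5:
            insert = reverse_complement(insert)
        rec = encode_colorspace(insert, "T")
        colors = list(rec[1:])
        for _ in range(int(rng.integers(0, 4))):  # up to 3 color errors
            i = int(rng.integers(0, len(colors)))
            colors[i] = str((int(colors[i]) + int(rng.integers(1, 4))) % 4)
        read = ColorRead("r", rec[0], "".join(colors))
        got = {
            (h.start, h.strand, h.mm_seed, h.mm_tail)
            for h in match_read(cat, read, params)
        }
        expected = brute_force_hits(genome, read.colors[1:], params)
        assert got == expected


def test_loosening_budget_is_monotone(toy_catalog):
    rng = np.random.default_rng(11)
    reads = []
    for i in range(30):
        pos = int(rng.integers(0, 500))
        insert = toy_catalog.contigs["chr1"][pos : pos + 22]
        rec = encode_colorspace(insert, "T")
        colors = list(rec[1:])
        for _ in range(int(rng.integers(0, 4))):
            j = int(rng.integers(0, len(colors)))
            colors[j] = str((int(colors[j]) + 1) % 4)
        reads.append(ColorRead(f"r{i}", "T", "".join(colors)))
    strict = MatchParams(seed_mismatch_max=0, tail_mismatch_max=0)
    loose = MatchParams(seed_mismatch_max=1, tail_mismatch_max=2)
    n_strict = sum(bool(match_read(toy_catalog, r, strict)) for r in reads)
    n_loose = sum(bool(match_read(toy_catalog, r, loose)) for r in reads)
    assert n_loose >= n_strict


# ---------------------------------------------------------------------------
# exclusive assignment
# ---------------------------------------------------------------------------

def _overlapping_catalog():
    """A mature miRNA nested inside a tRNA span: hierarchy must pick miRNA."""
    rng = np.random.default_rng(23)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    cat = AnnotationCatalog(
        contigs={"c": seq},
        features=[
            Feature("t1", "tRNA", "c", 90, 162, "+"),
            Feature("m1", "miRNA_human", "c", 100, 122, "+"),
        ],
    )
    build_color_index(cat, 8)
    return cat


def test_hierarchy_resolves_overlap_to_mirna():
    cat = _overlapping_catalog()
    insert = cat.contigs["c"][100:122]
    r = make_read(insert, n_colors=len(insert))
    a = assign_read(match_read(cat, r), cat, "r")
    assert a.category == "miRNA_human" and a.feature_id == "m1"


def test_hierarchy_order_is_configurable():
    cat = _overlapping_catalog()
    cat.hierarchy = ["tRNA", "miRNA_human"]
    insert = cat.contigs["c"][100:122]
    r = make_read(insert, n_colors=len(insert))
    a = assign_read(match_read(cat, r), cat, "r")
    assert a.category == "tRNA"


def test_intronic_hit_is_non_annotated(toy_catalog):
    insert = toy_catalog.contigs["chr1"][400:425]  # featureless region
    r = make_read(insert, n_colors=len(insert))
    a = assign_read(match_read(toy_catalog, r), toy_catalog, "r")
    assert a.category == NON_ANNOTATED and a.feature_id is None


def test_no_hits_is_unmapped(toy_catalog):
    r = ColorRead("r", "T", "0123" * 6)
    hits = match_read(toy_catalog, r)
    a = assign_read(hits, toy_catalog, "r")
    if not hits:  # random colors could in principle match; only assert shape
        assert a.category == UNMAPPED and a.start is None


def test_half_overlap_rule():
    """A read must cover a feature by >= 50% of its length to take it."""
    rng = np.random.default_rng(31)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 300))
    cat = AnnotationCatalog(
        contigs={"c": seq},
        features=[Feature("m1", "miRNA_human", "c", 100, 122, "+")],
    )
    build_color_index(cat, 8)
    # read 22 bases, 12 overlapping the feature: overlap*2 >= 22 -> assigned
    r = make_read(seq[90:112], n_colors=22)
    assert assign_read(match_read(cat, r), cat).category == "miRNA_human"
    # read 22 bases, only 8 overlapping -> non_annotated
    r = make_read(seq[86:108], n_colors=22)
    assert assign_read(match_read(cat, r), cat).category == NON_ANNOTATED


def test_assign_all_pure_mirna_sample(toy_catalog):
    insert = toy_catalog.contigs["chr1"][100:122]
    reads = [make_read(insert, f"r{i}", n_colors=22) for i in range(50)]
    table, summary = assign_all({"s1": reads}, toy_catalog, MatchParams())
    assert (table["category"] == "miRNA_human").all()
    assert summary.loc[summary["sample"] == "s1", "fraction"].sum() == pytest.approx(1)
    assert summary["fraction"].iloc[0] == pytest.approx(1.0)


def test_assign_all_mixture_fractions(toy_catalog):
    mir = toy_catalog.contigs["chr1"][100:122]
    intron = toy_catalog.contigs["chr1"][420:445]
    reads = [make_read(mir, f"m{i}", n_colors=22) for i in range(60)] + [
        make_read(intron, f"n{i}", n_colors=25) for i in range(40)
    ]
    table, summary = assign_all({"s": reads}, toy_catalog, MatchParams())
    frac = summary.set_index("category")["fraction"]
    assert frac["miRNA_human"] == pytest.approx(0.60)
    assert frac[NON_ANNOTATED] == pytest.approx(0.40)


def test_assignment_conservation_and_exclusivity(small_assignments):
    """Per sample: every retained read appears exactly once, in one category."""
    cfg, catalog, truth, table, summary = small_assignments
    for sample, sub in table.groupby("sample"):
        assert len(sub) == cfg.depth
        assert sub["read_id"].is_unique
        mapped = sub[~sub["category"].isin([UNMAPPED, "too_short"])]
        s = summary[summary["sample"] == sample]
        assert s["count"].sum() == len(mapped)
        assert s["fraction"].sum() == pytest.approx(1.0, abs=1e-9)


def test_category_fractions_recover_planted_mixture(small_assignments):
    """Mapped-read class fractions sit near the planted category budgets."""
    cfg, catalog, truth, table, summary = small_assignments
    planted = {}
    for e in truth.emitters:
        planted[e.category] = planted.get(e.category, 0.0) + e.weights["ND"]
    s = summary[summary["sample"] == "ND.1.F"].set_index("category")["fraction"]
    for cat_name, expect in planted.items():
        assert abs(s.get(cat_name, 0.0) - expect) < 0.05
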