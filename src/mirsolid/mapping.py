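"""Adapter trimming, color-space matching, and exclusive read assignment.

Matching follows the SOLiD small-RNA convention: a trimmed read of t colors
represents a t-base insert; the first color pairs the insert's first base
with the sequencing primer (or the 3' adapter's last base) and is dropped,
leaving t-1 anchor-independent internal colors that are compared directly
against the genome's color string on both strands.  Mismatches are counted
in color space with a split budget: at most ``seed_mismatch_max`` within the
first ``seed_len`` colors (the "seed"), at most ``tail_mismatch_max`` in the
remainder.  Reads shorter than the seed use their full length as the seed.

Reads sequenced from the 3' end observe the reverse complement of the
insert; their internal colors are reversed before matching (colors are
complement-invariant).

Each mapped read is assigned to exactly one category: among its
minimum-mismatch hits, the highest-priority hierarchy class whose feature
overlaps the hit by at least half the read wins; genome hits with no such
feature are ``non_annotated``; readless-of-hits reads are ``unmapped``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import NON_ANNOTATED, TOO_SHORT, UNMAPPED, AnnotationCatalog, Feature
from .colorspace import (
    FROM_3P,
    ColorRead,
    NucleotideSeq,
    ReadBatch,
    colors_to_array,
    internal_colors,
)

_PAD = 250  # padding value never equal to a color (0-3)


@dataclass(frozen=True)
class MatchParams:
    """Color-space mismatch budget and insert-length window."""

    seed_len: int = 18
    seed_mismatch_max: int = 1
    tail_mismatch_max: int = 2
    min_trimmed_len: int = 15
    max_trimmed_len: int = 50

    def __post_init__(self) -> None:
        if self.seed_len < 1:
            raise ValueError("seed_len must be >= 1")
        if self.seed_mismatch_max < 0 or self.tail_mismatch_max < 0:
            raise ValueError("mismatch budgets must be >= 0")
        if self.min_trimmed_len > self.max_trimmed_len:
            raise ValueError("min_trimmed_len > max_trimmed_len")


@dataclass(frozen=True)
class Hit:
    """One genomic match; start/end are 0-based half-open base coordinates."""

    contig: str
    start: int
    end: int
    strand: str
    mm_seed: int
    mm_tail: int

    @property
    def mismatches(self) -> int:
        return self.mm_seed + self.mm_tail


@dataclass
class Assignment:
    """Exclusive category for one read, with its best hit if mapped."""

    read_id: str
    category: str
    feature_id: str | None = None
    contig: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    mm_seed: int = 0
    mm_tail: int = 0


# ---------------------------------------------------------------------------
# Adapter trimming
# ---------------------------------------------------------------------------

def adapter_internal_colors(adapter: "NucleotideSeq | str") -> np.ndarray:
    return colors_to_array(internal_colors(adapter))


def trim_adapter(
    read: ColorRead,
    adapter: "NucleotideSeq | str",
    min_overlap: int = 6,
) -> ColorRead:
    """Remove a 3' adapter read-through from one read.

    The longest read suffix whose colors match a prefix of the adapter's
    internal colors (exactly, or with one mismatch when the overlap spans at
    least 10 colors) is removed together with the one anchor-dependent
    junction color that precedes it.  Untrimmable reads return unchanged.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    arr = colors_to_array(read.colors)
    t = _trim_batch(arr[None, :], adapter_internal_colors(adapter), min_overlap)[0]
    if t >= len(read.colors):
        return read
    return replace(read, colors=read.colors[:t], quals=read.quals[:t] if read.quals else [])


def _trim_batch(
    reads: np.ndarray, adapter_colors: np.ndarray, min_overlap: int
) -> np.ndarray:
    """Vectorized trimming: returns the trimmed color length per read.

    ``reads`` is an (N, L) uint8 matrix of raw color values.  The junction
    color at index t (insert length in colors) is anchor-dependent and is
    skipped; the adapter comparison starts at t + 1.
    """
    n, length = reads.shape
    trimmed = np.full(n, length, dtype=np.int32)
    undecided = np.ones(n, dtype=bool)
    # longest suffix first: smallest junction index t
    for t in range(1, length - min_overlap):
        o = min(length - t - 1, adapter_colors.size)
        if o < min_overlap:
            break
        seg = reads[:, t + 1 : t + 1 + o]
        mm = (seg != adapter_colors[:o]).sum(axis=1)
        ok = undecided & ((mm == 0) | ((o >= 10) & (mm <= 1)))
        trimmed[ok] = t
        undecided &= ~ok
        if not undecided.any():
            break
    return trimmed


# ---------------------------------------------------------------------------
# Matching
# ---------------------------------------------------------------------------

def matchable_colors(read: ColorRead) -> np.ndarray:
    """Internal colors used for genome matching.

    Drops the anchor-dependent first color; 3'-direction reads are
    reverse-complemented (color reversal) so all matching is insert-sense.
    """
    arr = colors_to_array(read.colors)[1:]
    if read.direction == FROM_3P:
        arr = arr[::-1]
    return arr


def match_read(
    catalog: AnnotationCatalog, read: ColorRead, params: MatchParams | None = None
) -> list[Hit]:
    """All genomic hits of one trimmed read under the mismatch budget.

    Uses the color k-mer index (seed-and-extend with pigeonhole seeding)
    when the catalog carries one and the read is long enough; otherwise
    scans every offset.  Hits are sorted by total mismatches, then contig,
    position and strand.
    """
    params = params or MatchParams()
    if len(read.colors) < params.min_trimmed_len:
        return []
    colors = matchable_colors(read)
    n = colors.size
    mat = colors[None, :].copy()
    df = _match_batch(catalog, mat, np.array([n], dtype=np.int64), params)
    names = list(catalog.contig_colors())
    clens = {nm: arr.size for nm, arr in catalog.contig_colors().items()}
    hits = []
    for row in df.itertuples(index=False):
        name = names[row.contig_idx]
        if row.strand_code == 0:
            start = int(row.rev_off)
            strand = "+"
        else:
            start = clens[name] - int(row.rev_off) - n
            strand = "-"
        hits.append(
            Hit(
                contig=name,
                start=start,
                end=start + n + 1,
                strand=strand,
                mm_seed=int(row.mm_seed),
                mm_tail=int(row.mm_tail),
            )
        )
    hits.sort(key=lambda h: (h.mismatches, h.contig, h.start, h.strand))
    return hits


def assign_read(
    hits: Sequence[Hit], catalog: AnnotationCatalog, read_id: str = ""
) -> Assignment:
    """Distribute one read exclusively given its hits.

    Among minimum-mismatch hits, the highest-priority class whose leaf
    feature overlaps a hit by >= 50% of the read wins; ties break by
    hierarchy priority, then leftmost coordinate.
    """
    if not hits:
        return Assignment(read_id=read_id, category=UNMAPPED)
    best_mm = min(h.mismatches for h in hits)
    best_hits = [h for h in hits if h.mismatches == best_mm]
    leaves = catalog.leaf_features()
    candidates: list[tuple[int, int, str, Feature, Hit]] = []
    for h in best_hits:
        rlen = h.end - h.start
        for f in leaves:
            if f.contig != h.contig or f.strand != h.strand:
                continue
            overlap = min(f.end, h.end) - max(f.start, h.start)
            if overlap * 2 >= rlen:
                candidates.append(
                    (catalog.priority(f.rna_class), h.start, f.feature_id, f, h)
                )
    if not candidates:
        h = min(best_hits, key=lambda h: (h.contig, h.start, h.strand))
        return Assignment(
            read_id=read_id,
            category=NON_ANNOTATED,
            contig=h.contig,
            start=h.start,
            end=h.end,
            strand=h.strand,
            mm_seed=h.mm_seed,
            mm_tail=h.mm_tail,
        )
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    _, _, _, f, h = candidates[0]
    return Assignment(
        read_id=read_id,
        category=f.rna_class,
        feature_id=f.feature_id,
        contig=h.contig,
        start=h.start,
        end=h.end,
        strand=h.strand,
        mm_seed=h.mm_seed,
        mm_tail=h.mm_tail,
    )


# ---------------------------------------------------------------------------
# Batch pipeline (vectorized): trim -> match -> assign for whole samples
# ---------------------------------------------------------------------------

class _StrandedGenome:
    """Concatenated per-strand color arrays with contig boundary padding."""

    def __init__(self, catalog: AnnotationCatalog, pad: int = 64):
        cc = catalog.contig_colors()
        self.names = list(cc)
        self.starts: dict[str, int] = {}
        parts_f, parts_r = [], []
        pos = 0
        gap = np.full(pad, _PAD, dtype=np.uint8)
        for name in self.names:
            arr = cc[name]
            self.starts[name] = pos
            parts_f.append(arr)
            parts_r.append(arr[::-1])
            parts_f.append(gap)
            parts_r.append(gap)
            pos += arr.size + pad
        self.fwd = np.concatenate(parts_f) if parts_f else gap.copy()
        self.rev = np.concatenate(parts_r) if parts_r else gap.copy()
        # map a global offset back to (contig index, local offset)
        self.bounds = np.array([self.starts[n] for n in self.names], dtype=np.int64)
        self.lengths = np.array([cc[n].size for n in self.names], dtype=np.int64)

    def locate(self, global_off: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ci = np.searchsorted(self.bounds, global_off, side="right") - 1
        return ci, global_off - self.bounds[ci]


def _pack_windows(mat: np.ndarray, starts: np.ndarray, k: int) -> np.ndarray:
    weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.uint64)
    idx = starts[:, None] + np.arange(k)
    win = np.take_along_axis(mat, idx, axis=1).astype(np.uint64)
    return win @ weights


def _match_batch(
    catalog: AnnotationCatalog,
    mat: np.ndarray,
    lengths: np.ndarray,
    params: MatchParams,
) -> pd.DataFrame:
    """Match N unique reads (rows of ``mat``, padded with _PAD) at once.

    Returns a DataFrame of hits: read_idx, contig_idx, strand (0/1 code),
    color offset (forward-strand coords on '-' handled later), mm_seed,
    mm_tail.  Reads long enough for two disjoint index k-mers inside the
    seed go through the k-mer index (pigeonhole over a 1-mismatch seed);
    shorter reads fall back to a full scan.
    """
    index = catalog.color_index
    sg = _StrandedGenome(catalog)
    n_reads = mat.shape[0]
    hits_frames: list[pd.DataFrame] = []

    k = index.k if index is not None else 0
    eligible = (
        (lengths >= 2 * k) & (np.minimum(lengths, params.seed_len) >= 2 * k)
        if index is not None and params.seed_mismatch_max <= 1
        else np.zeros(n_reads, dtype=bool)
    )

    if eligible.any():
        hits_frames.append(
            _match_indexed(catalog, sg, mat, lengths, params, np.nonzero(eligible)[0])
        )
    rest = np.nonzero(~eligible)[0]
    if rest.size:
        hits_frames.append(_match_scan(catalog, mat, lengths, params, rest))
    if not hits_frames:
        return _empty_hits()
    return pd.concat(hits_frames, ignore_index=True)


def _empty_hits() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_idx": np.empty(0, dtype=np.int64),
            "contig_idx": np.empty(0, dtype=np.int64),
            "strand_code": np.empty(0, dtype=np.int8),
            "rev_off": np.empty(0, dtype=np.int64),
            "mm_seed": np.empty(0, dtype=np.int64),
            "mm_tail": np.empty(0, dtype=np.int64),
        }
    )


def _verify(
    sg: _StrandedGenome,
    mat: np.ndarray,
    lengths: np.ndarray,
    params: MatchParams,
    read_idx: np.ndarray,
    strand_code: np.ndarray,
    goff: np.ndarray,
) -> pd.DataFrame:
    """Count seed/tail mismatches for candidate (read, strand, offset) triples."""
    if read_idx.size == 0:
        return _empty_hits()
    lmax = mat.shape[1]
    out_frames = []
    for sc, genome in ((0, sg.fwd), (1, sg.rev)):
        m = strand_code == sc
        if not m.any():
            continue
        ri = read_idx[m]
        go = goff[m]
        n = lengths[ri]
        span = np.minimum(lmax, int(n.max()))
        idx = go[:, None] + np.arange(span)
        np.clip(idx, 0, genome.size - 1, out=idx)
        win = genome[idx]
        neq = (win != mat[ri, :span]).astype(np.int32)
        cum = np.cumsum(neq, axis=1)
        s = np.minimum(params.seed_len, n)
        mm_seed = np.take_along_axis(cum, (s - 1)[:, None], axis=1)[:, 0]
        mm_tot = np.take_along_axis(cum, (n - 1)[:, None], axis=1)[:, 0]
        mm_tail = mm_tot - mm_seed
        ok = (mm_seed <= params.seed_mismatch_max) & (
            mm_tail <= params.tail_mismatch_max
        )
        # reject windows that run off the genome/into padding
        ok &= go + n <= genome.size
        ci, local = sg.locate(go)
        ok &= local + n <= sg.lengths[ci]
        out_frames.append(
            pd.DataFrame(
                {
                    "read_idx": ri[ok],
                    "contig_idx": ci[ok],
                    "strand_code": np.full(int(ok.sum()), sc, dtype=np.int8),
                    "rev_off": local[ok],
                    "mm_seed": mm_seed[ok],
                    "mm_tail": mm_tail[ok],
                }
            )
        )
    if not out_frames:
        return _empty_hits()
    return pd.concat(out_frames, ignore_index=True)


def _match_indexed(
    catalog: AnnotationCatalog,
    sg: _StrandedGenome,
    mat: np.ndarray,
    lengths: np.ndarray,
    params: MatchParams,
    rows: np.ndarray,
) -> pd.DataFrame:
    index = catalog.color_index
    assert index is not None
    k = index.k
    cand_read, cand_strand, cand_goff = [], [], []
    for w0 in (0, k):  # two disjoint seed windows
        keys = _pack_windows(mat[rows], np.full(rows.size, w0), k)
        lo = np.searchsorted(index.keys, keys, side="left")
        hi = np.searchsorted(index.keys, keys, side="right")
        counts = hi - lo
        if counts.sum() == 0:
            continue
        rep_rows = np.repeat(rows, counts)
        # expand [lo, hi) ranges into flat indices
        flat = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi) if b > a])
        ci = index.contig_idx[flat]
        sc = index.strand_code[flat]
        off = index.offsets[flat].astype(np.int64)
        # hit start offset = k-mer offset - window start within read
        start = off - w0
        gstart = sg.bounds[ci] + start
        valid = start >= 0
        cand_read.append(rep_rows[valid])
        cand_strand.append(sc[valid])
        cand_goff.append(gstart[valid])
    if not cand_read:
        return _empty_hits()
    read_idx = np.concatenate(cand_read)
    strand_code = np.concatenate(cand_strand).astype(np.int8)
    goff = np.concatenate(cand_goff)
    # dedupe candidates arising from both windows
    key = np.stack([read_idx, strand_code.astype(np.int64), goff], axis=1)
    _, uniq = np.unique(key, axis=0, return_index=True)
    return _verify(
        sg,
        mat,
        lengths,
        params,
        read_idx[uniq],
        strand_code[uniq],
        goff[uniq],
    )


def _match_scan(
    catalog: AnnotationCatalog,
    mat: np.ndarray,
    lengths: np.ndarray,
    params: MatchParams,
    rows: np.ndarray,
) -> pd.DataFrame:
    """Exhaustive per-read scan (used for reads too short to index-seed)."""
    sg = _StrandedGenome(catalog)
    frames = []
    contig_colors = catalog.contig_colors()
    names = list(contig_colors)
    for r in rows:
        n = int(lengths[r])
        colors = mat[r, :n]
        for ci, name in enumerate(names):
            cc = contig_colors[name]
            for sc, arr in ((0, cc), (1, cc[::-1])):
                if arr.size < n:
                    continue
                win = np.lib.stride_tricks.sliding_window_view(arr, n)
                neq = win != colors
                s = min(params.seed_len, n)
                mm_seed = neq[:, :s].sum(axis=1)
                mm_tail = neq[:, s:].sum(axis=1)
                ok = (mm_seed <= params.seed_mismatch_max) & (
                    mm_tail <= params.tail_mismatch_max
                )
                offs = np.nonzero(ok)[0]
                if offs.size:
                    frames.append(
                        pd.DataFrame(
                            {
                                "read_idx": np.full(offs.size, r, dtype=np.int64),
                                "contig_idx": np.full(offs.size, ci, dtype=np.int64),
                                "strand_code": np.full(offs.size, sc, dtype=np.int8),
                                "rev_off": offs.astype(np.int64),
                                "mm_seed": mm_seed[offs].astype(np.int64),
                                "mm_tail": mm_tail[offs].astype(np.int64),
                            }
                        )
                    )
    if not frames:
        return _empty_hits()
    return pd.concat(frames, ignore_index=True)


def _assign_batch(
    catalog: AnnotationCatalog,
    hits: pd.DataFrame,
    lengths: np.ndarray,
    n_reads: int,
) -> pd.DataFrame:
    """Pick the exclusive category/feature for each read from its hit set.

    Returns one row per read index with category / feature / locus columns;
    reads without hits are absent (caller marks them unmapped).
    """
    if hits.empty:
        return pd.DataFrame(
            columns=[
                "read_idx", "category", "feature_id", "contig",
                "start", "end", "strand", "mm_seed", "mm_tail",
            ]
        )
    names = list(catalog.contig_colors())
    clens = np.array([catalog.contig_colors()[n].size for n in names], dtype=np.int64)
    h = hits.copy()
    n = lengths[h["read_idx"].to_numpy()]
    rev = h["strand_code"].to_numpy() == 1
    off = h["rev_off"].to_numpy()
    clen_h = clens[h["contig_idx"].to_numpy()]
    # base-coordinate span: t = n+1 bases
    start = np.where(rev, clen_h - off - n, off)
    h["start"] = start
    h["end"] = start + n + 1
    h["mm"] = h["mm_seed"] + h["mm_tail"]

    # keep only minimum-mismatch hits per read
    h["best"] = h.groupby("read_idx")["mm"].transform("min")
    h = h[h["mm"] == h["best"]].reset_index(drop=True)

    # feature overlap >= 50% of read; vectorized loop over (few) leaf features
    n_h = len(h)
    prio = np.full(n_h, len(catalog.hierarchy) + 1, dtype=np.int32)
    feat_idx = np.full(n_h, -1, dtype=np.int64)
    leaves = catalog.leaf_features()
    name_to_ci = {nm: i for i, nm in enumerate(names)}
    hs = h["start"].to_numpy()
    he = h["end"].to_numpy()
    hci = h["contig_idx"].to_numpy()
    hsc = h["strand_code"].to_numpy()
    rlen = he - hs
    # candidate sort key: (priority, feature start) so lower wins
    best_key = np.full(n_h, np.iinfo(np.int64).max, dtype=np.int64)
    for fi, f in enumerate(leaves):
        fc = name_to_ci.get(f.contig)
        if fc is None:
            continue
        f_sc = 0 if f.strand == "+" else 1
        overlap = np.minimum(he, f.end) - np.maximum(hs, f.start)
        mask = (hci == fc) & (hsc == f_sc) & (overlap * 2 >= rlen)
        if not mask.any():
            continue
        p = catalog.priority(f.rna_class)
        key = (np.int64(p) << 40) | np.int64(f.start)
        upd = mask & (key < best_key)
        best_key[upd] = key
        prio[upd] = p
        feat_idx[upd] = fi

    h["prio"] = prio
    h["feat_idx"] = feat_idx
    # order hits within read: priority, then hit start, then contig/strand
    h = h.sort_values(
        ["read_idx", "prio", "start", "contig_idx", "strand_code"], kind="stable"
    )
    top = h.drop_duplicates("read_idx", keep="first").reset_index(drop=True)

    feat_ids = np.array([f.feature_id for f in leaves] + [""], dtype=object)
    classes = np.array([f.rna_class for f in leaves] + [NON_ANNOTATED], dtype=object)
    fi = top["feat_idx"].to_numpy()
    top["feature_id"] = np.where(fi >= 0, feat_ids[fi], None)
    top["category"] = classes[fi]
    top["contig"] = np.array(names, dtype=object)[top["contig_idx"].to_numpy()]
    top["strand"] = np.where(top["strand_code"].to_numpy() == 0, "+", "-")
    return top[
        [
            "read_idx", "category", "feature_id", "contig",
            "start", "end", "strand", "mm_seed", "mm_tail",
        ]
    ]


def assign_all(
    reads_by_sample: Mapping[str, Sequence[ColorRead]],
    catalog: AnnotationCatalog,
    params: MatchParams | None = None,
    adapter: "NucleotideSeq | str | None" = None,
    min_overlap: int = 6,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trim, match, and exclusively assign every read of every sample.

    Returns ``(assignment_table, class_summary)``.  The assignment table has
    one row per retained read (columns: sample, read_id, category,
    feature_id, contig, start, end, strand, mm_seed, mm_tail); the summary
    gives per-sample category fractions over mapped reads (they sum to 1).
    Samples with zero mapped reads are excluded from the summary.
    """
    params = params or MatchParams()
    adapter_colors = (
        adapter_internal_colors(adapter) if adapter is not None else None
    )
    tables = []
    for sample, reads in reads_by_sample.items():
        tables.append(
            _assign_sample(sample, reads, catalog, params, adapter_colors, min_overlap)
        )
    table = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(
            columns=[
                "sample", "read_id", "category", "feature_id", "contig",
                "start", "end", "strand", "mm_seed", "mm_tail",
            ]
        )
    )
    summary = class_distribution(table)
    return table, summary


def _assign_sample(
    sample: str,
    reads: "Sequence[ColorRead] | ReadBatch",
    catalog: AnnotationCatalog,
    params: MatchParams,
    adapter_colors: np.ndarray | None,
    min_overlap: int,
) -> pd.DataFrame:
    if isinstance(reads, ReadBatch):
        n = len(reads)
        raw = reads.colors
        raw_len = np.full(n, raw.shape[1], dtype=np.int32)
        rev_flag = np.full(n, reads.direction == FROM_3P)
        read_ids: Sequence[str] = reads.read_ids()
    else:
        n = len(reads)
        if n:
            lmax = max(len(r.colors) for r in reads)
            raw = np.full((n, lmax), _PAD, dtype=np.uint8)
            raw_len = np.empty(n, dtype=np.int32)
            rev_flag = np.empty(n, dtype=bool)
            for i, r in enumerate(reads):
                arr = colors_to_array(r.colors)
                raw[i, : arr.size] = arr
                raw_len[i] = arr.size
                rev_flag[i] = r.direction == FROM_3P
        read_ids = [r.read_id for r in reads]
    if n == 0:
        return pd.DataFrame(
            columns=[
                "sample", "read_id", "category", "feature_id", "contig",
                "start", "end", "strand", "mm_seed", "mm_tail",
            ]
        )

    if adapter_colors is not None:
        tlen = _trim_batch(raw, adapter_colors, min_overlap)
    else:
        tlen = raw_len.astype(np.int32)
    tlen = np.minimum(tlen, params.max_trimmed_len)
    too_short = tlen < params.min_trimmed_len

    # matchable colors: drop the anchor-dependent first color; reverse rows
    # of 3'-direction reads (vectorized gather)
    lmax = raw.shape[1]
    mlen = np.maximum(tlen - 1, 0)
    body = raw[:, 1:]
    width = body.shape[1]
    mat = np.full((n, width), _PAD, dtype=np.uint8)
    fwd = ~rev_flag & ~too_short
    if fwd.any():
        sub = body[fwd]
        msk = np.arange(width) < mlen[fwd][:, None]
        mat[np.ix_(fwd, np.arange(width))] = np.where(msk, sub, _PAD)
    rev = rev_flag & ~too_short
    if rev.any():
        sub = body[rev]
        ml = mlen[rev]
        j = np.arange(width)
        gather = ml[:, None] - 1 - j
        valid = gather >= 0
        np.clip(gather, 0, width - 1, out=gather)
        revd = np.take_along_axis(sub, gather, axis=1)
        mat[np.ix_(rev, j)] = np.where(valid, revd, _PAD)

    keep = ~too_short
    keep_idx = np.nonzero(keep)[0]
    cat_full = np.full(n, TOO_SHORT, dtype=object)
    cols_full: dict[str, np.ndarray] = {
        "feature_id": np.full(n, None, dtype=object),
        "contig": np.full(n, None, dtype=object),
        "start": np.full(n, np.nan),
        "end": np.full(n, np.nan),
        "strand": np.full(n, None, dtype=object),
        "mm_seed": np.zeros(n, dtype=np.int64),
        "mm_tail": np.zeros(n, dtype=np.int64),
    }
    if keep_idx.size:
        sub = mat[keep_idx]
        sub_len = mlen[keep_idx]
        uniq, inverse = np.unique(sub, axis=0, return_inverse=True)
        # representative length per unique row (identical rows share padding,
        # hence length)
        uniq_len = np.zeros(uniq.shape[0], dtype=np.int64)
        uniq_len[inverse] = sub_len
        hits = _match_batch(catalog, uniq, uniq_len, params)
        assigned = _assign_batch(catalog, hits, uniq_len, uniq.shape[0])
        aidx = assigned["read_idx"].to_numpy()
        u_cat = np.full(uniq.shape[0], UNMAPPED, dtype=object)
        u_cat[aidx] = assigned["category"].to_numpy()
        cat_full[keep_idx] = u_cat[inverse]
        for col, fill, dtype in [
            ("feature_id", None, object),
            ("contig", None, object),
            ("start", np.nan, float),
            ("end", np.nan, float),
            ("strand", None, object),
            ("mm_seed", 0, np.int64),
            ("mm_tail", 0, np.int64),
        ]:
            arr_col = np.full(uniq.shape[0], fill, dtype=dtype)
            arr_col[aidx] = assigned[col].to_numpy()
            cols_full[col][keep_idx] = arr_col[inverse]
    records = pd.DataFrame(
        {
            "sample": sample,
            "read_id": read_ids,
            "category": cat_full,
            "feature_id": cols_full["feature_id"],
            "contig": cols_full["contig"],
            "start": pd.array(cols_full["start"]).astype("Int64"),
            "end": pd.array(cols_full["end"]).astype("Int64"),
            "strand": cols_full["strand"],
            "mm_seed": cols_full["mm_seed"],
            "mm_tail": cols_full["mm_tail"],
        }
    )
    return records


def class_distribution(table: pd.DataFrame) -> pd.DataFrame:
    """Per-sample category fractions over mapped reads (sum to 1).

    Mapped = assigned to a class or non_annotated; unmapped/too-short reads
    are excluded, as are samples with no mapped reads at all.
    """
    mapped = table[~table["category"].isin([UNMAPPED, TOO_SHORT])]
    if mapped.empty:
        return pd.DataFrame(columns=["sample", "category", "fraction"])
    counts = (
        mapped.groupby(["sample", "category"]).size().rename("count").reset_index()
    )
    totals = counts.groupby("sample")["count"].transform("sum")
    counts["fraction"] = counts["count"] / totals
    return counts[["sample", "category", "count", "fraction"]]
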