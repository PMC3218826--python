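"""Near-identical miRNA disambiguation by exact color-space census.

When two candidate miRNAs differ by a single 3'-terminal base (as with an
annotated mature sequence and an opposite-strand near-copy), base-space
counts cannot tell genuine reads of the rarer species from sequencing
errors of the abundant one.  The census works directly on the raw color
reads: each candidate sequence is converted to color space and counted by
exact substring match, and the quality values at the discriminating color
positions are inspected — a real species should be backed by high-quality
colors at exactly the positions that distinguish it.

A single internal base substitution changes two adjacent colors while a
terminal substitution changes one, so the discriminating positions of a
3'-divergent pair are a single color index.

Candidates are matched through their anchor-independent internal colors
(the first color of a sequenced insert depends on the adapter's last base
and is excluded).  By default a match must sit at read offset 0, where
small-RNA inserts start; any-offset search is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .colorspace import (
    ColorRead,
    NucleotideSeq,
    colors_to_array,
    encode_colorspace,
    internal_colors,
    reverse_complement,
)

FROM_5P = "from_5p"
FROM_3P = "from_3p"


@dataclass
class CensusResult:
    """Perfect-match read counts for one candidate in one search direction."""

    candidate_id: str
    direction: str
    counts: dict[str, int] = field(default_factory=dict)
    discriminating_positions: list[int] = field(default_factory=list)
    mean_quality: dict[int, float] = field(default_factory=dict)


def discriminating_positions(
    seq_a: "NucleotideSeq | str",
    seq_b: "NucleotideSeq | str",
    anchor: str = "T",
    max_length_diff: int = 4,
) -> list[int]:
    """Color positions at which two candidates' encodings differ.

    Both sequences are encoded behind a shared anchor base; unequal lengths
    are compared over the shorter sequence (3'-end padding policy), with the
    trailing bases treated as additional discriminating evidence outside the
    returned positions.  A length difference beyond ``max_length_diff`` is
    rejected as non-alignable.
    """
    a = seq_a.seq if isinstance(seq_a, NucleotideSeq) else seq_a
    b = seq_b.seq if isinstance(seq_b, NucleotideSeq) else seq_b
    a = a.upper().replace("U", "T")
    b = b.upper().replace("U", "T")
    if abs(len(a) - len(b)) > max_length_diff:
        raise ValueError(
            f"length mismatch {len(a)} vs {len(b)} exceeds the padding policy"
        )
    n = min(len(a), len(b))
    ca = encode_colorspace(a[:n], anchor)[1:]
    cb = encode_colorspace(b[:n], anchor)[1:]
    return [i for i in range(n) if ca[i] != cb[i]]


def _candidate_internal(seq: str, direction: str) -> np.ndarray:
    s = seq.upper().replace("U", "T")
    if direction == FROM_3P:
        s = reverse_complement(s)
    return colors_to_array(internal_colors(s))


def perfect_match_census(
    reads_by_sample: Mapping[str, Sequence[ColorRead]],
    candidates: Sequence[NucleotideSeq],
    directions: Sequence[str] = (FROM_5P, FROM_3P),
    anchored: bool = True,
) -> list[CensusResult]:
    """Count raw reads containing each candidate's exact color encoding.

    For the 5'-direction search the candidate's internal colors must match
    the read colors starting right after the primer-junction color (offset
    0 of the insert); the 3'-direction search uses the reverse-complement
    colors.  With ``anchored=False`` the encoding may occur at any offset.
    """
    results = []
    # pre-pack reads per sample into padded matrices once
    packed: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for sample, reads in reads_by_sample.items():
        if not reads:
            packed[sample] = (np.empty((0, 0), dtype=np.uint8), np.empty(0, int))
            continue
        lmax = max(len(r.colors) for r in reads)
        mat = np.full((len(reads), lmax), 250, dtype=np.uint8)
        lens = np.empty(len(reads), dtype=np.int64)
        for i, r in enumerate(reads):
            arr = colors_to_array(r.colors)
            mat[i, : arr.size] = arr
            lens[i] = arr.size
        packed[sample] = (mat, lens)
    for cand in candidates:
        for direction in directions:
            pat = _candidate_internal(cand.seq, direction)
            counts = {}
            for sample, (mat, lens) in packed.items():
                counts[sample] = int(
                    _census_mask(mat, lens, pat, anchored).sum()
                )
            results.append(
                CensusResult(
                    candidate_id=cand.name or cand.seq,
                    direction=direction,
                    counts=counts,
                )
            )
    return results


def _census_mask(
    mat: np.ndarray, lens: np.ndarray, pattern: np.ndarray, anchored: bool
) -> np.ndarray:
    """Boolean mask of reads matching the pattern.

    Read color 0 pairs the primer with the insert's first base and is
    anchor-dependent; insert-internal colors start at read index 1.
    """
    m = pattern.size
    if mat.shape[1] < m + 1:
        return np.zeros(mat.shape[0], dtype=bool)
    if anchored:
        return (
            (lens >= m + 1)
            & (mat[:, 1 : 1 + m] == pattern).all(axis=1)
        )
    hit = np.zeros(mat.shape[0], dtype=bool)
    for off in range(1, mat.shape[1] - m + 1):
        hit |= (lens >= off + m) & (mat[:, off : off + m] == pattern).all(axis=1)
    return hit


def matched_read_ids(
    reads: Sequence[ColorRead],
    candidate: NucleotideSeq,
    direction: str = FROM_5P,
    anchored: bool = True,
) -> list[str]:
    """Read ids of perfect color-space matches of one candidate."""
    if not reads:
        return []
    lmax = max(len(r.colors) for r in reads)
    mat = np.full((len(reads), lmax), 250, dtype=np.uint8)
    lens = np.empty(len(reads), dtype=np.int64)
    for i, r in enumerate(reads):
        arr = colors_to_array(r.colors)
        mat[i, : arr.size] = arr
        lens[i] = arr.size
    pat = _candidate_internal(candidate.seq, direction)
    mask = _census_mask(mat, lens, pat, anchored)
    return [r.read_id for r, hit in zip(reads, mask) if hit]


def positional_quality(
    reads: Sequence[ColorRead],
    matched_ids: Sequence[str],
    positions: Sequence[int],
) -> pd.DataFrame:
    """Mean/sd of quality at given color positions over matched reads.

    Also reports the read-wide mean quality of the matched reads for
    comparison; an empty matched set yields missing values.
    """
    wanted = set(matched_ids)
    quals = [r.quals for r in reads if r.read_id in wanted and r.quals]
    rows = []
    if quals:
        q = np.array(quals, dtype=float)
        read_wide = float(q.mean())
        for p in positions:
            if p < 0 or p >= q.shape[1]:
                raise ValueError(f"position {p} outside read length {q.shape[1]}")
            rows.append(
                {
                    "position": p,
                    "mean_quality": float(q[:, p].mean()),
                    "sd_quality": float(q[:, p].std(ddof=0)),
                    "read_wide_mean": read_wide,
                    "n_reads": q.shape[0],
                }
            )
    else:
        for p in positions:
            rows.append(
                {
                    "position": p,
                    "mean_quality": np.nan,
                    "sd_quality": np.nan,
                    "read_wide_mean": np.nan,
                    "n_reads": 0,
                }
            )
    return pd.DataFrame(rows)
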