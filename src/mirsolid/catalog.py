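"""Reference sequences and class-tagged annotations for exclusive assignment.

The catalog bundles a toy (or real) genome with features tagged by small-RNA
class (human miRNA, other-species miRNA, transcript, piRNA, tRNA, rRNA,
snoRNA, other ncRNA) and an ordered hierarchy used to distribute mapped
reads exclusively: a read overlapping several feature classes is counted
once, for the highest-priority class.

Coordinates are 1-based inclusive in GFF3 on disk and 0-based half-open in
memory.  A color-space k-mer index over both genome strands supports
seed-and-extend matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import numpy as np
from Bio import SeqIO

from .colorspace import colors_to_array, internal_colors

RNA_CLASSES = (
    "miRNA_human",
    "miRNA_other_species",
    "transcript",
    "piRNA",
    "tRNA",
    "rRNA",
    "snoRNA",
    "other_ncRNA",
)

#: Exclusive assignment order (highest priority first); reads mapping to the
#: genome but to no feature fall through to ``non_annotated``.
DEFAULT_HIERARCHY = list(RNA_CLASSES)

NON_ANNOTATED = "non_annotated"
UNMAPPED = "unmapped"
TOO_SHORT = "too_short"


class CatalogError(ValueError):
    """Invalid reference input (coordinates, classes, hierarchy)."""


@dataclass
class Feature:
    """A class-tagged genomic feature; start/end are 0-based half-open."""

    feature_id: str
    rna_class: str
    contig: str
    start: int
    end: int
    strand: str
    parent: str | None = None

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise CatalogError(
                f"{self.feature_id}: unknown rna_class {self.rna_class!r}"
            )
        if self.start >= self.end:
            raise CatalogError(f"{self.feature_id}: start >= end")
        if self.strand not in "+-":
            raise CatalogError(f"{self.feature_id}: invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


class ColorIndex:
    """Exact k-mer index over contig color strings, both strands.

    Keys are base-4 packed color k-mers; positions are stored sorted by key
    so batch queries reduce to ``searchsorted``.  Offsets are color-space
    offsets into each contig's internal color string (forward strand) or its
    reversal (reverse strand).
    """

    def __init__(self, contig_colors: dict[str, np.ndarray], k: int):
        if k < 8:
            raise CatalogError("index k-mer below 8 colors is too dense to be useful")
        if k > 18:
            raise CatalogError("index k-mer cannot exceed the 18-color seed")
        self.k = k
        self.contig_names = list(contig_colors)
        keys_parts, contig_parts, strand_parts, offset_parts = [], [], [], []
        weights = 4 ** np.arange(k - 1, -1, -1, dtype=np.uint64)
        for ci, name in enumerate(self.contig_names):
            fwd = contig_colors[name].astype(np.uint64)
            for strand_code, arr in ((0, fwd), (1, fwd[::-1])):
                if arr.size < k:
                    continue
                win = np.lib.stride_tricks.sliding_window_view(arr, k)
                keys = win @ weights
                keys_parts.append(keys)
                contig_parts.append(np.full(keys.size, ci, dtype=np.int32))
                strand_parts.append(np.full(keys.size, strand_code, dtype=np.int8))
                offset_parts.append(np.arange(keys.size, dtype=np.int32))
        if keys_parts:
            keys = np.concatenate(keys_parts)
            order = np.argsort(keys, kind="stable")
            self.keys = keys[order]
            self.contig_idx = np.concatenate(contig_parts)[order]
            self.strand_code = np.concatenate(strand_parts)[order]
            self.offsets = np.concatenate(offset_parts)[order]
        else:
            self.keys = np.empty(0, dtype=np.uint64)
            self.contig_idx = np.empty(0, dtype=np.int32)
            self.strand_code = np.empty(0, dtype=np.int8)
            self.offsets = np.empty(0, dtype=np.int32)
        self._weights = weights

    def pack(self, colors: np.ndarray) -> np.uint64:
        if colors.size != self.k:
            raise CatalogError(f"query must be exactly {self.k} colors")
        return np.uint64(colors.astype(np.uint64) @ self._weights)

    def query(self, colors: "np.ndarray | str") -> list[tuple[str, int, str]]:
        """Look up one color k-mer; returns (contig, offset, strand) hits."""
        if isinstance(colors, str):
            colors = colors_to_array(colors)
        key = self.pack(colors)
        lo = np.searchsorted(self.keys, key, side="left")
        hi = np.searchsorted(self.keys, key, side="right")
        return [
            (
                self.contig_names[self.contig_idx[i]],
                int(self.offsets[i]),
                "+" if self.strand_code[i] == 0 else "-",
            )
            for i in range(lo, hi)
        ]

    def query_range(self, key: np.uint64) -> tuple[int, int]:
        lo = int(np.searchsorted(self.keys, key, side="left"))
        hi = int(np.searchsorted(self.keys, key, side="right"))
        return lo, hi


@dataclass
class AnnotationCatalog:
    """Genome, features, assignment hierarchy, and the color k-mer index."""

    contigs: dict[str, str]
    features: list[Feature]
    hierarchy: list[str] = field(default_factory=lambda: list(DEFAULT_HIERARCHY))
    color_index: ColorIndex | None = None

    def __post_init__(self) -> None:
        if len(set(self.hierarchy)) != len(self.hierarchy):
            raise CatalogError("hierarchy contains repeated classes")
        unknown = set(self.hierarchy) - set(RNA_CLASSES)
        if unknown:
            raise CatalogError(f"hierarchy names unknown classes {unknown}")
        by_id = {f.feature_id: f for f in self.features}
        for f in self.features:
            if f.contig not in self.contigs:
                raise CatalogError(f"{f.feature_id}: unknown contig {f.contig!r}")
            if f.end > len(self.contigs[f.contig]):
                raise CatalogError(
                    f"{f.feature_id}: end {f.end} beyond contig "
                    f"{f.contig} length {len(self.contigs[f.contig])}"
                )
            if f.parent is not None:
                p = by_id.get(f.parent)
                if p is None:
                    raise CatalogError(f"{f.feature_id}: unknown parent {f.parent}")
                if (
                    p.contig != f.contig
                    or p.strand != f.strand
                    or not (p.start <= f.start and f.end <= p.end)
                ):
                    raise CatalogError(
                        f"{f.feature_id}: parent {f.parent} does not span child"
                    )
        self._by_id = by_id
        self._children: dict[str, list[Feature]] = {}
        for f in self.features:
            if f.parent is not None:
                self._children.setdefault(f.parent, []).append(f)
        self._contig_colors: dict[str, np.ndarray] | None = None

    def feature(self, feature_id: str) -> Feature:
        return self._by_id[feature_id]

    def children(self, feature_id: str) -> list[Feature]:
        return self._children.get(feature_id, [])

    def leaf_features(self) -> list[Feature]:
        """Assignment targets: features without children (mature arms, not
        precursors)."""
        return [f for f in self.features if f.feature_id not in self._children]

    def priority(self, category: str) -> int:
        """Smaller is higher priority; non-hierarchy categories sort last."""
        try:
            return self.hierarchy.index(category)
        except ValueError:
            return len(self.hierarchy)

    def contig_colors(self) -> dict[str, np.ndarray]:
        """Internal color string of each contig, as a uint8 array."""
        if self._contig_colors is None:
            self._contig_colors = {
                name: colors_to_array(internal_colors(seq)) if len(seq) > 1
                else np.empty(0, dtype=np.uint8)
                for name, seq in self.contigs.items()
            }
        return self._contig_colors


def load_catalog(
    genome_fasta: "str | Path",
    annotations_gff3: "str | Path",
    hierarchy: list[str] | None = None,
) -> AnnotationCatalog:
    """Load a genome FASTA plus a GFF3 whose features carry ``rna_class``.

    Every feature must carry an ``rna_class`` attribute from the known class
    set; coordinates are validated against contig lengths.
    """
    contigs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome_fasta), "fasta")
    }
    if not contigs:
        raise CatalogError(f"no sequences in {genome_fasta}")
    try:
        db = gffutils.create_db(
            str(annotations_gff3),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
        gff_features = list(db.all_features())
    except gffutils.exceptions.EmptyInputError:
        gff_features = []  # valid: all mapped reads will be non-annotated
    features = []
    for f in gff_features:
        attrs = f.attributes
        if "rna_class" not in attrs:
            raise CatalogError(f"feature {f.id}: missing rna_class attribute")
        parents = attrs.get("Parent", [])
        features.append(
            Feature(
                feature_id=f.id,
                rna_class=attrs["rna_class"][0],
                contig=f.seqid,
                start=f.start - 1,  # GFF3 1-based inclusive -> 0-based half-open
                end=f.end,
                strand=f.strand,
                parent=parents[0] if parents else None,
            )
        )
    return AnnotationCatalog(
        contigs=contigs,
        features=features,
        hierarchy=list(hierarchy) if hierarchy is not None else list(DEFAULT_HIERARCHY),
    )


def build_color_index(catalog: AnnotationCatalog, k: int = 8) -> ColorIndex:
    """Build (and attach) the color-space k-mer index over both strands."""
    index = ColorIndex(catalog.contig_colors(), k)
    catalog.color_index = index
    return index
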