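"""SOLiD di-base (color-space) sequences: encoding, decoding, and csfasta I/O.

SOLiD sequencers emit reads as a known primer base followed by a string of
"colors" 0-3, where each color encodes the transition between two adjacent
nucleotides.  The transition code is the XOR of the 2-bit base codes
(A=0, C=1, G=2, T=3), which reproduces the standard di-base matrix:
identical pair -> 0, A<->C = 1, A<->G = 2, A<->T = 3, C<->G = 3, C<->T = 2,
G<->T = 1.  Two useful consequences of the XOR formulation are used
throughout this package:

* a color string plus any one anchor base determines the nucleotide
  sequence uniquely (prefix-XOR decoding);
* colors are complement-invariant, so the color string of a reverse
  complement is simply the reversed color string.

Quality values are carried one integer per color, read verbatim from
``.qual`` files with no Phred rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

_BASES = "ACGT"
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASE_OF = dict(enumerate(_BASES))

# vectorized byte-level lookup tables
BASE_TO_CODE = np.full(256, 255, dtype=np.uint8)
for _b, _c in _CODE.items():
    BASE_TO_CODE[ord(_b)] = _c
    BASE_TO_CODE[ord(_b.lower())] = _c
CODE_TO_BASE = np.frombuffer(_BASES.encode(), dtype=np.uint8).copy()

FROM_5P = "from_5p"
FROM_3P = "from_3p"


class ColorspaceError(ValueError):
    """Malformed color-space input (bad alphabet or record structure)."""


@dataclass
class ColorRead:
    """One SOLiD read: primer base, color string, per-color qualities.

    ``direction`` records which library adapter set produced the read
    (sequencing proceeded from the 5' or the 3' end of the insert);
     3'-direction reads observe the reverse complement of the insert.
    """

    read_id: str
    primer: str
    colors: str
    quals: list[int] = field(default_factory=list)
    direction: str = FROM_5P

    def __post_init__(self) -> None:
        if self.primer not in _CODE:
            raise ColorspaceError(f"invalid primer base {self.primer!r}")
        if any(c not in "0123" for c in self.colors):
            raise ColorspaceError(f"invalid color symbol in {self.colors!r}")
        if self.quals and len(self.quals) != len(self.colors):
            raise ColorspaceError(
                f"{self.read_id}: {len(self.quals)} qualities for "
                f"{len(self.colors)} colors"
            )
        if any(q < 0 for q in self.quals):
            raise ColorspaceError(f"{self.read_id}: negative quality value")
        if self.direction not in (FROM_5P, FROM_3P):
            raise ColorspaceError(f"invalid direction {self.direction!r}")

    def __len__(self) -> int:
        return len(self.colors)


@dataclass
class NucleotideSeq:
    """A plain DNA sequence; U is mapped to T on construction."""

    seq: str
    name: str = ""

    def __post_init__(self) -> None:
        self.seq = self.seq.upper().replace("U", "T")
        if not self.seq:
            raise ColorspaceError(f"{self.name or 'sequence'}: empty sequence")
        bad = set(self.seq) - set(_BASES)
        if bad:
            raise ColorspaceError(f"{self.name or 'sequence'}: non-ACGT {bad}")

    def __len__(self) -> int:
        return len(self.seq)


def _as_seq(seq: "NucleotideSeq | str") -> str:
    s = seq.seq if isinstance(seq, NucleotideSeq) else seq
    s = s.upper().replace("U", "T")
    if not s:
        raise ColorspaceError("empty sequence")
    if set(s) - set(_BASES):
        raise ColorspaceError(f"non-ACGT character in {s!r}")
    return s


def dibase_color(b1: str, b2: str) -> int:
    """Transition color for an ordered base pair."""
    try:
        return _CODE[b1] ^ _CODE[b2]
    except KeyError as exc:
        raise ColorspaceError(f"non-ACGT base {exc.args[0]!r}") from None


def encode_colorspace(seq: "NucleotideSeq | str", primer: str) -> str:
    """Encode a nucleotide sequence as ``primer + colors``.

    Color i is the di-base transition between base i-1 and base i, with the
    primer acting as base -1; the output carries one color per input base.
    """
    s = _as_seq(seq)
    if primer not in _CODE:
        raise ColorspaceError(f"invalid primer base {primer!r}")
    codes = BASE_TO_CODE[np.frombuffer(s.encode(), dtype=np.uint8)]
    prev = np.empty_like(codes)
    prev[0] = _CODE[primer]
    prev[1:] = codes[:-1]
    colors = prev ^ codes
    return primer + "".join(chr(ord("0") + c) for c in colors)


def decode_colorspace(colors_with_primer: str) -> str:
    """Decode ``primer + colors`` back to the unique nucleotide sequence."""
    if not colors_with_primer:
        raise ColorspaceError("empty color record")
    primer, colors = colors_with_primer[0], colors_with_primer[1:]
    if primer not in _CODE:
        raise ColorspaceError(f"record must start with a base, got {primer!r}")
    if any(c not in "0123" for c in colors):
        raise ColorspaceError(f"malformed color symbol in {colors!r}")
    if not colors:
        return ""
    arr = np.frombuffer(colors.encode(), dtype=np.uint8) - ord("0")
    # prefix XOR: base_i = primer ^ c_0 ^ ... ^ c_i
    codes = np.bitwise_xor.accumulate(arr) ^ _CODE[primer]
    return "".join(_BASE_OF[int(c)] for c in codes)


def internal_colors(seq: "NucleotideSeq | str") -> str:
    """Anchor-independent colors: transitions between adjacent bases only."""
    s = _as_seq(seq)
    return encode_colorspace(s, "A")[2:]  # drop primer and primer-junction color


def reverse_complement(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


def reverse_complement_colors(colors: str) -> str:
    """Color string of a sequence's reverse complement.

    Because colors are complement-invariant, this is plain reversal.  The
    input must carry no primer base.
    """
    if any(c not in "0123" for c in colors):
        raise ColorspaceError(f"invalid color symbol in {colors!r}")
    return colors[::-1]


def colors_to_array(colors: str) -> np.ndarray:
    return np.frombuffer(colors.encode(), dtype=np.uint8) - ord("0")


def array_to_colors(arr: np.ndarray) -> str:
    return (arr.astype(np.uint8) + ord("0")).tobytes().decode()


@dataclass
class ReadBatch:
    """A whole sample's reads as arrays (one direction per batch).

    ``colors`` is an (N, L) uint8 matrix of color values 0-3 (no primer
    column; the shared primer base is stored once), ``quals`` an (N, L)
    integer matrix.  Row i corresponds to read id ``{sample}_{i}``.
    """

    sample: str
    colors: np.ndarray
    quals: np.ndarray
    primer: str = "T"
    direction: str = FROM_5P

    def __len__(self) -> int:
        return int(self.colors.shape[0])

    def read_ids(self) -> list[str]:
        return [f"{self.sample}_{i}" for i in range(len(self))]

    def to_color_reads(self) -> list[ColorRead]:
        ids = self.read_ids()
        return [
            ColorRead(
                ids[i],
                self.primer,
                array_to_colors(self.colors[i]),
                [int(q) for q in self.quals[i]] if self.quals.size else [],
                self.direction,
            )
            for i in range(len(self))
        ]

    @classmethod
    def from_color_reads(cls, sample: str, reads: "Sequence[ColorRead]") -> "ReadBatch":
        """Pack equal-length reads of one direction into a batch."""
        if not reads:
            return cls(sample, np.empty((0, 0), np.uint8), np.empty((0, 0), int))
        lengths = {len(r.colors) for r in reads}
        if len(lengths) != 1:
            raise ColorspaceError("a ReadBatch requires equal-length reads")
        lmax = lengths.pop()
        colors = np.empty((len(reads), lmax), dtype=np.uint8)
        quals = np.zeros((len(reads), lmax), dtype=np.int16)
        for i, r in enumerate(reads):
            colors[i] = colors_to_array(r.colors)
            if r.quals:
                quals[i] = r.quals
        return cls(
            sample, colors, quals, reads[0].primer, reads[0].direction
        )


# ---------------------------------------------------------------------------
# csfasta / .qual I/O
# ---------------------------------------------------------------------------

def _fasta_records(path: "str | Path") -> Iterator[tuple[str, str]]:
    """Yield (id, payload) from a csfasta-style file; '#' lines are comments."""
    name = None
    payload: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                if name is not None:
                    yield name, "".join(payload)
                name = line[1:].split()[0]
                payload = []
            else:
                if name is None:
                    raise ColorspaceError(
                        f"{path}:{lineno}: data before first '>' header"
                    )
                payload.append(line)
    if name is not None:
        yield name, "".join(payload)


def read_csfasta(path: "str | Path") -> Iterator[tuple[str, str, str]]:
    """Yield (read_id, primer, colors) records from a csfasta file."""
    for name, payload in _fasta_records(path):
        if not payload or payload[0] not in _CODE:
            raise ColorspaceError(
                f"{path}: read {name}: record must start with a primer base"
            )
        colors = payload[1:]
        if any(c not in "0123" for c in colors):
            raise ColorspaceError(f"{path}: read {name}: malformed color symbol")
        yield name, payload[0], colors


def read_qual(path: "str | Path") -> Iterator[tuple[str, list[int]]]:
    """Yield (read_id, qualities) from a .qual file (space-separated ints)."""
    # .qual payloads contain spaces, so the csfasta reader (which joins
    # continuation lines without a separator) cannot be reused.
    name = None
    payload: list[str] = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith(">"):
                if name is not None:
                    yield name, [int(t) for t in " ".join(payload).split()]
                name = line[1:].split()[0]
                payload = []
            else:
                payload.append(line)
    if name is not None:
        yield name, [int(t) for t in " ".join(payload).split()]


def load_color_reads(
    csfasta_path: "str | Path",
    qual_path: "str | Path | None" = None,
    direction: str = FROM_5P,
) -> list[ColorRead]:
    """Load paired csfasta/.qual files into ColorRead records."""
    quals: dict[str, list[int]] = {}
    if qual_path is not None:
        quals = dict(read_qual(qual_path))
    reads = []
    for read_id, primer, colors in read_csfasta(csfasta_path):
        q = quals.get(read_id, [])
        if q and len(q) != len(colors):
            raise ColorspaceError(
                f"{read_id}: {len(q)} qualities for {len(colors)} colors"
            )
        reads.append(ColorRead(read_id, primer, colors, q, direction))
    return reads


def write_csfasta(reads: Iterable[ColorRead], path: "str | Path") -> None:
    with open(path, "w") as fh:
        fh.write("# csfasta\n")
        for r in reads:
            fh.write(f">{r.read_id}\n{r.primer}{r.colors}\n")


def write_qual(reads: Iterable[ColorRead], path: "str | Path") -> None:
    with open(path, "w") as fh:
        fh.write("# qual\n")
        for r in reads:
            fh.write(f">{r.read_id}\n{' '.join(map(str, r.quals))}\n")
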