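"""Canonical miRNA seed-site scanning in 3'UTRs and target-set enrichment.

Site types follow the canonical definitions: the seed is miRNA bases 2-7
(2-8 including m8), matched by perfect Watson-Crick complementarity on the
UTR sense strand (no G:U wobble); the "anchoring adenosine" is an A in the
target opposite miRNA base 1, regardless of that base's identity.

Reading the UTR 5'->3' a site looks like ``[m8][m7..m2][A1]``:

* 6mer      — complement of bases 2-7;
* 7mer-A1   — 6mer followed by the anchoring A;
* 7mer-m8   — complement of bases 2-8;
* 8mer      — 7mer-m8 followed by the anchoring A.

Each 6mer core occurrence is reported once, at its strongest extension.
Enrichment of predicted targets among regulated genes uses the upper
hypergeometric tail.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom

from .colorspace import NucleotideSeq, reverse_complement

SITE_TYPES = ("6mer", "7mer_A1", "7mer_m8", "8mer")
_STRENGTH = {"8mer": 3, "7mer_m8": 2, "7mer_A1": 1, "6mer": 0}


@dataclass(frozen=True)
class SeedSite:
    """One seed-match site; start/end are 1-based inclusive UTR coordinates."""

    utr_id: str
    mirna_id: str
    site_type: str
    start: int
    end: int
    site_seq: str


def find_seed_sites(
    mirna: "NucleotideSeq | str", utr: "NucleotideSeq | str"
) -> list[SeedSite]:
    """All canonical seed-match sites of one miRNA in one UTR.

    The miRNA may be RNA or DNA (U mapped to T); the UTR is the DNA sense
    strand.  Overlapping extensions of the same core are collapsed to the
    strongest type (8mer > 7mer-m8 > 7mer-A1 > 6mer).
    """
    mir = mirna if isinstance(mirna, NucleotideSeq) else NucleotideSeq(mirna, "miRNA")
    u = utr if isinstance(utr, NucleotideSeq) else NucleotideSeq(utr, "UTR")
    if len(mir) < 8:
        raise ValueError("miRNA must be at least 8 nt to define seed sites")
    seq = u.seq
    core = reverse_complement(mir.seq[1:7])  # complement of bases 2-7
    m8 = reverse_complement(mir.seq[7])  # complement of base 8
    sites: list[SeedSite] = []
    start = 0
    while True:
        i = seq.find(core, start)
        if i < 0:
            break
        start = i + 1
        has_m8 = i >= 1 and seq[i - 1] == m8
        has_a1 = i + 6 < len(seq) and seq[i + 6] == "A"
        if has_m8 and has_a1:
            site_type, s, e = "8mer", i - 1, i + 7
        elif has_m8:
            site_type, s, e = "7mer_m8", i - 1, i + 6
        elif has_a1:
            site_type, s, e = "7mer_A1", i, i + 7
        else:
            site_type, s, e = "6mer", i, i + 6
        sites.append(
            SeedSite(
                utr_id=u.name or "UTR",
                mirna_id=mir.name or "miRNA",
                site_type=site_type,
                start=s + 1,
                end=e,
                site_seq=seq[s:e],
            )
        )
    return sites


def enrichment_test(
    targets: set[str], regulated: set[str], universe: set[str]
) -> tuple[float, float, int]:
    """Hypergeometric over-representation of targets among regulated genes.

    Returns (upper-tail P of the observed overlap or larger, fold
    enrichment observed/expected, observed overlap).
    """
    if not universe:
        raise ValueError("empty gene universe")
    if not targets <= universe:
        raise ValueError("targets must be a subset of the universe")
    if not regulated <= universe:
        raise ValueError("regulated genes must be a subset of the universe")
    n_univ = len(universe)
    n_targ = len(targets)
    n_reg = len(regulated)
    k = len(targets & regulated)
    p = float(hypergeom.sf(k - 1, n_univ, n_targ, n_reg))
    expected = n_targ * n_reg / n_univ
    fold = k / expected if expected > 0 else float("nan")
    return p, float(fold), k
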