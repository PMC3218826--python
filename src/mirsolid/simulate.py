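"""Synthetic reference, ground truth, and SOLiD color-space reads.

The generator emulates the statistical structure of a small-RNA deep
sequencing experiment on differentiating adipose-derived stem cells so the
whole pipeline can be exercised against known truth without any external
database:

* ~150 miRNA precursors with 5p/3p arms and a highly skewed abundance
  distribution — two mature miRNAs dominate (~30% and ~14% of miRNA reads
  at baseline), most others sit below 1%;
* a five-member miRNA family planted up-regulated so its relative
  abundance rises from ~1% of miRNA reads at baseline to ~5% after
  differentiation, plus further planted up- and down-regulated miRNAs
  (21 up / 5 down in total among abundance-passing features);
* a condition-specific novel 3p arm with exactly zero baseline reads, and
  an opposite-strand decoy mature sequence differing at one 3'-terminal
  base, expressed at 1/14 of the novel arm;
* 5'-tRNA fragments, rRNA/snoRNA/transcript degradation windows, piRNAs,
  an intronic un-annotated 21-nt locus, and intergenic background;
* 35-color reads in both sequencing directions (two technical replicates
  per biological replicate), with adapter read-through for short inserts,
  +-1-2 nt isomiR end jitter, and color errors injected at a
  quality-linked rate (error probability 10^(-q/10), capped).

All randomness flows from one master seed through named substreams, so the
reference, the abundances, and each sample's reads are independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .catalog import (
    DEFAULT_HIERARCHY,
    AnnotationCatalog,
    Feature,
    build_color_index,
)
from .colorspace import (
    BASE_TO_CODE,
    FROM_3P,
    FROM_5P,
    ReadBatch,
    reverse_complement,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


@dataclass
class SimulationConfig:
    """Study-scale defaults for the synthetic experiment.

    Abundance fractions are within-category read fractions; category
    budgets mirror the observed class distribution (miRNAs ~43% of mapped
    reads, ~38% non-annotated, a few percent each for tRNA/rRNA/piRNA/
    snoRNA/transcript classes).
    """

    seed: int = 1
    reads_seed: int | None = None  # vary sequencing noise under fixed truth
    conditions: tuple[str, ...] = ("ND", "AD8")
    n_bio_replicates: int = 2
    directions: tuple[str, ...] = (FROM_5P, FROM_3P)
    depth: int = 100_000
    read_len: int = 35
    primer: str = "T"
    adapter: str = "CGCCTTGGCCGTACAGCAGCCTCTT"

    n_mirnas: int = 150
    n_trna: int = 10
    n_rrna: int = 2
    n_snorna: int = 5
    n_pirna: int = 20
    n_other_ncrna: int = 5
    n_mirna_other: int = 5
    n_genes: int = 4

    category_fractions: dict = field(
        default_factory=lambda: {
            "miRNA_human": 0.43,
            "non_annotated": 0.38,
            "transcript": 0.05,
            "tRNA": 0.04,
            "rRNA": 0.03,
            "piRNA": 0.03,
            "snoRNA": 0.02,
            "other_ncRNA": 0.015,
            "miRNA_other_species": 0.005,
        }
    )

    abundance_sigma: float = 1.5  # log-normal spread of unregulated miRNAs
    dominant_fractions: tuple[float, float] = (0.302, 0.138)
    family_size: int = 5
    family_nd_fraction: float = 0.011
    family_lfcs: tuple[float, ...] = (3.05, 2.49, 1.82, 1.41, 2.0)
    up_lfcs: tuple[float, ...] = (
        4.32, 4.24, 2.53, 4.51, 1.46, 2.41, 4.51, 1.98,
        1.25, 3.73, 2.15, 1.53, 1.27, 2.82, 3.14,
    )
    down_nd_cpm: tuple[float, ...] = (1338.0, 13065.0, 367.0, 1718.0, 19329.0)
    down_lfcs: tuple[float, ...] = (-1.48, -1.57, -2.09, -1.3, -1.29)
    novel_arm3p_ad8_fraction: float = 0.00045  # ~450 per million at day 8
    novel_arm5p_ad8_fraction: float = 0.0002  # below the 300-cpm filter
    decoy_ratio: float = 14.0  # novel arm / decoy abundance
    arm_bias: float = 0.85  # dominant arm share for unregulated precursors
    minor_arm_ratio: float = 0.02  # minor/major for designated features

    bio_noise_sd: float = 0.15  # log2 sd per feature x biological replicate
    jitter5: dict = field(
        default_factory=lambda: {0: 0.92, 1: 0.03, -1: 0.03, 2: 0.01, -2: 0.01}
    )
    jitter3: dict = field(
        default_factory=lambda: {0: 0.80, 1: 0.08, -1: 0.08, 2: 0.02, -2: 0.02}
    )

    # linear quality decay along the read; error prob = 10^(-q/10), capped
    q_start: float = 32.0
    q_slope: float = 0.55
    q_noise_sd: float = 2.0
    error_cap: float = 0.25
    flat_quality: float | None = None  # constant quality overrides the decay

    trf_len: int = 20  # 5'-tRNA fragment length
    window_len_range: tuple[int, int] = (17, 30)
    intronic_lfc: float = 1.5
    intronic_fraction: float = 0.06  # of the non-annotated category


@dataclass
class Emitter:
    """One read source: a mature arm, a fragment rule, or a window pool."""

    emitter_id: str
    category: str
    kind: str  # arm | frag5p | window | fixed
    contig: str
    start: int
    end: int
    strand: str
    weights: dict  # condition -> overall read fraction
    lfc: float = 0.0
    feature_id: str | None = None
    arm: str | None = None


@dataclass
class TruthTable:
    """Planted truth: per-feature abundances and per-read origins."""

    emitters: list[Emitter]
    mirna_cpm: pd.DataFrame  # mature miRNA x condition, true cpm
    true_log2fc: pd.Series  # cpm-scale AD-vs-baseline log2 fold change
    planted_up: list[str]
    planted_down: list[str]
    conditions: dict = field(default_factory=dict)  # sample -> condition
    technical_groups: dict = field(default_factory=dict)  # sample -> bio unit
    reads: dict = field(default_factory=dict)  # sample -> per-read DataFrame

    def abundances(self, condition: str) -> pd.Series:
        return pd.Series(
            {e.emitter_id: e.weights[condition] for e in self.emitters}
        )


# ---------------------------------------------------------------------------
# Reference generation
# ---------------------------------------------------------------------------

def generate_reference(
    config: SimulationConfig,
) -> tuple[AnnotationCatalog, TruthTable]:
    """Build the toy genome, its GFF3-style catalog, and feature truth.

    Deterministic for a fixed config seed.  The novel precursor is the
    last miRNA locus; the decoy mature sequence is planted on the opposite
    strand nearby, differing from the novel 3p arm at its final base.
    """
    rng = np.random.default_rng([config.seed, 11])
    features: list[Feature] = []
    arm_rows = []  # feature_id, precursor, arm, start, end, strand

    cursor = 50
    chr1_parts: list[tuple[int, str | None, int]] = []  # start, None=random, len

    def place(length: int) -> int:
        nonlocal cursor
        start = cursor
        cursor += length + 30
        return start

    # miRNA precursors with 5p/3p arms
    n_roles = 3 + config.family_size + len(config.up_lfcs) + len(config.down_lfcs)
    if 0 < config.n_mirnas < n_roles:
        raise ValueError(
            f"n_mirnas must be 0 or >= {n_roles} to fit the planted role layout"
        )
    novel_arm3_span = None
    for i in range(1, config.n_mirnas + 1):
        novel = i == config.n_mirnas
        name = "sim-mir-642a" if novel else f"sim-mir-{i:03d}"
        l5 = int(rng.integers(21, 24))
        l3 = int(rng.integers(21, 24))
        loop = 15
        length = l5 + loop + l3
        start = place(length)
        features.append(
            Feature(name, "miRNA_human", "chr1", start, start + length, "+")
        )
        base = "sim-miR-642a" if novel else f"sim-miR-{i:03d}"
        features.append(
            Feature(f"{base}-5p", "miRNA_human", "chr1", start, start + l5, "+", name)
        )
        features.append(
            Feature(
                f"{base}-3p",
                "miRNA_human",
                "chr1",
                start + length - l3,
                start + length,
                "+",
                name,
            )
        )
        arm_rows.append((f"{base}-5p", name, "5p", start, start + l5))
        arm_rows.append((f"{base}-3p", name, "3p", start + length - l3, start + length))
        if novel:
            novel_arm3_span = (start + length - l3, start + length)
    # opposite-strand decoy adjacent to the novel precursor
    if novel_arm3_span is not None:
        decoy_len = novel_arm3_span[1] - novel_arm3_span[0]
        decoy_start = place(decoy_len)
        features.append(
            Feature(
                "sim-miR-642b-3p", "miRNA_human", "chr1", decoy_start,
                decoy_start + decoy_len, "-",
            )
        )

    simple = [
        ("sim-tRNA", "tRNA", config.n_trna, lambda: 72),
        ("sim-rRNA", "rRNA", config.n_rrna, lambda: 150),
        ("sim-snoRNA", "snoRNA", config.n_snorna, lambda: 80),
        ("sim-piRNA", "piRNA", config.n_pirna, lambda: int(rng.integers(26, 32))),
        ("sim-ncRNA", "other_ncRNA", config.n_other_ncrna, lambda: 60),
        ("sim-xmiR", "miRNA_other_species", config.n_mirna_other, lambda: 22),
    ]
    for prefix, klass, count, length_of in simple:
        for i in range(1, count + 1):
            length = length_of()
            start = place(length)
            features.append(
                Feature(f"{prefix}-{i:02d}", klass, "chr1", start, start + length, "+")
            )
    chr1_len = cursor + 50

    # chr2: transcripts (two exons, unannotated intron) + intergenic tail
    cursor = 50
    intronic_span = None
    for g in range(1, config.n_genes + 1):
        e1 = place(600)
        intron_start = e1 + 600
        cursor = intron_start + 300  # unannotated intron between the exons
        e2 = place(600)
        features.append(
            Feature(f"sim-gene{g}-exon1", "transcript", "chr2", e1, e1 + 600, "+")
        )
        features.append(
            Feature(f"sim-gene{g}-exon2", "transcript", "chr2", e2, e2 + 600, "+")
        )
        if g == 1:
            mid = intron_start + 140
            intronic_span = (mid, mid + 21)
    intergenic_start = cursor + 100
    chr2_len = intergenic_start + 3000

    genome = {
        "chr1": _random_seq(rng, chr1_len),
        "chr2": _random_seq(rng, chr2_len),
    }
    if novel_arm3_span is not None:
        # plant the decoy: reverse strand copy of the novel 3p arm, one
        # 3'-terminal base changed.  The substituted base is chosen not to
        # equal the adapter's first base: otherwise a 3'-shortened isomiR of
        # the twin reads through into the adapter and becomes byte-identical
        # to the decoy, conflating end jitter with the planted species.
        twin = genome["chr1"][novel_arm3_span[0] : novel_arm3_span[1]]
        last = twin[-1]
        new_last = next(
            b for b in "ACGT" if b != last and b != config.adapter[0]
        )
        decoy_seq = twin[:-1] + new_last
        g1 = genome["chr1"]
        genome["chr1"] = (
            g1[:decoy_start]
            + reverse_complement(decoy_seq)
            + g1[decoy_start + decoy_len :]
        )

    catalog = AnnotationCatalog(
        contigs=genome, features=features, hierarchy=list(DEFAULT_HIERARCHY)
    )
    build_color_index(catalog, 8)
    truth = _build_truth(config, catalog, arm_rows, intronic_span, intergenic_start)
    return catalog, truth


def _build_truth(
    config: SimulationConfig,
    catalog: AnnotationCatalog,
    arm_rows: list,
    intronic_span: tuple[int, int],
    intergenic_start: int,
) -> TruthTable:
    rng = np.random.default_rng([config.seed, 12])
    cond_nd = config.conditions[0]
    cond_ad = config.conditions[-1]

    arms = pd.DataFrame(
        arm_rows, columns=["feature_id", "precursor", "arm", "start", "end"]
    )
    n_pre = config.n_mirnas
    pre_ids = arms["precursor"].unique()

    # role layout over precursor indices (0-based): 0-1 dominants, then the
    # family, then extra ups, then downs, last is the novel precursor
    n_fam = config.family_size
    n_up = len(config.up_lfcs)
    n_down = len(config.down_lfcs)
    roles: dict[str, tuple[str, int]] = {}
    for j, p in enumerate(pre_ids):
        if j < 2:
            roles[p] = ("dom", j)
        elif j < 2 + n_fam:
            roles[p] = ("family", j - 2)
        elif j < 2 + n_fam + n_up:
            roles[p] = ("up", j - 2 - n_fam)
        elif j < 2 + n_fam + n_up + n_down:
            roles[p] = ("down", j - 2 - n_fam - n_up)
        elif j == n_pre - 1:
            roles[p] = ("novel", 0)
        else:
            roles[p] = ("regular", 0)

    major_arm = {
        p: ("3p" if rng.random() < 0.5 else "5p") for p in pre_ids
    }
    if n_pre > 0:
        # the condition-specific novel product is the 3p arm
        major_arm[pre_ids[-1]] = "3p"

    w_nd: dict[str, float] = {}
    lfc: dict[str, float] = {}
    w_ad_abs: dict[str, float] = {}  # absolute AD weights (novel/decoy)

    fam_shares = rng.lognormal(0.0, 0.3, n_fam)
    fam_shares /= fam_shares.sum()
    up_nd_cpm = np.exp(rng.uniform(np.log(300.0), np.log(5000.0), n_up))
    up_nd_cpm = np.maximum(up_nd_cpm, 450.0 / 2 ** np.array(config.up_lfcs))
    regular_draw = rng.lognormal(0.0, config.abundance_sigma, n_pre)

    for j, p in enumerate(pre_ids):
        role, idx = roles[p]
        maj, minr = (
            (f"{_arm_id(p, major_arm[p])}"),
            (f"{_arm_id(p, '5p' if major_arm[p] == '3p' else '3p')}"),
        )
        if role == "dom":
            w = config.dominant_fractions[idx]
            w_nd[maj] = w
            w_nd[minr] = w * config.minor_arm_ratio
        elif role == "family":
            w = config.family_nd_fraction * fam_shares[idx]
            w_nd[maj] = w
            w_nd[minr] = w * config.minor_arm_ratio
            lfc[maj] = lfc[minr] = config.family_lfcs[idx]
        elif role == "up":
            w = up_nd_cpm[idx] / 1e6
            w_nd[maj] = w
            w_nd[minr] = w * config.minor_arm_ratio
            lfc[maj] = lfc[minr] = config.up_lfcs[idx]
        elif role == "down":
            w = config.down_nd_cpm[idx] / 1e6
            w_nd[maj] = w
            w_nd[minr] = w * config.minor_arm_ratio
            lfc[maj] = lfc[minr] = config.down_lfcs[idx]
        elif role == "novel":
            w_nd[maj] = 0.0
            w_nd[minr] = 0.0
            w_ad_abs[maj] = config.novel_arm3p_ad8_fraction
            w_ad_abs[minr] = config.novel_arm5p_ad8_fraction
        else:
            w_nd[maj] = regular_draw[j] * config.arm_bias
            w_nd[minr] = regular_draw[j] * (1.0 - config.arm_bias)
    if n_pre > 0:
        w_nd["sim-miR-642b-3p"] = 0.0
        w_ad_abs["sim-miR-642b-3p"] = (
            config.novel_arm3p_ad8_fraction / config.decoy_ratio
        )

    # scale the unregulated bulk so baseline weights sum to one
    pre_of = arms.set_index("feature_id")["precursor"].to_dict() if n_pre else {}
    regular_ids = [
        a for a in w_nd if roles.get(pre_of.get(a, ""), ("x",))[0] == "regular"
    ]
    fixed = sum(w for a, w in w_nd.items() if a not in regular_ids)
    reg_total = sum(w_nd[a] for a in regular_ids)
    if w_nd:
        if reg_total <= 0 or fixed >= 1.0:
            raise ValueError("infeasible abundance configuration")
        scale = (1.0 - fixed) / reg_total
        for a in regular_ids:
            w_nd[a] *= scale

    arm_ids = list(w_nd)
    nd = np.array([w_nd[a] for a in arm_ids])
    ad = np.array(
        [w_ad_abs.get(a, w_nd[a] * 2.0 ** lfc.get(a, 0.0)) for a in arm_ids]
    )
    if arm_ids:
        ad = ad / ad.sum()
    mirna_cpm = pd.DataFrame(
        {cond_nd: nd * 1e6, cond_ad: ad * 1e6}, index=pd.Index(arm_ids, name="feature")
    )
    with np.errstate(divide="ignore"):
        true_lfc = pd.Series(
            np.log2(mirna_cpm[cond_ad] / mirna_cpm[cond_nd]), index=mirna_cpm.index
        )

    planted_up = [a for a in arm_ids if lfc.get(a, 0) > 0 and _is_major(a, major_arm, pre_of)]
    if n_pre > 0:
        planted_up.append(_arm_id(pre_ids[-1], "3p"))
    planted_down = [
        a for a in arm_ids if lfc.get(a, 0) < 0 and _is_major(a, major_arm, pre_of)
    ]

    emitters: list[Emitter] = []
    cat_frac = config.category_fractions
    for a in arm_ids:
        f = catalog.feature(a)
        emitters.append(
            Emitter(
                emitter_id=a,
                category="miRNA_human",
                kind="arm",
                contig=f.contig,
                start=f.start,
                end=f.end,
                strand=f.strand,
                weights={
                    cond_nd: cat_frac["miRNA_human"] * w_nd[a],
                    cond_ad: cat_frac["miRNA_human"] * ad[arm_ids.index(a)],
                },
                lfc=float(true_lfc[a]) if np.isfinite(true_lfc[a]) else np.inf,
                feature_id=a,
                arm=a[-2:],
            )
        )

    def spread(klass: str, ids: list[str], sigma: float, kind: str) -> None:
        w = rng.lognormal(0.0, sigma, len(ids))
        w /= w.sum()
        for fid, wi in zip(ids, w):
            f = catalog.feature(fid)
            emitters.append(
                Emitter(
                    emitter_id=fid,
                    category=klass,
                    kind=kind,
                    contig=f.contig,
                    start=f.start,
                    end=f.end,
                    strand=f.strand,
                    weights={c: cat_frac[klass] * wi for c in (cond_nd, cond_ad)},
                    feature_id=fid,
                )
            )

    by_class: dict[str, list[str]] = {}
    for f in catalog.features:
        if f.rna_class != "miRNA_human" and f.parent is None:
            by_class.setdefault(f.rna_class, []).append(f.feature_id)
    spread("tRNA", by_class["tRNA"], 0.8, "frag5p")
    spread("rRNA", by_class["rRNA"], 0.3, "window")
    spread("snoRNA", by_class["snoRNA"], 1.0, "window")
    spread("piRNA", by_class["piRNA"], 1.0, "arm")
    spread("other_ncRNA", by_class["other_ncRNA"], 1.0, "window")
    spread("miRNA_other_species", by_class["miRNA_other_species"], 1.0, "arm")
    spread("transcript", by_class["transcript"], 0.5, "window")

    # non-annotated mass: an up-regulated intronic locus + intergenic noise,
    # renormalized so the category budget is unchanged across conditions
    na = cat_frac["non_annotated"]
    fi = config.intronic_fraction
    fi_ad = fi * 2.0 ** config.intronic_lfc / (fi * 2.0 ** config.intronic_lfc + 1 - fi)
    emitters.append(
        Emitter(
            emitter_id="sim-intronic-NCOA2like",
            category="non_annotated",
            kind="arm",
            contig="chr2",
            start=intronic_span[0],
            end=intronic_span[1],
            strand="+",
            weights={cond_nd: na * fi, cond_ad: na * fi_ad},
            lfc=config.intronic_lfc,
        )
    )
    emitters.append(
        Emitter(
            emitter_id="sim-intergenic",
            category="non_annotated",
            kind="window",
            contig="chr2",
            start=intergenic_start,
            end=len(catalog.contigs["chr2"]) - 10,
            strand="+",
            weights={cond_nd: na * (1.0 - fi), cond_ad: na * (1.0 - fi_ad)},
        )
    )

    # normalize each condition exactly to 1
    for cond in (cond_nd, cond_ad):
        total = sum(e.weights[cond] for e in emitters)
        for e in emitters:
            e.weights[cond] /= total

    return TruthTable(
        emitters=emitters,
        mirna_cpm=mirna_cpm,
        true_log2fc=true_lfc,
        planted_up=sorted(set(planted_up)),
        planted_down=sorted(set(planted_down)),
    )


def _arm_id(precursor: str, arm: str) -> str:
    return precursor.replace("sim-mir-", "sim-miR-") + f"-{arm}"


def _is_major(arm_id: str, major_arm: dict, pre_of: dict) -> bool:
    p = pre_of.get(arm_id)
    return p is not None and arm_id.endswith(major_arm.get(p, ""))


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def sample_names(config: SimulationConfig) -> list[tuple[str, str, str, str]]:
    """(sample, condition, biological unit, direction) in canonical order."""
    out = []
    for cond in config.conditions:
        for b in range(1, config.n_bio_replicates + 1):
            for d, direction in enumerate(config.directions):
                tag = "F" if direction == FROM_5P else "R"
                out.append((f"{cond}.{b}.{tag}", cond, f"{cond}.{b}", direction))
    return out


def simulate_reads(
    config: SimulationConfig,
    catalog: AnnotationCatalog,
    truth: TruthTable,
) -> dict[str, ReadBatch]:
    """Draw every sample's reads and record per-read truth.

    Reads are drawn multinomially from the condition's emitter weights
    (perturbed per biological replicate by log-normal noise shared between
    the two technical directions), given isomiR end jitter, encoded to
    colors behind the primer, and corrupted by quality-linked color errors.
    """
    samples: dict[str, ReadBatch] = {}
    emitter_w = {
        cond: np.array([e.weights[cond] for e in truth.emitters])
        for cond in config.conditions
    }
    rseed = config.seed if config.reads_seed is None else config.reads_seed
    noise: dict[str, np.ndarray] = {}
    for ci, cond in enumerate(config.conditions):
        for b in range(1, config.n_bio_replicates + 1):
            rng = np.random.default_rng([rseed, 20, ci, b])
            noise[f"{cond}.{b}"] = 2.0 ** (
                config.bio_noise_sd * rng.standard_normal(len(truth.emitters))
            )
    for si, (sample, cond, unit, direction) in enumerate(sample_names(config)):
        rng = np.random.default_rng([rseed, 30, si])
        p = emitter_w[cond] * noise[unit]
        p = p / p.sum()
        counts = rng.multinomial(config.depth, p)
        batch, reads_df = _simulate_sample(
            config, catalog, truth, sample, direction, counts, rng
        )
        samples[sample] = batch
        truth.reads[sample] = reads_df
        truth.conditions[sample] = cond
        truth.technical_groups[sample] = unit
    return samples


def _emitter_insert(
    e: Emitter, genome: str, j5: int, j3: int, config: SimulationConfig
) -> str:
    """Insert sequence (5'->3' of the small RNA) for jitter offsets.

    Positive j5/j3 extend the 5'/3' end into flanking sequence; negative
    values trim.
    """
    if e.kind == "frag5p":
        if e.strand == "+":
            s = max(0, e.start - j5)
            t = min(len(genome), e.start + config.trf_len + j3)
            return genome[s:t]
        s = max(0, e.end - config.trf_len - j3)
        t = min(len(genome), e.end + j5)
        return reverse_complement(genome[s:t])
    # arm / fixed: the whole feature with end jitter
    if e.strand == "+":
        s = max(0, e.start - j5)
        t = min(len(genome), e.end + j3)
        return genome[s:t]
    s = max(0, e.start - j3)
    t = min(len(genome), e.end + j5)
    return reverse_complement(genome[s:t])


def _simulate_sample(
    config: SimulationConfig,
    catalog: AnnotationCatalog,
    truth: TruthTable,
    sample: str,
    direction: str,
    counts: np.ndarray,
    rng: np.random.Generator,
) -> tuple[ReadBatch, pd.DataFrame]:
    rl = config.read_len
    j5_vals = np.array(list(config.jitter5))
    j5_p = np.array([config.jitter5[v] for v in j5_vals], dtype=float)
    j5_p /= j5_p.sum()
    j3_vals = np.array(list(config.jitter3))
    j3_p = np.array([config.jitter3[v] for v in j3_vals], dtype=float)
    j3_p /= j3_p.sum()

    tmpl_strs: list[str] = []
    tmpl_counts: list[int] = []
    tmpl_emit: list[int] = []
    tmpl_j5: list[int] = []
    tmpl_j3: list[int] = []
    wmin, wmax = config.window_len_range
    for ei, (e, n) in enumerate(zip(truth.emitters, counts)):
        if n == 0:
            continue
        genome = catalog.contigs[e.contig]
        if e.kind in ("arm", "fixed", "frag5p"):
            j5 = rng.choice(j5_vals, n, p=j5_p)
            j3 = rng.choice(j3_vals, n, p=j3_p)
            combos, combo_counts = np.unique(
                (j5 + 2) * 8 + (j3 + 2), return_counts=True
            )
            for combo, cn in zip(combos, combo_counts):
                a, b = divmod(int(combo), 8)
                ja, jb = a - 2, b - 2
                ins = _emitter_insert(e, genome, ja, jb, config)
                tmpl_strs.append(ins)
                tmpl_counts.append(int(cn))
                tmpl_emit.append(ei)
                tmpl_j5.append(ja)
                tmpl_j3.append(jb)
        else:  # window: independent start/length per read
            span = e.end - e.start
            lens = rng.integers(wmin, min(wmax, span) + 1, n)
            starts = e.start + rng.integers(0, np.maximum(span - lens + 1, 1))
            for s, ln in zip(starts, lens):
                tmpl_strs.append(genome[int(s) : int(s) + int(ln)])
                tmpl_counts.append(1)
                tmpl_emit.append(ei)
                tmpl_j5.append(0)
                tmpl_j3.append(0)

    if not tmpl_strs:
        empty = np.empty((0, rl), dtype=np.uint8)
        return (
            ReadBatch(sample, empty, empty.copy(), config.primer, direction),
            pd.DataFrame(columns=["emitter", "n_errors", "off5", "off3"]),
        )

    # assemble primer+35 base strings, encode all templates at once
    pieces = []
    for ins in tmpl_strs:
        s = (reverse_complement(ins) if direction == FROM_3P else ins) + config.adapter
        while len(s) < rl:  # degenerate very short inserts
            s += config.adapter
        pieces.append(config.primer + s[:rl])
    joined = "".join(pieces)
    buf = np.frombuffer(joined.encode(), dtype=np.uint8).reshape(len(pieces), rl + 1)
    codes = BASE_TO_CODE[buf]
    tmpl_colors = (codes[:, :-1] ^ codes[:, 1:]).astype(np.uint8)

    counts_arr = np.array(tmpl_counts)
    colors = np.repeat(tmpl_colors, counts_arr, axis=0)
    emit_idx = np.repeat(np.array(tmpl_emit), counts_arr)
    off5 = np.repeat(np.array(tmpl_j5), counts_arr)
    off3 = np.repeat(np.array(tmpl_j3), counts_arr)
    n_reads = colors.shape[0]

    # qualities and quality-linked color errors
    if config.flat_quality is not None:
        quals = np.full((n_reads, rl), config.flat_quality, dtype=float)
    else:
        quals = (
            config.q_start
            - config.q_slope * np.arange(rl)
            + config.q_noise_sd * rng.standard_normal((n_reads, rl))
        )
    quals = np.clip(np.rint(quals), 2, 40).astype(np.int16)
    err_p = np.minimum(10.0 ** (-quals / 10.0), config.error_cap)
    mask = rng.random((n_reads, rl)) < err_p
    delta = rng.integers(1, 4, (n_reads, rl), dtype=np.uint8)
    colors = np.where(mask, (colors + delta) % 4, colors)

    perm = rng.permutation(n_reads)
    colors = colors[perm]
    quals = quals[perm]
    reads_df = pd.DataFrame(
        {
            "emitter": np.array([truth.emitters[i].emitter_id for i in emit_idx])[
                perm
            ],
            "n_errors": mask.sum(axis=1)[perm],
            "off5": off5[perm],
            "off3": off3[perm],
        }
    )
    batch = ReadBatch(sample, colors, quals, config.primer, direction)
    return batch, reads_df


def default_study_scenario(seed: int = 1) -> SimulationConfig:
    """The bundled study-scale scenario (all defaults, given seed)."""
    return SimulationConfig(seed=seed)


def simulate_study(
    config: SimulationConfig,
) -> tuple[AnnotationCatalog, TruthTable, dict[str, ReadBatch]]:
    """Reference + truth + all samples' reads in one call."""
    catalog, truth = generate_reference(config)
    samples = simulate_reads(config, catalog, truth)
    return catalog, truth, samples


# ---------------------------------------------------------------------------
# Plain-text export
# ---------------------------------------------------------------------------

def write_reference(
    catalog: AnnotationCatalog, fasta_path: "str | Path", gff3_path: "str | Path"
) -> None:
    """Write the genome FASTA and the rna_class-tagged GFF3."""
    with open(fasta_path, "w") as fh:
        for name, seq in catalog.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    type_of = {
        "miRNA_human": "miRNA",
        "miRNA_other_species": "miRNA",
        "transcript": "exon",
        "piRNA": "piRNA",
        "tRNA": "tRNA",
        "rRNA": "rRNA",
        "snoRNA": "snoRNA",
        "other_ncRNA": "ncRNA",
    }
    with open(gff3_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in catalog.features:
            ftype = (
                "miRNA_primary_transcript"
                if f.parent is None and f.rna_class == "miRNA_human" and
                any(c.parent == f.feature_id for c in catalog.features)
                else type_of[f.rna_class]
            )
            attrs = f"ID={f.feature_id};rna_class={f.rna_class}"
            if f.parent:
                attrs += f";Parent={f.parent}"
            fh.write(
                f"{f.contig}\tmirsolid_sim\t{ftype}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t.\t{attrs}\n"
            )


def write_sample(
    batch: ReadBatch, csfasta_path: "str | Path", qual_path: "str | Path"
) -> None:
    """Write one sample's reads as csfasta + .qual."""
    ids = batch.read_ids()
    with open(csfasta_path, "w") as fh:
        fh.write(f"# simulated sample {batch.sample} ({batch.direction})\n")
        for i in range(len(batch)):
            row = (batch.colors[i] + ord("0")).astype(np.uint8).tobytes().decode()
            fh.write(f">{ids[i]}\n{batch.primer}{row}\n")
    with open(qual_path, "w") as fh:
        fh.write(f"# simulated sample {batch.sample} qualities\n")
        for i in range(len(batch)):
            fh.write(f">{ids[i]}\n{' '.join(map(str, batch.quals[i]))}\n")


def write_truth(truth: TruthTable, path: "str | Path") -> None:
    """Feature-level truth as TSV (cpm per condition, true log2 fold change)."""
    df = truth.mirna_cpm.copy()
    df["true_log2fc"] = truth.true_log2fc
    df["planted_up"] = df.index.isin(truth.planted_up)
    df["planted_down"] = df.index.isin(truth.planted_down)
    df.to_csv(path, sep="\t")
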