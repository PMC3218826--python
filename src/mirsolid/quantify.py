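"""miRNA count matrices, per-million normalization, abundance summaries,
pre-miR coverage/arm profiles, and the qPCR comparative-CT utility.

Counts are integer reads per mature miRNA per sample; normalized values are
reads per 10^6 miRNA reads within the sample (so each sample's normalized
column sums to exactly 10^6 when it has any miRNA reads).  Relative
abundance of a feature set is its share of the sample's miRNA reads, as a
percentage; condition-level values average the per-sample percentages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import AnnotationCatalog

MIRNA_CLASS = "miRNA_human"
NORM_TOTAL = 1_000_000.0


@dataclass
class CountMatrix:
    """Raw and normalized mature-miRNA counts with condition labels."""

    raw: pd.DataFrame  # features x samples, integer counts
    normalized: pd.DataFrame  # features x samples, per-10^6-miRNA-reads
    conditions: dict[str, str]  # sample -> condition

    @property
    def features(self) -> pd.Index:
        return self.raw.index

    @property
    def samples(self) -> pd.Index:
        return self.raw.columns

    def condition_samples(self, condition: str) -> list[str]:
        return [s for s in self.samples if self.conditions.get(s) == condition]


@dataclass
class PremirProfile:
    """Per-base read coverage of a precursor and its 5p/3p arm usage."""

    precursor_id: str
    coverage: pd.DataFrame  # positions x samples
    arm5p_count: pd.Series
    arm3p_count: pd.Series
    arm3p_fraction: pd.Series


def count_features(
    assignments: pd.DataFrame,
    catalog: AnnotationCatalog,
    conditions: "dict[str, str] | None" = None,
    mirna_class: str = MIRNA_CLASS,
) -> CountMatrix:
    """Raw counts: reads assigned to each mature human miRNA, per sample.

    Every mature (leaf) miRNA feature keeps a row even with zero reads.
    """
    mirna_features = [
        f.feature_id for f in catalog.leaf_features() if f.rna_class == mirna_class
    ]
    samples = sorted(assignments["sample"].unique())
    sub = assignments[assignments["category"] == mirna_class]
    raw = (
        sub.groupby(["feature_id", "sample"])
        .size()
        .unstack(fill_value=0)
        .reindex(index=mirna_features, columns=samples, fill_value=0)
        .astype(int)
    )
    raw.index.name = "feature"
    cm = CountMatrix(raw=raw, normalized=raw.astype(float) * np.nan,
                     conditions=dict(conditions or {}))
    return normalize_cpm(cm)


def normalize_cpm(counts: CountMatrix) -> CountMatrix:
    """Scale each sample to 10^6 total miRNA reads.

    Samples with zero miRNA reads get missing (NaN) normalized values.
    """
    raw = counts.raw
    totals = raw.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = raw.div(totals, axis=1) * NORM_TOTAL
    norm[raw.columns[totals == 0]] = np.nan
    return CountMatrix(raw=raw, normalized=norm, conditions=counts.conditions)


def relative_abundance(
    counts: CountMatrix,
    feature_set: "list[str] | set[str]",
    by_condition: bool = False,
) -> pd.Series:
    """Percentage of total miRNA reads carried by a feature set.

    Per sample by default; with ``by_condition`` the per-sample percentages
    are averaged within each condition (condition-level abundances are
    averages of per-sample shares, not pooled counts).
    """
    feats = [f for f in feature_set if f in counts.normalized.index]
    per_sample = counts.normalized.loc[feats].sum(axis=0) / NORM_TOTAL * 100.0
    if not feats:
        per_sample = pd.Series(0.0, index=counts.normalized.columns)
    if not by_condition:
        return per_sample
    cond = pd.Series({s: counts.conditions.get(s, "?") for s in per_sample.index})
    return per_sample.groupby(cond).mean()


def premir_profile(
    assignments: pd.DataFrame,
    catalog: AnnotationCatalog,
    precursor_id: str,
) -> PremirProfile:
    """Coverage along a precursor and the 5p/3p arm split.

    Coverage[i] counts reads whose best hit overlaps base i of the
    precursor (5'->3' in precursor orientation).  Arm counts are reads
    whose hit overlaps the mature 5p (resp. 3p) child by at least half the
    read length.
    """
    pre = catalog.feature(precursor_id)
    children = catalog.children(precursor_id)
    arm5 = next((c for c in children if c.feature_id.endswith("5p")), None)
    arm3 = next((c for c in children if c.feature_id.endswith("3p")), None)
    if arm5 is None and arm3 is None and children:
        # fall back on coordinate order: 5p arm is nearer the precursor 5' end
        ordered = sorted(children, key=lambda f: f.start)
        if pre.strand == "-":
            ordered = ordered[::-1]
        arm5 = ordered[0]
        arm3 = ordered[-1] if len(ordered) > 1 else None

    sub = assignments.dropna(subset=["start"])
    sub = sub[
        (sub["contig"] == pre.contig)
        & (sub["strand"] == pre.strand)
        & (sub["end"].astype(int) > pre.start)
        & (sub["start"].astype(int) < pre.end)
    ]
    samples = sorted(assignments["sample"].unique())
    length = len(pre)
    cov = pd.DataFrame(0, index=pd.RangeIndex(length, name="position"), columns=samples)
    a5 = pd.Series(0, index=samples, dtype=int)
    a3 = pd.Series(0, index=samples, dtype=int)
    for row in sub.itertuples(index=False):
        s = max(int(row.start), pre.start) - pre.start
        e = min(int(row.end), pre.end) - pre.start
        if pre.strand == "-":
            s, e = length - e, length - s
        if e <= s:
            continue
        cov.loc[s : e - 1, row.sample] += 1
        rlen = int(row.end) - int(row.start)
        for arm, acc in ((arm5, a5), (arm3, a3)):
            if arm is None:
                continue
            ov = min(arm.end, int(row.end)) - max(arm.start, int(row.start))
            if ov * 2 >= rlen:
                acc[row.sample] += 1
    total = a5 + a3
    with np.errstate(invalid="ignore"):
        frac = a3 / total.replace(0, np.nan)
    return PremirProfile(
        precursor_id=precursor_id,
        coverage=cov,
        arm5p_count=a5,
        arm3p_count=a3,
        arm3p_fraction=frac,
    )


def comparative_ct(ct_target: float, ct_refs: "list[float]") -> float:
    """qPCR comparative-CT normalized expression, 2^-(deltaCT).

    deltaCT = CT(target) - mean(CT of reference genes); the log2 fold
    change between two samples is -(deltaCT_a - deltaCT_b).
    """
    if not ct_refs:
        raise ValueError("at least one reference CT value is required")
    if not np.all(np.isfinite([ct_target, *ct_refs])):
        raise ValueError("CT values must be finite")
    delta = ct_target - float(np.mean(ct_refs))
    return float(2.0 ** (-delta))
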