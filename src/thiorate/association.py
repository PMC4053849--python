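"""Associating transcription-rate Q10 with gene features.

Three kinds of evidence link the temperature response of transcription
to gene regulation: the frequency of binary gene features (chromatin
marks, promoter motif presence, mutant-response membership) across Q10
bins; rank tests comparing Q10 between gene groups; and rank
correlations of rates against numeric transcript features (length, GC/U
content, intron count).

Motif presence is scanned in upstream promoter sequences with IUPAC
degenerate patterns, optionally on both strands.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq
from scipy import stats

from thiorate.core_model import (
    ANNOTATION_FEATURES,
    GeneSetCollection,
    ValidationError,
)
from thiorate.kinetics import GeneKinetics
from thiorate.thermal_response import ThermalProfile

#: Default Q10 bin edges: eight unit-width bins over (0, 8).
DEFAULT_Q10_BINS = tuple(float(x) for x in range(0, 9))

#: Default promoter motif consensi (IUPAC), overridable in config.
DEFAULT_MOTIFS = {
    "G_box": "CACGTG",
    "evening_element": "AAATATCT",
    "morning_element": "CCACAC",
    "ABRE": "ACGTGKC",
    "HSE_tail": "TTCNNGAA",
    "HSE_head": "GAANNTTC",
    "CArG_box": "CCWWWWWWGG",
}


@dataclass
class Q10BinTable:
    """Feature frequencies across half-open Q10 bins [lo, hi).

    ``counts``: genes per bin; ``percent``: DataFrame (bin x feature) of
    100 * |bin & feature| / |bin|, NaN for empty bins; ``n_out_of_range``:
    genes whose Q10 falls outside [first, last).
    """

    bin_edges: tuple[float, ...]
    counts: pd.Series
    percent: pd.DataFrame
    n_out_of_range: int

    @property
    def labels(self) -> list[str]:
        return list(self.counts.index)

    def to_tsv(self, path: str | Path) -> None:
        out = self.percent.copy()
        out.insert(0, "n_genes", self.counts)
        out.to_csv(path, sep="\t", index_label="q10_bin")


@dataclass(frozen=True)
class GroupComparison:
    """Two-group rank comparison (Mann-Whitney U, two-sided)."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    u_statistic: float
    p_value: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValidationError("p_value must be in (0, 1]")
        if not 0 <= self.u_statistic <= self.n_a * self.n_b:
            raise ValidationError("U statistic out of range")


def bin_feature_frequency(
    profiles: list[ThermalProfile],
    features: GeneSetCollection | Mapping[str, Iterable[str]],
    bin_edges: Iterable[float] = DEFAULT_Q10_BINS,
    *,
    value: str = "q10_syn",
) -> Q10BinTable:
    """Percentage of genes carrying each feature, per Q10 bin.

    Bins are half-open [lo, hi); genes with Q10 outside the binned range
    (or undefined) are excluded from every bin and counted in
    ``n_out_of_range``.  ``value`` selects q10_syn (default) or q10_dec.
    """
    edges = [float(e) for e in bin_edges]
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValidationError("bin edges must be strictly increasing, length >= 2")
    if not features:
        raise ValidationError("need at least one feature set")
    if value not in ("q10_syn", "q10_dec"):
        raise ValidationError(f"unknown Q10 field {value!r}")

    q = np.array([getattr(p, value) for p in profiles], dtype=float)
    genes = np.array([p.gene_id for p in profiles])
    in_range = np.isfinite(q) & (q >= edges[0]) & (q < edges[-1])
    n_out = int((~in_range).sum())
    # right=False gives half-open [lo, hi) bins
    bin_idx = np.digitize(q[in_range], edges, right=False) - 1
    genes_in = genes[in_range]

    labels = [f"[{lo:g},{hi:g})" for lo, hi in zip(edges, edges[1:])]
    counts = pd.Series(0, index=labels, dtype=int, name="n_genes")
    percent = pd.DataFrame(np.nan, index=labels, columns=sorted(features))
    for b, label in enumerate(labels):
        members = set(genes_in[bin_idx == b])
        counts[label] = len(members)
        if not members:
            continue
        for name in percent.columns:
            fset = set(features[name])
            percent.loc[label, name] = 100.0 * len(members & fset) / len(members)
    return Q10BinTable(
        bin_edges=tuple(edges), counts=counts, percent=percent, n_out_of_range=n_out
    )


def _mannwhitney(
    a: np.ndarray, b: np.ndarray, name_a: str, name_b: str
) -> GroupComparison:
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size * b.size <= 10_000 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return GroupComparison(
        group_a=name_a,
        group_b=name_b,
        n_a=int(a.size),
        n_b=int(b.size),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        u_statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
    )


def compare_groups(
    profiles: list[ThermalProfile],
    set_a: Iterable[str],
    set_b: Iterable[str],
    value: str = "q10_syn",
    *,
    name_a: str = "A",
    name_b: str = "B",
) -> GroupComparison:
    """Compare a Q10 field between two gene groups (Mann-Whitney U).

    The test is exact (distribution enumeration) when the product of
    group sizes is at most 10,000 and there are no ties, otherwise the
    tie-corrected normal approximation is used.
    """
    if value not in ("q10_syn", "q10_dec"):
        raise ValidationError(f"unknown Q10 field {value!r}")
    by_gene = {p.gene_id: getattr(p, value) for p in profiles}
    a = np.array(
        [by_gene[g] for g in set_a if g in by_gene and np.isfinite(by_gene[g])]
    )
    b = np.array(
        [by_gene[g] for g in set_b if g in by_gene and np.isfinite(by_gene[g])]
    )
    if a.size == 0 or b.size == 0:
        raise ValidationError("a group is empty after intersecting with profiles")
    return _mannwhitney(a, b, name_a, name_b)


#: The standard IUPAC nucleotide alphabet (DNA).
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN")


def iupac_regex(motif: str) -> str:
    """Expand an IUPAC degenerate DNA pattern to a regex."""
    parts = []
    for ch in motif.upper():
        if ch not in IUPAC_CODES:
            raise ValidationError(f"invalid IUPAC code {ch!r} in motif {motif!r}")
        bases = ambiguous_dna_values[ch]
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def scan_promoter_motif(
    promoters: str | Path | Mapping[str, str],
    motif: str,
    both_strands: bool = True,
) -> frozenset[str]:
    """Genes whose upstream sequence contains the motif.

    ``promoters`` is a FASTA path (record id = gene_id) or a mapping
    gene_id -> sequence.  Sequences must be A/C/G/T/N.  With
    ``both_strands`` a match on the reverse complement also counts.
    """
    pattern = re.compile(iupac_regex(motif))
    if isinstance(promoters, (str, Path)):
        records = {r.id: str(r.seq) for r in SeqIO.parse(str(promoters), "fasta")}
    else:
        records = {k: str(v) for k, v in promoters.items()}
    hits = set()
    for gene, seq in records.items():
        seq = seq.upper()
        if re.search(r"[^ACGTN]", seq):
            bad = re.search(r"[^ACGTN]", seq).group()
            raise ValidationError(
                f"promoter {gene!r} contains non-ACGTN character {bad!r}"
            )
        if pattern.search(seq):
            hits.add(gene)
        elif both_strands and pattern.search(str(Seq(seq).reverse_complement())):
            hits.add(gene)
    return frozenset(hits)


def scan_motif_collection(
    promoters: str | Path | Mapping[str, str],
    motifs: Mapping[str, str] | None = None,
    both_strands: bool = True,
) -> GeneSetCollection:
    """Scan several named motifs; returns one gene set per motif."""
    out = GeneSetCollection()
    for name, motif in (motifs or DEFAULT_MOTIFS).items():
        out[name] = scan_promoter_motif(promoters, motif, both_strands)
    return out


def rate_feature_correlation(
    kin: list[GeneKinetics], annotation: pd.DataFrame
) -> pd.DataFrame:
    """Spearman correlation of rates against numeric transcript features.

    For each of half_life and syn_rate against each annotation column
    (cDNA/UTR lengths, GC and U content, intron count), computed over
    genes with the rate defined and the feature present.  Constant
    features yield NaN rho with p = NaN.
    """
    rates = pd.DataFrame(
        {
            "half_life": {k.gene_id: k.half_life for k in kin},
            "syn_rate": {k.gene_id: k.syn_rate for k in kin},
        }
    )
    rows = []
    for feature in ANNOTATION_FEATURES:
        if feature not in annotation.columns:
            continue
        feat = annotation[feature]
        for rate_type in ("half_life", "syn_rate"):
            joined = pd.concat([rates[rate_type], feat], axis=1, join="inner").dropna()
            n = len(joined)
            if n < 10:
                raise ValidationError(
                    f"need >= 10 genes with both {rate_type} and {feature}, have {n}"
                )
            if joined[feature].nunique() < 2 or joined[rate_type].nunique() < 2:
                rho, p = float("nan"), float("nan")
            else:
                rho, p = stats.spearmanr(joined[rate_type], joined[feature])
            rows.append(
                {
                    "feature": feature,
                    "rate_type": rate_type,
                    "spearman_rho": float(rho),
                    "p_value": float(p),
                    "n": n,
                }
            )
    return pd.DataFrame(rows)


def intronless_halflife_split(
    kin: list[GeneKinetics],
    annotation: pd.DataFrame,
    bin_edges: Iterable[float] = (0.0, 1.0, 2.0, 4.0, 8.0, np.inf),
) -> tuple[pd.DataFrame, GroupComparison]:
    """Half-life distributions of intronless versus intron-containing genes.

    Returns a histogram table (bin x {intronless, with_introns} counts)
    and a Mann-Whitney comparison of the two half-life samples.
    """
    if "intron_count" not in annotation.columns:
        raise ValidationError("annotation lacks intron_count")
    edges = np.array(list(bin_edges), dtype=float)
    t12 = pd.Series({k.gene_id: k.half_life for k in kin}).dropna()
    joined = pd.concat(
        [t12.rename("half_life"), annotation["intron_count"]], axis=1, join="inner"
    ).dropna()
    intronless = joined.loc[joined["intron_count"] == 0, "half_life"].to_numpy()
    with_introns = joined.loc[joined["intron_count"] > 0, "half_life"].to_numpy()
    if intronless.size == 0 or with_introns.size == 0:
        raise ValidationError("degenerate partition: one intron class is empty")
    labels = [f"[{lo:g},{hi:g})" for lo, hi in zip(edges, edges[1:])]
    hist = pd.DataFrame(
        {
            "intronless": np.histogram(intronless, bins=edges)[0],
            "with_introns": np.histogram(with_introns, bins=edges)[0],
        },
        index=labels,
    )
    cmp = _mannwhitney(intronless, with_introns, "intronless", "with_introns")
    return hist, cmp
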