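"""Temperature coefficients and temperature-responsive gene classes.

The temperature coefficient Q10 of a rate is the factor by which it
changes over a 10 degree interval,

    Q10 = (rate_warm / rate_cool) ** (10 / delta_T),

computed per gene for both the synthesis rate alpha and the decay
constant lambda (equivalently t1/2_cool / t1/2_warm).  Passive Arrhenius
chemistry predicts Q10 of 2-3; transcripts that deviate are candidates
for active temperature regulation.

Differential abundance between temperatures is scored with a moderated
d-statistic in the style of significance analysis of microarrays (SAM):
a two-sample difference on log2 intensities, damped by a
variance-stabilizing offset s0, with the false discovery rate estimated
by label permutation.  Genes are then classified by abundance
fold-change: warm genes (WG, at least two-fold higher at the warmer
temperature), cool genes (CG, at least two-fold lower) and unchanged
genes (UG); a parallel 1.5-fold-and-significant call gives the
up/down/unchanged split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

from thiorate.core_model import ExpressionSet, TOTAL_FRACTIONS, ValidationError
from thiorate.kinetics import GeneKinetics


def q10(rate_warm: float, rate_cool: float, delta_T: float = 10.0) -> float:
    """Temperature coefficient of a rate, normalized to 10 degrees.

    Returns NaN when either rate is non-positive (undefined for that
    gene).
    """
    if delta_T <= 0:
        raise ValidationError("delta_T must be positive")
    if not (rate_warm > 0 and rate_cool > 0):
        return float("nan")
    return (rate_warm / rate_cool) ** (10.0 / delta_T)


@dataclass(frozen=True)
class SamResult:
    """Moderated-statistic outcome for one gene."""

    gene_id: str
    d_stat: float
    fold_change: float  # warm / cool abundance ratio (geometric-mean based)
    significant: bool
    delta_used: float
    estimated_fdr: float


@dataclass(frozen=True)
class ThermalProfile:
    """Per-gene two-temperature summary."""

    gene_id: str
    q10_syn: float
    q10_dec: float
    fold_change: float
    sig_flag: bool
    change_class: str  # WG / UG / CG, by fold alone
    change_class_1p5: str  # up / down / unchanged, fold AND significance

    def __post_init__(self) -> None:
        if self.change_class not in ("WG", "UG", "CG"):
            raise ValidationError(f"bad change_class {self.change_class!r}")
        if self.change_class_1p5 not in ("up", "down", "unchanged"):
            raise ValidationError(f"bad change_class_1p5 {self.change_class_1p5!r}")


def _total_columns(es: ExpressionSet, temperature: float) -> np.ndarray:
    ids = [
        s.sample_id
        for s in es.samples
        if s.temperature == temperature and s.fraction in TOTAL_FRACTIONS
    ]
    if len(ids) < 2:
        raise ValidationError(
            f"need at least 2 total-RNA samples at {temperature} degrees C"
        )
    return es.values[ids].to_numpy(dtype=float)


def _d_stats(
    log_warm: np.ndarray, log_cool: np.ndarray, s0: float
) -> tuple[np.ndarray, np.ndarray]:
    """Moderated d and pooled standard error s per gene (rows)."""
    n1, n2 = log_warm.shape[1], log_cool.shape[1]
    diff = log_warm.mean(axis=1) - log_cool.mean(axis=1)
    sse = ((log_warm - log_warm.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (log_cool - log_cool.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * sse / (n1 + n2 - 2))
    denom = s + s0
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    return d, s


def _choose_s0(log_warm: np.ndarray, log_cool: np.ndarray) -> float:
    """Pick s0 among percentiles of {s_i} that flattens |d| dispersion.

    For each candidate (percentiles 0, 5, ..., 100 of the per-gene
    standard errors) the genes are split into quintiles of s and the
    candidate minimizing the coefficient of variation of the quintile
    spreads of d is kept.
    """
    _, s = _d_stats(log_warm, log_cool, 0.0)
    candidates = np.percentile(s, np.arange(0, 101, 5))
    order = np.argsort(s, kind="stable")
    bins = np.array_split(order, 5)
    best_s0, best_cv = candidates[0], np.inf
    for s0 in candidates:
        d, _ = _d_stats(log_warm, log_cool, float(s0))
        spreads = []
        for idx in bins:
            if idx.size == 0:
                continue
            med = np.median(d[idx])
            spreads.append(np.median(np.abs(d[idx] - med)))
        spreads = np.asarray(spreads)
        if spreads.size == 0 or spreads.mean() == 0:
            continue
        cv = spreads.std() / spreads.mean()
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return float(best_s0)


def abundance_fold_change(
    es: ExpressionSet, temp_warm: float, temp_cool: float
) -> pd.Series:
    """Per-gene warm/cool ratio of geometric-mean total-RNA abundance.

    Uses every total-RNA sample (both timepoints, all replicates) at
    each temperature; genes with a non-positive intensity in any total
    sample get NaN.
    """
    warm = _total_columns(es, temp_warm)
    cool = _total_columns(es, temp_cool)
    with np.errstate(divide="ignore", invalid="ignore"):
        lw = np.where(warm > 0, np.log2(np.where(warm > 0, warm, 1.0)), np.nan)
        lc = np.where(cool > 0, np.log2(np.where(cool > 0, cool, 1.0)), np.nan)
    fold = np.power(2.0, lw.mean(axis=1) - lc.mean(axis=1))
    return pd.Series(fold, index=es.values.index)


def sam_test(
    es: ExpressionSet,
    temp_warm: float,
    temp_cool: float,
    *,
    n_perm: int = 500,
    target_fdr: float = 0.01,
    seed: int = 0,
    log_offset: float = 8.0,
) -> list[SamResult]:
    """Permutation-FDR differential abundance between two temperatures.

    The statistic is d = (mean_warm - mean_cool) / (s + s0) on
    log2(intensity + ``log_offset``) over all total-RNA samples, with s
    the pooled standard error and s0 a percentile of the s distribution
    chosen to decouple d from s.  Null d values come from relabeling the
    samples (all distinct balanced relabelings when there are at most
    ``n_perm`` of them, otherwise ``n_perm`` drawn with ``seed``).  The
    significance threshold is the smallest cut Delta whose estimated
    FDR — median permuted exceedance count over observed exceedance
    count — is at or below ``target_fdr``; genes with |d| beyond Delta
    are flagged.
    """
    if not 0.0 < target_fdr <= 1.0:
        raise ValidationError("target_fdr must be in (0, 1]")
    if n_perm < 25:
        raise ValidationError("need n_perm >= 25")
    warm = _total_columns(es, temp_warm)
    cool = _total_columns(es, temp_cool)
    if warm.shape[1] < 2 or cool.shape[1] < 2:
        raise ValidationError("need at least 2 replicates per group")
    data = np.log2(np.concatenate([warm, cool], axis=1) + log_offset)
    n1 = warm.shape[1]
    n_cols = data.shape[1]

    s0 = _choose_s0(data[:, :n1], data[:, n1:])
    d_obs, _ = _d_stats(data[:, :n1], data[:, n1:], s0)

    all_perms = list(combinations(range(n_cols), n1))
    rng = np.random.default_rng(seed)
    if len(all_perms) > n_perm:
        pick = rng.choice(len(all_perms), size=n_perm, replace=False)
        perms = [all_perms[i] for i in pick]
    else:
        perms = all_perms

    null_abs = np.empty((len(perms), data.shape[0]))
    for i, grp in enumerate(perms):
        grp = list(grp)
        rest = [j for j in range(n_cols) if j not in set(grp)]
        d_null, _ = _d_stats(data[:, grp], data[:, rest], s0)
        null_abs[i] = np.abs(d_null)

    abs_obs = np.abs(d_obs)
    # scan candidate thresholds from small to large; exceedance is strict
    candidates = np.unique(abs_obs)
    obs_sorted = np.sort(abs_obs)
    null_sorted = np.sort(null_abs, axis=1)
    delta_used = math.inf
    fdr_at_delta = 0.0
    for cut in candidates:
        n_obs = obs_sorted.size - np.searchsorted(obs_sorted, cut, side="right")
        if n_obs == 0:
            break
        per_perm = np.array(
            [row.size - np.searchsorted(row, cut, side="right") for row in null_sorted]
        )
        fdr = float(np.median(per_perm)) / n_obs
        if fdr <= target_fdr:
            delta_used = float(cut)
            fdr_at_delta = fdr
            break

    fold = abundance_fold_change(es, temp_warm, temp_cool)
    significant = abs_obs > delta_used if math.isfinite(delta_used) else np.zeros(
        abs_obs.size, dtype=bool
    )
    return [
        SamResult(
            gene_id=g,
            d_stat=float(d_obs[i]),
            fold_change=float(fold.iloc[i]),
            significant=bool(significant[i]),
            delta_used=delta_used,
            estimated_fdr=fdr_at_delta,
        )
        for i, g in enumerate(es.values.index)
    ]


def classify_genes(
    kin_cool: list[GeneKinetics],
    kin_warm: list[GeneKinetics],
    sam: list[SamResult],
    *,
    fold_1p5: float = 1.5,
    fold_2: float = 2.0,
    delta_T: float | None = None,
) -> tuple[list[ThermalProfile], list[str]]:
    """Attach Q10s and abundance classes to every rateable gene.

    A gene enters the output when it has defined rates at both
    temperatures and a SAM result.  ``fold_change`` comes from the SAM
    result (all total samples, geometric mean).  Thresholds use >=
    semantics: a fold of exactly 2 is a warm gene.  Returns the profiles
    and the list of excluded gene_ids.
    """
    if fold_1p5 <= 1 or fold_2 <= 1:
        raise ValidationError("fold thresholds must exceed 1")
    cool = {k.gene_id: k for k in kin_cool}
    warm = {k.gene_id: k for k in kin_warm}
    sam_by_gene = {r.gene_id: r for r in sam}
    if delta_T is None:
        temps = {k.temperature for k in kin_cool} | {k.temperature for k in kin_warm}
        delta_T = max(temps) - min(temps) if len(temps) == 2 else 10.0

    profiles: list[ThermalProfile] = []
    excluded: list[str] = []
    for g in sam_by_gene:
        kc, kw = cool.get(g), warm.get(g)
        if (
            kc is None
            or kw is None
            or kc.drop_reason != "none"
            or kw.drop_reason != "none"
        ):
            excluded.append(g)
            continue
        r = sam_by_gene[g]
        fold = r.fold_change
        if not np.isfinite(fold):
            excluded.append(g)
            continue
        if fold >= fold_2:
            change = "WG"
        elif fold <= 1.0 / fold_2:
            change = "CG"
        else:
            change = "UG"
        if r.significant and fold >= fold_1p5:
            change_1p5 = "up"
        elif r.significant and fold <= 1.0 / fold_1p5:
            change_1p5 = "down"
        else:
            change_1p5 = "unchanged"
        profiles.append(
            ThermalProfile(
                gene_id=g,
                q10_syn=q10(kw.syn_rate, kc.syn_rate, delta_T),
                q10_dec=q10(kw.lam, kc.lam, delta_T),
                fold_change=fold,
                sig_flag=r.significant,
                change_class=change,
                change_class_1p5=change_1p5,
            )
        )
    return profiles, excluded


def profiles_table(profiles: list[ThermalProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [p.gene_id for p in profiles],
            "q10_syn": [p.q10_syn for p in profiles],
            "q10_dec": [p.q10_dec for p in profiles],
            "fold_change": [p.fold_change for p in profiles],
            "sig_flag": [p.sig_flag for p in profiles],
            "change_class": [p.change_class for p in profiles],
            "change_class_1p5": [p.change_class_1p5 for p in profiles],
        }
    )


def classification_summary(profiles: list[ThermalProfile]) -> pd.DataFrame:
    """Counts and Q10 location statistics per abundance class."""
    df = profiles_table(profiles)
    rows = []
    for cls, sub in df.groupby("change_class"):
        rows.append(
            {
                "change_class": cls,
                "n_genes": len(sub),
                "mean_q10_syn": sub["q10_syn"].mean(),
                "median_q10_syn": sub["q10_syn"].median(),
                "mean_q10_dec": sub["q10_dec"].mean(),
                "median_q10_dec": sub["q10_dec"].median(),
            }
        )
    return pd.DataFrame(rows)


def save_profiles(profiles: list[ThermalProfile], path: str | Path) -> None:
    profiles_table(profiles).to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_profiles(path: str | Path) -> list[ThermalProfile]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        ThermalProfile(
            gene_id=str(r.gene_id),
            q10_syn=float(r.q10_syn),
            q10_dec=float(r.q10_dec),
            fold_change=float(r.fold_change),
            sig_flag=bool(r.sig_flag),
            change_class=str(r.change_class),
            change_class_1p5=str(r.change_class_1p5),
        )
        for r in df.itertuples()
    ]


def sam_table(sam: list[SamResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in sam],
            "d_stat": [r.d_stat for r in sam],
            "fold_change": [r.fold_change for r in sam],
            "significant": [r.significant for r in sam],
            "delta_used": [r.delta_used for r in sam],
            "estimated_fdr": [r.estimated_fdr for r in sam],
        }
    )
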