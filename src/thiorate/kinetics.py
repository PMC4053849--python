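"""Per-gene half-lives, decay constants and synthesis rates.

Under first-order decay, the scale-corrected pre-existing amount P
remaining after a labeling window tL relates to the starting total A0 by
P = A0 * exp(-lambda * tL), giving

    t1/2 = -tL * ln2 / ln(P / A0),        lambda = ln2 / t1/2.

The newly synthesized amount N observed at the end of the window
under-counts transcription by the part that already decayed; correcting
for within-window decay gives the hourly synthesis rate

    alpha = N * lambda / (1 - exp(-lambda * tL)).

Genes for which the model is not identifiable — P >= A0 (half-life too
long for the labeling window to resolve), non-positive amounts, or
over-dispersed replicates — are dropped with an explicit reason rather
than silently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from thiorate.core_model import ExpressionSet, ValidationError

LN2 = math.log(2.0)

#: drop_reason values, in the order they are checked.
DROP_REASONS = (
    "none",
    "absent_call",
    "high_cv",
    "nonpositive_A0",
    "nonpositive_P",
    "ratio_ge_1",
    "nonpositive_N",
)


@dataclass(frozen=True)
class GeneKinetics:
    """Estimated kinetics of one gene at one temperature.

    Rate fields are NaN exactly when ``drop_reason`` is not ``"none"``.
    """

    gene_id: str
    temperature: float
    A0: float  # replicate-mean total at labeling start, array units
    A_end: float  # replicate-mean total at labeling end
    P: float  # corrected replicate-mean pre-existing amount
    N: float  # corrected replicate-mean newly synthesized amount
    half_life: float = float("nan")  # hours
    lam: float = float("nan")  # 1/h
    syn_rate: float = float("nan")  # units/h
    drop_reason: str = "none"

    def __post_init__(self) -> None:
        if self.drop_reason not in DROP_REASONS:
            raise ValidationError(f"unknown drop_reason {self.drop_reason!r}")
        defined = not math.isnan(self.half_life)
        if (self.drop_reason == "none") != defined:
            raise ValidationError(
                f"{self.gene_id}: drop_reason {self.drop_reason!r} inconsistent "
                "with defined rates"
            )


def half_life(P: float, A0: float, tL: float) -> float:
    """Half-life in hours from the surviving pre-existing fraction.

    Returns NaN when the estimate is undefined: non-positive P or A0, or
    P >= A0 (no measurable decay within the window).
    """
    if tL <= 0:
        raise ValidationError("labeling time must be positive")
    if P <= 0 or A0 <= 0 or P >= A0:
        return float("nan")
    return -tL * LN2 / math.log(P / A0)


def decay_constant(half_life_h: float) -> float:
    """First-order decay constant lambda = ln2 / t1/2, in 1/h."""
    if not half_life_h > 0:
        raise ValidationError("half-life must be positive")
    return LN2 / half_life_h


def synthesis_rate(N: float, lam: float, tL: float, *, series_cutoff: float = 1e-8) -> float:
    """Hourly synthesis rate from the newly synthesized amount.

    For lam * tL below ``series_cutoff`` the exact expression is 0/0 to
    machine precision and the no-decay limit N / tL is used; the two
    branches agree to first order.  Returns NaN for negative N.
    """
    if lam <= 0:
        raise ValidationError("decay constant must be positive")
    if tL <= 0:
        raise ValidationError("labeling time must be positive")
    if N < 0:
        return float("nan")
    x = lam * tL
    if x < series_cutoff:
        return N / tL
    return N * lam / (1.0 - math.exp(-x))


def estimate_gene_kinetics(
    es_corrected: ExpressionSet,
    temperature: float,
    tL: float | None = None,
    *,
    max_total_cv: float | None = None,
) -> list[GeneKinetics]:
    """Estimate kinetics for every gene at one temperature.

    ``es_corrected`` must already carry scale-corrected PE and NS
    intensities (see :mod:`thiorate.normalization`) and all four
    fractions at ``temperature``.  Replicates are averaged
    (arithmetically, on linear intensities) before rate computation.
    ``tL`` defaults to the labeling time recorded in the sample
    metadata.

    When ``max_total_cv`` is given, genes whose end-of-labeling total
    has a replicate coefficient of variation above it are dropped as
    too variable to rate reliably (``drop_reason="high_cv"``).

    Output order matches input gene order.
    """
    for fraction in ("total_start", "total_end", "newly_synthesized", "pre_existing"):
        if not es_corrected.select(temperature, fraction):
            raise ValidationError(
                f"no {fraction!r} samples at {temperature} degrees C"
            )
    if tL is None:
        tL = es_corrected.labeling_time(temperature)

    a0 = es_corrected.replicate_mean(temperature, "total_start")
    a_end = es_corrected.replicate_mean(temperature, "total_end")
    p = es_corrected.replicate_mean(temperature, "pre_existing")
    n = es_corrected.replicate_mean(temperature, "newly_synthesized")

    cv = None
    if max_total_cv is not None:
        totals = es_corrected.columns(temperature, "total_end")
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = totals.std(axis=1, ddof=1) / totals.mean(axis=1)

    out: list[GeneKinetics] = []
    for g in es_corrected.gene_ids:
        common = dict(
            gene_id=g,
            temperature=temperature,
            A0=float(a0[g]),
            A_end=float(a_end[g]),
            P=float(p[g]),
            N=float(n[g]),
        )
        reason = "none"
        if cv is not None and (not np.isfinite(cv[g]) or cv[g] > max_total_cv):
            reason = "high_cv"
        elif a0[g] <= 0:
            reason = "nonpositive_A0"
        elif p[g] <= 0:
            reason = "nonpositive_P"
        elif p[g] >= a0[g]:
            reason = "ratio_ge_1"
        elif n[g] < 0:
            reason = "nonpositive_N"
        if reason != "none":
            out.append(GeneKinetics(**common, drop_reason=reason))
            continue
        t12 = half_life(common["P"], common["A0"], tL)
        lam = decay_constant(t12)
        alpha = synthesis_rate(common["N"], lam, tL)
        out.append(
            GeneKinetics(**common, half_life=t12, lam=lam, syn_rate=alpha)
        )
    return out


def kinetics_table(kin: list[GeneKinetics]) -> pd.DataFrame:
    """Flatten a kinetics list to a DataFrame (column names match TSV)."""
    return pd.DataFrame(
        {
            "gene_id": [k.gene_id for k in kin],
            "temperature": [k.temperature for k in kin],
            "A0": [k.A0 for k in kin],
            "A_end": [k.A_end for k in kin],
            "P": [k.P for k in kin],
            "N": [k.N for k in kin],
            "half_life": [k.half_life for k in kin],
            "lambda": [k.lam for k in kin],
            "syn_rate": [k.syn_rate for k in kin],
            "drop_reason": [k.drop_reason for k in kin],
        }
    )


def save_kinetics(kin: list[GeneKinetics], path: str | Path) -> None:
    kinetics_table(kin).to_csv(path, sep="\t", index=False, float_format="%.17g")


def load_kinetics(path: str | Path) -> list[GeneKinetics]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    return [
        GeneKinetics(
            gene_id=str(row["gene_id"]),
            temperature=float(row["temperature"]),
            A0=float(row["A0"]),
            A_end=float(row["A_end"]),
            P=float(row["P"]),
            N=float(row["N"]),
            half_life=float(row["half_life"]),
            lam=float(row["lambda"]),
            syn_rate=float(row["syn_rate"]),
            drop_reason=str(row["drop_reason"]),
        )
        for _, row in df.iterrows()
    ]
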