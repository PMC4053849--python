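"""Regression-based rescaling of separated RNA fractions.

Equal RNA amounts are hybridized for the newly synthesized (NS),
pre-existing (PE) and total (T) samples, so the separated-fraction chip
intensities are not on the total-sample scale.  For each gene the true
fractions must satisfy

    Cp * PE/T + Cn * NS/T = 1,

where Cp and Cn are the unknown per-chip scale factors.  Rearranged,

    PE/T = 1/Cp - (Cn/Cp) * NS/T,

so an ordinary least-squares fit of PE/T against NS/T across genes gives
Cp = 1/intercept and Cn = -slope/intercept.  One fit per temperature, on
replicate-mean intensities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from thiorate.core_model import ExpressionSet, ValidationError


@dataclass(frozen=True)
class CorrectionFactors:
    """Fitted fraction scale factors for one temperature.

    Cp rescales pre-existing intensities and Cn newly synthesized
    intensities onto the total-sample scale; both must be positive for
    a physically meaningful fit (intercept > 0, slope < 0).
    """

    temperature: float
    Cp: float
    Cn: float
    intercept: float
    slope: float
    n_genes_used: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.Cp <= 0 or self.Cn <= 0:
            raise ValidationError("correction factors must be positive")
        if not np.isclose(self.Cp, 1.0 / self.intercept):
            raise ValidationError("Cp inconsistent with intercept")
        if not np.isclose(self.Cn, -self.slope / self.intercept):
            raise ValidationError("Cn inconsistent with slope/intercept")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CorrectionFactors":
        return cls(**json.loads(Path(path).read_text()))


def compute_fraction_ratios(
    es: ExpressionSet, temperature: float
) -> tuple[pd.DataFrame, list[str]]:
    """Per-gene NS/T and PE/T ratios at one temperature.

    Ratios use the replicate-mean intensity of each fraction against the
    replicate-mean end-of-labeling total.  Genes whose mean total is not
    strictly positive cannot be ratioed; they are excluded and returned
    as the second element.

    Returns
    -------
    (ratios, excluded)
        ``ratios``: DataFrame indexed by gene_id with columns
        ``ns_over_t``, ``pe_over_t``; ``excluded``: gene_ids dropped for
        non-positive totals.
    """
    for fraction in ("total_end", "newly_synthesized", "pre_existing"):
        if not es.select(temperature, fraction):
            raise ValidationError(
                f"no {fraction!r} samples at {temperature} degrees C"
            )
    total = es.replicate_mean(temperature, "total_end")
    ns = es.replicate_mean(temperature, "newly_synthesized")
    pe = es.replicate_mean(temperature, "pre_existing")
    ok = total > 0
    excluded = list(total.index[~ok])
    ratios = pd.DataFrame(
        {"ns_over_t": ns[ok] / total[ok], "pe_over_t": pe[ok] / total[ok]}
    )
    ratios.index.name = "gene_id"
    return ratios, excluded


def fit_correction_factors(
    ratios: pd.DataFrame,
    temperature: float = float("nan"),
    *,
    ratio_bound: float = 3.0,
) -> CorrectionFactors:
    """OLS fit of PE/T on NS/T, inverted to the scale factors Cp and Cn.

    Genes with either ratio outside [0, ``ratio_bound``] are treated as
    gross outliers (typically near-zero totals) and excluded from the
    fit.  Requires at least three retained genes, a positive intercept
    and a negative slope; anything else indicates non-physical data and
    raises.
    """
    x = ratios["ns_over_t"].to_numpy(dtype=float)
    y = ratios["pe_over_t"].to_numpy(dtype=float)
    keep = (
        np.isfinite(x)
        & np.isfinite(y)
        & (x >= 0)
        & (y >= 0)
        & (x <= ratio_bound)
        & (y <= ratio_bound)
    )
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValidationError(
            f"need at least 3 genes with finite in-range ratios, have {x.size}"
        )
    fit = stats.linregress(x, y)
    if fit.intercept <= 0:
        raise ValidationError(
            f"non-physical Cp: regression intercept {fit.intercept:.4g} <= 0"
        )
    if fit.slope >= 0:
        raise ValidationError(
            f"non-physical Cn: regression slope {fit.slope:.4g} >= 0"
        )
    return CorrectionFactors(
        temperature=temperature,
        Cp=1.0 / fit.intercept,
        Cn=-fit.slope / fit.intercept,
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        n_genes_used=int(x.size),
        r_squared=float(fit.rvalue**2),
    )


def apply_correction(es: ExpressionSet, cf: CorrectionFactors) -> ExpressionSet:
    """Rescale PE and NS intensities at ``cf.temperature`` by Cp and Cn.

    Total-RNA samples are untouched.  After correction the mean-level
    closure Cp*PE + Cn*NS ~ T holds for well-behaved genes.
    """
    if not es.select(cf.temperature):
        raise ValidationError(f"no samples at {cf.temperature} degrees C")
    out = es.copy()
    for s in out.samples:
        if s.temperature != cf.temperature:
            continue
        if s.fraction == "pre_existing":
            out.values[s.sample_id] = out.values[s.sample_id] * cf.Cp
        elif s.fraction == "newly_synthesized":
            out.values[s.sample_id] = out.values[s.sample_id] * cf.Cn
    return out


def normalize_all(
    es: ExpressionSet, *, ratio_bound: float = 3.0
) -> tuple[ExpressionSet, dict[float, CorrectionFactors]]:
    """Fit and apply correction factors for every temperature in ``es``."""
    out = es
    factors: dict[float, CorrectionFactors] = {}
    for temp in es.temperatures():
        ratios, _ = compute_fraction_ratios(es, temp)
        cf = fit_correction_factors(ratios, temp, ratio_bound=ratio_bound)
        out = apply_correction(out, cf)
        factors[temp] = cf
    return out, factors
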