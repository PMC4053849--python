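"""Domain types, TSV readers/writers, validation and detection-call filtering.

The in-memory container is :class:`ExpressionSet`: a gene x sample matrix
of linear-scale summarized intensities (MAS5-style), an optional matrix
of present/marginal/absent detection calls, and per-sample metadata
describing temperature, RNA fraction, replicate and labeling time.

All file I/O is tab-separated text with a header row.  Gene identifiers
are opaque strings (AGI locus codes in real Arabidopsis use).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: The four RNA fractions of the labeling design.
FRACTIONS = ("total_start", "total_end", "newly_synthesized", "pre_existing")

#: Fractions measured on total (unseparated) RNA.
TOTAL_FRACTIONS = ("total_start", "total_end")

#: Fractions collected at the end of the labeling window; these carry tL.
TIMED_FRACTIONS = ("total_end", "newly_synthesized", "pre_existing")

#: Valid MAS5 detection calls: present, marginal, absent.
CALLS = ("P", "M", "A")


class ValidationError(ValueError):
    """Raised when an input file or container violates its contract."""


@dataclass(frozen=True)
class SampleMeta:
    """Metadata for one hybridization.

    Parameters
    ----------
    sample_id
        Unique column identifier in the expression matrix.
    temperature
        Growth/labeling temperature in degrees Celsius.
    fraction
        One of ``total_start``, ``total_end``, ``newly_synthesized``,
        ``pre_existing``.
    replicate
        Biological replicate number (1-based).
    labeling_time
        4SU labeling duration tL in hours.  Required for every fraction
        collected at the end of labeling; ignored for ``total_start``.
    """

    sample_id: str
    temperature: float
    fraction: str
    replicate: int
    labeling_time: float | None = None

    def __post_init__(self) -> None:
        if self.fraction not in FRACTIONS:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown fraction {self.fraction!r}; "
                f"expected one of {FRACTIONS}"
            )
        if self.replicate < 1:
            raise ValidationError(
                f"sample {self.sample_id!r}: replicate must be a positive integer"
            )
        if self.fraction in TIMED_FRACTIONS:
            if self.labeling_time is None or not np.isfinite(self.labeling_time):
                raise ValidationError(
                    f"sample {self.sample_id!r}: fraction {self.fraction!r} "
                    "requires a labeling_time"
                )
            if self.labeling_time <= 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: labeling_time must be > 0"
                )

    @property
    def key(self) -> tuple[float, str, int]:
        return (self.temperature, self.fraction, self.replicate)


@dataclass
class ExpressionSet:
    """Gene x sample intensity matrix with metadata and optional calls.

    ``values`` is a DataFrame indexed by gene_id with one column per
    sample_id, in the order of ``samples``.  Intensities are linear
    scale and non-negative.  ``calls`` shares the same shape and holds
    ``P``/``M``/``A`` detection flags.
    """

    values: pd.DataFrame
    samples: list[SampleMeta]
    calls: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValidationError("duplicate sample_id in metadata")
        keys = [s.key for s in self.samples]
        if len(set(keys)) != len(keys):
            dup = [k for k in keys if keys.count(k) > 1][0]
            raise ValidationError(
                f"duplicate (temperature, fraction, replicate) triple {dup}"
            )
        if list(self.values.columns) != sample_ids:
            missing = set(sample_ids) ^ set(self.values.columns)
            if missing:
                raise ValidationError(
                    f"matrix columns and sample metadata disagree on: {sorted(missing)}"
                )
            # same set, different order: align to metadata order
            self.values = self.values[sample_ids]
        self.values.index.name = "gene_id"
        if self.calls is not None:
            self.calls.index.name = "gene_id"
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene_ids: {dups[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            g, s = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite intensity at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        if (arr < 0).any():
            g, s = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative intensity at gene {self.values.index[g]!r}, "
                f"sample {self.values.columns[s]!r}"
            )
        if self.calls is not None:
            if not self.calls.index.equals(self.values.index) or list(
                self.calls.columns
            ) != list(self.values.columns):
                self.calls = self.calls.reindex(
                    index=self.values.index, columns=self.values.columns
                )
            if self.calls.isna().any().any():
                raise ValidationError("calls matrix does not cover all genes/samples")
            bad = ~self.calls.isin(CALLS)
            if bad.any().any():
                g = bad.any(axis=1).idxmax()
                raise ValidationError(
                    f"invalid detection call for gene {g!r}; expected one of {CALLS}"
                )

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    def meta_frame(self) -> pd.DataFrame:
        """Sample metadata as a DataFrame indexed by sample_id."""
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self.samples],
                "temperature": [s.temperature for s in self.samples],
                "fraction": [s.fraction for s in self.samples],
                "replicate": [s.replicate for s in self.samples],
                "labeling_time": [
                    s.labeling_time if s.labeling_time is not None else np.nan
                    for s in self.samples
                ],
            }
        ).set_index("sample_id", drop=False)

    def temperatures(self) -> list[float]:
        return sorted({s.temperature for s in self.samples})

    def select(
        self, temperature: float | None = None, fraction: str | None = None
    ) -> list[SampleMeta]:
        """Samples matching the given temperature and/or fraction."""
        out = self.samples
        if temperature is not None:
            out = [s for s in out if s.temperature == temperature]
        if fraction is not None:
            out = [s for s in out if s.fraction == fraction]
        return list(out)

    def columns(
        self, temperature: float | None = None, fraction: str | None = None
    ) -> pd.DataFrame:
        """Intensity sub-matrix for matching samples."""
        ids = [s.sample_id for s in self.select(temperature, fraction)]
        return self.values[ids]

    def replicate_mean(self, temperature: float, fraction: str) -> pd.Series:
        """Per-gene arithmetic mean intensity across replicates."""
        sub = self.columns(temperature, fraction)
        if sub.shape[1] == 0:
            raise ValidationError(
                f"no {fraction!r} samples at {temperature} degrees C"
            )
        return sub.mean(axis=1)

    def labeling_time(self, temperature: float) -> float:
        """The (unique) labeling time tL at a temperature, in hours."""
        times = {
            s.labeling_time
            for s in self.samples
            if s.temperature == temperature and s.fraction in TIMED_FRACTIONS
        }
        if not times:
            raise ValidationError(f"no labeled samples at {temperature} degrees C")
        if len(times) > 1:
            raise ValidationError(
                f"inconsistent labeling times at {temperature} degrees C: {sorted(times)}"
            )
        return times.pop()

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionSet":
        values = self.values.loc[list(gene_ids)]
        calls = self.calls.loc[list(gene_ids)] if self.calls is not None else None
        return ExpressionSet(values=values, samples=list(self.samples), calls=calls)

    def copy(self) -> "ExpressionSet":
        return ExpressionSet(
            values=self.values.copy(),
            samples=list(self.samples),
            calls=self.calls.copy() if self.calls is not None else None,
        )

    # -- I/O -------------------------------------------------------------------

    def save(
        self,
        matrix_path: str | Path,
        meta_path: str | Path,
        calls_path: str | Path | None = None,
    ) -> None:
        """Write matrix / metadata / calls as TSV with full float precision."""
        self.values.to_csv(matrix_path, sep="\t", index_label="gene_id", float_format="%.17g")
        self.meta_frame().to_csv(meta_path, sep="\t", index=False)
        if calls_path is not None:
            if self.calls is None:
                raise ValidationError("no calls matrix to write")
            self.calls.to_csv(calls_path, sep="\t", index_label="gene_id")


def load_expression_set(
    matrix_path: str | Path,
    meta_path: str | Path,
    calls_path: str | Path | None = None,
) -> ExpressionSet:
    """Read an expression set from TSV files.

    The metadata table must have columns ``sample_id``, ``temperature``,
    ``fraction``, ``replicate``, ``labeling_time``; matrix column headers
    must match the sample_ids exactly.  On return, genes are sorted
    lexicographically and samples ordered by (temperature, fraction,
    replicate).
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0, float_precision="round_trip")
    values.index = values.index.astype(str)
    meta = pd.read_csv(meta_path, sep="\t")
    required = {"sample_id", "temperature", "fraction", "replicate", "labeling_time"}
    missing_cols = required - set(meta.columns)
    if missing_cols:
        raise ValidationError(f"metadata missing columns: {sorted(missing_cols)}")
    meta_ids = set(meta["sample_id"].astype(str))
    matrix_ids = set(map(str, values.columns))
    orphans = matrix_ids - meta_ids
    if orphans:
        raise ValidationError(
            f"matrix columns absent from sample metadata: {sorted(orphans)}"
        )
    absent = meta_ids - matrix_ids
    if absent:
        raise ValidationError(
            f"metadata samples missing from matrix: {sorted(absent)}"
        )
    samples = [
        SampleMeta(
            sample_id=str(row.sample_id),
            temperature=float(row.temperature),
            fraction=str(row.fraction),
            replicate=int(row.replicate),
            labeling_time=None if pd.isna(row.labeling_time) else float(row.labeling_time),
        )
        for row in meta.itertuples()
    ]
    samples.sort(key=lambda s: s.key)
    values = values.sort_index()
    calls = None
    if calls_path is not None:
        calls = pd.read_csv(calls_path, sep="\t", index_col=0)
        calls.index = calls.index.astype(str)
        calls = calls.sort_index()
    return ExpressionSet(values=values, samples=samples, calls=calls)


def filter_present(
    es: ExpressionSet, *, marginal_is_present: bool = True
) -> tuple[ExpressionSet, list[str]]:
    """Drop genes not detected in every total-RNA sample.

    A gene is kept only when its detection call differs from ``A``
    (absent) in every ``total_start`` and ``total_end`` sample at both
    temperatures; by default marginal (``M``) calls count as present.
    Returns the filtered set and the list of dropped gene_ids, input
    order preserved.
    """
    if es.calls is None:
        raise ValidationError("filter_present requires a calls matrix")
    total_ids = [s.sample_id for s in es.samples if s.fraction in TOTAL_FRACTIONS]
    if not total_ids:
        raise ValidationError("no total-RNA samples in expression set")
    sub = es.calls[total_ids]
    if marginal_is_present:
        keep_mask = (sub != "A").all(axis=1)
    else:
        keep_mask = (sub == "P").all(axis=1)
    kept = [g for g, k in zip(es.values.index, keep_mask) if k]
    dropped = [g for g, k in zip(es.values.index, keep_mask) if not k]
    return es.subset_genes(kept), dropped


@dataclass(frozen=True)
class GeneAnnotation:
    """Numeric transcript features for one gene."""

    gene_id: str
    cdna_length: float
    utr5_length: float
    utr3_length: float
    gc_content: float
    u_content: float
    intron_count: int

    def __post_init__(self) -> None:
        for name in ("cdna_length", "utr5_length", "utr3_length"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{self.gene_id}: {name} must be >= 0")
        for name in ("gc_content", "u_content"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{self.gene_id}: {name} must be in [0, 1]")
        if self.intron_count < 0:
            raise ValidationError(f"{self.gene_id}: intron_count must be >= 0")


ANNOTATION_FEATURES = (
    "cdna_length",
    "utr5_length",
    "utr3_length",
    "gc_content",
    "u_content",
    "intron_count",
)


def load_annotation(path: str | Path) -> pd.DataFrame:
    """Read a gene-annotation TSV into a validated DataFrame (index gene_id)."""
    df = pd.read_csv(path, sep="\t")
    if "gene_id" not in df.columns:
        raise ValidationError("annotation table missing gene_id column")
    df = df.set_index("gene_id")
    missing = set(ANNOTATION_FEATURES) - set(df.columns)
    if missing:
        raise ValidationError(f"annotation table missing columns: {sorted(missing)}")
    for row in df.itertuples():
        GeneAnnotation(
            gene_id=str(row.Index),
            cdna_length=row.cdna_length,
            utr5_length=row.utr5_length,
            utr3_length=row.utr3_length,
            gc_content=row.gc_content,
            u_content=row.u_content,
            intron_count=int(row.intron_count),
        )
    return df


class GeneSetCollection(dict):
    """Named gene sets (chromatin marks, mutant-response lists, motif hits).

    A mapping ``name -> frozenset of gene_ids``; sets may overlap.
    """

    def __setitem__(self, name: str, genes: Iterable[str]) -> None:
        genes = frozenset(map(str, genes))
        if any(not g for g in genes):
            raise ValidationError(f"gene set {name!r} contains an empty gene_id")
        super().__setitem__(str(name), genes)

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Iterable[str]]) -> "GeneSetCollection":
        out = cls()
        for k, v in mapping.items():
            out[k] = v
        return out

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneSetCollection":
        """Read two-column (set_name, gene_id) TSV, header optional."""
        df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
        if df.shape[1] != 2:
            raise ValidationError(
                f"{path}: expected two columns (set_name, gene_id), got {df.shape[1]}"
            )
        if list(df.iloc[0]) == ["set_name", "gene_id"]:
            df = df.iloc[1:]
        out = cls()
        for name, sub in df.groupby(0):
            out[str(name)] = sub[1].tolist()
        return out

    @classmethod
    def from_gene_list(cls, name: str, path: str | Path) -> "GeneSetCollection":
        """Read a one-gene-per-line text file as a single named set."""
        genes = [
            line.strip()
            for line in Path(path).read_text().splitlines()
            if line.strip() and not line.startswith("#")
        ]
        out = cls()
        out[name] = genes
        return out

    def to_tsv(self, path: str | Path) -> None:
        rows = [
            {"set_name": name, "gene_id": g}
            for name in sorted(self)
            for g in sorted(self[name])
        ]
        pd.DataFrame(rows, columns=["set_name", "gene_id"]).to_csv(
            path, sep="\t", index=False
        )
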