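"""Domain containers and delimited-text I/O shared by every analysis stage.

The pipeline works on four aligned objects: a :class:`SampleTable` holding
the response (post-treatment log-triglyceride, natural-log mg/dL) and named
covariates; one or more :class:`MarkerMatrix` objects (methylation beta
values in [0, 1] or additive SNP dosages in [0, 2]); a
:class:`MarkerAnnotation` mapping marker ids to genomic coordinates; and a
:class:`RegionSet` naming the marker sets to be tested.

Coordinates are 1-based inclusive base-pair positions, the convention of
common CpG-array annotation files.  Missing values are handled by
complete-case analysis: rows with any missing value among the used columns
are dropped (and counted) at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DataError

logger = logging.getLogger(__name__)

#: tolerance within which marginally out-of-range values are clipped
#: rather than rejected (floating-point dust from upstream pipelines)
RANGE_CLIP_TOL = 1e-9

_VALUE_RANGE = {"methylation": (0.0, 1.0), "genotype": (0.0, 2.0)}


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SampleTable:
    """Aligned response and covariates for n independent individuals.

    ``covariates`` has one named column per adjustment variable (no
    intercept column; design matrices add the intercept explicitly).
    """

    sample_ids: tuple[str, ...]
    response: np.ndarray          # shape (n,)
    covariates: pd.DataFrame      # shape (n, c), named columns
    n_dropped: int = 0            # incomplete rows removed at read time

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if len(set(self.sample_ids)) != n:
            raise DataError("sample ids are not unique")
        if n < 3:
            raise DataError(f"need at least 3 complete samples, got {n}")
        if self.response.shape != (n,) or len(self.covariates) != n:
            raise DataError("response/covariates not aligned with sample ids")
        if np.isnan(self.response).any() or self.covariates.isna().to_numpy().any():
            raise DataError("missing values remain after alignment")

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def design_matrix(self) -> np.ndarray:
        """Covariate design matrix with a leading intercept column."""
        return np.column_stack(
            [np.ones(self.n), self.covariates.to_numpy(dtype=float)]
        )

    @property
    def design_columns(self) -> tuple[str, ...]:
        return ("intercept",) + tuple(self.covariates.columns)


@dataclass(frozen=True)
class MarkerMatrix:
    """n x m matrix of marker values, row-aligned with a SampleTable.

    ``marker_kind`` is ``"methylation"`` (beta values in [0, 1]) or
    ``"genotype"`` (additive ALT-allele dosages in [0, 2]).
    """

    sample_ids: tuple[str, ...]
    marker_ids: tuple[str, ...]
    values: np.ndarray            # shape (n, m)
    marker_kind: str

    def __post_init__(self) -> None:
        if self.marker_kind not in _VALUE_RANGE:
            raise ConfigurationError(
                f"unknown marker kind {self.marker_kind!r}"
            )
        if len(set(self.marker_ids)) != len(self.marker_ids):
            raise DataError("marker ids are not unique")
        if self.values.shape != (len(self.sample_ids), len(self.marker_ids)):
            raise DataError(
                f"value matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.marker_ids)} markers"
            )
        object.__setattr__(
            self, "values",
            _enforce_range(self.values, self.marker_kind,
                           self.sample_ids, self.marker_ids),
        )

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def m(self) -> int:
        return len(self.marker_ids)

    def restrict_markers(self, marker_ids: Sequence[str]) -> "MarkerMatrix":
        """Column-subset (in the given order) to the listed markers."""
        index = {mid: j for j, mid in enumerate(self.marker_ids)}
        try:
            cols = [index[mid] for mid in marker_ids]
        except KeyError as exc:
            raise ConfigurationError(f"unknown marker id {exc.args[0]!r}") from exc
        return replace(
            self, marker_ids=tuple(marker_ids), values=self.values[:, cols]
        )

    def restrict_samples(self, sample_ids: Sequence[str]) -> "MarkerMatrix":
        index = {sid: i for i, sid in enumerate(self.sample_ids)}
        try:
            rows = [index[sid] for sid in sample_ids]
        except KeyError as exc:
            raise DataError(f"unknown sample id {exc.args[0]!r}") from exc
        return replace(
            self, sample_ids=tuple(sample_ids), values=self.values[rows, :]
        )


def _enforce_range(values, kind, sample_ids, marker_ids):
    lo, hi = _VALUE_RANGE[kind]
    values = np.asarray(values, dtype=float)
    bad = (values < lo - RANGE_CLIP_TOL) | (values > hi + RANGE_CLIP_TOL)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise DataError(
            f"{kind} value {values[i, j]!r} outside [{lo}, {hi}] for marker "
            f"{marker_ids[j]!r}, sample {sample_ids[i]!r}"
        )
    if np.isnan(values).any():
        i, j = map(int, np.argwhere(np.isnan(values))[0])
        raise DataError(
            f"missing {kind} value for marker {marker_ids[j]!r}, "
            f"sample {sample_ids[i]!r}"
        )
    return np.clip(values, lo, hi)


@dataclass(frozen=True)
class MarkerAnnotation:
    """Genomic coordinates (1-based) for CpG and SNP markers."""

    table: pd.DataFrame  # columns: marker_id, chrom, pos, kind

    REQUIRED = ("marker_id", "chrom", "pos", "kind")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ConfigurationError(f"annotation lacks columns {missing}")
        if self.table["marker_id"].duplicated().any():
            dup = self.table["marker_id"][self.table["marker_id"].duplicated()]
            raise DataError(f"duplicate annotation for marker {dup.iloc[0]!r}")
        if (self.table["pos"] < 1).any():
            raise DataError("annotation positions must be >= 1 (1-based)")
        object.__setattr__(
            self, "table", self.table.reset_index(drop=True)
        )

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in set(self.table["marker_id"])

    def lookup(self, marker_id: str) -> tuple[str, int, str]:
        """Return (chromosome, position, kind) for one marker."""
        row = self.table[self.table["marker_id"] == marker_id]
        if row.empty:
            raise ConfigurationError(f"marker {marker_id!r} not annotated")
        r = row.iloc[0]
        return str(r["chrom"]), int(r["pos"]), str(r["kind"])

    def on_chromosome(self, chrom: str,
                      kind: str | None = None) -> pd.DataFrame:
        sub = self.table[self.table["chrom"].astype(str) == str(chrom)]
        if kind is not None:
            sub = sub[sub["kind"] == kind]
        return sub


@dataclass(frozen=True)
class Region:
    """One named marker set: an anchor +/- window or an explicit list."""

    name: str
    members: tuple[str, ...]
    anchor: str | None = None
    window_kbp: float | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ConfigurationError(f"region {self.name!r} has no members")
        if self.anchor is not None and self.anchor not in self.members:
            raise ConfigurationError(
                f"anchor {self.anchor!r} is not a member of region {self.name!r}"
            )


@dataclass(frozen=True)
class RegionSet:
    regions: tuple[Region, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            raise ConfigurationError("region names are not unique")

    def __iter__(self):
        return iter(self.regions)

    def __len__(self) -> int:
        return len(self.regions)

    def __getitem__(self, name: str) -> Region:
        for r in self.regions:
            if r.name == name:
                return r
        raise KeyError(name)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_sample_table(path: str | Path, response_col: str,
                      covariate_cols: Sequence[str],
                      sep: str = "\t") -> SampleTable:
    """Read a phenotype/covariate table from delimited text.

    The first column is the sample id.  Rows with a missing response or
    covariate value are dropped; the drop count is logged and recorded on
    the returned table.
    """
    df = pd.read_csv(path, sep=sep, comment="#", dtype={0: str},
                     float_precision="round_trip")
    id_col = df.columns[0]
    used = [response_col, *covariate_cols]
    for col in used:
        if col not in df.columns:
            raise ConfigurationError(
                f"column {col!r} not found in {path} "
                f"(available: {list(df.columns[1:])})"
            )
        df[col] = pd.to_numeric(df[col], errors="coerce")
    complete = df.dropna(subset=used)
    n_dropped = len(df) - len(complete)
    if n_dropped:
        logger.info("read_sample_table: dropped %d incomplete row(s) from %s",
                    n_dropped, path)
    if len(complete) < 3:
        raise DataError(
            f"fewer than 3 complete rows in {path} "
            f"({len(complete)} complete, {n_dropped} dropped)"
        )
    return SampleTable(
        sample_ids=tuple(complete[id_col].astype(str)),
        response=complete[response_col].to_numpy(dtype=float),
        covariates=complete[list(covariate_cols)].reset_index(drop=True),
        n_dropped=n_dropped,
    )


def write_sample_table(table: SampleTable, path: str | Path,
                       response_col: str = "post_lntg",
                       sep: str = "\t") -> None:
    df = pd.DataFrame({"sample_id": table.sample_ids})
    df[response_col] = table.response
    for col in table.covariates.columns:
        df[col] = table.covariates[col].to_numpy()
    df.to_csv(path, sep=sep, index=False)


def read_marker_matrix(path: str | Path, kind: str,
                       sep: str = "\t") -> MarkerMatrix:
    """Read a samples x markers matrix from delimited text.

    First column: sample id; remaining columns: one marker each.
    For genotypes a biallelic VCF may be read instead via
    :func:`read_genotypes_vcf`.
    """
    df = pd.read_csv(path, sep=sep, comment="#", dtype={0: str},
                     float_precision="round_trip")
    id_col = df.columns[0]
    marker_ids = tuple(str(c) for c in df.columns[1:])
    if not marker_ids:
        raise DataError(f"no marker columns in {path}")
    values = df[list(df.columns[1:])].apply(
        pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    return MarkerMatrix(
        sample_ids=tuple(df[id_col].astype(str)),
        marker_ids=marker_ids,
        values=values,
        marker_kind=kind,
    )


def write_marker_matrix(matrix: MarkerMatrix, path: str | Path,
                        sep: str = "\t") -> None:
    df = pd.DataFrame(matrix.values, columns=list(matrix.marker_ids))
    df.insert(0, "sample_id", list(matrix.sample_ids))
    # float repr round-trips exactly
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_genotypes_vcf(path: str | Path) -> MarkerMatrix:
    """Read additive dosages (ALT-allele count) from a biallelic VCF.

    Multi-allelic records are skipped with a warning.  Missing genotypes
    are a data error: complete-case handling operates on rows, not calls.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ConfigurationError(
            "VCF input requires the optional cyvcf2 dependency"
        ) from exc

    vcf = VCF(str(path))
    samples = tuple(vcf.samples)
    marker_ids: list[str] = []
    columns: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            logger.warning("skipping non-biallelic record %s:%s (%d ALT alleles)",
                           variant.CHROM, variant.POS, len(variant.ALT))
            continue
        name = variant.ID or f"{variant.CHROM}:{variant.POS}"
        dosage = np.empty(len(samples))
        for i, gt in enumerate(variant.genotypes):
            alleles = gt[:-1]
            if any(a < 0 for a in alleles):
                raise DataError(
                    f"missing genotype for sample {samples[i]!r} at {name}"
                )
            dosage[i] = sum(1 for a in alleles if a > 0)
        marker_ids.append(name)
        columns.append(dosage)
    if not marker_ids:
        raise DataError(f"no usable biallelic records in {path}")
    return MarkerMatrix(
        sample_ids=samples,
        marker_ids=tuple(marker_ids),
        values=np.column_stack(columns),
        marker_kind="genotype",
    )


def read_annotation(path: str | Path, sep: str = "\t") -> MarkerAnnotation:
    """Read BED-like 4-column annotation: chrom, pos, marker_id, kind.

    A header row with those names is accepted; headerless files are
    detected by the second field of the first line being numeric.
    """
    first = pd.read_csv(path, sep=sep, header=None, nrows=1, comment="#")
    has_header = not str(first.iloc[0, 1]).strip().lstrip("+-").isdigit()
    if has_header:
        df = pd.read_csv(path, sep=sep, comment="#")
        df = df.rename(columns=str.lower)
    else:
        df = pd.read_csv(path, sep=sep, header=None, comment="#",
                         names=["chrom", "pos", "marker_id", "kind"])
    df = df[["marker_id", "chrom", "pos", "kind"]].copy()
    df["chrom"] = df["chrom"].astype(str)
    df["marker_id"] = df["marker_id"].astype(str)
    df["pos"] = pd.to_numeric(df["pos"]).astype(int)
    return MarkerAnnotation(table=df)


def write_annotation(annotation: MarkerAnnotation, path: str | Path,
                     sep: str = "\t") -> None:
    annotation.table[["chrom", "pos", "marker_id", "kind"]].to_csv(
        path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def align_samples(table: SampleTable, matrices: Iterable[MarkerMatrix],
                  ) -> tuple[SampleTable, list[MarkerMatrix]]:
    """Restrict all inputs to the shared sample ids, in the table's order.

    Idempotent; the intersection size is logged.  An empty intersection is
    a data error.
    """
    matrices = list(matrices)
    shared = set(table.sample_ids)
    for mat in matrices:
        shared &= set(mat.sample_ids)
    if not shared:
        raise DataError("no samples shared by all inputs")
    keep = [sid for sid in table.sample_ids if sid in shared]
    logger.info("align_samples: %d of %d table samples retained",
                len(keep), table.n)
    row_of = {sid: i for i, sid in enumerate(table.sample_ids)}
    rows = [row_of[sid] for sid in keep]
    aligned_table = SampleTable(
        sample_ids=tuple(keep),
        response=table.response[rows],
        covariates=table.covariates.iloc[rows].reset_index(drop=True),
        n_dropped=table.n_dropped,
    )
    aligned_matrices = [m.restrict_samples(keep) for m in matrices]
    return aligned_table, aligned_matrices
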