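"""File formats and the sample-metadata schema.

The pipeline's substrate is a genes x samples matrix of non-negative
probe-set signal values together with a sample sheet that assigns every
array to a (strain, condition, replicate) cell of the experimental design:
three genotypes (the PKA-proficient reference and two PKA-null suppressor
strains) crossed with an ethanol baseline, a 30-minute glucose pulse,
steady growth on glucose+ethanol, and an optional PKA-activation
pseudo-condition.

Two matrix dialects are read: a plain tab-delimited table (header row of
sample ids, gene ids in column one) and the GEO Series Matrix data block,
which has the same shape between its begin/end sentinels.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Strain",
    "Condition",
    "SampleDescriptor",
    "ExpressionMatrix",
    "FormatError",
    "SchemaError",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_series_matrix",
    "read_sample_sheet",
    "write_sample_sheet",
    "write_classification_report",
    "read_classification_report",
]


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class SchemaError(ValueError):
    """Sample metadata violates the design schema."""


class Strain(Enum):
    """Genotype of an array's culture."""

    REF_PKA_PLUS = "REF_PKA_PLUS"        # TPK1 TPK2 TPK3 reference
    TPK_NULL_MSN = "TPK_NULL_MSN"        # tpk1 tpk2 tpk3 msn2 msn4
    TPK_NULL_YAK = "TPK_NULL_YAK"        # tpk1 tpk2 tpk3 yak1


class Condition(Enum):
    """Culture condition at sampling."""

    ETHANOL = "ETHANOL"                  # gluconeogenic baseline, 2% ethanol
    GLUCOSE_30MIN = "GLUCOSE_30MIN"      # 30 min after 4% glucose addition
    GLUCOSE_GROWTH = "GLUCOSE_GROWTH"    # exponential growth, glucose+ethanol
    PKA_ACTIVATED = "PKA_ACTIVATED"      # cAMP-driven PKA activation, no glucose


@dataclass(frozen=True)
class SampleDescriptor:
    """Metadata for one array: which strain, condition and replicate."""

    sample_id: str
    strain: Strain
    condition: Condition
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise SchemaError(
                f"replicate index must be a positive integer, got {self.replicate}"
            )

    @property
    def group(self) -> tuple[Strain, Condition]:
        return (self.strain, self.condition)


@dataclass
class ExpressionMatrix:
    """Genes x samples grid of non-negative signal values.

    ``data`` is a DataFrame indexed by gene id with one column per sample
    id.  ``scaled`` records whether per-array global scaling has been
    applied; factor computation requires scaled, replicate-averaged input.
    """

    data: pd.DataFrame
    scaled: bool = False

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups[:5]}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if np.any(values < 0):
            gi, si = np.argwhere(values < 0)[0]
            raise FormatError(
                f"negative signal value at gene {self.data.index[gi]!r}, "
                f"sample {self.data.columns[si]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def with_data(self, data: pd.DataFrame, *, scaled: bool | None = None) -> "ExpressionMatrix":
        return ExpressionMatrix(data=data, scaled=self.scaled if scaled is None else scaled)


def _parse_cell(token: str, gene: str, sample: str) -> float:
    try:
        value = float(token)
    except ValueError:
        raise FormatError(
            f"non-numeric value {token!r} at gene {gene!r}, sample {sample!r}"
        ) from None
    if value < 0:
        raise FormatError(
            f"negative signal value {value} at gene {gene!r}, sample {sample!r}"
        )
    return value


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read a tab-delimited expression matrix.

    First row is a header of sample ids; first column holds gene ids;
    every remaining cell must parse as a non-negative number.  Returns a
    matrix flagged ``scaled=False`` (raw signal convention).
    """
    path = Path(path)
    with path.open() as fh:
        lines = [line.rstrip("\n").rstrip("\r") for line in fh if line.strip()]
    if not lines:
        raise FormatError(f"{path}: empty file, expected a header row")
    header = lines[0].split("\t")
    if len(header) < 2:
        raise FormatError(f"{path}: header row must name at least one sample")
    sample_ids = header[1:]
    genes: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(
                f"{path}:{lineno}: expected {len(header)} columns, got {len(fields)}"
            )
        gene = fields[0]
        genes.append(gene)
        rows.append([_parse_cell(tok, gene, sid) for tok, sid in zip(fields[1:], sample_ids)])
    data = pd.DataFrame(rows, index=pd.Index(genes, name="gene"), columns=sample_ids, dtype=float)
    matrix = ExpressionMatrix(data=data, scaled=False)
    logger.info("read %s: %d genes x %d samples", path, *matrix.shape)
    return matrix


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the tab-delimited matrix dialect read by :func:`read_expression_tsv`.

    Values are written at full precision; rounding is a presentation
    concern left to reports.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("gene\t" + "\t".join(matrix.sample_ids) + "\n")
        for gene, row in zip(matrix.gene_ids, matrix.data.to_numpy()):
            fh.write(gene + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


_SM_BEGIN = "!series_matrix_table_begin"
_SM_END = "!series_matrix_table_end"


def read_series_matrix(path: str | Path) -> ExpressionMatrix:
    """Read the data block of a GEO Series Matrix file.

    Only the table between the begin/end sentinels is parsed; metadata
    lines outside it are counted and logged.  Quoted identifiers are
    unquoted.  Deposited values are post-processing, so the result is
    flagged ``scaled=True``.
    """
    path = Path(path)
    in_block = False
    header: list[str] | None = None
    genes: list[str] = []
    rows: list[list[float]] = []
    ignored = 0
    saw_end = False
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n").rstrip("\r")
            if not line:
                continue
            stripped = line.strip()
            if stripped.lower() == _SM_BEGIN:
                in_block = True
                continue
            if stripped.lower() == _SM_END:
                saw_end = True
                break
            if not in_block:
                ignored += 1
                continue
            fields = [f.strip('"') for f in line.split("\t")]
            if header is None:
                header = fields
                continue
            if len(fields) != len(header):
                raise FormatError(
                    f"{path}: ragged row for {fields[0]!r}: "
                    f"expected {len(header)} columns, got {len(fields)}"
                )
            gene = fields[0]
            genes.append(gene)
            rows.append([_parse_cell(tok, gene, sid) for tok, sid in zip(fields[1:], header[1:])])
    if header is None or not saw_end:
        raise FormatError(f"{path}: no data block delimited by {_SM_BEGIN}/{_SM_END}")
    data = pd.DataFrame(
        rows, index=pd.Index(genes, name="gene"), columns=header[1:], dtype=float
    )
    matrix = ExpressionMatrix(data=data, scaled=True)
    logger.info(
        "read %s: %d genes x %d samples (%d metadata lines ignored)",
        path, *matrix.shape, ignored,
    )
    return matrix


def _parse_enum(enum_cls, token: str, lineno: int, path: Path):
    try:
        return enum_cls[token.strip().upper()]
    except KeyError:
        valid = ", ".join(m.name for m in enum_cls)
        raise SchemaError(
            f"{path}:{lineno}: unknown {enum_cls.__name__.lower()} token {token!r} "
            f"(valid: {valid})"
        ) from None


def read_sample_sheet(path: str | Path) -> list[SampleDescriptor]:
    """Read a tab-delimited sample sheet with columns
    sample_id, strain, condition, replicate.

    Strain/condition tokens are case-folded to the schema enums; anything
    else is a hard error, never a silent coercion.
    """
    path = Path(path)
    with path.open() as fh:
        lines = [line.rstrip("\n").rstrip("\r") for line in fh if line.strip()]
    if not lines:
        raise SchemaError(f"{path}: empty sample sheet")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    required = ["sample_id", "strain", "condition", "replicate"]
    if header[: len(required)] != required:
        raise SchemaError(
            f"{path}: header must start with {required}, got {header}"
        )
    descriptors: list[SampleDescriptor] = []
    seen_triples: set[tuple[Strain, Condition, int]] = set()
    seen_ids: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        if len(fields) < 4:
            raise SchemaError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
        sample_id = fields[0].strip()
        strain = _parse_enum(Strain, fields[1], lineno, path)
        condition = _parse_enum(Condition, fields[2], lineno, path)
        try:
            rep = int(fields[3])
        except ValueError:
            raise SchemaError(
                f"{path}:{lineno}: replicate must be an integer, got {fields[3]!r}"
            ) from None
        triple = (strain, condition, rep)
        if triple in seen_triples:
            raise SchemaError(
                f"{path}:{lineno}: duplicate (strain, condition, replicate) "
                f"triple ({strain.name}, {condition.name}, {rep})"
            )
        if sample_id in seen_ids:
            raise SchemaError(f"{path}:{lineno}: duplicate sample_id {sample_id!r}")
        seen_triples.add(triple)
        seen_ids.add(sample_id)
        descriptors.append(SampleDescriptor(sample_id, strain, condition, rep))
    logger.info("read %s: %d sample descriptors", path, len(descriptors))
    return descriptors


def write_sample_sheet(samples: Sequence[SampleDescriptor], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("sample_id\tstrain\tcondition\treplicate\n")
        for s in samples:
            fh.write(f"{s.sample_id}\t{s.strain.name}\t{s.condition.name}\t{s.replicate}\n")


def match_samples(
    matrix: ExpressionMatrix, samples: Sequence[SampleDescriptor]
) -> dict[str, SampleDescriptor]:
    """Map every matrix column to its descriptor; error on unmatched columns."""
    by_id = {s.sample_id: s for s in samples}
    if len(by_id) != len(samples):
        raise SchemaError("sample sheet contains duplicate sample ids")
    missing = [sid for sid in matrix.sample_ids if sid not in by_id]
    if missing:
        raise SchemaError(f"matrix samples without a descriptor: {missing}")
    return {sid: by_id[sid] for sid in matrix.sample_ids}


# --- classification report -------------------------------------------------

_REPORT_COLUMNS = [
    "gene",
    "direction",
    "ref_factor",
    "msn_factor",
    "yak_factor",
    "activation_factor",
    "ref_responsive",
    "strength",
    "supporting_strain",
    "pka_class",
    "class_flag",
    "transience",
    "gluconeogenic",
    "suppressor_balance",
    "floored",
]


def write_classification_report(profiles: Sequence, path: str | Path) -> None:
    """Write one row per gene regulatory profile plus a JSON count sidecar.

    The sidecar (``<path>.summary.json``) holds category counts for
    machine consumption; the TSV carries full-precision factors.
    """
    if not profiles:
        raise ValueError("no profiles to report")
    path = Path(path)

    def fmt(value) -> str:
        if value is None:
            return "NA"
        if isinstance(value, bool):
            return str(value).lower()
        if isinstance(value, float):
            return repr(value)
        if isinstance(value, Enum):
            return value.name
        return str(value)

    with path.open("w") as fh:
        fh.write("\t".join(_REPORT_COLUMNS) + "\n")
        for p in profiles:
            fh.write("\t".join(fmt(getattr(p, c)) for c in _REPORT_COLUMNS) + "\n")

    summary = {
        "n_genes": len(profiles),
        "pka_class": _count(profiles, "pka_class"),
        "strength": _count(profiles, "strength"),
        "transience": _count(profiles, "transience"),
        "gluconeogenic": _count(profiles, "gluconeogenic"),
        "direction": _count(profiles, "direction"),
    }
    sidecar = path.with_suffix(path.suffix + ".summary.json")
    sidecar.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    logger.info("wrote %s (%d rows) and %s", path, len(profiles), sidecar)


def _count(profiles: Sequence, attr: str) -> dict[str, int]:
    counts: dict[str, int] = {}
    for p in profiles:
        value = getattr(p, attr)
        key = value.name if isinstance(value, Enum) else ("NA" if value is None else str(value))
        counts[key] = counts.get(key, 0) + 1
    return dict(sorted(counts.items()))


def read_classification_report(path: str | Path) -> pd.DataFrame:
    """Re-read a written report as a DataFrame (labels as strings)."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if list(frame.columns) != _REPORT_COLUMNS:
        raise FormatError(f"{path}: unexpected report columns {list(frame.columns)}")
    for col in ("ref_factor", "msn_factor", "yak_factor", "activation_factor"):
        # float() round-trips repr() exactly; pd.to_numeric may lose an ulp
        frame[col] = frame[col].map(lambda v: np.nan if v == "NA" else float(v))
    return frame
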