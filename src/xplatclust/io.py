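"""Readers and writers for the tabular and sequence formats the pipeline touches.

Expression matrices travel as TSV with genes as rows and samples as columns.
Sample names follow the grammar ``t{hours}_r{replicate}`` (e.g. ``t4_r1`` for
the 4 h sample, replicate 1); hours may be any nonnegative number and every
matrix must contain at least one sample at the 0 h baseline.  Annotations are
two-column TSVs of (gene, functional class) pairs, one row per pair.  Promoter
regions are plain FASTA over the alphabet ACGTN.

All readers validate strictly: what a writer of this package never emits, the
corresponding reader rejects with a :class:`FormatError` naming the offending
record.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "AnnotationTable",
    "parse_sample_name",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_annotation_tsv",
    "write_annotation_tsv",
    "read_fasta",
    "write_fasta",
]


class FormatError(ValueError):
    """A file violates the package's format contracts."""


_SAMPLE_RE = re.compile(r"^t(?P<time>\d+(?:\.\d+)?)_r(?P<rep>\d+)$")

PLATFORMS = ("array", "counts")


def parse_sample_name(name: str) -> tuple[float, int]:
    """Parse ``t{hours}_r{rep}`` into (hours, replicate).

    >>> parse_sample_name("t18_r2")
    (18.0, 2)
    """
    m = _SAMPLE_RE.match(name)
    if m is None:
        raise FormatError(
            f"sample name {name!r} does not match the t{{hours}}_r{{rep}} grammar"
        )
    return float(m.group("time")), int(m.group("rep"))


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values for one platform.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns named per the sample grammar.
        For the ``counts`` platform all values must be nonnegative integers
        (stored as floats is permitted as long as they are integral).
    platform
        ``"array"`` (intensity-valued) or ``"counts"``.
    """

    values: pd.DataFrame
    platform: str

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"platform must be one of {PLATFORMS}, got {self.platform!r}")
        idx = self.values.index
        if idx.duplicated().any():
            dup = sorted(set(idx[idx.duplicated()]))
            raise FormatError(f"duplicate gene id(s): {', '.join(map(str, dup))}")
        # parse (and thereby validate) every sample name
        meta = self.sample_meta
        if not (meta["time"] == 0).any():
            raise FormatError("no sample at the 0 h baseline time")
        vals = self.values.to_numpy()
        if not np.isfinite(vals).all():
            raise FormatError("expression values must be finite")
        if self.platform == "counts":
            if (vals < 0).any() or not np.array_equal(vals, np.rint(vals)):
                bad = np.argwhere((vals < 0) | (vals != np.rint(vals)))[0]
                raise FormatError(
                    "counts platform requires nonnegative integers; offending value "
                    f"at gene {self.values.index[bad[0]]!r}, "
                    f"sample {self.values.columns[bad[1]]!r}"
                )

    @property
    def sample_meta(self) -> pd.DataFrame:
        """Per-sample metadata parsed from column names (time, replicate, platform)."""
        parsed = [parse_sample_name(c) for c in self.values.columns]
        return pd.DataFrame(
            {
                "time": [p[0] for p in parsed],
                "replicate": [p[1] for p in parsed],
                "platform": self.platform,
            },
            index=self.values.columns,
        )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def times(self) -> list[float]:
        """Sorted unique time points (hours)."""
        return sorted(set(self.sample_meta["time"]))


@dataclass
class AnnotationTable:
    """Mapping from gene id to a set of functional class labels.

    Genes may be unannotated (absent from the mapping); a gene may carry
    several classes.  ``vocabulary`` is the declared label universe; labels in
    ``mapping`` outside it are rejected at construction.
    """

    mapping: dict[str, set[str]]
    vocabulary: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        for gene, classes in self.mapping.items():
            if not classes:
                raise FormatError(f"gene {gene!r} has an empty class set")
            if self.vocabulary is not None:
                unknown = classes - set(self.vocabulary)
                if unknown:
                    raise FormatError(
                        f"gene {gene!r} carries label(s) outside the declared "
                        f"vocabulary: {sorted(unknown)}"
                    )

    def classes_of(self, gene: str) -> set[str]:
        return set(self.mapping.get(gene, set()))

    @property
    def all_classes(self) -> list[str]:
        if self.vocabulary is not None:
            return list(self.vocabulary)
        out: set[str] = set()
        for classes in self.mapping.values():
            out |= classes
        return sorted(out)

    def __len__(self) -> int:
        return len(self.mapping)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        return self.mapping == other.mapping


def read_expression_tsv(path, platform: str) -> ExpressionMatrix:
    """Read a gene x sample expression TSV.

    The first column holds gene ids; remaining column names encode time and
    replicate as ``t{hours}_r{rep}``.  Raises :class:`FormatError` on duplicate
    gene ids, a missing baseline, or (counts platform) non-integer values.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns")
    df.index = df.index.astype(str)
    df = df.astype(float)
    return ExpressionMatrix(values=df, platform=platform)


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    if matrix.platform == "counts":
        out = out.astype(np.int64)
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_annotation_tsv(path, vocabulary: tuple[str, ...] | None = None) -> AnnotationTable:
    """Read a two-column (gene_id, class) TSV into an :class:`AnnotationTable`.

    A header line ``gene_id<TAB>class`` is accepted and skipped.  Multi-class
    genes are aggregated into sets.
    """
    mapping: dict[str, set[str]] = {}
    n_rows = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if lineno == 1 and parts[:2] == ["gene_id", "class"]:
                continue
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise FormatError(f"{path}: malformed annotation row at line {lineno}")
            mapping.setdefault(parts[0], set()).add(parts[1])
            n_rows += 1
    if n_rows == 0:
        raise FormatError(f"{path}: empty annotation file")
    return AnnotationTable(mapping=mapping, vocabulary=vocabulary)


def write_annotation_tsv(table: AnnotationTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tclass\n")
        for gene in sorted(table.mapping):
            for cls in sorted(table.mapping[gene]):
                fh.write(f"{gene}\t{cls}\n")


_FASTA_ALPHABET = set("ACGTN")


def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as an ordered list of (id, uppercased sequence).

    Sequences must be over ACGTN (case-insensitive); ids must be unique.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        for pos, ch in enumerate(seq, start=1):
            if ch not in _FASTA_ALPHABET:
                raise FormatError(
                    f"{path}: illegal character {ch!r} in record {rec.id!r} at position {pos}"
                )
        records.append((rec.id, seq))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    return records


def write_fasta(records: list[tuple[str, str]], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
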