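"""Shared data model and tab-separated I/O.

The pipeline moves label-free MS quantifications around as :class:`QuantMatrix`
objects: a features x samples table of raw-scale intensities in which a missing
value (``NaN`` in memory, ``NA`` or an empty cell on disk) means *not detected*
and is never imputed or confused with zero. Protein sequences travel as
:class:`ProteinRecord`, the experimental layout as a list of
:class:`SampleDesign`, and glycosylation sites are addressed by
:class:`SiteKey` — 1-based protein coordinates with the Asn residue itself as
the position, matching UniProt site conventions.

All on-disk formats are plain tab-separated text with a header line; FASTA is
read through Bio.SeqIO.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: X is tolerated in input sequences (unknown residue from database searches).
SEQUENCE_ALPHABET = AMINO_ACIDS | {"X"}

CONTROL = "control"
MUTANT = "mutant"
GENOTYPES = (CONTROL, MUTANT)

FeatureKind = Literal["protein", "glycosite", "unmodified_peptide"]

#: strings treated as a missing cell on read; "NA" is written back out.
NA_VALUES = ("", "NA")


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier, its amino-acid sequence and annotation labels."""

    protein_id: str
    sequence: str
    annotations: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.protein_id or any(c.isspace() for c in self.protein_id):
            raise ParseError(f"protein id {self.protein_id!r} must be a non-empty token")
        if len(self.sequence) < 1:
            raise ParseError(f"protein {self.protein_id}: empty sequence")
        bad = set(self.sequence) - SEQUENCE_ALPHABET
        if bad:
            raise ParseError(
                f"protein {self.protein_id}: invalid residue(s) {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


class SiteKey(NamedTuple):
    """Address of one Asn residue: (protein_id, 1-based position of the Asn)."""

    protein_id: str
    position: int

    def __str__(self) -> str:
        return f"{self.protein_id}:{self.position}"

    @classmethod
    def parse(cls, feature_id: str) -> "SiteKey":
        pid, sep, pos = feature_id.rpartition(":")
        if not sep or not pid:
            raise ParseError(f"feature id {feature_id!r} is not '<protein_id>:<position>'")
        try:
            position = int(pos)
        except ValueError as exc:
            raise ParseError(f"feature id {feature_id!r}: position is not an integer") from exc
        if position < 1:
            raise ParseError(f"feature id {feature_id!r}: position must be >= 1")
        return cls(pid, position)


@dataclass(frozen=True)
class SampleDesign:
    """One MS sample: id, genotype and litter/batch pairing."""

    sample_id: str
    genotype: str
    pair_id: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ParseError(
                f"sample {self.sample_id}: genotype {self.genotype!r} not in {GENOTYPES}"
            )
        if self.pair_id < 1:
            raise ParseError(f"sample {self.sample_id}: pair_id must be >= 1")


def validate_design(design: Sequence[SampleDesign], paired: bool = False) -> None:
    """Check sample-id uniqueness and, if *paired*, the one-per-genotype pairing."""
    ids = [s.sample_id for s in design]
    if len(set(ids)) != len(ids):
        raise ParseError("duplicate sample ids in design")
    if paired:
        for genotype in GENOTYPES:
            pairs = [s.pair_id for s in design if s.genotype == genotype]
            if sorted(pairs) != sorted(set(pairs)):
                raise ParseError(f"pair_id repeated within genotype {genotype!r}")
        ctrl = {s.pair_id for s in design if s.genotype == CONTROL}
        mut = {s.pair_id for s in design if s.genotype == MUTANT}
        if ctrl != mut:
            raise ParseError("paired design requires every pair_id once per genotype")


class QuantMatrix:
    """Features x samples raw-scale intensity table with explicit missingness.

    ``values`` is a pandas DataFrame whose index are feature ids and whose
    columns follow the order of ``design``. ``NaN`` encodes MISSING (not
    detected); detected intensities are finite and >= 0. Intensities stay on
    the raw scale — statistical routines log2-transform internally so that I/O
    is lossless.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        design: Sequence[SampleDesign],
        feature_kind: FeatureKind,
    ) -> None:
        validate_design(design)
        expected = [s.sample_id for s in design]
        if list(values.columns) != expected:
            if set(values.columns) != set(expected):
                unknown = set(values.columns) ^ set(expected)
                raise ParseError(f"sample columns do not match design: {sorted(unknown)}")
            values = values[expected]
        if values.index.has_duplicates:
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise ParseError(f"duplicate feature ids: {dupes[:5]}")
        arr = values.to_numpy(dtype=float)
        finite = np.isfinite(arr) | np.isnan(arr)
        if not finite.all():
            raise ParseError("intensities must be finite or missing")
        with np.errstate(invalid="ignore"):
            if (arr < 0).any():
                raise ParseError("negative intensity encountered")
        self.values = values.astype(float)
        self.design = list(design)
        self.feature_kind: FeatureKind = feature_kind

    # -- views ------------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def columns_for(self, genotype: str) -> list[str]:
        return [s.sample_id for s in self.design if s.genotype == genotype]

    @property
    def control_columns(self) -> list[str]:
        return self.columns_for(CONTROL)

    @property
    def mutant_columns(self) -> list[str]:
        return self.columns_for(MUTANT)

    def detected(self) -> pd.DataFrame:
        """Boolean detection mask (True where a value was observed)."""
        return self.values.notna()

    def n_detected(self, genotype: str) -> pd.Series:
        return self.values[self.columns_for(genotype)].notna().sum(axis=1)

    def log2(self) -> pd.DataFrame:
        """log2 intensities with MISSING preserved as NaN (never log of 0)."""
        with np.errstate(divide="ignore"):
            return np.log2(self.values)

    def subset(self, feature_ids: Iterable[str]) -> "QuantMatrix":
        return QuantMatrix(self.values.loc[list(feature_ids)], self.design, self.feature_kind)

    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, QuantMatrix):
            return NotImplemented
        return (
            self.feature_kind == other.feature_kind
            and self.design == other.design
            and self.values.equals(other.values)
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a (possibly multi-line) FASTA file into ProteinRecords.

    Sequences are upper-cased; duplicate ids and empty sequences are rejected
    with the offending line named.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: dict[str, int] = {}
    header_lines = _fasta_header_lines(path)
    with path.open() as handle:
        for i, rec in enumerate(SeqIO.parse(handle, "fasta")):
            line_no = header_lines[i] if i < len(header_lines) else -1
            if not rec.id:
                raise ParseError(f"{path}:{line_no}: malformed FASTA header")
            if rec.id in seen:
                raise ParseError(
                    f"{path}:{line_no}: duplicate protein id {rec.id!r} "
                    f"(first seen at line {seen[rec.id]})"
                )
            seq = str(rec.seq).upper()
            if not seq:
                raise ParseError(f"{path}:{line_no}: empty sequence for {rec.id!r}")
            seen[rec.id] = line_no
            records.append(ProteinRecord(rec.id, seq))
    if not records and path.stat().st_size > 0:
        raise ParseError(f"{path}:1: no FASTA records found")
    return records


def _fasta_header_lines(path: Path) -> list[int]:
    out = []
    with path.open() as fh:
        for n, line in enumerate(fh, start=1):
            if line.startswith(">"):
                out.append(n)
            elif line.strip() and not out:
                raise ParseError(f"{path}:{n}: sequence data before any FASTA header")
    return out


def write_fasta(proteins: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with Path(path).open("w") as fh:
        for p in proteins:
            fh.write(f">{p.protein_id}\n")
            for i in range(0, len(p.sequence), width):
                fh.write(p.sequence[i : i + width] + "\n")


def read_design_table(path: str | Path) -> list[SampleDesign]:
    """Read the sample design TSV (columns sample_id, genotype, pair_id)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "genotype": str})
    required = {"sample_id", "genotype", "pair_id"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: design table needs columns {sorted(required)}")
    design = [
        SampleDesign(row.sample_id, row.genotype, int(row.pair_id))
        for row in df.itertuples(index=False)
    ]
    validate_design(design)
    return design


def write_design_table(design: Sequence[SampleDesign], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in design],
            "genotype": [s.genotype for s in design],
            "pair_id": [s.pair_id for s in design],
        }
    ).to_csv(path, sep="\t", index=False)


def read_quant_table(
    path: str | Path,
    design: Sequence[SampleDesign],
    kind: FeatureKind,
) -> QuantMatrix:
    """Read a features x samples TSV; empty cells or ``NA`` are MISSING.

    Columns may come in any order but must match the design's sample ids
    exactly; the returned matrix follows the design order.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=list(NA_VALUES),
        keep_default_na=False,
    )
    expected = {s.sample_id for s in design}
    unknown = set(df.columns) - expected
    missing = expected - set(df.columns)
    if unknown:
        raise ParseError(f"{path}: unknown sample column(s) {sorted(unknown)}")
    if missing:
        raise ParseError(f"{path}: design sample(s) absent from table: {sorted(missing)}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ParseError(f"{path}: non-numeric intensity in column {col!r}")
    try:
        return QuantMatrix(df, design, kind)
    except ParseError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_quant_table(matrix: QuantMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = out.index.name or "feature_id"
    out.to_csv(path, sep="\t", na_rep="NA")


# ---------------------------------------------------------------------------
# generic result tables
# ---------------------------------------------------------------------------

def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as TSV with a header; round-trips through
    :func:`read_results` (floats keep full precision, MISSING becomes NA)."""
    out = results.copy()
    if out.index.name is not None:
        out = out.reset_index()
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=list(NA_VALUES), keep_default_na=False)


def read_known_sites(path: str | Path) -> set[SiteKey]:
    """Read a two-column (protein_id, position) TSV of known glycosites."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if len(cols) < 2:
        raise ParseError(f"{path}: known-site list needs columns protein_id, position")
    out = set()
    for row in df.itertuples(index=False):
        pos = int(row[1])
        if pos < 1:
            raise ParseError(f"{path}: position {pos} must be >= 1")
        out.add(SiteKey(str(row[0]), pos))
    return out


def write_known_sites(sites: Iterable[SiteKey], path: str | Path) -> None:
    rows = sorted(sites)
    pd.DataFrame(rows, columns=["protein_id", "position"]).to_csv(
        path, sep="\t", index=False
    )


def proteins_by_id(proteins: Iterable[ProteinRecord]) -> dict[str, ProteinRecord]:
    out: dict[str, ProteinRecord] = {}
    for p in proteins:
        if p.protein_id in out:
            raise ParseError(f"duplicate protein id {p.protein_id!r}")
        out[p.protein_id] = p
    return out
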