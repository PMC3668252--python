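"""Alignment and table I/O, the character alphabet, and IUPAC semantics.

Conventions used throughout the package:

* columns are 0-based, intervals half-open ``[start, end)``;
* the haplotype alphabet is ``{A, C, G, T, -, N}``; rows whose role is
  ``diploid_consensus`` may additionally carry the six two-base IUPAC
  ambiguity codes ``{R, Y, S, W, K, M}`` (a diploid superimposes at most two
  bases, so three- and four-fold codes are rejected);
* ``-`` is an alignment gap, ``N`` is missing/unreadable data.

A direct-sequencing consensus with a two-base code at a site is the in-silico
abstraction of a chromatogram showing both parental peaks ("additivity").
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

from .errors import AlignmentError, AlphabetError, MetadataError

__all__ = [
    "Taxon",
    "Role",
    "SampleRecord",
    "SiteAlignment",
    "GerminationRecord",
    "iupac_union",
    "iupac_split",
    "read_fasta_alignment",
    "read_germination_table",
    "write_tables",
]

BASES = ("A", "C", "G", "T")

#: two-base ambiguity codes only — the diploid case
PAIR_TO_CODE: Mapping[frozenset, str] = {
    frozenset("AG"): "R",
    frozenset("CT"): "Y",
    frozenset("CG"): "S",
    frozenset("AT"): "W",
    frozenset("GT"): "K",
    frozenset("AC"): "M",
}
CODE_TO_PAIR: Mapping[str, frozenset] = {c: p for p, c in PAIR_TO_CODE.items()}

HAPLOTYPE_ALPHABET = frozenset("ACGT-N")
AMBIGUITY_CODES = frozenset(CODE_TO_PAIR)
CONSENSUS_ALPHABET = HAPLOTYPE_ALPHABET | AMBIGUITY_CODES
_MULTIFOLD = frozenset("BDHV")


class Taxon(str, enum.Enum):
    SPECIES_A = "species_A"
    SPECIES_B = "species_B"
    HYBRID = "hybrid"
    UNKNOWN = "unknown"


class Role(str, enum.Enum):
    HAPLOTYPE = "haplotype"
    DIPLOID_CONSENSUS = "diploid_consensus"


def iupac_union(base1: str, base2: str) -> str:
    """Code for the superposition of two unambiguous bases.

    Returns the base itself when the two are equal; symmetric in its
    arguments. Gaps and N are not bases and are rejected.
    """
    if base1 not in BASES or base2 not in BASES:
        raise AlphabetError(
            f"iupac_union requires unambiguous bases, got {base1!r}, {base2!r}"
        )
    if base1 == base2:
        return base1
    return PAIR_TO_CODE[frozenset((base1, base2))]


def iupac_split(code: str) -> frozenset:
    """Set of unambiguous bases a code stands for; inverse of iupac_union.

    ``N`` expands to all four bases.
    """
    if code in BASES:
        return frozenset((code,))
    if code in CODE_TO_PAIR:
        return CODE_TO_PAIR[code]
    if code == "N":
        return frozenset(BASES)
    raise AlphabetError(f"unsupported IUPAC code {code!r}")


@dataclass(frozen=True)
class SampleRecord:
    """Metadata for one aligned row.

    ``readable_prefix`` is the number of leading columns readable before a
    heterozygous-indel frame shift made the trace uninterpretable; ``None``
    means the whole row is readable.
    """

    sample_id: str
    taxon: Taxon
    population: str
    role: Role
    readable_prefix: int | None = None


@dataclass(frozen=True)
class GerminationRecord:
    taxon: str
    germinated: int
    total: int

    def __post_init__(self):
        if self.total <= 0:
            raise MetadataError(f"{self.taxon}: spore total must be positive")
        if not 0 <= self.germinated <= self.total:
            raise MetadataError(
                f"{self.taxon}: germinated ({self.germinated}) outside "
                f"[0, {self.total}]"
            )


@dataclass(frozen=True)
class SiteAlignment:
    """A per-locus multiple sequence alignment with sample metadata."""

    locus_name: str
    samples: tuple[SampleRecord, ...]
    matrix: tuple[str, ...]

    def __post_init__(self):
        if len(self.samples) != len(self.matrix):
            raise AlignmentError(
                f"{self.locus_name}: {len(self.samples)} sample records for "
                f"{len(self.matrix)} rows"
            )
        if not self.matrix:
            raise AlignmentError(f"{self.locus_name}: empty alignment")
        ncol = len(self.matrix[0])
        if ncol < 1:
            raise AlignmentError(f"{self.locus_name}: zero-length alignment")
        seen: set[str] = set()
        for rec, row in zip(self.samples, self.matrix):
            if len(row) != ncol:
                raise AlignmentError(
                    f"{self.locus_name}: ragged alignment — row "
                    f"{rec.sample_id} has length {len(row)}, expected {ncol}"
                )
            if rec.sample_id in seen:
                raise MetadataError(
                    f"{self.locus_name}: duplicate sample_id {rec.sample_id}"
                )
            seen.add(rec.sample_id)
            allowed = (
                CONSENSUS_ALPHABET
                if rec.role is Role.DIPLOID_CONSENSUS
                else HAPLOTYPE_ALPHABET
            )
            bad = set(row) - allowed
            if bad:
                detail = (
                    "3/4-fold ambiguity codes are not produced by a diploid "
                    "and are rejected"
                    if bad & _MULTIFOLD
                    else "outside the alignment alphabet"
                )
                raise AlphabetError(
                    f"{self.locus_name}/{rec.sample_id}: illegal character(s) "
                    f"{sorted(bad)} — {detail}"
                )
            if rec.readable_prefix is not None and not (
                0 <= rec.readable_prefix <= ncol
            ):
                raise MetadataError(
                    f"{self.locus_name}/{rec.sample_id}: readable_prefix "
                    f"{rec.readable_prefix} outside [0, {ncol}]"
                )

    @property
    def columns(self) -> int:
        return len(self.matrix[0])

    def row(self, sample_id: str) -> str:
        for rec, row in zip(self.samples, self.matrix):
            if rec.sample_id == sample_id:
                return row
        raise KeyError(sample_id)

    def record(self, sample_id: str) -> SampleRecord:
        for rec in self.samples:
            if rec.sample_id == sample_id:
                return rec
        raise KeyError(sample_id)

    def subset(
        self,
        roles: Iterable[Role] | None = None,
        taxa: Iterable[Taxon] | None = None,
    ) -> "SiteAlignment":
        roles = set(roles) if roles is not None else None
        taxa = set(taxa) if taxa is not None else None
        keep = [
            i
            for i, rec in enumerate(self.samples)
            if (roles is None or rec.role in roles)
            and (taxa is None or rec.taxon in taxa)
        ]
        return replace(
            self,
            samples=tuple(self.samples[i] for i in keep),
            matrix=tuple(self.matrix[i] for i in keep),
        )


_SHEET_COLUMNS = ("sample_id", "taxon", "population", "role")


def _read_sample_sheet(
    path: str | Path, taxon_map: Mapping[str, str] | None
) -> dict[str, SampleRecord]:
    sheet = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise MetadataError(f"sample sheet {path}: missing columns {missing}")
    records: dict[str, SampleRecord] = {}
    for _, row in sheet.iterrows():
        label = row["taxon"]
        if taxon_map and label in taxon_map:
            label = taxon_map[label]
        try:
            taxon = Taxon(label)
        except ValueError:
            raise MetadataError(
                f"sample sheet {path}: taxon label {row['taxon']!r} not one of "
                f"{[t.value for t in Taxon]} and not in the taxon map"
            ) from None
        try:
            role = Role(row["role"])
        except ValueError:
            raise MetadataError(
                f"sample sheet {path}: unknown role {row['role']!r}"
            ) from None
        rp_raw = str(row.get("readable_prefix", "")).strip()
        rp = int(rp_raw) if rp_raw not in ("", "nan") else None
        records[row["sample_id"]] = SampleRecord(
            sample_id=row["sample_id"],
            taxon=taxon,
            population=row["population"],
            role=role,
            readable_prefix=rp,
        )
    return records


def read_fasta_alignment(
    path: str | Path,
    sample_sheet: str | Path,
    locus_name: str | None = None,
    taxon_map: Mapping[str, str] | None = None,
) -> SiteAlignment:
    """Read a gapped FASTA alignment plus its sample sheet.

    Characters are uppercased and ``U`` mapped to ``T``. Every FASTA id must
    appear in the sheet; row order follows the FASTA file.
    """
    path = Path(path)
    records = _read_sample_sheet(sample_sheet, taxon_map)
    samples: list[SampleRecord] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id not in records:
            raise MetadataError(
                f"{path}: FASTA id {rec.id!r} missing from sample sheet"
            )
        samples.append(records[rec.id])
        rows.append(str(rec.seq).upper().replace("U", "T"))
    if not rows:
        raise AlignmentError(f"{path}: no FASTA records")
    return SiteAlignment(
        locus_name=locus_name or path.stem,
        samples=tuple(samples),
        matrix=tuple(rows),
    )


def write_fasta_alignment(aln: SiteAlignment, path: str | Path) -> Path:
    """Write an alignment back to FASTA (one line per sequence) plus nothing
    else; pair with :func:`write_sample_sheet` for a full round trip."""
    path = Path(path)
    with open(path, "w", newline="\n") as fh:
        for rec, row in zip(aln.samples, aln.matrix):
            fh.write(f">{rec.sample_id}\n{row}\n")
    return path


def write_sample_sheet(aln: SiteAlignment, path: str | Path) -> Path:
    frame = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in aln.samples],
            "taxon": [r.taxon.value for r in aln.samples],
            "population": [r.population for r in aln.samples],
            "role": [r.role.value for r in aln.samples],
            "readable_prefix": [
                "" if r.readable_prefix is None else r.readable_prefix
                for r in aln.samples
            ],
        }
    )
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return Path(path)


def read_germination_table(path: str | Path) -> list[GerminationRecord]:
    frame = pd.read_csv(path, sep="\t")
    for col in ("taxon", "germinated", "total"):
        if col not in frame.columns:
            raise MetadataError(f"germination table {path}: missing {col!r}")
    return [
        GerminationRecord(str(r.taxon), int(r.germinated), int(r.total))
        for r in frame.itertuples()
    ]


def write_tables(
    tables: Mapping[str, pd.DataFrame], out_dir: str | Path
) -> list[Path]:
    """Write named DataFrames as byte-stable TSVs.

    Column order is taken from each frame as-is; floats use a fixed ``%.6g``
    format and lines end with LF, so writing the same object twice yields
    byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name in tables:
        target = out_dir / f"{name}.tsv"
        tables[name].to_csv(
            target,
            sep="\t",
            index=False,
            float_format="%.6g",
            lineterminator="\n",
        )
        written.append(target)
    return written
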