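"""Reading, validating and writing species-labelled protein FASTA files.

The unit of everything downstream is a :class:`Proteome`: an ordered
collection of protein sequences that all belong to one community member
species.  The species label is always supplied by the caller, never parsed
out of FASTA headers, because header dialects vary wildly between
annotation services while the unit of peptide disjointness is the species.

Sequences are normalised on input: uppercased, whitespace stripped and
trailing stop characters (``*``) removed.  Ambiguity codes (B, X, Z, U, O)
are accepted because real annotated proteomes contain them, but an internal
``*`` is always an error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

#: the 20 standard amino acids
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")
#: ambiguity / non-standard codes tolerated on input (Asx, any, Glx, Sec, Pyl)
AMBIGUOUS_RESIDUES = frozenset("BXZUO")
VALID_RESIDUES = STANDARD_RESIDUES | AMBIGUOUS_RESIDUES


class FastaFormatError(ValueError):
    """Raised when a FASTA file violates the input contract."""


def clean_sequence(raw: str) -> str:
    """Normalise a raw amino-acid string.

    Uppercases, strips whitespace, and removes terminal stop characters.
    An internal ``*`` is an error (it would indicate a frame problem in the
    annotation rather than a conventional trailing stop).
    """
    seq = "".join(raw.split()).upper().rstrip("*")
    if "*" in seq:
        raise FastaFormatError("internal stop character '*' in sequence")
    return seq


@dataclass
class ProteinRecord:
    """One protein sequence carrying its species label.

    ``sequence`` may be empty only for records that were trimmed down to
    nothing; such records are kept for reporting but omitted when writing
    FASTA output.
    """

    protein_id: str
    description: str
    sequence: str
    species: str

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def has_ambiguous(self) -> bool:
        return any(c in AMBIGUOUS_RESIDUES for c in self.sequence)

    def validate(self, invalid_residues: str = "warn") -> None:
        """Check the input invariants for a freshly loaded record.

        Parameters
        ----------
        invalid_residues:
            ``"error"`` rejects characters outside the accepted alphabet,
            ``"warn"`` logs and keeps them.
        """
        if not self.sequence:
            raise FastaFormatError(f"{self.protein_id}: empty sequence")
        if any(c.isspace() for c in self.protein_id) or not self.protein_id:
            raise FastaFormatError(f"invalid protein id {self.protein_id!r}")
        bad = set(self.sequence) - VALID_RESIDUES
        if bad:
            msg = (
                f"{self.species}/{self.protein_id}: residues outside accepted "
                f"alphabet: {''.join(sorted(bad))}"
            )
            if invalid_residues == "error":
                raise FastaFormatError(msg)
            logger.warning(msg)


@dataclass
class Proteome:
    """Ordered protein records of a single species.

    Record order is preserved from input to output so that trimmed
    proteomes line up with their sources.
    """

    species: str
    records: list[ProteinRecord] = field(default_factory=list)

    def __iter__(self) -> Iterator[ProteinRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, i):
        return self.records[i]

    @property
    def protein_ids(self) -> list[str]:
        return [r.protein_id for r in self.records]

    def n_residues(self) -> int:
        return sum(len(r) for r in self.records)

    def check(self) -> None:
        ids = set()
        for rec in self.records:
            if rec.species != self.species:
                raise ValueError(
                    f"record {rec.protein_id} labelled {rec.species!r} inside "
                    f"proteome {self.species!r}"
                )
            if rec.protein_id in ids:
                raise FastaFormatError(f"duplicate protein id {rec.protein_id!r}")
            ids.add(rec.protein_id)


def read_fasta(
    path: str | Path,
    species: str,
    invalid_residues: str = "warn",
) -> Proteome:
    """Load one species' reference proteome from a FASTA file.

    Sequences are uppercased and trailing ``*`` stripped.  Duplicate
    identifiers within a file, empty files and internal stop characters are
    errors; residues outside the accepted alphabet are rejected or kept with
    a warning according to ``invalid_residues``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        desc = entry.description
        if desc.startswith(entry.id):
            desc = desc[len(entry.id):].strip()
        rec = ProteinRecord(
            protein_id=entry.id,
            description=desc,
            sequence=clean_sequence(str(entry.seq)),
            species=species,
        )
        rec.validate(invalid_residues=invalid_residues)
        if rec.protein_id in seen:
            raise FastaFormatError(f"{path}: duplicate protein id {rec.protein_id!r}")
        seen.add(rec.protein_id)
        records.append(rec)
    if not records:
        raise FastaFormatError(f"{path}: no FASTA entries found")
    return Proteome(species=species, records=records)


def write_fasta(proteome: Proteome, path: str | Path, width: int = 60) -> int:
    """Write a proteome to FASTA, wrapped at ``width`` columns.

    Records whose sequence is empty (proteins trimmed to nothing) are
    omitted with a warning -- search engines reject empty entries -- but
    remain available in the tabular trim reports.  Returns the number of
    records written.
    """
    path = Path(path)
    n_written = 0
    with open(path, "w", encoding="utf-8") as fh:
        for rec in proteome:
            if not rec.sequence:
                logger.warning(
                    "%s/%s trimmed to zero length; omitted from FASTA output",
                    rec.species, rec.protein_id,
                )
                continue
            header = f">{rec.protein_id} {rec.description}".rstrip()
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")
            n_written += 1
    if n_written == 0:
        logger.warning("%s: wrote an empty FASTA file", path)
    return n_written


#: sort keys applied (in this order, when present) before writing any report
_REPORT_SORT_KEYS = ("species", "protein_id", "start")


def write_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write a tabular report as tab-separated UTF-8 with a header line.

    Row order is made deterministic by sorting on species, then protein_id,
    then start coordinate (whichever of those columns exist).
    """
    df = pd.DataFrame(rows)
    keys = [k for k in _REPORT_SORT_KEYS if k in df.columns]
    if keys and len(df):
        df = df.sort_values(keys, kind="stable")
    df.to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a report written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t", encoding="utf-8")
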