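"""Deterministic in-silico tryptic digestion with sequence coordinates.

Two cleavage rules are provided:

``trypsin_strict``
    cleave C-terminally of K or R, suppressed when the next residue is
    proline (the convention used by common digestion tools and search
    engines).
``trypsin_p``
    cleave after every K or R regardless of the following residue.

Coordinates are 0-based half-open throughout the library
(``sequence[start:end] == peptide``); human-facing reports render 1-based
inclusive positions.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .proteome_io import AMBIGUOUS_RESIDUES, Proteome

TRYPSIN_STRICT = "trypsin_strict"
TRYPSIN_P = "trypsin_p"
RULES = (TRYPSIN_STRICT, TRYPSIN_P)


@dataclass(frozen=True)
class DigestParams:
    """Digestion settings.

    Defaults (no missed cleavages, minimum peptide length 7) are the
    settings of the reference-proteome trimming workflow: shorter peptides
    are in most cases incompatible with MS identification, and sharing is
    evaluated on fully cleaved products.
    """

    rule: str = TRYPSIN_STRICT
    missed_cleavages: int = 0
    min_len: int = 7

    def __post_init__(self) -> None:
        if self.rule not in RULES:
            raise ValueError(f"unknown cleavage rule {self.rule!r}; choose from {RULES}")
        if self.missed_cleavages < 0:
            raise ValueError("missed_cleavages must be >= 0")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


@dataclass(frozen=True)
class PeptideOccurrence:
    """One peptide at one position of one parent protein.

    ``start``/``end`` are 0-based half-open on the parent sequence;
    ``n_missed`` counts internal uncleaved sites spanned by the peptide.
    """

    peptide: str
    species: str
    protein_id: str
    start: int
    end: int
    n_missed: int = 0

    def __len__(self) -> int:
        return self.end - self.start


def cleavage_sites(sequence: str, rule: str) -> list[int]:
    """Internal cut positions: a site at ``i`` means a cut between
    ``sequence[i-1]`` and ``sequence[i]``."""
    if rule not in RULES:
        raise ValueError(f"unknown cleavage rule {rule!r}")
    n = len(sequence)
    sites = []
    for i in range(1, n):
        if sequence[i - 1] in "KR":
            if rule == TRYPSIN_STRICT and sequence[i] == "P":
                continue
            sites.append(i)
    return sites


def cleave(
    sequence: str,
    params: DigestParams,
    species: str = "",
    protein_id: str = "",
) -> list[PeptideOccurrence]:
    """Cleave one sequence into peptides with coordinates.

    With ``missed_cleavages == 0`` the returned peptides partition the
    sequence exactly; with ``missed_cleavages == k`` every concatenation of
    at most ``k + 1`` consecutive base fragments is additionally returned.
    No length filter is applied here (see :func:`digest_proteome`).
    Output is ordered by (n_missed, start).
    """
    if not sequence:
        raise ValueError("cannot cleave an empty sequence")
    bounds = [0] + cleavage_sites(sequence, params.rule) + [len(sequence)]
    out: list[PeptideOccurrence] = []
    n_frag = len(bounds) - 1
    for m in range(params.missed_cleavages + 1):
        for i in range(n_frag - m):
            start, end = bounds[i], bounds[i + m + 1]
            out.append(
                PeptideOccurrence(
                    peptide=sequence[start:end],
                    species=species,
                    protein_id=protein_id,
                    start=start,
                    end=end,
                    n_missed=m,
                )
            )
    return out


@dataclass
class PeptideIndex:
    """All digested peptides of one species, keyed by peptide string.

    Only peptides of length >= ``params.min_len`` are indexed, and peptides
    containing ambiguity codes are excluded (identical-string comparison on
    unknown residues is meaningless) but counted in
    ``n_ambiguous_excluded``.
    """

    species: str
    params: DigestParams
    peptides: dict[str, list[PeptideOccurrence]] = field(default_factory=dict)
    n_ambiguous_excluded: int = 0

    def __contains__(self, peptide: str) -> bool:
        return peptide in self.peptides

    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def n_occurrences(self) -> int:
        return sum(len(v) for v in self.peptides.values())


def digest_proteome(proteome: Proteome, params: DigestParams | None = None) -> PeptideIndex:
    """Digest every protein of a proteome into a :class:`PeptideIndex`.

    Records with empty sequences (proteins trimmed to nothing) are skipped.
    Occurrence lists are sorted by (protein_id, start).
    """
    params = params or DigestParams()
    index = PeptideIndex(species=proteome.species, params=params)
    for rec in proteome:
        if not rec.sequence:
            continue
        for occ in cleave(rec.sequence, params, species=rec.species,
                          protein_id=rec.protein_id):
            if len(occ) < params.min_len:
                continue
            if any(c in AMBIGUOUS_RESIDUES for c in occ.peptide):
                index.n_ambiguous_excluded += 1
                continue
            index.peptides.setdefault(occ.peptide, []).append(occ)
    for occs in index.peptides.values():
        occs.sort(key=lambda o: (o.protein_id, o.start))
    return index


@dataclass(frozen=True)
class DigestSummary:
    n_distinct_peptides: int
    n_occurrences: int
    per_protein: dict[str, int]


def peptide_counts(index: PeptideIndex) -> DigestSummary:
    """Summarise an index: distinct peptides, total occurrences, and the
    number of indexed occurrences per protein."""
    per_protein: Counter[str] = Counter()
    n_occ = 0
    for occs in index.peptides.values():
        n_occ += len(occs)
        for occ in occs:
            per_protein[occ.protein_id] += 1
    return DigestSummary(
        n_distinct_peptides=len(index.peptides),
        n_occurrences=n_occ,
        per_protein=dict(per_protein),
    )


def index_table(index: PeptideIndex):
    """Flatten an index for TSV export (1-based inclusive positions are in
    ``start_1based``/``end_1based``; slicing coordinates retained)."""
    import pandas as pd

    rows = []
    for pep, occs in index.peptides.items():
        for o in occs:
            rows.append(
                {
                    "species": o.species or index.species,
                    "peptide": pep,
                    "protein_id": o.protein_id,
                    "start": o.start,
                    "end": o.end,
                    "start_1based": o.start + 1,
                    "end_1based": o.end,
                    "n_missed": o.n_missed,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["species", "peptide", "protein_id", "start", "end",
                 "start_1based", "end_1based", "n_missed"],
    )
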