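"""Shared-peptide detection and excision across community proteomes.

Peptides produced by in-silico digestion that occur in two or more species
are indistinguishable by MS and bias both identification and
quantification.  This module finds them by identical string matching,
excises them from every proteome by deleting the matched digest fragments
and concatenating the flanking sequence, and reports per-protein trimming
and pairwise proteome overlap.

Removal is coordinate-based over digest fragments, never raw substring
search: a shared string occurring *inside* a longer, species-unique peptide
is left untouched.

Two modes are offered.  ``single_pass`` digests, removes and verifies once,
which reproduces the published workflow; ``fixpoint`` repeats the cycle
until a verification re-digest finds no shared peptides, which is a
provable guarantee.  With fully cleaved peptides (no missed cleavages)
fragment boundaries are themselves cleavage sites, so excising whole
fragments cannot create new cleavage contexts and a single pass already
reaches the fixpoint; when the shared-peptide universe is widened to
missed-cleavage products, excision can create novel junction peptides and
only ``fixpoint`` guarantees disjointness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .digest import DigestParams, PeptideIndex, cleave, digest_proteome
from .proteome_io import ProteinRecord, Proteome

logger = logging.getLogger(__name__)

SINGLE_PASS = "single_pass"
FIXPOINT = "fixpoint"
MODES = (SINGLE_PASS, FIXPOINT)


def canonical_peptide(peptide: str, il_equivalence: bool = False) -> str:
    """Canonical form used for identity comparison.

    With ``il_equivalence`` the isobaric residues I and L are collapsed
    (they cannot be distinguished by standard MS); default is plain
    identical-string matching.
    """
    return peptide.replace("I", "L") if il_equivalence else peptide


@dataclass
class SharedPeptideSet:
    """Peptides found in two or more species, with provenance.

    Keys are canonical peptide strings (see :func:`canonical_peptide`).
    """

    peptides: set[str] = field(default_factory=set)
    provenance: dict[str, set[str]] = field(default_factory=dict)
    il_equivalence: bool = False

    def canonical(self, peptide: str) -> str:
        return canonical_peptide(peptide, self.il_equivalence)

    def __contains__(self, peptide: str) -> bool:
        return self.canonical(peptide) in self.peptides

    def __len__(self) -> int:
        return len(self.peptides)

    def __bool__(self) -> bool:
        return bool(self.peptides)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "peptide": pep,
                "n_species": len(self.provenance.get(pep, ())),
                "species": ",".join(sorted(self.provenance.get(pep, ()))),
            }
            for pep in sorted(self.peptides)
        ]
        return pd.DataFrame(rows, columns=["peptide", "n_species", "species"])


def _check_indexes(indexes: list[PeptideIndex]) -> None:
    if len(indexes) < 2:
        raise ValueError("shared-peptide detection needs at least 2 species")
    species = [ix.species for ix in indexes]
    if len(set(species)) != len(species):
        raise ValueError(f"duplicate species labels: {species}")
    params = {ix.params for ix in indexes}
    if len(params) != 1:
        raise ValueError("all indexes must be built with identical DigestParams")


def find_shared(
    indexes: list[PeptideIndex],
    il_equivalence: bool = False,
) -> SharedPeptideSet:
    """Peptide strings present in at least two species' indexes."""
    _check_indexes(indexes)
    provenance: dict[str, set[str]] = {}
    for ix in indexes:
        for pep in ix.peptides:
            provenance.setdefault(canonical_peptide(pep, il_equivalence), set()).add(
                ix.species
            )
    shared = {pep for pep, sp in provenance.items() if len(sp) >= 2}
    return SharedPeptideSet(
        peptides=shared,
        provenance={p: provenance[p] for p in shared},
        il_equivalence=il_equivalence,
    )


@dataclass
class OverlapMatrix:
    """Pairwise counts of distinct shared peptides and the per-species
    percentages they represent.

    ``counts`` is symmetric with each species' own distinct-peptide total on
    the diagonal; ``percentages[a][b] = 100 * counts[a][b] / totals[a]`` is
    row-normalised and therefore asymmetric (the same shared count is a
    different fraction of each species' peptide universe).
    """

    species: list[str]
    counts: pd.DataFrame
    totals: dict[str, int]
    percentages: pd.DataFrame


def overlap_matrix(
    indexes: list[PeptideIndex],
    il_equivalence: bool = False,
) -> OverlapMatrix:
    """Pairwise distinct-peptide overlap between species."""
    _check_indexes(indexes)
    species = [ix.species for ix in indexes]
    sets = {
        ix.species: {canonical_peptide(p, il_equivalence) for p in ix.peptides}
        for ix in indexes
    }
    counts = pd.DataFrame(0, index=species, columns=species, dtype=int)
    for a in species:
        for b in species:
            counts.loc[a, b] = len(sets[a]) if a == b else len(sets[a] & sets[b])
    totals = {sp: len(sets[sp]) for sp in species}
    pct = counts.astype(float)
    for a in species:
        pct.loc[a] = 100.0 * counts.loc[a] / max(1, totals[a])
    return OverlapMatrix(species=species, counts=counts, totals=totals, percentages=pct)


@dataclass
class TrimRecord:
    """What was removed from one protein, in ORIGINAL-sequence coordinates.

    Spans are non-overlapping and sorted by start; the trimmed length always
    reconciles: ``trimmed_length == original_length - sum(end - start)``.
    """

    species: str
    protein_id: str
    removed_spans: list[tuple[int, int, str]] = field(default_factory=list)
    original_length: int = 0
    trimmed_length: int = 0

    @property
    def n_peptides_removed(self) -> int:
        return len(self.removed_spans)

    @property
    def n_residues_removed(self) -> int:
        return sum(e - s for s, e, _ in self.removed_spans)

    @property
    def became_empty(self) -> bool:
        return self.original_length > 0 and self.trimmed_length == 0


@dataclass
class TrimResult:
    """Outcome of trimming a community of proteomes."""

    trimmed_proteomes: list[Proteome]
    records: list[TrimRecord]
    shared: SharedPeptideSet
    params: DigestParams
    mode: str
    residual_shared: SharedPeptideSet
    n_rounds: int = 1


def _matching_spans(
    sequence: str,
    shared: SharedPeptideSet,
    params: DigestParams,
) -> list[tuple[int, int]]:
    """Digest-fragment spans of ``sequence`` whose peptide string is shared,
    merged where overlapping (overlaps only arise with missed cleavages)."""
    spans = [
        (o.start, o.end)
        for o in cleave(sequence, params)
        if len(o) >= params.min_len and o.peptide in shared
    ]
    if not spans:
        return []
    spans.sort()
    merged = [spans[0]]
    for s, e in spans[1:]:
        ls, le = merged[-1]
        if s <= le:
            merged[-1] = (ls, max(le, e))
        else:
            merged.append((s, e))
    return merged


def trim_protein(
    record: ProteinRecord,
    shared: SharedPeptideSet,
    params: DigestParams | None = None,
) -> tuple[ProteinRecord, TrimRecord]:
    """Excise every shared digest fragment from one protein.

    Remaining fragments are concatenated in order; the returned
    :class:`TrimRecord` lists each removed span on the original sequence.
    """
    params = params or DigestParams()
    seq = record.sequence
    spans = _matching_spans(seq, shared, params) if seq else []
    trimmed_seq = seq
    if spans:
        kept = []
        prev = 0
        for s, e in spans:
            kept.append(seq[prev:s])
            prev = e
        kept.append(seq[prev:])
        trimmed_seq = "".join(kept)
    trim_rec = TrimRecord(
        species=record.species,
        protein_id=record.protein_id,
        removed_spans=[(s, e, seq[s:e]) for s, e in spans],
        original_length=len(seq),
        trimmed_length=len(trimmed_seq),
    )
    new_record = ProteinRecord(
        protein_id=record.protein_id,
        description=record.description,
        sequence=trimmed_seq,
        species=record.species,
    )
    return new_record, trim_rec


def _excise_from_intervals(
    intervals: list[tuple[int, int]],
    cur_start: int,
    cur_end: int,
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Remove current-coordinate span [cur_start, cur_end) from a list of
    alive original-coordinate intervals; return (new intervals, removed
    original spans)."""
    new: list[tuple[int, int]] = []
    removed: list[tuple[int, int]] = []
    offset = 0
    for a, b in intervals:
        length = b - a
        s, e = offset, offset + length
        lo, hi = max(s, cur_start), min(e, cur_end)
        if lo < hi:
            if s < lo:
                new.append((a, a + (lo - s)))
            removed.append((a + (lo - s), a + (hi - s)))
            if hi < e:
                new.append((a + (hi - s), b))
        else:
            new.append((a, b))
        offset = e
    return new, removed


def trim_proteomes(
    proteomes: list[Proteome],
    params: DigestParams | None = None,
    mode: str = SINGLE_PASS,
    il_equivalence: bool = False,
    max_rounds: int = 100,
) -> TrimResult:
    """Digest, detect shared peptides, and excise them from every proteome.

    ``single_pass`` performs one digest/remove cycle and then verifies by
    re-digesting (``residual_shared`` reports anything still shared);
    ``fixpoint`` iterates until the verification digest is clean, which
    terminates because the total residue count strictly decreases while any
    shared peptide remains.
    """
    params = params or DigestParams()
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; choose from {MODES}")
    if len(proteomes) < 2 or len({p.species for p in proteomes}) < 2:
        raise ValueError("trimming requires proteomes from at least 2 species")
    for p in proteomes:
        p.check()

    # per-protein state: surviving original-coordinate intervals + removals
    current: dict[str, list[ProteinRecord]] = {
        p.species: list(p.records) for p in proteomes
    }
    alive: dict[tuple[str, str], list[tuple[int, int]]] = {}
    removed: dict[tuple[str, str], list[tuple[int, int, str]]] = {}
    original_len: dict[tuple[str, str], int] = {}
    for p in proteomes:
        for rec in p:
            key = (p.species, rec.protein_id)
            alive[key] = [(0, len(rec.sequence))] if rec.sequence else []
            removed[key] = []
            original_len[key] = len(rec.sequence)

    shared_initial: SharedPeptideSet | None = None
    n_rounds = 0
    while True:
        n_rounds += 1
        if n_rounds > max_rounds:
            raise RuntimeError(f"trimming did not converge in {max_rounds} rounds")
        indexes = [
            digest_proteome(Proteome(sp, recs), params)
            for sp, recs in current.items()
        ]
        shared = find_shared(indexes, il_equivalence=il_equivalence)
        if shared_initial is None:
            shared_initial = shared
        if not shared:
            break
        for sp, recs in current.items():
            new_recs = []
            for rec in recs:
                key = (sp, rec.protein_id)
                spans = (
                    _matching_spans(rec.sequence, shared, params)
                    if rec.sequence
                    else []
                )
                seq = rec.sequence
                # excise right-to-left so earlier current coordinates stay valid
                for s, e in reversed(spans):
                    pep = seq[s:e]
                    alive[key], orig_spans = _excise_from_intervals(alive[key], s, e)
                    removed[key].extend((a, b, pep) for a, b in orig_spans)
                    seq = seq[:s] + seq[e:]
                new_recs.append(
                    ProteinRecord(rec.protein_id, rec.description, seq, rec.species)
                )
            current[sp] = new_recs
        if mode == SINGLE_PASS:
            break

    # verification re-digest
    ver_indexes = [
        digest_proteome(Proteome(sp, recs), params) for sp, recs in current.items()
    ]
    residual = find_shared(ver_indexes, il_equivalence=il_equivalence)
    if mode == FIXPOINT and residual:  # pragma: no cover - loop exits on empty
        raise AssertionError("fixpoint mode ended with residual shared peptides")
    if residual:
        logger.warning(
            "%d peptides remain shared after a single trimming pass; "
            "re-run with mode='fixpoint' for guaranteed disjointness",
            len(residual),
        )

    trim_records = []
    for p in proteomes:
        for rec in p:
            key = (p.species, rec.protein_id)
            spans = sorted(removed[key])
            trim_records.append(
                TrimRecord(
                    species=p.species,
                    protein_id=rec.protein_id,
                    removed_spans=spans,
                    original_length=original_len[key],
                    trimmed_length=original_len[key]
                    - sum(e - s for s, e, _ in spans),
                )
            )
    trimmed = [Proteome(p.species, current[p.species]) for p in proteomes]
    return TrimResult(
        trimmed_proteomes=trimmed,
        records=trim_records,
        shared=shared_initial,
        params=params,
        mode=mode,
        residual_shared=residual,
        n_rounds=n_rounds,
    )


def trim_summary(result: TrimResult, include_untrimmed: bool = False) -> pd.DataFrame:
    """Per-protein trimming report.

    Untouched proteins are suppressed unless ``include_untrimmed``.
    """
    rows = []
    for tr in result.records:
        if not include_untrimmed and tr.n_peptides_removed == 0:
            continue
        rows.append(
            {
                "species": tr.species,
                "protein_id": tr.protein_id,
                "n_peptides_removed": tr.n_peptides_removed,
                "n_residues_removed": tr.n_residues_removed,
                "original_length": tr.original_length,
                "trimmed_length": tr.trimmed_length,
                "fraction_removed": (
                    tr.n_residues_removed / tr.original_length
                    if tr.original_length
                    else 0.0
                ),
                "became_empty": tr.became_empty,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "species", "protein_id", "n_peptides_removed", "n_residues_removed",
            "original_length", "trimmed_length", "fraction_removed", "became_empty",
        ],
    )


def trim_totals(result: TrimResult) -> pd.DataFrame:
    """Per-species trimming totals."""
    rows = {}
    for tr in result.records:
        row = rows.setdefault(
            tr.species,
            {
                "species": tr.species,
                "n_proteins": 0,
                "n_proteins_trimmed": 0,
                "n_proteins_emptied": 0,
                "n_peptides_removed": 0,
                "n_residues_removed": 0,
                "original_residues": 0,
                "trimmed_residues": 0,
            },
        )
        row["n_proteins"] += 1
        row["n_proteins_trimmed"] += int(tr.n_peptides_removed > 0)
        row["n_proteins_emptied"] += int(tr.became_empty)
        row["n_peptides_removed"] += tr.n_peptides_removed
        row["n_residues_removed"] += tr.n_residues_removed
        row["original_residues"] += tr.original_length
        row["trimmed_residues"] += tr.trimmed_length
    return pd.DataFrame(sorted(rows.values(), key=lambda r: r["species"]))
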