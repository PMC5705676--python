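"""Shared-peptide detection, excision, overlap statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from proteotrim import (
    DigestParams,
    ProteinRecord,
    digest_proteome,
    find_shared,
    overlap_matrix,
    trim_protein,
    trim_proteomes,
    trim_summary,
    trim_totals,
)
from proteotrim.trim import FIXPOINT, SINGLE_PASS, SharedPeptideSet, canonical_peptide
from proteotrim.simulate import (
    PlantedPeptideSpec,
    ProteomeSimConfig,
    simulate_proteomes,
)

from conftest import make_proteome
from oracles import shared_peptides_by_rescan

AA = "ACDEFGHIKLMNPQRSTVWY"


def indexes_of(proteomes, params=None):
    return [digest_proteome(p, params or DigestParams()) for p in proteomes]


class TestFindShared:
    def test_simple_intersection(self):
        a = make_proteome("A", {"a1": "AAAAAAAKSSSSSSSK"})
        b = make_proteome("B", {"b1": "SSSSSSSKTTTTTTTK"})
        shared = find_shared(indexes_of([a, b]))
        assert shared.peptides == {"SSSSSSSK"}
        assert shared.provenance == {"SSSSSSSK": {"A", "B"}}

    def test_identical_proteomes_share_everything(self):
        seqs = {"p1": "AAAAAAAKSSSSSSSKWWWWWWWK"}
        a = make_proteome("A", seqs)
        b = make_proteome("B", seqs)
        idx = indexes_of([a, b])
        shared = find_shared(idx)
        assert shared.peptides == set(idx[0].peptides)

    def test_planted_fixture_recovered_exactly(self):
        cfg = ProteomeSimConfig(
            species=("A", "B", "C", "D"),
            n_proteins=25,
            length_range=(100, 250),
            planted_shared=tuple(
                PlantedPeptideSpec(length=9 + i % 4, species=("A", "B"))
                for i in range(10)
            )
            + (PlantedPeptideSpec(length=10, species=("C", "D"), n_insertions=2),),
            seed=11,
        )
        proteomes, truth = simulate_proteomes(cfg)
        shared = find_shared(indexes_of(proteomes))
        assert shared.peptides == truth.expected_shared

    def test_requires_two_species_and_matching_params(self):
        a = make_proteome("A", {"a1": "AAAAAAAK"})
        b = make_proteome("B", {"b1": "AAAAAAAK"})
        with pytest.raises(ValueError, match="at least 2"):
            find_shared(indexes_of([a]))
        mixed = [
            digest_proteome(a, DigestParams(min_len=7)),
            digest_proteome(b, DigestParams(min_len=8)),
        ]
        with pytest.raises(ValueError, match="identical DigestParams"):
            find_shared(mixed)

    def test_il_equivalence_flag(self):
        a = make_proteome("A", {"a1": "IIIVVVVK"})
        b = make_proteome("B", {"b1": "LLLVVVVK"})
        assert not find_shared(indexes_of([a, b]))
        shared = find_shared(indexes_of([a, b]), il_equivalence=True)
        assert shared.peptides == {canonical_peptide("IIIVVVVK", True)}


class TestOverlapMatrix:
    def test_toy_counts_and_percentages(self):
        a = make_proteome("A", {"a1": "AAAAAAAKSSSSSSSK"})
        b = make_proteome("B", {"b1": "SSSSSSSKTTTTTTTK"})
        mat = overlap_matrix(indexes_of([a, b]))
        assert mat.counts.loc["A", "B"] == 1
        assert mat.counts.loc["A", "A"] == mat.totals["A"] == 2
        assert mat.percentages.loc["A", "B"] == 50.0
        assert mat.percentages.loc["B", "A"] == 50.0

    def test_disjoint_proteomes_have_zero_off_diagonal(self):
        a = make_proteome("A", {"a1": "AAAAAAAK"})
        b = make_proteome("B", {"b1": "TTTTTTTK"})
        mat = overlap_matrix(indexes_of([a, b]))
        assert mat.counts.loc["A", "B"] == 0
        assert mat.counts.loc["B", "A"] == 0

    def test_symmetry_of_counts_and_asymmetry_of_percentages(self):
        cfg = ProteomeSimConfig(
            species=("A", "B"),
            n_proteins=30,
            planted_shared=tuple(
                PlantedPeptideSpec(length=9, species=("A", "B")) for _ in range(15)
            ),
            seed=3,
        )
        proteomes, _ = simulate_proteomes(cfg)
        mat = overlap_matrix(indexes_of(proteomes))
        assert (mat.counts.to_numpy() == mat.counts.to_numpy().T).all()
        expected_pct = 100.0 * mat.counts.loc["A", "B"] / mat.totals["A"]
        assert mat.percentages.loc["A", "B"] == pytest.approx(expected_pct)


class TestTrimProtein:
    SHARED = SharedPeptideSet(
        peptides={"SSSSSSSK"}, provenance={"SSSSSSSK": {"A", "B"}}
    )

    def test_excision_with_span_record(self):
        rec = ProteinRecord("p1", "", "AAAAAAAKSSSSSSSKCCCCCCCK", "A")
        new, tr = trim_protein(rec, self.SHARED)
        assert new.sequence == "AAAAAAAKCCCCCCCK"
        assert tr.removed_spans == [(8, 16, "SSSSSSSK")]
        assert tr.trimmed_length == tr.original_length - tr.n_residues_removed

    def test_untouched_protein_is_identity(self):
        rec = ProteinRecord("p1", "", "WWWWWWWKCCCCCCCK", "A")
        new, tr = trim_protein(rec, self.SHARED)
        assert new.sequence == rec.sequence
        assert tr.removed_spans == []

    def test_protein_that_is_one_shared_peptide_becomes_empty(self):
        rec = ProteinRecord("p1", "", "SSSSSSSK", "A")
        new, tr = trim_protein(rec, self.SHARED)
        assert new.sequence == ""
        assert tr.trimmed_length == 0
        assert tr.became_empty

    def test_shared_string_inside_longer_peptide_untouched(self):
        # SSSSSSSK occurs as a substring of the single fragment
        # WSSSSSSSKPAAAK (K before P does not cleave under the strict rule),
        # so coordinate-based removal must leave it alone
        rec = ProteinRecord("p1", "", "WSSSSSSSKPAAAK", "A")
        new, tr = trim_protein(rec, self.SHARED)
        assert new.sequence == rec.sequence
        assert tr.removed_spans == []

    def test_multiple_occurrences_all_removed(self):
        rec = ProteinRecord("p1", "", "SSSSSSSKAAAAAAAKSSSSSSSK", "A")
        new, tr = trim_protein(rec, self.SHARED)
        assert new.sequence == "AAAAAAAK"
        assert [s for s, _e, _p in tr.removed_spans] == [0, 16]


class TestTrimProteomes:
    def test_toy_pair_single_pass(self, toy_pair):
        result = trim_proteomes(toy_pair, mode=SINGLE_PASS)
        by_species = {p.species: p for p in result.trimmed_proteomes}
        assert by_species["A"][0].sequence == "AAAAAAAKCCCCCCCK"
        assert by_species["B"][0].sequence == "TTTTTTTK"
        assert result.shared.peptides == {"SSSSSSSK"}
        assert not result.residual_shared

    def test_single_species_is_error(self):
        a = make_proteome("A", {"a1": "AAAAAAAK"})
        with pytest.raises(ValueError, match="2 species"):
            trim_proteomes([a])

    def test_within_species_repeats_not_removed(self):
        # the same peptide in two proteins of ONE species is not
        # between-species sharing and must survive
        a = make_proteome("A", {"a1": "WWWWWWWK", "a2": "WWWWWWWKCCCCCCCK"})
        b = make_proteome("B", {"b1": "TTTTTTTK"})
        result = trim_proteomes([a, b])
        assert not result.shared
        trimmed_a = next(p for p in result.trimmed_proteomes if p.species == "A")
        assert [r.sequence for r in trimmed_a] == ["WWWWWWWK", "WWWWWWWKCCCCCCCK"]

    def test_missed_cleavage_universe_can_need_fixpoint(self):
        # with missed-cleavage peptides in the shared universe, excising a
        # fragment joins its two short (sub-min_len, hence never shared)
        # neighbours into a novel 1-missed junction peptide; here A and B
        # both form AAAK|DDDK after losing their (different) middle
        # fragments, so a single pass leaves residual sharing that only
        # fixpoint mode removes
        a = make_proteome("A", {"a1": "AAAKSSSSSSSKDDDK"})
        b = make_proteome("B", {"b1": "AAAKTTTTTTTKDDDK"})
        c = make_proteome("C", {"c1": "SSSSSSSK", "c2": "TTTTTTTK"})
        params = DigestParams(missed_cleavages=1)
        single = trim_proteomes([a, b, c], params, mode=SINGLE_PASS)
        assert single.residual_shared.peptides == {"AAAKDDDK"}
        fix = trim_proteomes([a, b, c], params, mode=FIXPOINT)
        assert not fix.residual_shared
        assert fix.n_rounds > single.n_rounds

    def test_fixpoint_is_idempotent(self):
        cfg = ProteomeSimConfig(
            species=("A", "B", "C"),
            n_proteins=20,
            length_range=(80, 200),
            planted_shared=tuple(
                PlantedPeptideSpec(length=8 + i % 5, species=("A", "B", "C")[: 2 + i % 2])
                for i in range(12)
            ),
            seed=5,
        )
        proteomes, _ = simulate_proteomes(cfg)
        once = trim_proteomes(proteomes, mode=FIXPOINT)
        again = trim_proteomes(once.trimmed_proteomes, mode=FIXPOINT)
        assert not again.shared
        for p1, p2 in zip(once.trimmed_proteomes, again.trimmed_proteomes):
            assert [r.sequence for r in p1] == [r.sequence for r in p2]

    def test_conservation_and_never_grow_on_fixtures(self):
        cfg = ProteomeSimConfig(
            species=("A", "B"),
            n_proteins=25,
            planted_shared=tuple(
                PlantedPeptideSpec(length=10, species=("A", "B")) for _ in range(8)
            ),
            seed=9,
        )
        proteomes, _ = simulate_proteomes(cfg)
        originals = {
            (p.species, r.protein_id): r.sequence for p in proteomes for r in p
        }
        result = trim_proteomes(proteomes, mode=FIXPOINT)
        trimmed = {
            (p.species, r.protein_id): r.sequence
            for p in result.trimmed_proteomes
            for r in p
        }
        for tr in result.records:
            orig = originals[(tr.species, tr.protein_id)]
            new = trimmed[(tr.species, tr.protein_id)]
            assert len(new) <= len(orig)
            assert tr.trimmed_length == tr.original_length - tr.n_residues_removed
            assert tr.trimmed_length == len(new)
            # spans sorted, non-overlapping, and excising them yields the output
            spans = tr.removed_spans
            assert spans == sorted(spans)
            for (s1, e1, _), (s2, _e2, _) in zip(spans, spans[1:]):
                assert e1 <= s2
            rebuilt = []
            prev = 0
            for s, e, pep in spans:
                assert orig[s:e] == pep
                rebuilt.append(orig[prev:s])
                prev = e
            rebuilt.append(orig[prev:])
            assert "".join(rebuilt) == new

    def test_species_unique_peptides_survive(self):
        cfg = ProteomeSimConfig(
            species=("A", "B"),
            n_proteins=20,
            planted_shared=tuple(
                PlantedPeptideSpec(length=9, species=("A", "B")) for _ in range(6)
            ),
            seed=13,
        )
        proteomes, _ = simulate_proteomes(cfg)
        idx_before = indexes_of(proteomes)
        shared = find_shared(idx_before).peptides
        result = trim_proteomes(proteomes, mode=FIXPOINT)
        idx_after = {
            p.species: digest_proteome(p) for p in result.trimmed_proteomes
        }
        removed_spans = {
            (tr.species, tr.protein_id): [(s, e) for s, e, _ in tr.removed_spans]
            for tr in result.records
        }
        for ix in idx_before:
            for pep, occs in ix.peptides.items():
                if pep in shared:
                    continue
                for occ in occs:
                    spans = removed_spans[(occ.species, occ.protein_id)]
                    if any(s < occ.end and occ.start < e for s, e in spans):
                        continue  # overlapping a removed span: no claim
                    assert pep in idx_after[ix.species].peptides

    def test_residual_empty_verified_by_independent_scanner(self):
        rng = np.random.default_rng(21)
        cfg = ProteomeSimConfig(
            species=("A", "B", "C"),
            n_proteins=15,
            length_range=(80, 200),
            planted_shared=tuple(
                PlantedPeptideSpec(length=int(rng.integers(8, 13)), species=("A", "B"))
                for _ in range(10)
            ),
            seed=17,
        )
        proteomes, _ = simulate_proteomes(cfg)
        result = trim_proteomes(proteomes, mode=FIXPOINT)
        fastas = {
            p.species: {r.protein_id: r.sequence for r in p}
            for p in result.trimmed_proteomes
        }
        assert shared_peptides_by_rescan(fastas) == set()


class TestTrimReports:
    def test_toy_summary_rows(self, toy_pair):
        result = trim_proteomes(toy_pair)
        df = trim_summary(result)
        assert len(df) == 2
        assert (df["n_peptides_removed"] == 1).all()
        assert (df["n_residues_removed"] == 8).all()

    def test_untouched_rows_suppressed_unless_requested(self):
        a = make_proteome("A", {"a1": "AAAAAAAK", "a2": "SSSSSSSK"})
        b = make_proteome("B", {"b1": "SSSSSSSK"})
        result = trim_proteomes([a, b])
        assert set(trim_summary(result)["protein_id"]) == {"a2", "b1"}
        assert len(trim_summary(result, include_untrimmed=True)) == 3

    def test_totals_match_planted_ground_truth(self):
        cfg = ProteomeSimConfig(
            species=("A", "B"),
            n_proteins=20,
            planted_shared=tuple(
                PlantedPeptideSpec(length=10, species=("A", "B")) for _ in range(5)
            ),
            seed=23,
        )
        proteomes, truth = simulate_proteomes(cfg)
        if truth.accidental_shared:  # keep the arithmetic exact
            pytest.skip("accidental collision in fixture")
        result = trim_proteomes(proteomes)
        totals = trim_totals(result).set_index("species")
        for sp in ("A", "B"):
            planted_here = [
                pl for pl in truth.planted if pl.species == sp
            ]
            assert totals.loc[sp, "n_peptides_removed"] == len(planted_here)
            assert totals.loc[sp, "n_residues_removed"] == sum(
                pl.end - pl.start for pl in planted_here
            )


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_trim_disjointness_property_random_communities(seed):
    """For random 2-species communities, fixpoint trimming always ends
    disjoint and conserves residues exactly."""
    rng = np.random.default_rng(seed)
    cfg = ProteomeSimConfig(
        species=("A", "B"),
        n_proteins=8,
        length_range=(60, 150),
        planted_shared=tuple(
            PlantedPeptideSpec(length=int(rng.integers(8, 12)), species=("A", "B"))
            for _ in range(int(rng.integers(0, 5)))
        ),
        seed=seed,
    )
    proteomes, _ = simulate_proteomes(cfg)
    result = trim_proteomes(proteomes, mode=FIXPOINT)
    assert not result.residual_shared
    for tr in result.records:
        assert tr.trimmed_length == tr.original_length - tr.n_residues_removed
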