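"""Seeded generators for desk-scale test data with machine-readable truth.

Three generators emulate the three inputs of the workflow:

* random proteomes with cross-species shared tryptic peptides planted at
  known positions (each planted peptide is an exact tryptic product:
  insertions happen only at cleavage-site boundaries),
* log2 intensity matrices with planted group effects and missingness,
* pathway annotations with one planted over-represented pathway.

All generators are pure functions of their configuration, including the
seed.  Accidental background sharing (two random proteomes happening to
produce the same peptide) is detected post hoc and *reported* in the ground
truth rather than prevented, so tests can compare against the full truth
without biasing the sequence statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .digest import DigestParams, cleavage_sites, digest_proteome
from .proteome_io import ProteinRecord, Proteome
from .stats import GroupDesign
from .trim import find_shared
from .enrichment import PathwayAnnotation

#: residues drawn for background sequence, excluding the cleavage residues
_NON_CLEAVAGE = tuple("ACDEFGHILMNPQSTVWY")
_CLEAVAGE = ("K", "R")


@dataclass(frozen=True)
class PlantedPeptideSpec:
    """One peptide string to plant into a subset of species.

    ``n_insertions`` placements are made per listed species (possibly in
    different proteins).
    """

    length: int
    species: tuple[str, ...]
    n_insertions: int = 1

    def __post_init__(self) -> None:
        if self.length < 7:
            raise ValueError("planted peptides must be at least 7 residues")


@dataclass(frozen=True)
class ProteomeSimConfig:
    """Random-proteome settings.

    Background residues are drawn i.i.d. with K/R at a combined frequency
    ``cleavage_freq`` (default 1/9, giving a mean tryptic fragment of ~9
    residues, realistic for bacterial proteomes) and the remaining mass
    uniform over the other 18 residues.
    """

    species: tuple[str, ...] = ("sp1", "sp2", "sp3", "sp4")
    n_proteins: int = 50
    length_range: tuple[int, int] = (120, 400)
    cleavage_freq: float = 1.0 / 9.0
    planted_shared: tuple[PlantedPeptideSpec, ...] = ()
    rule: str = "trypsin_strict"
    seed: int = 0


@dataclass(frozen=True)
class PlantedPlacement:
    peptide: str
    species: str
    protein_id: str
    start: int
    end: int


@dataclass
class ProteomeTruth:
    """Ground truth emitted alongside simulated proteomes."""

    planted: list[PlantedPlacement]
    planted_peptides: set[str]
    #: peptides planted into >= 2 species (the intended shared set)
    planted_shared: set[str]
    #: background peptides that happen to be shared, found by re-digestion
    accidental_shared: set[str]
    #: the full shared set a detector should recover (planted + accidental)
    expected_shared: set[str]


def _residue_probs(cleavage_freq: float) -> tuple[list[str], np.ndarray]:
    letters = list(_CLEAVAGE) + list(_NON_CLEAVAGE)
    probs = np.empty(len(letters))
    probs[:2] = cleavage_freq / 2.0
    probs[2:] = (1.0 - cleavage_freq) / len(_NON_CLEAVAGE)
    return letters, probs


def _random_tryptic_peptide(rng: np.random.Generator, length: int) -> str:
    """A peptide that digests as exactly one fragment: no internal K/R,
    terminal K or R, and a non-proline first residue."""
    first = rng.choice([c for c in _NON_CLEAVAGE if c != "P"])
    middle = rng.choice(list(_NON_CLEAVAGE), size=length - 2)
    last = rng.choice(list(_CLEAVAGE))
    return str(first) + "".join(middle) + str(last)


def _insertion_points(sequence: str, rule: str) -> list[int]:
    """Positions where inserting a tryptic peptide keeps it an exact
    digestion product: cleavage boundaries not followed by proline."""
    points = [0] + cleavage_sites(sequence, rule)
    if sequence and sequence[-1] in "KR":
        points.append(len(sequence))
    if rule == "trypsin_strict":
        points = [p for p in points if p == len(sequence) or sequence[p] != "P"]
    return points


def simulate_proteomes(cfg: ProteomeSimConfig) -> tuple[list[Proteome], ProteomeTruth]:
    """Generate one random proteome per species with planted shared
    peptides, then verify the truth by re-digesting the output."""
    rng = np.random.default_rng(cfg.seed)
    letters, probs = _residue_probs(cfg.cleavage_freq)
    lo, hi = cfg.length_range
    proteomes: dict[str, list[ProteinRecord]] = {}
    for sp in cfg.species:
        records = []
        for i in range(cfg.n_proteins):
            length = int(rng.integers(lo, hi + 1))
            seq = "".join(rng.choice(letters, size=length, p=probs))
            records.append(
                ProteinRecord(f"{sp}_p{i + 1:04d}", "simulated protein", seq, sp)
            )
        proteomes[sp] = records

    placements: list[PlantedPlacement] = []
    planted_peptides: set[str] = set()
    planted_shared: set[str] = set()
    for spec in cfg.planted_shared:
        peptide = _random_tryptic_peptide(rng, spec.length)
        planted_peptides.add(peptide)
        if len(set(spec.species)) >= 2:
            planted_shared.add(peptide)
        for sp in spec.species:
            if sp not in proteomes:
                raise ValueError(f"planted species {sp!r} not in config species")
            for _ in range(spec.n_insertions):
                order = rng.permutation(len(proteomes[sp]))
                placed = False
                for j in order:
                    rec = proteomes[sp][j]
                    points = _insertion_points(rec.sequence, cfg.rule)
                    if not points:
                        continue
                    pos = int(rng.choice(points))
                    new_seq = rec.sequence[:pos] + peptide + rec.sequence[pos:]
                    proteomes[sp][j] = replace(rec, sequence=new_seq)
                    # shift earlier placements in the same protein
                    for k, pl in enumerate(placements):
                        if (pl.species, pl.protein_id) == (sp, rec.protein_id) \
                                and pl.start >= pos:
                            placements[k] = replace(
                                pl,
                                start=pl.start + len(peptide),
                                end=pl.end + len(peptide),
                            )
                    placements.append(
                        PlantedPlacement(
                            peptide=peptide,
                            species=sp,
                            protein_id=rec.protein_id,
                            start=pos,
                            end=pos + len(peptide),
                        )
                    )
                    placed = True
                    break
                if not placed:
                    raise ValueError(
                        f"could not place a {spec.length}-mer in species {sp!r}: "
                        "proteins too short or no valid boundary"
                    )

    result = [Proteome(sp, proteomes[sp]) for sp in cfg.species]

    # self-consistency: every placement must slice out its peptide, and the
    # planted peptide must appear in the species' digest index
    params = DigestParams(rule=cfg.rule)
    indexes = {p.species: digest_proteome(p, params) for p in result}
    by_protein = {
        (p.species, r.protein_id): r.sequence for p in result for r in p
    }
    for pl in placements:
        seq = by_protein[(pl.species, pl.protein_id)]
        if seq[pl.start:pl.end] != pl.peptide:
            raise AssertionError("placement bookkeeping is inconsistent")
        if pl.peptide not in indexes[pl.species]:
            raise AssertionError("planted peptide missing from digest index")

    if len(cfg.species) >= 2:
        shared_now = find_shared(list(indexes.values())).peptides
    else:
        shared_now = set()
    accidental = shared_now - planted_shared
    truth = ProteomeTruth(
        planted=placements,
        planted_peptides=planted_peptides,
        planted_shared=planted_shared,
        accidental_shared=accidental,
        expected_shared=set(shared_now),
    )
    return result, truth


def four_species_community(seed: int = 0) -> ProteomeSimConfig:
    """A four-species benchmark community with two closely related members.

    Two species (``xan``/``ste``) share planted peptides amounting to
    roughly 16% of each one's distinct digested peptides, mirroring the
    overlap level seen between closely related community members, while the
    other two species (``pae``/``mic``) share only a handful of peptides
    with anyone.
    """
    rng = np.random.default_rng(seed)
    planted = [
        PlantedPeptideSpec(length=int(rng.integers(8, 15)), species=("xan", "ste"))
        for _ in range(130)
    ]
    planted += [
        PlantedPeptideSpec(length=int(rng.integers(8, 15)), species=("pae", "mic"))
        for _ in range(3)
    ]
    planted += [
        PlantedPeptideSpec(length=int(rng.integers(8, 15)), species=("xan", "pae"))
        for _ in range(2)
    ]
    return ProteomeSimConfig(
        species=("xan", "ste", "pae", "mic"),
        n_proteins=60,
        length_range=(150, 250),
        planted_shared=tuple(planted),
        seed=seed,
    )


@dataclass(frozen=True)
class IntensitySimConfig:
    """Label-free intensity simulation settings.

    Defaults mirror the study design the statistics are meant for: 1000
    proteins, 5 replicates per condition, log2 baselines around 25 (typical
    LFQ scale), within-group SD 0.5, a 2-unit (i.e. 4x within-group SD)
    log2 effect on 10% of proteins, and 10% missing values.
    """

    n_proteins: int = 1000
    n_per_group: int = 5
    baseline_mean: float = 25.0
    baseline_sd: float = 2.0
    within_group_sd: float = 0.5
    effect_size: float = 2.0
    affected_fraction: float = 0.1
    missing_rate: float = 0.1
    intensity_dependent_missing: bool = False
    group1: str = "single"
    group2: str = "community"
    seed: int = 0


@dataclass
class IntensityTruth:
    affected: set[str]
    effects: dict[str, float]


def simulate_intensities(
    cfg: IntensitySimConfig,
) -> tuple[pd.DataFrame, GroupDesign, IntensityTruth]:
    """Simulate a proteins x samples log2 intensity matrix.

    Values are baseline + (planted effect in group 2 for the affected
    subset, random sign) + Gaussian noise; missingness is applied after,
    either completely at random or weighted towards low intensities.
    """
    rng = np.random.default_rng(cfg.seed)
    ids = [f"prot_{i + 1:05d}" for i in range(cfg.n_proteins)]
    samples = [f"{cfg.group1}_{j + 1}" for j in range(cfg.n_per_group)] + [
        f"{cfg.group2}_{j + 1}" for j in range(cfg.n_per_group)
    ]
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_proteins)
    n_affected = int(round(cfg.affected_fraction * cfg.n_proteins))
    affected_idx = rng.choice(cfg.n_proteins, size=n_affected, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_affected)
    effect = np.zeros(cfg.n_proteins)
    effect[affected_idx] = signs * cfg.effect_size

    values = baseline[:, None] + rng.normal(
        0.0, cfg.within_group_sd, size=(cfg.n_proteins, 2 * cfg.n_per_group)
    )
    values[:, cfg.n_per_group:] += effect[:, None]

    if cfg.missing_rate > 0:
        if cfg.intensity_dependent_missing:
            z = (values - values.mean()) / max(values.std(), 1e-12)
            w = 1.0 / (1.0 + np.exp(z))  # low intensity -> higher weight
            p_miss = np.clip(cfg.missing_rate * w / w.mean(), 0.0, 0.95)
        else:
            p_miss = np.full_like(values, cfg.missing_rate)
        values[rng.random(values.shape) < p_miss] = np.nan

    matrix = pd.DataFrame(values, index=ids, columns=samples)
    design = GroupDesign(
        {s: (cfg.group1 if i < cfg.n_per_group else cfg.group2)
         for i, s in enumerate(samples)},
        group1=cfg.group1,
        group2=cfg.group2,
    )
    truth = IntensityTruth(
        affected={ids[i] for i in affected_idx},
        effects={ids[i]: float(effect[i]) for i in affected_idx},
    )
    return matrix, design, truth


@dataclass(frozen=True)
class AnnotationSimConfig:
    """Pathway-annotation simulation settings.

    ``planted_fraction`` is the fraction of the planted pathway's members
    drawn from the supplied SCA set (0 disables planting); other pathways
    sample members uniformly from the universe.
    """

    n_pathways: int = 20
    size_range: tuple[int, int] = (10, 40)
    planted_fraction: float = 0.5
    seed: int = 0


@dataclass
class AnnotationTruth:
    planted_pathway: str | None


def simulate_annotation(
    universe,
    sca,
    cfg: AnnotationSimConfig,
) -> tuple[PathwayAnnotation, AnnotationTruth]:
    """Random multi-membership pathway annotation over ``universe`` with at
    most one pathway enriched in the ``sca`` set."""
    rng = np.random.default_rng(cfg.seed)
    universe = sorted(map(str, universe))
    sca = sorted(set(map(str, sca)) & set(universe))
    non_sca = sorted(set(universe) - set(sca))
    lo, hi = cfg.size_range
    mapping: dict[str, set[str]] = {p: set() for p in universe}
    names: dict[str, str] = {}
    planted_id: str | None = None
    for i in range(cfg.n_pathways):
        pw = f"PW{i + 1:03d}"
        names[pw] = f"Pathway {i + 1}"
        size = int(rng.integers(lo, min(hi, len(universe)) + 1))
        if i == 0 and cfg.planted_fraction > 0 and sca:
            planted_id = pw
            k = min(len(sca), int(round(cfg.planted_fraction * size)))
            members = list(rng.choice(sca, size=k, replace=False))
            pool = non_sca if len(non_sca) >= size - k else universe
            members += list(rng.choice(pool, size=size - k, replace=False))
        else:
            members = list(rng.choice(universe, size=size, replace=False))
        for prot in members:
            mapping[str(prot)].add(pw)
    annotation = PathwayAnnotation(
        {p: frozenset(v) for p, v in mapping.items() if v}, names
    )
    return annotation, AnnotationTruth(planted_pathway=planted_id)
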