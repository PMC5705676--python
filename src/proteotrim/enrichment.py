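"""Direction-aware pathway over-representation for SCA proteins.

Proteins whose abundance changed significantly (SCA proteins) are tested
per pathway and per direction of change (increased / decreased) with a
one-sided Fisher's exact test on the 2x2 table

                  in pathway   not in pathway
    SCA               a              b
    not SCA           c              g

over the universe of annotated proteins, i.e. the hypergeometric tail
P[X >= a].  Benjamini-Hochberg correction is applied across pathways within
each direction.  Pathways are gene sets with multi-membership, so tests are
not independent; no significance cutoff is hard-coded and the full table is
returned sorted by adjusted p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

INCREASED = "increased"
DECREASED = "decreased"


@dataclass
class PathwayAnnotation:
    """Protein -> pathway membership plus display names.

    The annotation universe is the set of proteins with at least one
    pathway; a protein may belong to several pathways.
    """

    protein_pathways: dict[str, frozenset[str]]
    pathway_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.protein_pathways = {
            p: frozenset(v) for p, v in self.protein_pathways.items() if v
        }

    @property
    def universe(self) -> set[str]:
        return set(self.protein_pathways)

    @property
    def pathways(self) -> list[str]:
        out = set()
        for v in self.protein_pathways.values():
            out |= v
        return sorted(out)

    def members(self, pathway_id: str) -> set[str]:
        return {p for p, v in self.protein_pathways.items() if pathway_id in v}

    def name(self, pathway_id: str) -> str:
        return self.pathway_names.get(pathway_id, pathway_id)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PathwayAnnotation":
        """Build from a long table with columns protein_id, pathway_id and
        optionally pathway_name."""
        mapping: dict[str, set[str]] = {}
        names: dict[str, str] = {}
        for row in df.itertuples(index=False):
            mapping.setdefault(str(row.protein_id), set()).add(str(row.pathway_id))
            if hasattr(row, "pathway_name") and not pd.isna(row.pathway_name):
                names[str(row.pathway_id)] = str(row.pathway_name)
        return cls({p: frozenset(v) for p, v in mapping.items()}, names)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"protein_id": p, "pathway_id": pw, "pathway_name": self.name(pw)}
            for p in sorted(self.protein_pathways)
            for pw in sorted(self.protein_pathways[p])
        ]
        return pd.DataFrame(rows, columns=["protein_id", "pathway_id", "pathway_name"])


def fisher_one_sided(a: int, b: int, c: int, g: int) -> float:
    """One-sided (over-representation) Fisher p-value for a 2x2 table.

    With ``N = a+b+c+g``, ``K = a+c`` pathway members and ``n = a+b`` drawn
    SCA proteins, this is the hypergeometric tail P[X >= a].
    """
    if min(a, b, c, g) < 0:
        raise ValueError("counts must be non-negative")
    n_total = a + b + c + g
    if n_total == 0:
        raise ValueError("all-zero contingency table")
    return float(hypergeom.sf(a - 1, n_total, a + c, a + b))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class EnrichmentResult:
    """Full over-representation table plus bookkeeping.

    ``n_unannotated`` counts SCA proteins per direction that could not be
    mapped to any pathway and were excluded before testing.
    """

    table: pd.DataFrame
    universe_size: int
    n_unannotated: dict[str, int]


def _odds_ratio(a: int, b: int, c: int, g: int) -> float:
    if b * c == 0:
        return float("inf") if a * g > 0 else float("nan")
    return a * g / (b * c)


def enrich(
    sca_increased,
    sca_decreased,
    annotation: PathwayAnnotation,
    universe: str = "annotated",
    detected=None,
    combine_directions: bool = False,
) -> EnrichmentResult:
    """Test every (pathway, direction) pair for SCA over-representation.

    Parameters
    ----------
    sca_increased, sca_decreased:
        Protein ids with significantly increased / decreased abundance.
        Both sets are intersected with the universe before testing.
    universe:
        ``"annotated"`` (default) uses all annotated proteins of the
        reference proteome; ``"detected"`` restricts the universe to the
        supplied ``detected`` protein set.
    combine_directions:
        Additionally test the union of both SCA sets as direction ``"any"``.

    BH correction is applied across pathways within each direction.  The
    returned table is unfiltered and sorted by adjusted p-value.
    """
    univ = annotation.universe
    if universe == "detected":
        if detected is None:
            raise ValueError("universe='detected' requires a detected protein set")
        univ = univ & set(detected)
    elif universe != "annotated":
        raise ValueError("universe must be 'annotated' or 'detected'")
    if not univ:
        raise ValueError("empty annotation universe")

    pathway_members = {
        pw: annotation.members(pw) & univ for pw in annotation.pathways
    }
    pathway_members = {pw: m for pw, m in pathway_members.items() if m}
    n_total = len(univ)

    directions = {
        INCREASED: set(map(str, sca_increased)),
        DECREASED: set(map(str, sca_decreased)),
    }
    if combine_directions:
        directions["any"] = directions[INCREASED] | directions[DECREASED]

    rows = []
    n_unannotated = {}
    for direction, sca in directions.items():
        sca_in = sca & univ
        n_unannotated[direction] = len(sca) - len(sca_in)
        p_raws = []
        block = []
        for pw, members in sorted(pathway_members.items()):
            a = len(sca_in & members)
            b = len(sca_in) - a
            c = len(members) - a
            g = n_total - a - b - c
            p = fisher_one_sided(a, b, c, g)
            p_raws.append(p)
            block.append(
                {
                    "pathway_id": pw,
                    "pathway_name": annotation.name(pw),
                    "direction": direction,
                    "n_sca_in_pathway": a,
                    "n_sca_not_in_pathway": b,
                    "n_other_in_pathway": c,
                    "n_other_not_in_pathway": g,
                    "odds_ratio": _odds_ratio(a, b, c, g),
                    "p_raw": p,
                    "pathway_fraction_of_proteome": (a + c) / n_total,
                    "sca_fraction_of_sca": a / (a + b) if (a + b) else 0.0,
                }
            )
        adj = bh_adjust(p_raws)
        for row, p_adj in zip(block, adj):
            row["p_adj"] = float(p_adj)
        rows.extend(block)

    table = pd.DataFrame(
        rows,
        columns=[
            "pathway_id", "pathway_name", "direction",
            "n_sca_in_pathway", "n_sca_not_in_pathway",
            "n_other_in_pathway", "n_other_not_in_pathway",
            "odds_ratio", "p_raw", "p_adj",
            "pathway_fraction_of_proteome", "sca_fraction_of_sca",
        ],
    )
    if len(table):
        table = table.sort_values(
            ["p_adj", "p_raw", "pathway_id", "direction"], kind="stable"
        ).reset_index(drop=True)
    return EnrichmentResult(
        table=table, universe_size=n_total, n_unannotated=n_unannotated
    )
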