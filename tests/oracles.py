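"""Independent reference implementations used to check the library.

Everything here is deliberately written in a different style from the
package (plain loops, substring scans, exhaustive enumeration) so that a
bug in the implementation is unlikely to be mirrored by the oracle.
"""

from __future__ import annotations

import itertools
import math


def brute_force_cleave(sequence: str, rule: str, missed: int):
    """Enumerate peptides by first marking every cleavage site, then
    listing all runs of at most ``missed + 1`` consecutive fragments.

    Returns a list of (peptide, start, end, n_missed) tuples.
    """
    cut_after = []
    for i, ch in enumerate(sequence):
        if ch not in "KR":
            continue
        if i == len(sequence) - 1:
            continue
        if rule == "trypsin_strict" and sequence[i + 1] == "P":
            continue
        cut_after.append(i)
    starts = [0] + [i + 1 for i in cut_after]
    ends = [i + 1 for i in cut_after] + [len(sequence)]
    fragments = list(zip(starts, ends))
    out = []
    for m in range(missed + 1):
        for i in range(len(fragments) - m):
            s = fragments[i][0]
            e = fragments[i + m][1]
            out.append((sequence[s:e], s, e, m))
    return out


def rescan_peptide_occurrences(sequences: dict[str, str], peptides):
    """Count occurrences of given peptide strings by brute substring
    re-scanning, keeping only matches that lie on digestion fragments is
    NOT attempted here: the caller must pass fully cleaved peptides and the
    scan checks flanking context instead.

    Returns {peptide: [(protein_id, start), ...]} for exact tryptic
    occurrences under the strict rule.
    """
    found: dict[str, list[tuple[str, int]]] = {p: [] for p in peptides}
    for pid, seq in sequences.items():
        for pep in peptides:
            start = 0
            while True:
                k = seq.find(pep, start)
                if k < 0:
                    break
                end = k + len(pep)
                left_ok = k == 0 or (seq[k - 1] in "KR" and pep[0] != "P")
                right_ok = end == len(seq) or (pep[-1] in "KR" and seq[end] != "P")
                internal_cut = any(
                    pep[i] in "KR" and (i + 1 < len(pep) and pep[i + 1] != "P")
                    for i in range(len(pep) - 1)
                )
                if left_ok and right_ok and not internal_cut:
                    found[pep].append((pid, k))
                start = k + 1
    return found


def shared_peptides_by_rescan(fastas: dict[str, dict[str, str]],
                              rule: str = "trypsin_strict",
                              min_len: int = 7) -> set[str]:
    """Shared-peptide detection written as an independent scanner: digest
    every protein with :func:`brute_force_cleave` at zero missed cleavages
    and intersect the per-species peptide sets."""
    per_species = {}
    for sp, proteins in fastas.items():
        peps = set()
        for seq in proteins.values():
            if not seq:
                continue
            for pep, _s, _e, _m in brute_force_cleave(seq, rule, 0):
                if len(pep) >= min_len and not (set(pep) & set("BXZUO")):
                    peps.add(pep)
        per_species[sp] = peps
    shared = set()
    species = list(per_species)
    for a, b in itertools.combinations(species, 2):
        shared |= per_species[a] & per_species[b]
    return shared


def welch_t(x, y) -> float:
    """Classical Welch t statistic, written long-hand."""
    nx, ny = len(x), len(y)
    mx = sum(x) / nx
    my = sum(y) / ny
    vx = sum((v - mx) ** 2 for v in x) / (nx - 1)
    vy = sum((v - my) ** 2 for v in y) / (ny - 1)
    return (mx - my) / math.sqrt(vx / nx + vy / ny)


def hypergeom_upper_tail(a: int, b: int, c: int, g: int) -> float:
    """One-sided Fisher p by exhaustive enumeration of all tables with the
    same margins, using exact rational arithmetic via math.comb."""
    n_total = a + b + c + g
    k_pathway = a + c
    n_draw = a + b
    denom = math.comb(n_total, n_draw)
    p = 0
    lo = max(0, n_draw - (n_total - k_pathway))
    hi = min(k_pathway, n_draw)
    for x in range(lo, hi + 1):
        if x >= a:
            p += math.comb(k_pathway, x) * math.comb(n_total - k_pathway, n_draw - x)
    return p / denom


def bh_step_up(p_values):
    """Benjamini-Hochberg by the textbook step-up recipe."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p_values[i] * m / rank)
        adjusted[i] = running
    return adjusted


def brute_force_permutation_fdr(values, n1, s0, alpha):
    """Loop-based permutation-FDR procedure over ALL distinct relabelings
    (identity excluded), for tiny matrices.

    ``values`` is a list of per-protein sample lists (no missing values);
    the first ``n1`` columns are group 1.  Returns (cutoff, flags).
    """
    n = len(values[0])

    def d_stat(row, idx1):
        idx2 = [i for i in range(n) if i not in idx1]
        x = [row[i] for i in idx1]
        y = [row[i] for i in idx2]
        mx = sum(x) / len(x)
        my = sum(y) / len(y)
        vx = sum((v - mx) ** 2 for v in x) / (len(x) - 1)
        vy = sum((v - my) ** 2 for v in y) / (len(y) - 1)
        return (mx - my) / (s0 + math.sqrt(vx / len(x) + vy / len(y)))

    identity = tuple(range(n1))
    obs = [abs(d_stat(row, list(identity))) for row in values]
    perms = [c for c in itertools.combinations(range(n), n1) if c != identity]
    perm_abs = []
    for c in perms:
        perm_abs.extend(abs(d_stat(row, list(c))) for row in values)

    candidates = sorted(set(obs))
    best = None
    fdrs = []
    for cand in candidates:
        n_obs = sum(1 for v in obs if v >= cand)
        n_perm = sum(1 for v in perm_abs if v >= cand) / len(perms)
        fdr = min(1.0, max(0.0, n_perm / max(1, n_obs)))
        fdrs.append(fdr)
    # monotone non-increasing via running minimum
    mono = []
    cur = 1.0
    for f in fdrs:
        cur = min(cur, f)
        mono.append(cur)
    for cand, f in zip(candidates, mono):
        if f <= alpha:
            best = cand
            break
    if best is None:
        return math.inf, [False] * len(values)
    return best, [v >= best for v in obs]
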