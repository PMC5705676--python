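# Methods

This note documents the models, algorithmic choices and numerical
conventions behind `proteotrim`, and what the synthetic-data validation
does and does not demonstrate.

## In-silico digestion

Proteins are cleaved C-terminally of lysine (K) and arginine (R). Two rule
variants are exposed because published pipelines differ and the guarantee
given by trimming differs between them (see below):

- `trypsin_strict` (default): cleavage is suppressed when the next residue
  is proline. This is the convention of the common digestion tools and of
  search-engine tryptic digestion.
- `trypsin_p`: cleavage after every K/R.

Keil sub-rules (e.g. cleavage of WKP/MRP) are deliberately not modelled.
N-terminal methionine loss is not modelled either; digestion operates on
the annotated sequence as given. Coordinates are 0-based half-open
everywhere in the library (`sequence[start:end] == peptide`); reports
additionally render 1-based inclusive positions for human reading.

Defaults: **no missed cleavages** and **minimum peptide length 7** — the
operating point of the trimming workflow, since shorter peptides are in
most cases incompatible with MS identification. With 0 missed cleavages
the peptides partition each protein exactly (asserted as a property test);
with `k` missed cleavages every concatenation of ≤ k+1 consecutive
fragments is additionally produced.

Peptides containing ambiguity codes (B, X, Z, U, O) are excluded from the
peptide universe but tallied: identical-string comparison on unknown
residues is meaningless, and exclusion is conservative — an X can never
cause sequence to be removed. Ambiguity codes are otherwise accepted on
input (annotated proteomes contain them); a terminal `*` is stripped, an
internal `*` rejected.

## Shared-peptide trimming

A peptide is *shared* when its string (length ≥ 7, fully cleaved) occurs in
the digests of two or more species. Matching is case-sensitive identity on
uppercased sequences; an optional I/L-equivalence flag collapses the
isobaric leucine/isoleucine pair before matching (off by default, since the
plain workflow uses exact string identity).

Removal is **coordinate-based over digest fragments**, not substring
search: only occurrences that are themselves digest fragments are excised,
so a shared string embedded inside a longer species-unique peptide (e.g.
across a proline-suppressed site) is untouched. All occurrences are removed
from **all** species, including repeated occurrences within one protein.
Within-species repetition (the same peptide in two proteins of one species)
is *not* removal-eligible: that is the search engine's razor-peptide
problem, not a taxonomic ambiguity.

Two modes:

- `single_pass` (default): digest → detect → excise once, then verify by
  re-digesting; anything still shared is reported as `residual_shared`
  with a warning.
- `fixpoint`: repeat until the verification digest finds nothing shared.
  Termination is guaranteed because total residue count strictly decreases
  while any shared peptide remains.

With fully cleaved peptides the two modes coincide: every internal fragment
boundary is a cleavage site whose context (K/R before, non-proline after
under the strict rule) survives excision of whole neighbouring fragments,
so a single pass provably reaches the fixpoint under either rule. Novel
"junction" peptides *can* arise when the shared universe is widened to
missed-cleavage products (`--missed > 0`): excising a fragment joins its
two neighbours — which may individually be shorter than the length floor
and therefore never shared — into a new missed-cleavage peptide that may
match another species. The test suite constructs exactly this case and
shows that `fixpoint` mode eliminates it. Note the asymmetry between
trimming (always applied to fully cleaved fragments at recorded
coordinates) and detection (whose universe follows `missed_cleavages`);
search engines typically permit 2 missed cleavages, so trimmed databases
remain heuristic with respect to missed-cleavage identifications — this
mismatch is inherited from the underlying workflow and documented rather
than hidden.

Proteins trimmed to zero length are dropped from FASTA output (search
engines reject empty entries) but fully retained in the tabular reports.
Overlap is reported both as symmetric distinct-peptide counts and as
row-normalised percentages (the same shared count is a different fraction
of each species' peptide universe).

## Differential abundance

For each protein with intensities `x` (group 1) and `y` (group 2), after
dropping missing values:

    d = (mean(x) − mean(y)) / (s0 + sqrt(var(x)/n_x + var(y)/n_y))

with n−1 variances. `s0` (default **1**) is the SAM-style fudge factor
added to the unequal-variance (Welch) standard error; it de-emphasises
proteins whose variance is accidentally tiny. At `s0 = 0` the statistic is
exactly the classical Welch t (asserted against an independent
implementation to 1e−10).

Missing values are never imputed. A protein is *quantifiable* when it has
at least `ceil(0.6 · n_g)` valid values in **each** group (3 of 5 per
condition for a five-replicate design); everything else is excluded before
testing.

Significance uses a symmetric permutation FDR. Group labels are reshuffled
— exhaustively over all distinct relabelings when their count (excluding
the identity) is at most `n_permutations` (default **250**), otherwise by
that many seed-deterministic random draws — and |d| is recomputed under
each relabeling, excluding proteins that fall below two valid values per
permuted group. For candidate cutoffs c at the observed |d| values,

    FDR(c) = (mean over permutations of #{|d*| ≥ c}) / max(1, #{|d| ≥ c})

clipped to [0, 1] and made monotone non-increasing by a running minimum;
the chosen cutoff is the smallest c with FDR(c) ≤ α (default **0.05**).
This is a deliberately plain, fully documented estimator: it uses a
symmetric cutoff on |d| and no π₀ correction, so specific significant-
protein counts from tools with asymmetric-cutoff implementations are not
expected to be reproduced number-for-number.

## Pathway over-representation

Proteins with significantly changed abundance (SCA) are split by direction
of change and each (pathway, direction) pair is tested with a one-sided
Fisher's exact test — the hypergeometric tail P[X ≥ a] — on

|            | in pathway | not in pathway |
|------------|-----------:|---------------:|
| SCA        | a          | b              |
| not SCA    | c          | g              |

The default universe is **all annotated proteins** of the species'
reference proteome (pathway size is judged relative to the proteome); a
`detected`-universe option restricts to observed proteins, since either
convention is defensible. SCA proteins without any pathway annotation are
excluded from the table but counted and reported. Benjamini–Hochberg
correction is applied across pathways within each direction. Pathways are
overlapping gene sets, so the tests are not independent; no significance
cutoff is hard-coded and the full table is returned sorted by adjusted p.

## Synthetic data

The generators are pure functions of their configuration (including the
seed) and emit machine-readable ground truth.

- **Proteomes**: background residues are drawn i.i.d. with K/R at a
  combined 1/9 (mean tryptic fragment ≈ 9 residues, realistic for
  bacterial proteomes) and uniform mass on the other 18 residues. Planted
  shared peptides are exact tryptic products (no internal K/R, K/R
  terminus, non-proline start) inserted at cleavage boundaries, so the
  digest recovers them verbatim at recorded coordinates; the generator
  re-digests its own output to verify this at generation time. Accidental
  background sharing is *reported*, not prevented — preventing it would
  bias the sequence statistics the tests rely on. The
  `four_species_community` preset plants sharing at the ~16% level between
  two "related" members and trace-level sharing elsewhere.
- **Intensities**: value = protein baseline (Normal(25, 2) on the log2
  scale) + planted effect (default 2 log2 units = 4× the within-group SD
  of 0.5, on 10% of proteins, random sign, group 2 only) + Normal(0, 0.5)
  noise; missingness (default 10%) applied afterwards, either completely
  at random or weighted towards low intensities via a logistic weight.
- **Annotations**: random multi-membership pathways (default 20 pathways
  of 10–40 members over the universe) with one pathway drawing half its
  members from the supplied SCA set.

What this does **not** emulate: spectral identification and its error
modes, LFQ normalisation artifacts, correlated protein abundances
(complexes/operons), heavy-tailed intensity noise, or homology-structured
sequence similarity (real shared peptides come from conserved genes, not
random collisions). Passing tests therefore demonstrate the correctness of
the algorithms under their stated model, not the biological fidelity of
any particular dataset.

## Validation problem sizes

The test suite and `scripts/acceptance.py` validate at desk scale: 500
random sequences (≤ 200 aa) against a brute-force digestion enumerator; 50
random communities of 2–5 species (≤ 300 proteins) for trim conservation
and disjointness (verified by an independent substring scanner); a
four-species community of 60 proteins/species for the ~16% overlap
recovery; 10–20 replicates of 1000 proteins × (5 vs 5) at 250 permutations
for FDR control and power; 1000 random 2×2 tables (N ≤ 60) against an
exact enumeration oracle. These sizes make the full suite run in well
under a minute while keeping every estimate's Monte-Carlo error small
relative to its acceptance margin.

## Known limitations

- Trimming guarantees database-level disjointness for fully cleaved
  peptides only; identifications of missed-cleavage or modified peptides
  can still be ambiguous between species.
- The permutation-FDR estimator is symmetric in |d|; tools using
  asymmetric up/down cutoffs will flag slightly different sets.
- For small designs (e.g. 2 vs 2) the number of distinct relabelings is
  tiny, the FDR estimate is coarse, and the smallest attainable FDR may
  exceed α, in which case nothing is called significant.
- Fisher tests on overlapping pathways are positively dependent; BH is
  applied as is, as in standard practice, without dependency correction.
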