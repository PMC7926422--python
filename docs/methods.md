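# Methods

## The PPR recognition code

PLS-subfamily PPR editing factors bind single-stranded RNA with one motif
per nucleotide. The empirical code correlates the amino acids at each
motif's 5th and last positions with the aligned base. We train it as a
log-ratio table per motif type: tally, over alignments of known factors to
their targets, the weight with which each (aa5, aaLast) pair aligns with
A, C, G and U, and score

    score(pair, N) = ln((k + obs(pair, N)) / (k + exp(pair, N)))

with pseudocount k = 10. The expected count is the two-way independence
expectation within the motif type, `row_total(pair) × col_total(N) /
grand_total` — the count implied by the overall amino-acid-pair and
nucleotide frequencies if the two were unassociated. This null is the
standard one for contingency counts; it is isolated in
`code_scoring.expected_counts` so an external base-composition null could
be swapped in. Consequences of the formula worth knowing: a cell with
obs = exp scores exactly 0; a pair never observed for a motif type has
exp = 0 in every column and therefore scores 0 everywhere (unknown pairs
are neutral, not penalised); for fixed expected count the score is
strictly increasing in the observed count. Tables are keyed by the motif
label as given (P1 and P2 stay distinct); an optional coarsening map
(P1, P2 → P, etc.) pools fine labels at both training and lookup time for
sparse training sets.

### Alignment and scoring

Site windows end at the edited C. The E2 motif is anchored at offset −2
relative to that C (E1 then falls at −3, the C-terminal-most P/L/S motif
at −4) and each motif toward the N-terminus steps one base further 5′.
Proteins lacking E2 anchor their C-terminal-most motif at −4 by default
(`no_e2_anchor`); only E2-bearing factors are well characterised, so this
fallback is a convention, not an inference. A protein–site score is the
sum of per-motif lookups. Motifs aligned 5′ of the window, gap residues
(unannotatable code positions) and motif types absent from the tables
contribute exactly 0, so long arrays can overhang short conserved regions
without being dropped from the motif count. E1/E2 motifs act as anchors
only unless `score_terminal_motifs` is set and their types are present in
the tables — whether terminal motifs carry code information is unsettled,
so the default is conservative. Candidate ranking is competition ranking:
a protein outscored by k others has rank k + 1; exact ties share the
smaller rank. T is mapped to U and case normalised at every ingestion
point.

### Truncation semantics

`truncate_protein(p, k)` models a premature stop inside motif k: motifs
with index ≥ k, E1/E2 and the DYW domain are removed. The stop index must
lie in 1..len(motifs); indices past the array are rejected rather than
treated as no-ops, so "re-truncating" an already-truncated protein at the
original index is an error by design. The composition law
`truncate(truncate(p, j), k) == truncate(p, k)` for k ≤ j is the invariant
tests rely on.

## Editing quantification and differential calling

Editing extent at a site is edited/(edited + unedited) reads: T/(C+T) on
forward-strand transcripts, A/(G+A) where the transcript is on the reverse
strand of the reference. Other bases at the position are treated as
sequencing noise and excluded from the denominator; an all-bases
denominator is available via `all_bases_denominator`. Zero informative
coverage yields an explicitly undefined extent rather than an exception.

The per-position test between two genotypes is the Fisher exact test on
[[edited_A, unedited_A], [edited_B, unedited_B]], two-sided by the
minimum-likelihood convention (sum the probabilities of all outcomes no
more probable than the observed table). The implementation enumerates the
hypergeometric support in log space with `lgamma` — exact for any counts,
no normal approximation. Outcomes are included when
log pmf ≤ log pmf_obs + log1p(1e-7); the 1e-7 relative tie tolerance
absorbs floating-point noise among exactly tied probabilities and matches
the convention of the widely used implementations. Multiple testing uses
the Simes-Hochberg step-up adjustment (via statsmodels) over the family of
all positions showing C/U variation — any reference-C position (on the
transcript strand) with at least one edited read in either sample — not
just annotated sites. Odds ratios add a pseudocount of 0.5 to every cell
so they are finite with zero cells.

Calling thresholds: positions need ≥ `min_total` (default 10) informative
reads in both samples; a position is significant when adjusted p ≤ alpha
(default 0.05) and the absolute extent change is ≥ `delta_min` (default
0.10); a significant decrease to ≤ 5% of the wild-type extent
(`lost_ratio`) is classified "lost". The source study applied no extent
threshold, so its analysis corresponds to `delta_min = 0`; the default
cutoff exists to keep large-coverage trivial effects out of candidate
lists, and all three knobs are CLI flags. Published p-values for such
tables are typically multiplicity-adjusted over an unreported family size
and cannot be recomputed from per-site counts alone; the package therefore
treats reported percentages, not reported p-values, as reproducible.

`codon_effect` substitutes T at the edited CDS position and translates
both codons with the standard code. Under that code a third-position
C-to-T change is always synonymous; the bundled synonymous study site has
no reported codon identity, so a representative third-position codon
(`SYNONYMOUS_PLACEHOLDER_CODON`, labelled as such) stands in for it.

Optional SAM/BAM ingestion streams reads (no index required) and applies
mapping quality ≥ 10 and base quality ≥ 20 by default; the filter values
are logged since different studies use different cutoffs.

## Orthologue comparison

For each species the putative orthologue is scored against the homologous
site window in that species' own mitochondrial genome; a site is editable
when the genomic base is C and non-editable when it is T (rarely A or G).
The per-site test is a one-sided two-sample t-test of the alternative
"editable sites score higher". Welch's unequal-variance form is the
default because species panels are unbalanced in size and spread; the
pooled-variance form is a flag. Groups with fewer than two observations
are flagged untestable rather than raising. Two constant groups (zero
variance everywhere) are resolved analytically: p = 0.5 on equal means,
0 or 1 otherwise.

## Synthetic data: what it emulates, and what it does not

`GeneratorConfig` drives four seeded generators; each draws from its own
substream (`SeedSequence(seed, spawn_key=…)`), so outputs are reproducible
and adding a generator cannot perturb existing ones.

* Training observations: per motif type, 24 amino-acid pairs each receive
  a planted preferred base (the first four cover A/C/G/U so every base is
  constructible) and 40 aligned-base draws from a multinomial with the
  preferred base's probability ∝ exp(contrast), contrast 3.0 by default —
  strong but imperfect preferences, comparable to a well-trained code.
* Factor panel: a planted 17-motif factor (the architecture of the study's
  factor) whose pairs match its target window base-for-base, plus 204
  decoys with random pairs and 10–18 motifs — the size of the nuclear
  PLS-PPR complement scanned in such studies.
* Count matrices: 204 forward-strand reference-C sites. The default
  extent profile mirrors the study: four sites losing editing
  (0.95 → 0.0), three minor decreases at the published secondary-site
  extents, 197 unchanged background sites cycling over realistic
  organellar extents (0.30–0.99). The seven planted sites use the study's
  published read depths (40–16,837); background coverage is uniform on
  500–2,000. Edited counts are Binomial(coverage, extent); A/G miscalls
  are added at 0.1% each, which leaves the C+T denominator untouched.
* Orthologue panel: 20 editable + 20 non-editable species all carrying the
  planted factor. Non-editable species mutate the site base to T (80%;
  else A/G) and drift every window position at `divergence_rate` (default
  0.3); editable species drift at one tenth of that, emulating
  binding-site constraint.

Deliberate simplifications: reads are not simulated (no mapping or
duplicate structure, no strand bias, no quality-correlated errors);
editing extents are independent across sites (real neighbouring sites
co-vary); orthologue proteins are identical across species (real
orthologues diverge too, and N-terminal truncations occur); windows drift
under a uniform per-position substitution model. Passing tests therefore
demonstrate the statistical machinery and its calibration, not robustness
to alignment artefacts or phylogenetic correlation in real data.

## Numerical and scale choices

Fisher p-values below ~1e-308 underflow to 0.0, which is reported as-is.
Percentages print at two decimals and p-values at three significant
figures in tabular output. The exhaustive Fisher validation covers every
2×2 table with grand total ≤ 60 (635,375 tables, ~30 s); ranking recovery
uses 100 seeded trials of 205 proteins; the permutation-calibration
checks use 400–1,000 seeded trials. The acceptance script re-runs the
full study-profile simulation (204 sites), the 205-protein ranking and a
1,000-trial null calibration in a few seconds.
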