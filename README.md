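# ppredit

Analysis tools for plant organellar C-to-U RNA editing and the
pentatricopeptide-repeat (PPR) proteins that specify it.

In flowering-plant mitochondria, hundreds of genomic cytidines are
deaminated to uridine in mRNA. Site specificity comes from PLS-subfamily
PPR proteins: each ~35-aa motif in the tandem array contacts one
ribonucleotide, and the amino acids at a motif's 5th and last positions
largely determine the preferred base (the "PPR code"). `ppredit` is aimed
at researchers characterising editing factors from RNA-seq of wild-type
vs mutant plants: it quantifies editing, finds the sites a factor is
responsible for, scores candidate factors against sites with a trained
PPR code, and asks whether binding sites decay in species that no longer
need the edit.

## What it computes

**PPR-code scoring** (`ppredit.code_scoring`). From alignments of known
editing factors to their targets, per-motif-type tables score each
(aa5, aaLast) pair against each base:

    score(pair, N) = ln((k + obs(pair, N)) / (k + exp(pair, N))),  k = 10

where `exp` is the independence expectation (row total × column total /
grand total) within the motif type. A protein–site alignment anchors the
E2 motif two bases upstream of the edited C, steps one base 5' per motif
toward the N-terminus, and sums the per-motif lookups. Candidates are
ranked by competition ranking.

**Differential editing** (`ppredit.editing_quant`). From per-position
A/C/G/T read counts, editing extent at a site is T/(C+T) on the forward
strand (A/(G+A) on the reverse). Each position showing C/U variation is
tested between genotypes with a two-sided Fisher exact test
(minimum-likelihood convention, exact log-space hypergeometric
computation), corrected with the Simes-Hochberg step-up procedure; odds
ratios use a 0.5 pseudocount in every cell. Sites whose extent collapses
to ≤5% of the wild-type level are classified "lost". `codon_effect`
reports the amino-acid consequence of an edit within a CDS.

**Orthologue comparison** (`ppredit.ortho_compare`). Scores a factor's
orthologues against the homologous site sequence in each species and runs
a one-sided Welch t-test of whether editable-site species (genomic C)
score higher than non-editable ones (genomic T, rarely A/G).

**Synthetic data** (`ppredit.synthetic_data`). Seeded generators for all
of the above with planted ground truth: code training counts with known
base preferences, an exact-match factor among random decoys, binomial
read counts at chosen extents/coverages, and orthologue panels with
controlled binding-site divergence.

## Worked example

Editing extents and the differential test on the bundled study counts
(wild-type Col-0 vs the *mef100* mutant, seven mitochondrial sites):

```python
>>> from ppredit.datasets import MEF100_STUDY_SITES
>>> from ppredit.editing_quant import (fisher_differential, adjust_pvalues,
...                                    odds_ratio, codon_effect)
>>> p_raw = [fisher_differential(s.col0, s.mef100) for s in MEF100_STUDY_SITES]
>>> p_adj = adjust_pvalues(p_raw)
>>> for s, p in zip(MEF100_STUDY_SITES, p_adj):
...     print(f"{s.site:12s} {s.col0.percent:6.2f} {s.mef100.percent:6.2f} {p:.3g}")
nad1-493      95.38   6.04 0
nad1-500      88.67  79.34 1.96e-15
ccmFN2-356    95.00   0.00 2.13e-61
nad4-403      96.68   0.24 0
nad4-95        4.47   1.79 8.33e-06
nad4-84       37.60  18.39 8.59e-23
nad7-698      88.56   0.13 0
```

All seven sites are differentially edited; the four with near-total loss
(95→6%, 95→0%, 97→0.2%, 89→0.1%) are the sites whose editing requires the
mutated factor. The codon consequence of the *nad1*-493 edit:

```python
>>> codon_effect("CGT", 1)
CodonEffect(ref_codon='CGT', ref_aa='R', edited_codon='TGT', edited_aa='C',
            synonymous=False)
```

The same analyses run from the shell on TSV inputs:

```sh
ppredit simulate --outdir fx --seed 1
ppredit build-tables --observations fx/training_observations.tsv --outdir fx/tables
ppredit rank --proteins fx/proteins.tsv --sites fx/sites.tsv \
             --tables fx/tables --outdir out
ppredit diff-edit --counts-a fx/counts_wildtype.tsv \
                  --counts-b fx/counts_mutant.tsv --outdir out
ppredit compare-orthologues --records fx/orthologues.tsv \
                            --proteins fx/orthologue_proteins.tsv \
                            --tables fx/tables --outdir out
```

Each subcommand writes a `manifest.json` (parameters, input digests, seed,
version) so deterministic runs reproduce byte-for-byte.

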