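# Methods

This note documents the models, parameter choices and numerical
conventions behind `bulkbarcode`, and what its validation does and does
not demonstrate.

## The identification model

A pooled sample yields reads with the fusion-primer structure
`MID_f + tail1 + primer_f + insert + rc(primer_r) + rc(tail2) + rc(MID_r)`
(tails `CAGGACCAGGGTACGGTG` / `CGCAGAGAGGCTCCGTG`; template primers
COIAfor/LCO1490 for the 395 bp COI region and CB1/CB322R for the 343 bp
CytB region). Identification is deliberately reference-based rather than
OTU-based: each read is matched to a curated library of voucher
sequences and accepted only above a strict identity threshold. This
avoids sequence editing and chimera/OTU-inflation issues, at the price
of requiring a comprehensive library.

**Identity** is operational: the read is aligned end-gap-free against a
reference amplicon region (the read is a sub-region of the reference, so
reference end gaps are excluded from the denominator); identity =
matching columns / aligned columns, with internal gaps and N counting as
mismatches. The alignment is computed by edlib in infix mode. Among
minimal-edit-distance alignments the column count can differ by a column
or two, so identity is defined up to O(1/read length); the test suite's
independent dynamic-programming oracle asserts exact distance equality
and identity agreement within 2/len.

**Best hit.** Candidates are ordered by shared 8-mer count; a candidate
at edit distance *d* from a read of length *q* has identity at most
*q*/(*q*+*d*), so candidates provably below the current best are pruned
with banded distance computations only. The screened search therefore
returns exactly the brute-force argmax (a tested invariant). Ties across
species keep the lexicographically smallest species, are flagged, and
carry the runner-up identity for audit.

**Thresholds.** Acceptance is strictly greater than 0.97 by default
(per-gene overrides available); presence at a site requires strictly
more than `min_reads` (default 5) accepted reads summed over the chosen
scope of genes/directions/runs. Both comparisons are deliberately
strict: an occurrence with exactly 5 reads is *not* called present.
Success percentages are rounded half-up to two decimals
(103/107 → 96.26). "Missed species" counts species-site occurrences,
not species identities.

## Barcode validation

Pairwise distances use the Kimura 2-parameter model,
d = −½·ln((1−2P−Q)·√(1−2Q)), with P and Q the transition and
transversion proportions over compared sites. Sites where either base is
not a concrete A/C/G/T are excluded pairwise (numerator and
denominator). Pairs whose divergence makes the logarithm undefined are
flagged as saturated and excluded rather than silently dropped.
Sequences are used pre-aligned; equal-length amplicon regions are
compared positionally, and the module requires equal lengths rather than
aligning internally.

Trees are built with Saitou–Nei neighbour joining (deterministic
first-minimum tie-break). Additive matrices are recovered exactly — a
tested invariant, cross-checked against scikit-bio's independent NJ.
Negative branch-length estimates are clamped to zero with the deficit
moved to the sibling branch (configurable). Bootstrap support resamples
alignment columns with replacement; support for each internal
bipartition of the point-estimate tree is the percentage of replicate NJ
trees containing it (supports attach to the point tree; no consensus
tree is built).

## The simulator

The generator emulates the study conditions of a pooled two-gene
experiment, providing per-read ground truth:

| parameter | default | meaning |
|---|---|---|
| `substitution_rate` | 0.004 /base | per-base substitution error |
| `homopolymer_indel_rate` | 0.002 /run | ±1 length error per homopolymer run ≥3 |
| `mid_mistag_rate` | 0.08 | probability a read's MID pair is redrawn from tags in use |
| `reads_per_individual_mean` | 15 | expected reads per specimen per gene per run |
| `amplification_dispersion` | 0.6 | lognormal σ of the per-specimen amplification factor |
| `gene_failure` | none | species×gene amplification-success probability |
| `n_runs` | 2 | biological replicates sharing amplification factors |

Error rates are calibrated so that ≥99% of error-bearing reads stay
above 98% identity to their source haplotype — the regime in which a
97% acceptance threshold separates sequencing error from interspecific
divergence. Mis-tagging redraws both tags from pools already in use
(matching the observation that wrong combinations are made of known
tags), so a small fraction of jumped reads lands on another sample's
valid pair and is silently mis-binned — these are exactly the source of
"unexpected hits" and are flagged in the truth table whenever the
emitted pair differs from the sample's own. MID tags are generated
10-mers with pairwise Hamming distance ≥3; matching at demultiplexing is
exact, which maximises mis-tag detection.

Reference libraries with a programmed barcode gap place species on a
star phylogeny: Poisson multiple-hit substitutions with branch length
divergence/2 per tip, so the *estimated* (multiple-hit-corrected)
distance between tips matches the programmed value in expectation.
Divergence-summary validation uses a 20-species × 5-specimen library;
with fewer species the min/max of pair means occasionally fails to
bracket the programmed centre simply through small-sample spread.

What the simulator does **not** model: flowgram-level noise and
quality scores, chimeric amplicons, primer-site errors (errors are
confined to the insert; structural rejects in real data would be
higher), length variation of real CytB/tRNA regions, and DNA degradation
or body-size effects on template abundance. Passing the round-trip
checks therefore demonstrates the correctness of the analysis logic
under the stated error structure, not field-data performance.

## The bundled survey

`data/field_survey.tsv` is a ten-site, 46-species chironomid survey: per
(species, site), the number of individuals established by specimen-level
identification and the pooled amplicon reads assigned to that species.
Cells with reads but zero individuals are the unexpected hits. The table
was cross-checked against its own marginals: per-site read totals match
exactly; one column's individual sum exceeded its stated site total by
one, and the largest cell in that column was reduced by one so the table
is internally consistent (768 individuals overall; per-site totals
69, 78, 32, 167, 98, 28, 51, 99, 50, 96). The survey carries combined
read totals only, so survey-level analyses run on totals; per-gene /
per-direction / per-run scoping applies to pipeline-produced count
tables.

## Numerical and design choices

- Primer search is IUPAC-aware with a default tolerance of 2 mismatches
  and no indels in primer sites; N in a read matches any primer code but
  counts as a mismatch in identity scoring (an uncalled base should not
  veto trimming, but must not support a species call).
- Amplicon extraction accepts insert lengths within ±12 bp of the
  nominal length; gene assignment of reads uses a ±15 bp window around
  395/343 bp, wide enough for homopolymer indels while keeping the two
  genes unambiguous.
- Identity comparisons inside the best-hit search use exact integer
  cross-multiplication of (matches, columns) pairs, never float
  comparison, so tie handling is deterministic.
- Acceptance of identity/threshold comparisons is strict (`>`); the
  0.97 and 5-read defaults are surfaced in `IdentifyParams` /
  `PipelineConfig`.
- All randomness flows through `numpy.random.default_rng` seeds carried
  in parameter objects; identical configuration and seed reproduce
  byte-identical outputs (a tested invariant).
- Problem sizes used in validation: the simulated round-trip runs an
  8-site, 80-individual, 20-species community (~5,000 reads, two runs);
  oracle-equivalence checks use 1,000 read/library pairs; bootstrap
  uses B = 100 on 100-sequence libraries. These sizes make every
  stochastic check stable across seeds while keeping the whole suite
  fast.

## Known limitations

- Relative abundance is qualitative: read proportions track individual
  proportions, but amplification bias makes per-species correction
  factors (out of scope) necessary for quantitative abundance.
- The identity denominator convention (read span, reference end gaps
  free) differs from BLAST-style definitions by O(1/len); thresholds
  are defined with respect to this package's definition.
- Demultiplexing assumes vendor adapter removal has already happened;
  reads are expected to start at the forward or reverse MID.
- Equal-length positional comparison in the validation module is not a
  substitute for alignment when indel-bearing regions are compared.
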