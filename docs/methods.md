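# Methods

## Problem and pipeline

The package screens two "drug bags" — dispensing envelopes printed with
drug names, one per prescribing institution — for contraindicated
cross-bag drug combinations.  The pipeline is: catalog/table
preprocessing → dictionary-constrained token matching → cross-bag pair
enumeration → registry lookup → templated response, with an evaluation
layer (package accuracy, CER, WER) and a synthetic benchmark generator.
Real images and OCR engines sit behind a fixture interface
(`medscreen.ocr`): the pipeline consumes only ordered token text, so any
engine that produces `{text, order_index}` records can be plugged in.

## Name normalization

Contraindication is a property of the active ingredient, so dosage is
noise.  `normalize_name` NFC-normalizes, removes parenthesized groups
whose content is dosage-like, collapses whitespace, and strips.  A group
counts as dosage-like only when it contains a number immediately followed
by a dose unit (g, mg, mcg, μg, mL, L, IU, %) or consists solely of a bare
number; wordy parentheticals (manufacturer, brand qualifiers) are kept.
This is deliberately conservative — mangling a name is worse than leaving
a stray dosage, because matching is fuzzy anyway and a leftover
parenthetical merely lowers one similarity score.

NFC composition makes one Korean syllable block one code point, so the
character-level metrics count syllables uniformly with Latin letters.
All comparisons (catalog dedup, table membership, matching, metrics) are
case-insensitive; stored display forms keep the first-seen case, since
catalogs mix cases and OCR case errors are common.

## Matching

The similarity function is normalized Levenshtein,
`1 − lev(a,b)/max(|a|,|b|)`, on case-folded NFC text — the standard
choice for dictionary-constrained OCR post-correction; it makes the
acceptance threshold a fraction of the longer string's length.  The
default threshold is **0.7**, the operating point at which
dictionary-constrained extraction performs best in the drug-bag setting;
it is exposed as a parameter and a `--threshold` flag.

A token is resolved to the catalog entry with maximal similarity.  Ties
break to the longer entry, then lexicographically — longer first because
a longer entry matching equally well carries more corroborating
characters; the lexicographic step only guarantees determinism.

Extraction is two-pass: single tokens first, then space-joined
concatenations of adjacent pairs where neither member matched alone.
Word-box OCR engines segment multi-word product names into separate
tokens; the greedy left-to-right merge recovers them without
re-implementing region/affinity box grouping.  Consequences worth
knowing: acceptance per *token* is provably monotone in the threshold,
but the merge pass can in principle trade one single-token acceptance for
one merged acceptance as the threshold rises; on realistic fixtures the
total accepted count is monotone (checked on a 20-point grid in the
tests).  Reading order matters to the merge, so it is defined by
`order_index`, never by file order.

## Screening

Pairs are formed only across bags (each institution's own dispensing
already screens within-bag combinations): the Cartesian product in
bag-a-major order, never a pair drawn from one bag.  Lookup is unordered
and case-insensitive.  If the same drug is recovered from both bags the
self-pair {X, X} is checked like any other and flags only if the table
itself contains it — registries can list same-ingredient conflicts.
Unmatched tokens are carried in the JSON report as a warning list so a
user can see what the dictionary could not absorb.  The user-facing
message is a fixed template ("X and Y are contraindicated." / "No
contraindications exist."); a pluggable responder interface exists so a
paraphrasing layer (e.g. an LLM) could replace the template, but
correctness always lives in the table lookup, never in the responder.

## Metrics

CER and WER are `(S+D+I)/N` with `N` the reference length in characters
and words respectively.  Minimal-cost alignments can split S/D/I
differently, but the sum is the Levenshtein distance and thus invariant;
only the sum is used.  Both can exceed 1 when the hypothesis is much
longer than the reference.  The empty reference is an error (undefined
metric), not 0 or infinity.  Corpus aggregation pools edits over pooled
reference length (sum/sum, not mean of per-case rates), so every
reference word and character carries equal weight regardless of package
size; corpus accuracy is correct words over total words, where a word is
correct when its normalized form appears in the extracted list.  Package
accuracy divides recovered-name count by the configured package size
(default 8, each name contributing 0.125).

## Synthetic benchmark

`generate_catalog` draws multi-word product names from a syllable lexicon
(base word + form word like `tab.`/`cap.` + parenthesized dose), with a
configurable fraction of dosage variants of earlier names so that
normalization's duplicate-collapsing path is always exercised.  Names are
synthetic, not real Korean product names: same statistical shape (length,
word count, dosage suffixes), no licensing or download.

`corrupt_text` models print/scan degradation at the character level:
independent substitution (to a different random letter) and deletion per
character, plus a geometric number of insertions at each gap.  The
generator is a pure function of (seed, text) — the seed is mixed with a
CRC of the text so equal seeds on different tokens decorrelate while
remaining reproducible across processes.

The benchmark experiment builds three 8-drug packages: A = 3 drugs with
registered interaction partners + 5 clean, B = the 3 partners + 5 clean,
C = 8 clean; exactly 3 contraindicated pairs are planted between A and B,
and decoy table pairs touch only distractor drugs.  Print fonts function
as difficulty levels, so they are modeled as five noise conditions of
increasing severity — per-character (substitution, deletion, insertion)
rates (0, 0, 0) up to (0.060, 0.020, 0.020) — chosen to span clean print
through badly degraded scans.  With 10 replicates this yields 150 bag
fixtures.  Each fixture lays the package out as OCR word boxes:
boilerplate lines (pharmacy header, instructions) followed by each name
split into per-word tokens, all passed through the condition's noise.

What the generator does *not* emulate: real font geometry and confusion
matrices (visually similar glyphs are not more confusable), line-level
vs word-level engine segmentation differences, layout-dependent reading
order, and Korean phonology-aware errors.  Passing tests therefore show
the decision core is correct and robust to generic character noise — not
that any particular OCR engine reaches a particular accuracy on paper
bags.

## Numerical and scale choices

- Levenshtein is the package's own two-row DP; tests cross-check it
  against an independent C implementation (edlib) exhaustively on all
  4-symbol string pairs of length ≤ 4 (116,281 pairs) plus a 30,000-pair
  seeded sample at lengths up to 6 — exhaustive length-6 enumeration
  (~30M pairs) adds no new DP transition pattern at three orders of
  magnitude more runtime.
- Monte-Carlo noise calibration uses 1,000 seeds and a 99% binomial band;
  planted-pair recovery is checked across 20 generator seeds at zero
  noise; threshold monotonicity on a 20-point grid over fixed noisy
  fixtures.
- All generators are seeded; fixture files regenerate byte-identically
  for a fixed seed.
- Degenerate inputs: empty bags screen to an empty report with a distinct
  "no drugs recognized" message and exit code; empty catalogs, empty
  references and out-of-range rates/thresholds raise `InvalidInputError`
  (CLI exit code 2).

## Known limitations

- The adjacent-pair merge handles names split into two boxes; names split
  into three or more boxes (rare for two-word product names) are not
  reassembled.
- Matching is O(catalog × token length²) per token; for a national-scale
  catalog (tens of thousands of entries) a length-bucketed or trie-based
  prefilter would be the first optimization.
- Ingredient-code-level interaction logic, severity grading and
  dosage-dependent interactions are out of scope: the table is a flat
  set of product-name pairs.
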