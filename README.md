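# medscreen

Polypharmacy — taking five or more medications at once — exposes patients,
especially elderly cancer patients, to drug–drug interactions (DDIs) that
can blunt therapy or cause severe adverse reactions.  A patient typically
holds one dispensing envelope ("drug bag") per prescribing institution,
each printed with its drug names; no single institution sees the combined
regimen.  `medscreen` is a screening toolkit for exactly that gap: given
the OCR text of two drug bags, it recovers the drug names, forms every
cross-bag combination, and flags the pairs listed in a
contraindicated-combination registry.

It is written for pharmacoinformatics researchers and medication-safety
tool builders who want the decision core of such a pipeline — everything
downstream of the OCR engine — as a tested, deterministic library.

## Method

1. **Catalog normalization.** The product catalog (the matching dictionary)
   and the contraindication table are preprocessed by stripping parenthesized
   dosage expressions — `Acer cap.(0.1g)` and `Acer cap.(0.2g)` both become
   `Acer cap.` — and collapsing the resulting duplicates, since
   contraindication is a property of the ingredient, not the dose.
2. **Dictionary-constrained extraction.** Each OCR token *t* is matched to
   the catalog entry *e* maximizing normalized Levenshtein similarity

   $$\mathrm{sim}(t,e) = 1 - \frac{\mathrm{lev}(t,e)}{\max(|t|,|e|)}$$

   and accepted when the best similarity reaches a threshold (default
   **0.7**).  A second pass retries concatenations of adjacent unmatched
   tokens, recovering names split across OCR word boxes.
3. **Cross-bag screening.** With drugs $A_1..A_m$ from bag A and
   $B_1..B_n$ from bag B, all $m \times n$ cross-bag pairs are formed —
   never within-bag pairs like $A_1,A_2$ — and each is looked up
   (unordered, case-insensitive) in the contraindication table.
4. **Evaluation.** Extraction quality is scored by package accuracy
   (each of a bag's 8 names contributes 0.125), character error rate
   $\mathrm{CER}=(S+D+I)/N$ over reference characters (one Korean syllable
   block = one NFC character), and word error rate
   $\mathrm{WER}=(S+D+I)/N$ over reference drug names.

A synthetic benchmark generator stands in for real images: plausible
product names, character-level OCR noise (substitution/deletion/insertion),
and a three-package experiment — package A holds 3 drugs with registered
interaction partners plus 5 clean drugs, package B the 3 partners plus 5
clean, package C 8 clean — across 5 noise conditions × 10 replicates
(150 bag fixtures, 3 planted contraindicated pairs).

## Worked example

```sh
$ medscreen simulate --out demo --seed 11 --noise 0 --replicates 1
wrote 15 bag fixtures under demo/bags

$ medscreen screen --catalog demo/catalog.csv \
    --contraindications demo/contraindications.csv \
    --bag-a demo/bags/A_font1_rep01.json \
    --bag-b demo/bags/B_font1_rep01.json
Kasu tab. and Podol syr. are contraindicated.
Racenigi cap. and Molxadolsu cap. are contraindicated.
Prilgitelu syr. and Dolprilte gran. are contraindicated.
```

The three reported pairs are exactly the pairs this seed planted between
packages A and B (`demo/manifest.json`, `planted_pairs`); screening A
against the clean package C prints `No contraindications exist.`  Exit
codes: 0 success, 2 input error, 3 no drugs recognized.  `--format json`
emits the full screening report (per-bag drugs, all pairs checked, flagged
pairs, unmatched tokens).

From Python:

```python
from medscreen import generate_experiment, screen_bags

exp = generate_experiment(seed=11, noise_scale=0.0, replicates=1)
bags = {b.bag_id: b for b in exp.bags}
report = screen_bags(bags["A_font1_rep01"], bags["B_font1_rep01"],
                     exp.catalog, exp.table)
print(report.message)
```

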