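# microtraits

Extraction of phenotypic character matrices from prokaryotic taxonomic
descriptions, with rigid/relaxed evaluation against a gold standard.

## The problem

Published taxonomic descriptions of bacteria and archaea hold a vast
store of phenotypic information — cell shape and size, Gram stain,
motility, growth temperature/pH/salinity envelopes, metabolic substrates
and products, antibiotic physiology — written as natural-language prose.
Comparative and phylogenetic analyses, however, need this information as
a **taxon-by-character matrix**: taxa in rows, characters in columns,
character states in cells. Building such matrices by hand is the
bottleneck of microbial phenomics.

`microtraits` is a text-mining pipeline for people who need those
matrices: microbial systematists, comparative biologists, and curators
of trait databases. It reads descriptions (plain text, TSV, or a simple
XML wrapper), triages every sentence to a fixed schema of **42
phenotypic characters** in 8 categories with a bank of balanced binary
classifiers (one linear SVM per character), extracts character states
with linguistic rules (regular expressions, POS-tag windows, dependency
patterns) and knowledge-base term matching with coordination expansion,
and emits a matrix whose cells hold structured values

```
negation │ modifier │ main value │ unit │ sub-character
```

e.g. `not │ strictly │ anaerobic` or `2–3 │ % │ NaCl`.

## Scoring a matrix

The package also implements the matching methodology for scoring an
output matrix against an expert gold standard matrix (GSM). Each
extracted value is paired with a GSM value and assigned a **rigid** and
a **relaxed** hit score in {0, 0.5, 1}: exact field-wise match → 1/1;
main value and negation match with other fields differing → 0.5/1;
partial main-value match → 0.5/0.5; wrong value or negation mismatch →
0/0. Cell hit scores are the sum over an optimal one-to-one alignment,
and per character

```
P  = Σ hit scores / # extracted values
R  = Σ hit scores / # GSM values
F1 = 2PR / (P + R)
```

computed for rigid and relaxed scores separately; overall accuracy is
the total relaxed hit sum over the total number of GSM values.

## Worked example

```python
from microtraits import ExtractionPipeline, TaxonDescription
from microtraits.corpus_io import serialize_structured_value
from microtraits.fixtures import generate_term_lists

desc = TaxonDescription(
    taxon_name="Gracilimonas tropica",
    paragraphs=[
        "Cells are Gram-negative. Cells are 0.3–0.5 μm in diameter. "
        "DNA G + C content is 33.1–34.4 mol%. "
        "Growth occurs at temperatures in the range 38–68 °C (optimum, 60 °C) "
        "and at pH 1.8–4.0 (optimum, pH 3.0). "
        "Acid is produced from glucose and fructose."
    ],
)
pipe = ExtractionPipeline(term_lists=generate_term_lists())  # no triage
matrix = pipe.run([desc])
for cid in sorted(c for (_, c) in matrix.cells):
    values = matrix.get("Gracilimonas tropica", cid)
    print(cid, " # ".join(serialize_structured_value(v) for v in values))
```

prints

```
cell_diameter             0.3–0.5 │ μm
fermentation_products     Acid
fermentation_substrates_used glucose # fructose
gc_content                33.1–34.4 │ mol%
gram_stain                Gram-negative
ph_maximum                4.0
ph_minimum                1.8
ph_optimum                3.0
temperature_maximum       68 │ °C
temperature_minimum       38 │ °C
temperature_optimum       60 │ °C
```

— the G+C content came from the `<CD> mol%` POS pattern, the diameter
from the 3-token keyword window after the numeral, the six growth
values from the range/optimum grammar, the Gram stain from term
matching, and the fermentation product/substrates from the passive
"is produced from" dependency pattern with coordination expansion.

## Command line

```bash
microtraits simulate --n-taxa 50 --seed 7 --out data/        # synthetic corpus + GSM
microtraits train    --instances data/instances.tsv --seed 7 --out bank.joblib
microtraits extract  --descriptions data/descriptions.xml \
                     --terms data/termlists --model bank.joblib --out matrix.csv
microtraits evaluate --output matrix.csv --gsm data/gsm.csv --report report.csv
```

`extract --no-predictor` disables sentence triage and routes every
sentence to every extractor, which trades precision for a small recall
gain — useful for measuring what the classifier bank buys you.

Because no description corpus is redistributed, the `simulate` command
(the `fixtures` module) generates synthetic descriptions from sentence
templates with typed slots and an exactly known gold standard, which is
what the test suite trains and evaluates on.

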