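# Methods

## Pipeline overview

Input descriptions pass through four stages: **preprocessing** (entity
replacement, character whitelisting, whitespace normalization, sentence
splitting, token/POS/dependency annotation), **sentence triage** (a bank
of per-character binary classifiers), **character extraction**
(linguistic rules for numeric characters, term matching plus dependency
patterns for string characters), and **matrix assembly**. A separate
**evaluation** component scores any output matrix against a gold
standard matrix (GSM) with rigid/relaxed hit scores.

## Character schema

The 42 characters and their 8 categories are a closed schema
(`characters.py`). Thirteen characters are numeric — %G+C (mol%), three
cell dimensions (μm), and the minimum/optimum/maximum triplets for
temperature (°C), pH (dimensionless) and salt concentration (%, M,
g l−1, with a sub-character naming the salt, default NaCl). The
remaining 29 are categorical. Six categorical characters form three
polarity pairs (organic/inorganic/fermentation substrates used vs not
used). Each categorical character is marked for *phrase* matching
(terms matched inside noun phrases, the full phrase extracted, e.g.
"short chains") or *sentence* matching (states occurring verbatim, e.g.
"Gram-negative", "motile", "convex"); the antibiotic characters are
pattern-driven ("sensitive to …" / "resistant to …"), with their term
lists used to confirm pattern fillers rather than to fire on their own.

## Structured values

Values are five-field records `negation │ modifier │ main value │ unit │
sub-character`, main value required. On disk empty fields are omitted,
which makes short forms ambiguous (`not │ motile` is negation+main;
`plump │ rods` is modifier+main; `2–3 │ % │ NaCl` is main+unit+sub).
Parsing resolves this by value kind: categorical values take the last
field as main and classify the leading field with a negation-cue
lexicon (not/no/non/neither/…); numeric values anchor the main on the
first digit-bearing field, with earlier fields negation/modifier and
later fields unit then sub-character. This covers qualified numerics
(`up to │ 4 │ μm`) that a fixed right-to-left assignment would
misread. Serialization round-trips under these rules provided a
modifier is not itself a bare negation cue.

## Parser adapter

Annotation is behind a three-function adapter contract (`tokenize`,
`pos_tag`, `parse_dependencies`). The shipped default is a
deterministic rule-based parser: a regex tokenizer that keeps decimal
ranges ("0.35–0.5"), unit tokens ("mol%", "μm") and hyphenated
compounds ("Gram-negative", "non-motile") whole; a lexicon + suffix
tagger emitting Penn-style tags (CD on all numerals and ranges); and
pattern dependencies for the constructions the extractors consume —
passive `nsubjpass`/`nmod` edges ("Acid is produced from glucose") and
simple active `nsubj`/`dobj`/`nmod` edges. The choice of a built-in
deterministic adapter makes every extraction rule and every test
reproducible with no model downloads; parse quality on arbitrary prose
is naturally below a trained statistical parser, which can be plugged
in through the same contract when available. The abbreviation list for
the sentence splitter (sp., subsp., e.g., approx., …) and the POS
lexicon are data files editable without code changes.

Cleaning is whitelist-based: letters, digits, whitespace and the
punctuation the downstream rules need (`. , ; : ( ) [ ] % ° μ – - / + <
> = ' " │ # &`) are kept; other symbols (e.g. "⇑") are removed.
Near-equivalent codepoints are repaired first (µ→μ, −→-, ˚→°, em→en
dash, curly quotes) so that units and ranges survive. The function is
total and idempotent.

## Sentence triage

One linear SVM per character (scikit-learn `LinearSVC`, C=1 — a robust
default, configurable), trained on that character's labeled sentences
as positives and an equal-sized uniform sample (seeded, without
replacement) of other sentences as negatives: margin classifiers are
sensitive to class imbalance, and per-character positive counts vary
widely. Features are binary counts of lower-cased word unigrams and
bigrams with all numerals collapsed to a `NUM` placeholder, so numeric
sentences share features like "NUM μm" instead of fragmenting the
vocabulary; the vocabulary is fit on the training split only. Each of
the 42 models votes independently, so a sentence can be routed to zero,
one or several extractors. No probability calibration or threshold
tuning is applied — the native decision boundary is used. In
cross-validation, folds are formed over unique sentences (a sentence
and all its labels stay together, preventing leakage through duplicated
text) and negative sampling is redone inside each training fold;
characters with fewer than k distinct positive sentences are skipped
with a warning.

## Numeric extraction

* **%G+C**: any CD-tagged numeral immediately followed by `mol%`.
* **Cell dimensions**: a numeral is assigned to diameter/length/width
  when the dimension keyword occurs within a 3-token window after the
  numeral (the primary rule); a symmetric 3-token window *before* the
  numeral (for "width of 0.5–0.9 μm" phrasing) acts as a lower-priority
  fallback. The nearest keyword wins; ties at equal distance prefer the
  following keyword; one numeral feeds at most one dimension.
  Qualifiers ("up to", "at least", "about") become the modifier field.
* **Growth triplets**: numeric mentions are classified by quantity
  (°C unit or "temperature" anchor; "pH" anchor; a concentration unit
  with a salt token) and by slot from the clause-bounded left context —
  "optim…" claims the optimum, "at least"/"minimum" the minimum,
  "up to"/"maximum" the maximum; a bare range ("pH 6–8") splits into
  minimum and maximum. A point value with no cue is deliberately left
  unassigned: a growth observation ("Good growth occurs at 1–25 °C")
  is never promoted to an optimum, keeping the output true to the
  original wording. Duplicate slot assignments are all kept, with a
  warning.
* **Standardization**: unit spellings map to canonical forms through a
  data-file synonym table (microns/µm/um → μm; mol % → mol%; …), range
  dashes unify to the en-dash; the operation is idempotent and unknown
  units pass through with a log message. No unit conversion (e.g.
  M ↔ %) is attempted — values are compared after spelling
  standardization only.

## Categorical extraction

Noun phrases are chunked with the POS pattern `DT? (RB|JJ|VBN|NN|NNS)*
(NN|NNS|NNP)` (degree adverbs are allowed inside a phrase so "slightly
brown colonies" stays whole; the cue "not" is not). Comma/and/or-
separated phrases filling one syntactic slot share a coordination
group. Term matching is whole-word and case-insensitive, longest term
first, and extracts the **full phrase**, not the bare term — the list
term "chains" yields the value "short chains". When any phrase of a
coordination group matches, all phrases of that group become values.
Dependency patterns are declarative data (trigger lemma, voice,
particle constraints, role→character map): the shipped inventory covers
"is produced from" (product/substrate roles), bare passive "is
produced" (other metabolic products), "sensitive to"/"resistant to"
(antibiotics), "require(s)/required … for growth" (vitamins & cofactors,
salinity; term-list-filtered), and "ferment(s)". A role filler that
also term-matches its character's list is flagged high-confidence. A
negated trigger ("no acid is produced from …") reroutes each role to
the character's polarity partner, or drops roles without one.

Negation scope is our own construction (the routing behaviour follows
the paired-character design; the mechanism had to be defined): a scope
runs from a cue (not, no, neither, nor, without) through an immediately
following negated verb to the end of its coordination list or clause —
the next finite verb, semicolon, or sentence end. Candidates inside a
scope route to the polarity partner ("… but not mannitol" → Not Used);
for partnerless characters a "No"-determiner phrase is kept verbatim
("No spores") and other cues fill the negation field ("not │ motile").
Values spanning phrase boundaries ("rod-shaped with slightly irregular
sides and pointed ends") are not merged; one phrase is one value.

## Matrix assembly

Rows appear in first-appearance order of taxa; the column axis is
always the full 42-character schema. Within a cell, exact duplicate
values collapse to the first occurrence — repeated mentions are not
repeated character states. An empty cell means "not stated", never
"absent"; nothing is imputed. On disk the matrix is UTF-8 CSV with a
`Taxon` column plus the 42 display names, multiple values joined with
`" # "`; write→read→write is byte-identical.

## Evaluation

Pair scoring applies, in order: (1) negation polarity mismatch → 0/0;
(2) all fields equal → 1/1; (3) mains and negations equal, other fields
differ → 0.5/1; (4) extracted main strictly contains the GSM main as an
order-preserving whole-token subsequence (extra surrounding tokens) →
0.5/1; (5) extracted main a strict token subset of the GSM main, or
token sets overlapping without containment → 0.5/0.5; (6) otherwise
0/0. The rule-4/rule-5 asymmetry is intentional and pinned by tests:
over-extraction around a correct value costs only rigid credit, while
truncation costs both. Comparison happens after normalization —
lower-casing, whitespace collapse, unit standardization, and parsed
range equality for numeric mains (so `6-8` equals `6–8`); negation is
compared as polarity, with a leading "no/not/non-" on the main value
counting as negative.

Cell alignment is an optimal one-to-one assignment (Hungarian
algorithm) maximizing the relaxed sum with rigid sums breaking ties
(weights 1024:1, exactly lexicographic for any realistic cell size);
tests verify it against exhaustive search. The one-to-one constraint
automatically caps a cell's hit sum at min(n_extracted, n_gsm).
Unmatched values on either side count in the denominators. Cells empty
in **both** matrices are excluded from the P and R denominators, since
including them would leave precision undefined. A machine-readable
override file of (taxon, character, extracted, gsm, relaxed)
adjustments can amend pair-level relaxed scores, standing in for a
manual re-review of imperfect matches.

## Synthetic corpus

The generator renders one sentence per template per taxon from typed
slots (numeric ranges, term slots, coordination lists) over small
per-character vocabularies, together with the exact structured values
each sentence carries — so a generated corpus has a perfect gold
standard and perfectly labeled training instances. Templates cover the
constructions the extractors must handle, including the hard ones:
"(optimum, …)" parentheticals, "at least … optimally …", "but not"
coordination, "No spores", verbatim "non-motile". Slot vocabularies
are disjoint across characters by default so that noise-free recovery
is exact; `shared_terms=True` plants "filamentous" in both the Cell
Shape and Colony Shape lists to recreate the cross-character ambiguity
that makes sentence triage pay for itself, and `decoy_fraction` adds
never-used terms to stress precision. Distractor sentences (the
`noise` fraction) use a disjoint vocabulary and carry no values.

Default study conditions in the tests: 50 taxa, seed 7, noise 0 for
end-to-end recovery and the triage ablation; 10-fold cross-validation
on the same corpus's instances. These sizes exercise every template
and classifier while keeping the full suite fast. What passing shows:
the mechanisms (rules, routing, scoring) are exact on text they were
designed for. What it does not show: performance on real journal
prose, whose lexical variety, typography and ambiguity the templates
deliberately do not imitate — corpus-level scores require a real
annotated corpus, which is not redistributed here.

## Known limitations

* The fallback parser's dependency rules cover the shipped pattern
  inventory, not general grammar; exotic clause structures will be
  missed until an external parser is plugged in.
* No unit conversion, no ontology normalization of extracted phrases,
  no merging of cross-phrase values, no inference of optima from
  qualitative statements — all deliberate scope boundaries.
* Descriptions are not deduplicated: near-identical descriptions may
  encode different taxon concepts and are kept.
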