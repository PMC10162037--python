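# Methods

## Scope and model

`patriage` triages a patent corpus for quantitative small-molecule
bioactivity evidence on understudied (IDG Tdark/Tbio) protein targets.
The method is intentionally a pair of cheap, high-recall text scans — a
keyword scan over tables and a dictionary-plus-template scan over text
sections — combined into a six-group priority partition, aggregated per
patent family, followed by potency cut-off evaluation of curated
measurements. It is a *prioritisation* tool: the final judgement of
whether a patent truly contains usable data stays with a human curator,
whose verdicts re-enter the pipeline as read/positive labels.

The corpus is consumed in a normalized JSON-lines dialect (one object per
publication: `patent_id`, `family_id`, optional date, IPC/CPC codes, the
four text sections, flattened tables). Conversion from office-native XML
is out of scope; family membership is taken from the input, never
reconstructed.

## Matching rules

All matching operates on *normalized* text: whitespace runs collapsed to
single spaces, Unicode dashes (including the typographic minus in
`−log(IC50)`) folded to ASCII hyphen. Recorded offsets are 0-based
half-open positions in this normalized form, so a stored `[start, end)`
slice always reproduces its match.

**Keywords (tables only).** A keyword matches when not flanked by a letter
or digit; hyphens, parentheses and other punctuation are boundaries. Thus
`IC50-value` and `(IC50)` match, `NIC50`, `IC500` and the `Ki` inside
`Kinase` do not. The parenthesis rule means a cell `−log(IC50)` yields
both the `−log(IC50)` and the embedded `IC50` keyword — duplicate evidence
is harmless because the document-level signal is only "has ≥ 1 hit".
Two-letter symbols (`Ki`, `Kd`) are case-sensitive; everything else is
case-insensitive; multi-word keywords (`IC 50`, `concentration to
inhibit`) match across any whitespace. Keywords in the description or
claims never count: the table scan exists to find *tabulated* quantitative
results, and running-text occurrences are overwhelmingly narrative.

**Templates and mentions.** The default template set is the 35 raw phrase
patterns (39 after alternation expansion) of the form "Inhibitors of X",
"X antagonists", "Anti-X antibody", ... Alternation groups are expanded by
a single rule: if one side of the `|` is a case-insensitive prefix of the
other, the alternatives are whole tokens (`Blocks|block X`); otherwise the
pipe alternates a single character in place
(`Antibodies recognis|zing X` → recognising / recognizing). A mention is
emitted only when a dictionary name or gene symbol instantiates a template
inside one section — template fixed words match case-insensitively, names
of ≥ 4 characters case-insensitively, shorter symbols (e.g. `KIT`)
case-sensitively to limit false positives, and internal space/hyphen
variation in multi-word names is tolerated (`Cholesterol 24 hydroxylase`
matches `Cholesterol 24-hydroxylase`). The whole phrase is token-bounded.
Claims are scanned claim-by-claim with per-claim offsets. All
(target, template, position) combinations are reported, with no
longest-match suppression; output order is (section, claim, start,
target, pattern), which makes annotation files byte-deterministic.

The matcher compiles one regular expression per (template, name) pair with
an LRU cache. This is ample for desk-scale corpora and dictionaries
(thousands of documents × hundreds of names); scaling to the full
~36k-name TCRD dictionary over millions of patents would call for an
Aho-Corasick-style automaton, which is a known limitation, not a
correctness issue.

## Classification and aggregation

A patent's group is a total function of two booleans and a section set:
tables + title/abstract mention → G1; tables + other mentions → G2; the
table-less analogues → G3/G4; tables only → G5; neither → G6.
Title/abstract mentions take priority over description/claims, so the six
groups partition the corpus at patent level. Families take the *union* of
member groups (with `best_group` the highest priority member), which is
what produces cross-group overlap counts when filings disagree; per-group
family statistics therefore default to multi-membership accounting, with
best-group-only accounting available as a flag.

## Potency evaluation

Concentrations are normalized to nM (pM ÷ 1000, μM × 1000, mM × 10⁶,
M × 10⁹); p-type measurements (pIC50 etc., unitless) via `10^(9 − p)`.
Cut-offs are inclusive (≤), matching how they are stated: kinase 30 nM,
GPCR and nuclear receptor 100 nM, ion channel 10 μM, other 1 μM. Censored
values are treated conservatively: a `<`/`≤` concentration qualifies only
if the bound itself meets the cut-off, `>`/`≥` never qualifies, and the
directions invert for p-types where larger means more potent. All listed
activity types count equally. A target is a promotion candidate
(Tdark/Tbio → Tchem) when it has ≥ 1 qualifying measurement; targets
already at Tchem/Tclin are never re-promoted.

## Synthetic corpus generator

The generator emulates the *structural* features the pipeline keys on:
families of 1–3 publications, the four text sections, flattened tables,
IPC/CPC codes, planted keywords and template-embedded mentions, and a
configurable rate of near-miss decoys (`NIC50`, `IC500`, `Kinase`,
lowercase `ki`/`kd`, and true keywords placed in running text where they
must not count). Every patent is constructed to satisfy exactly its
planted group's defining predicate, and the guarantee is by construction,
not by checking: the decoy vocabulary is disjoint from every template
fixed word, and target names are only ever written inside deliberately
planted phrases, so no accidental mention can arise. The generator never
calls the annotator or classifier — planted-label recovery is therefore a
genuine end-to-end test of the matching rules, including every boundary
decision listed above.

Defaults (200 families × 1–3 patents, 25 targets, group mix
0.15/0.15/0.15/0.15/0.15/0.25, 30% decoy rate) were chosen to exercise all
six groups heavily rather than to mimic a real corpus's skew, where the
vast majority of patents are G6 and ~2% carry bioactivity tables; rate-like
statistics computed on synthetic output are *not* estimates of real-corpus
rates. What passing tests show is that the matching, classification and
aggregation rules are implemented exactly; they cannot show recall against
real patent prose, where targets appear under unlisted synonyms (e.g.
"CH24H" for cholesterol 24-hydroxylase) and tables arrive as OCR noise —
both documented failure modes of this approach.

The activity generator samples log-uniformly on either side of each
family's threshold with a 1% safety margin so that floating-point unit
conversion can never flip a planted truth flag, plants one exact boundary
measurement (= threshold, in nM, a unit whose conversion is exact) per
family, and mixes concentration types, p-types, units and censored
relations.

## Numerical choices

- Positive rates are rounded half-up to one decimal (49/291 → 16.8); the
  corpus flag percentage rounds half-up to an integer for headline use.
  Both use decimal arithmetic, not binary floats, so ties like 6.25%
  round up dependably.
- A rate over zero read families is reported as absent, not 0.
- p-type round trips (`p → nM → p`) are exact to ~1e-12 relative; the
  equality comparison at cut-off boundaries is deliberately plain `<=` on
  the normalized value, with exactness guaranteed only for values supplied
  in nM.
- Simulation uses a single `random.Random(seed)` stream per run; the seed
  is recorded in output headers, and identical seeds give byte-identical
  files.

## Design decisions on open points

- Keyword case-sensitivity (only `Ki`/`Kd` strict) and name
  case-sensitivity (< 4 characters strict) are precision choices for
  short tokens; the underlying procedure does not specify them.
- The same template list is applied to all four sections; there is no
  relaxed rule for descriptions/claims.
- The life-science flag is evaluated per patent, not per family, and is
  monotone in the code list.
- Plurals are covered only where the template list itself encodes them;
  no stemming is applied.
- Curation labels are inputs: the package computes yields from them but
  never guesses them.

## Problem sizes

Tests and the acceptance script run on synthetic corpora of roughly
200–750 patents, dictionaries of ~25 targets, and activity tables of
~250 measurements, with matcher/oracle agreement checked over 110+ random
adversarial documents — sizes at which the full suite completes in well
under a minute while still covering every rule and boundary.
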