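# Methods

This note documents the statistical model, the design choices made where
more than one reading was defensible, the synthetic data the package is
validated on, and the limits of what those validations show.

## The tagging model

The tagger is a second-order (trigram) HMM: each tag is conditioned on
the two preceding tags, each word on its own tag.  Every sentence is
framed by two opening boundary pseudo-tags and one closing one; the
boundary symbols are not part of the tag set k.  Decoding is exact
Viterbi over (previous, current)-tag state pairs in log-space, with
structural zeros as −∞ and ties broken toward the lower tag-set index at
every backpointer, so output is identical across runs and platforms.

### Transition smoothing

Raw trigram relative frequencies are mixed with bigram and unigram ones,
p = w₃f₃ + w₂f₂ + w₁f₁, with weights estimated by deleted interpolation:
each training trigram votes, with its count, for the order whose
held-out relative frequency (all counts reduced by one) is largest.
Ties go to the lower order (the conservative choice); trigrams for which
all three held-out frequencies are zero — singletons everywhere, which
can only arise in very small corpora — carry no evidence and do not
vote.  If no trigram votes at all, the weights fall back to uniform.
The mixture normalizes exactly over next tags for every conditioning
context observed in training; for entirely unseen contexts the unigram
term keeps every seen tag reachable.

### Emission cascade

p(w|t) is resolved by the first applicable source:

1. **Lexicon** — case-independent lookup (exact case preferred, then the
   most frequent surface form); returns the suffix-smoothed
   word-given-tag probability.
2. **Surface patterns** — numbers (optional sign, decimals, thousands
   separators), number ranges (digit–dash–digit), ordinals
   (`1st|2nd|3rd|[0-9]+th`, case-insensitive).  The matched pattern maps
   to a configured tag (default: the tag set's cardinal-number tag, MC,
   when present; otherwise the branch is skipped).
3. **Character features** — any unknown token that is not all-lowercase
   letters.  The feature string maps uppercase→`A`, lowercase→`a`,
   digit→`0`, Greek (U+0370–03FF, U+1F00–1FFF)→`g`, keeps `-./()`
   literally, maps other symbols to `S`, and collapses runs of the same
   symbol (`IL-2`→`A-0`).  Run-collapsing is a reconstruction choice: it
   bounds the feature space so rare long words still share shapes.
   The emission is count(feature, tag)/total(tag).
4. **Suffix prediction** — unknown all-lowercase words (matching is done
   on the lowercased word throughout).

If every tag scores zero the row falls back to uniform (and the event is
logged); this prevents path annihilation without affecting any informed
decision.

### The suffix table

All alphabetic, pattern-free lexicon words contribute every proper
ending of length 1..min(5, len−1): a suffix is a proper ending, so a
1-letter word contributes nothing.  The cap of 5 reflects that English
derivational suffixes rarely exceed 4–5 characters.  Two counts are kept
per (suffix, tag): `freq_1` increments by 1 per word type, `freq_n` by
the word's corpus frequency.  Counts are cumulative toward shorter
suffixes by construction.

### Probability interpolation (TnT-style)

P₀ = p(tag) (from the length-1 rows); Pᵢ = (p̂(tag|sᵢ) + θPᵢ₋₁)/(1+θ),
iterating from the shortest suffix to a depth chosen by:

1. the longest suffix of the word with a table entry for *any* tag;
2. always min(5, len−1);
3. per tag, the longest suffix with an entry for *that* tag (depth 0
   returns the prior).

θ is the sample standard deviation (divisor k−1, mean fixed at 1/k) of
the unconditional tag distribution, computed once per table — it is
context-independent.  λ₁ = 1/(1+θ) and λ₂ = θ/(1+θ) realize the
two-weight formulation with a single parameter.  A tag without a row at
a level where the suffix has rows for other tags contributes p̂ = 0
there; a level whose suffix has no rows under any tag (reachable only by
rule 2) carries no evidence and is skipped, which keeps the per-word
distribution over tags exactly normalized.  The result P(tag|suffix) is
converted to an emission score by Bayesian inversion
P(tag|suffix)·P(suffix)/P(tag), with P(tag) the tag's share of the whole
table's mass and P(suffix) the length-1 mass — a per-word constant whose
choice of length is immaterial in the decoder's argmax.

### Maximum Suffix Length (MSL)

Per tag, only the longest suffix s_t of the word with an entry for that
tag is consulted; the score is the tag's share of that suffix's mass,
freq(s_t, tag)/Σ_t′ freq(s_t, t′), used directly as the emission score
with no inversion step.  Two readings of the MSL denominator were
considered.  Normalizing by a per-tag word mass (making the score a
literal p(suffix|tag)) was implemented first and rejected by experiment:
any tag whose few word types share endings — above all small closed
classes — then wins on a length-1 match (e.g. P('y'|adverb) ≈ 1 beats
the correct tag's long-suffix score of ~0.005), and the predictor
collapses to ~34% accuracy, inverting the method-comparison result the
design targets.  The tag-proportion reading adopted here reproduces the
characteristic error signature of suffix tagging instead (rare deep
coincidences such as a fresh word ending like a closed-class word's
tail), at the small rate observed in practice.

The same scores smooth known words: a lexicon word w seen only under
some tags receives, for each unseen tag t supported by one of its
suffixes, smoothed(w,t) = β·msl(w,t)·c(w)/c(t) with β = 0.1.  The
c(w)/c(t) factor is the Bayes identity that places the suffix evidence
on the same word-given-tag scale as the seen-tag MLE c(w,t)/c(t); β
discounts it because the pairing was never observed.  β = 0 reproduces
the raw MLE exactly.  Smoothed values are not renormalized over words:
emission scores enter an argmax where per-tag constants matter only
relatively.

## Tokenization

Sentence splitting and token shaping follow two rules chosen to keep
complex biological names intact: punctuation is peeled only from token
edges (never between alphanumeric neighbours, and a parenthesis closing
a parenthetical opened inside a name, as in `Ca(2+)`, stays attached),
and a sentence boundary is placed after `.`, `!` or `?` only when the
next token begins with an uppercase letter or digit, except after dotted
abbreviations (`e.g.`) whose final period stays attached.  The boundary
decision is a pure function of the token stream, which makes
tokenization idempotent; the character multiset of the input (minus
whitespace) is always preserved.

## The synthetic data generator

The generator emulates the features of a real tagged biomedical corpus
that the tagger's components feed on, with 8 tags by default:

* six open classes with characteristic derivational endings
  (NN: -tion/-sion/-ment/-ness/-ity; JJ: -ous/-ive/-ial/-ic/-ed;
  VVG: -ing; VVN: -ed/-en; RR: -ly; VVGJ: -ing), two closed classes (II,
  DD) with small fixed vocabularies;
* inventories overlap the way English morphology does: -ing is mostly
  gerund but sometimes participial adjective (VVGJ), -ed splits between
  past participle and adjective — so suffix evidence is ambiguous with a
  skewed gold split;
* tag prevalences are skewed (VVGJ at 0.1 relative weight) as in real
  tag distributions, which is exactly the regime where dividing by a
  small P(tag) — the Bayesian-inversion step of the interpolation
  pathway — inflates rare tags;
* only `suffix_fraction` = 0.5 of each open tag's vocabulary carries an
  inventory ending; the rest are bare stems with diverse endings, as in
  a real lexicon (a tag whose types all share one final letter is not
  realistic and would distort length-1 statistics);
* word frequencies are Zipf-distributed (exponent 1.1), so the two
  counting methods genuinely differ;
* the tag sequence is a first-order Markov chain with
  Dirichlet-distributed successor rows (concentration 1.5, mean
  proportional to prevalence), presented through the trigram interface.
  A first-order backbone is a deliberate choice: a freely varying
  per-context trigram tensor is not recoverable to useful precision from
  5,000 sentences (~75k tokens spread over 64 contexts), whereas the
  pooled successor law is — so parameter recovery is a meaningful check
  rather than a noise measurement;
* sentences are 8–22 tokens; 5,000 training and 500 held-out sentences;
* unknown words are injected into held-out sentences at rate 0.3 by
  vocabulary partitioning (a disjoint, suffix-bearing pool per tag), not
  post-hoc deletion; held-out *known* words are drawn from words
  actually seen in training, so rate 0 guarantees full coverage.

Parameter recovery is validated on the balanced-prevalence
configuration (every tag weight 1, no unknown words): with skewed
prevalences the rare tag's row is visited too rarely at this corpus size
for any estimator to pin down, which would make the check a test of the
noise floor rather than of the counting code.  The recovery estimator
conditions on the sentence continuing (`continuation_bigram_mle`),
because sentence length is exogenous censoring: the raw successor MLE is
deflated by the escape mass P(EOS|t) ≈ 7%.  Measured recovery error is
≈ 0.01 absolute at 5,000 sentences.

What the generator does **not** emulate: real English stem phonotactics
(stems are letter-frequency strings, so deep cross-tag character
coincidences are rarer than in real text), genuinely second-order tag
dependence, annotation noise, and the long tail of a 60-tag set.
Passing tests therefore show that each component computes what it claims
and that the method ordering holds under morphology-driven ambiguity
with skewed tag frequencies; they do not certify accuracy figures on
real corpora.

## Numerical and procedural choices

* All decoding in log-space; −∞ for structural zeros; uniform emission
  fallback for all-zero rows.
* Tie-breaks: lower tag-set index in Viterbi backpointers and in the
  suffix-pathway argmax; lower order in deleted-interpolation votes.
* Lexicon keys preserve surface case; case-independent lookup is a view
  (exact case, then highest frequency, then lexicographic).
* Model persistence is a single versioned JSON archive with exact
  integer round-trip; it lives on the assembled model because only the
  model knows all components.
* The comparison harness trains once and tags held-out unknown words
  through the suffix pathway alone (the selection rule: absent from the
  lexicon case-independently, no surface pattern, all lowercase), so the
  8 parameter sets differ only in the quantity under study.

## Known limitations

* The tokenizer's sentence splitter is a minimal heuristic (terminator +
  capitalized continuation, dotted-abbreviation exception), not a
  disambiguator with an abbreviation dictionary.
* MSL inherits the deep-coincidence failure mode: an unknown word whose
  tail happens to extend a closed-class word's ending can be mis-tagged
  with high confidence; such words are rare but systematic.
* The interpolation pathway's Bayesian inversion divides by P(tag) and
  therefore over-scores rare tags; this is faithful to the method being
  compared, not a defect of the harness.
* Emission scores from different cascade branches are not calibrated
  against each other; within a sentence this is harmless because each
  token's score enters the argmax only across tags.
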