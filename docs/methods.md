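# Methods

## Task and model

`mrim` classifies emergency-period microblogs as useful/useless for rescue
operations by integrating two independent judges:

1. **TF-IDF + linear SVM** over unigrams. The term weighting is the exact
   form stated in the README: base-10 idf with a `1 + df` denominator and
   a tf denominator that counts *all* tokens of the document, including
   out-of-vocabulary ones. Two consequences are kept deliberately rather
   than "fixed": a term occurring in every training document has slightly
   negative idf (log10(D/(D+1))), and a term unseen in training has
   idf = log10(D). An optional `nonnegative_idf` switch clamps at zero for
   users who want the more common variant; it is off by default. No
   length normalization is applied.
2. **An expert-weighted rule scorer** over six dimensions (weights 0.20 /
   0.10 / 0.05 / 0.05 / 0.20 / 0.40; boundary score 40, inclusive). A
   dimension's value is the *sum* of its parameter scores
   (`min(raw/divisor, cap)` each); attention and user dimensions
   therefore max out at 3 × 33.3 = 99.9. The caps are fixed configuration
   (chosen in the original study to exceed ~90% of observed values);
   `percentile_caps` recomputes them for a new corpus when wanted. The
   emotion dimension uses |sentiment| by default — both strong positive
   and strong negative affect mark rescue-relevant content — with a
   `positive_only` mode available.

The **union integration** (a post is useless only when both judges say
so) makes the integrated recall ≥ each component's recall by
construction; the cost is that the false-positive sets pool. The
**weighted integration** `(1−w)·SVM + w·rule ≥ 40` is swept over a 0.01
grid; w = 0 and w = 1 reproduce the component methods exactly, and for
any w < 0.6 a positive SVM verdict alone forces a useful label
((1−w)·100 ≥ 40).

## Feature extraction

* **Markup stripping** removes well-formed and unclosed angle-bracket
  tags, embedded hyperlinks and topic-hashtag delimiters (the `#`
  characters go, the words inside a topic stay and count as words).
  The operation is idempotent and configurable by pattern list.
* **Segmentation** is greedy longest match against a dictionary, with two
  fallbacks: a maximal ASCII digit run becomes one token (so phone
  numbers survive whole, as mainstream Chinese segmenters treat number
  runs), otherwise one character. The tokenizer never loses or invents a
  character (property-tested) and is pluggable behind that contract.
* **Sentiment** is a left-to-right lexicon traversal. Degree adverbs and
  negations accumulate in the window since the previous emotional word
  and apply to the next emotional word only — the standard
  lexicon-method scope; k negations contribute (−1)^k. Polarities are
  ±1; degree multipliers carry magnitude.
* **Exact address**: a suffix from the five-level feature-word inventory
  preceded by ≥ `min_prefix` (default 2) non-stop-word, non-punctuation
  characters; the highest level (most specific) match is reported. The
  prefix requirement suppresses bare-suffix false positives; a named-
  entity-recognition hook can be plugged in but is disabled by default.
* **Contact**: mainland mobile (11 digits starting 1[3-9]), landline
  (3–4 digit area code, separator, 7–8 digits) and contact-keyword +
  digit-run patterns; the pattern list is configuration.

Lexicons ship as a small programmatically generated fixture set (the
full third-party sentiment dictionaries are not redistributable); any
directory of plain-text lexicon files in the documented formats can be
swapped in.

## Synthetic corpus generator

The generator emulates the study corpus's *printed* structure; per-record
content is synthetic. Defaults: n = 7979, useful rate 1936/7979, stratum
probabilities (both / contact-only / address-only / neither) =
5461/1202/331/985 over 7979, non-zero means 196.27 (likes), 2299.05
(prior posts), 5.97 (|sentiment|), ~35.9 words; 40% of the address-only
stratum malformed; 50% of top-attention-decile useless posts are media
reports; sentiment injected in 60% of sufficiently long posts.

Design points:

* **Labels first, two partially disjoint signal channels.**
  `token_signal` (default 0.7) raises the share of rescue-signal
  vocabulary in useful posts from a 5% base to 36.5% — the channel the
  SVM can learn. `feature_signal` (default 0.7) tilts the stratum
  assignment of useful posts toward "both" and shifts their engagement
  counts up (log-location +0.8 for attention, +0.3 for user counts) —
  the channel the rules key on. Both defaults are moderate-strength
  settings chosen once as plausible for rescue-topic streams. The
  stratum tilt is *marginal-preserving*: P(stratum|useless) is solved so
  the corpus-level stratum frequencies match the printed sizes in
  expectation for any tilt. At signal 0 both channels are independent of
  the label and no method can beat chance.
* **Counts** are zero-inflated lognormals rounded to integers. Only the
  category-level non-zero means are printed, so the tail shape
  (σ = 1.4–1.8), zero-inflation rates (5–45% by field) and the
  non-printed means (comments 60, shares 80, followers 400, fans 600)
  are free choices fixed once at realistic Weibo-like values. The base
  log-location is solved in closed form so the label-tilted mixture
  still hits each non-zero-mean target.
* **Word counts** come from a two-component lognormal mixture
  (weight 0.245 on LN(2.153, 1.214), rest LN(3.512, 0.801), clipped at
  101.5), fitted numerically so the ten rank-decile means track the
  study's ladder 3.16 … 97.73; measured deviations are ≤ 13% in the
  lowest decile and ≤ 5% elsewhere. Very short posts skip the longer
  planted units (no landline numbers below 6 words, no emotional
  language below 4 words, emotional words capped at wc/3) — without
  this, the planted units would put a floor under the shortest decile.
* **Sentiment plants** are contiguous snippets (optional negation,
  optional degree adverb, emotional word, repeated 1 + Poisson(6.0)
  times, capped by length); the rate is calibrated jointly with the
  word-count model so the mean |value| of sentiment-bearing posts is
  ≈ 5.97. The planted value is computed exactly during assembly.
* **Malformed addresses** replace the feature-word suffix with
  characters outside the inventory, emulating non-standard writing that
  defeats suffix matching; they occur only in the address-only stratum,
  at the printed 40%.
* **Media reports** are drawn, at rate 0.5, from the useless posts of
  the top attention decile; they are recomposed long (80–160 words) with
  signal-rich text mimicking useful language. They are the designed
  confound for both the attention-decile analysis and the text
  classifier.
* **Exact ground truth**: the emitted word count is accounted
  arithmetically from the planted units (a filler token counts 1, a
  mobile number 1, a landline 3, a well-formed address 1 — named places
  are dictionary words — a malformed address 1 + suffix length, stop
  words and markup 0), so re-running extraction must reproduce it
  exactly; this is asserted in the tests, not assumed.

What the generator does **not** emulate: real Chinese phrasing and
morphology, topic drift over the event timeline, duplicate/near-duplicate
posts, user-level correlation between posts, or any dependence structure
beyond label→(tokens, strata, counts). Passing tests on synthetic corpora
therefore demonstrate that the pipeline's arithmetic, protocol and
integration logic are correct and that each arm recovers the signal
channel it is designed for — not that the printed real-corpus F-measures
would be reproduced.

## Evaluation protocol

Useful = positive. P = tp/(tp+fp), R = tp/(tp+fn), F = F1; zero
denominators yield 0 by convention, and empty groups report absent (NaN)
metrics rather than zeros. The text arm is evaluated with stratified
tenfold cross-validation; vocabulary, document frequencies and the
classifier are rebuilt inside each training fold (a no-leakage test
corrupts held-out labels and asserts identical predictions). MRIM is the
union of the rule verdict and the *out-of-fold* SVM verdict, so all three
methods are compared on the same posts. Grouped analyses use rank-based
deciles (ties broken by id; smaller remainder groups first, so 7979 →
797 + 9×798) and apply the globally fitted methods per group — no
per-group retraining.

## Numerical and implementation choices

* LinearSVC (liblinear) with fixed `random_state` is the margin
  classifier; `C = 10` is the package default because the un-normalized
  printed TF-IDF yields feature norms around 0.1 and the conventional
  `C = 1` — which presumes unit-scale features — demonstrably underfits
  (CV F 0.24 vs 0.63 on the default corpus). `C`, the frequency
  threshold and its reading ("≥ 3" is total occurrences by default,
  document frequency optionally) are all exposed.
* The minimum-frequency reading, caps (literal 33.3, not 100/3),
  inclusive boundary (≥ 40) and 0.01 sweep grid follow the printed
  study configuration.
* All tie-breaks are deterministic (ids for grouping, smaller w for
  equal-F sweep points); every random draw flows from a single integer
  seed, and the end-to-end report is byte-identical across runs with the
  same seed.
* "Chance level" for null experiments is the F of a label-independent
  predictor with the method's own positive-prediction rate q:
  F_chance = 2rq/(r+q), r the corpus useful rate. This is the right
  reference because the arms have very different operating points under
  no signal (the SVM predicts almost nothing positive; the rule arm
  marks every contact-bearing post positive).

## Known limitations

* Under the study's printed stratum sizes, 83.5% of posts carry contact
  information, and the rule configuration marks every one of them useful
  (0.40 × 100 = 40, inclusive boundary). On any corpus with those
  marginals the rule arm's precision — and that of any union containing
  it — is bounded by useful_rate / contact_rate ≈ 0.29, capping the
  union's F near 0.45 however strong the signals are. The package
  reports what the arithmetic yields; see the integration docstrings.
* Address detection is feature-word matching only; the NER hook is a
  stub point, and no geocoding or address standardization is attempted.
* The rule weights are fixed expert configuration; nothing is learned
  from data on that arm, and no significance testing between methods is
  provided.
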