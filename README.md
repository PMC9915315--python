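# mrim — machine-learning + rule-based triage of crisis microblogs

During a sudden-onset disaster, microblogging platforms fill with short
posts — requests for rescue, addresses of trapped people, phone numbers,
but also chatter, reposts and media coverage. Emergency-management teams
need the small fraction of posts that can *directly* support rescue
operations, and they need to miss as few of them as possible. `mrim`
implements an integration method for that triage task: a machine-learning
text classifier and an expert-rule scorer each judge every post, and a
post is discarded only when **both** say it is useless.

## The method

**Text arm.** Posts are segmented into words (greedy longest dictionary
match with single-character fallback), stop words are removed, and each
document is vectorized with unigram TF-IDF using the weighting

```
tf(i,j) = n(i,j) / Σ_k n(k,j)        idf(i) = log10( |D| / (1 + df(i)) )
tfidf(i,j) = tf(i,j) · idf(i)
```

over a vocabulary of words occurring ≥ 3 times. A linear-kernel SVM is
trained on the vectors and evaluated by stratified tenfold
cross-validation; a useful prediction scores 100, useless 0.

**Rule arm.** Six expert-weighted dimensions score each post on 0–100:

| dim | meaning | parameters | weight |
|-----|---------|-----------|--------|
| A1 | attention | likes/10, comments/10, shares/10 (each capped 33.3) | 0.20 |
| A2 | user      | prior posts/100, followers/100, fans/100 (capped 33.3) | 0.10 |
| A3 | emotion   | \|lexicon sentiment value\| (capped 100) | 0.05 |
| A4 | words     | word count (capped 100) | 0.05 |
| A5 | address   | 100 if an exact address is detected | 0.20 |
| A6 | contact   | 100 if contact information is detected | 0.40 |

A post is useful iff the weighted total ≥ 40. Sentiment is a lexicon
traversal (polarity ±1, degree-adverb multipliers, negation sign flips);
an "exact address" is a span ending in a five-level inventory of Chinese
address feature words (镇 … 医院 … 单元) with a plausible name before it;
contact detection matches mainland phone-number shapes.

**Integration.** MRIM's union rule: useless only if both arms agree — so
recall never falls below either arm's. A weighted-score alternative,
`(1−w)·SVM_Score + w·Rule_Based_Score ≥ 40`, is provided with a sweep of
w over [0, 1].

The corpus the original study used is not publicly deposited, so the
package ships a synthetic generator (`mrim.synth`) reproducing its printed
structure — 7979 posts, 24.3% useful, the 68.4/15.1/4.1/12.3% address/
contact strata, heavy-tailed engagement counts, the word-count decile
ladder — plus its two contamination phenomena: non-standard address
writing (~40% of the address-only stratum) and professional-media reports
(long, high-attention, useless). Every generated post carries exact ground
truth, so the whole pipeline is testable end to end.

## Worked example

```python
from mrim import GeneratorSpec, run_experiment

report = run_experiment(GeneratorSpec(n=2000, seed=7), cv_folds=10)
print(report.methods[["precision", "recall", "f_measure"]].round(3))
```

prints

```
      precision  recall  f_measure
svm       0.642   0.521      0.575
rule      0.258   0.917      0.403
mrim      0.265   0.966      0.415
```

The union (MRIM) recall, 0.966, is above both arms' — it loses almost no
useful post — while its precision is pinned near the useful rate within
the contact-bearing strata, because under the study's printed corpus
structure 83.5% of all posts carry contact information and the rule arm
marks every one of them useful (0.40 × 100 = 40 hits the boundary
exactly). `report.sweep` holds the weighted-integration curve
(`report.best_w` was 0.56 here), and `report.by_word_count`,
`by_address_contact`, `by_attention` the grouped analyses. The
`examples/` directory has one narrative script per capability, and the
`mrim` command line exposes the same steps (`mrim generate`, `mrim
extract`, `mrim rule-score`, `mrim cv`, `mrim integrate`, `mrim sweep`,
`mrim evaluate`, `mrim experiment`).

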