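# embedhdp

Similarity metrics for **sentence suggestions in nursing-care records**.

Care-record applications can propose a sentence to the caregiver ("sentence
suggestion") to speed up free-text documentation.  Whether a suggestion is
*good* means whether it carries the same information as the sentence the
caregiver would actually have written (the ground truth) — and care-record
Japanese is short, often fragmentary, and dense with medical terms, which
surface-overlap metrics such as BLEU and ROUGE handle poorly.  This package
implements **EmbedHDP**, a topic-model based pair score designed for that
regime, together with from-scratch comparator metrics and a benchmark
harness that measures how well each metric correlates with human (caregiver)
similarity judgments.

## The score

For a suggestion *s₁* and ground truth *s₂*:

1. **Tokenize** each sentence (wakati-style surface tokens; Japanese
   particles は, を, の, … stay attached to their host words).
2. **Embed** every token with a subword-capable embedding backend
   (pretrained fastText in production; a seeded character-n-gram hash
   backend for testing), so rare medical terms still get vectors.
3. **Quantize** each token vector into a pseudo-Bag-of-Words: keep the
   L = 10 largest non-negative components, scale by 100, and treat
   embedding-dimension indices as terms.  Summing over tokens gives one
   pseudo-document per sentence: C₁, C₂ over a shared dictionary D.
4. **Fit a hierarchical Dirichlet process** topic model on the
   two-document corpus [C₁, C₂] (stick-breaking variational inference;
   the HDP needs no preset topic count).
5. **Score** = cos(T₁, T₂), the cosine of the two inferred topic
   distributions.  Both are non-negative, so the score lies in [0, 1].

Comparators implemented from their definitions: sentence-level BLEU (with
effective-order capping and floor-epsilon smoothing for short sentences),
ROUGE-N and ROUGE-L, Bag-of-Words cosine, plus an adapter slot for
BERTScore-style external scorers.  A length filter removes pairs where
either side exceeds 13 tokens — the regime where the topic representation
is known to degrade.

## Worked example

```sh
$ embedhdp score --s1 "コルセット作ることを報告する" \
                 --s2 "コルセットを作ることを勧められる" --backend stub
{"score": 0.325787317783956, "metric": "embedhdp", "config_digest": "e96741f8afe7"}
```

The two sentences ("report making a corset" / "advised making a corset")
share their informational core; the score reflects partial topical
overlap rather than exact n-gram matching.  Against pre-segmented text
the score tracks token-level content overlap smoothly:

```python
from embedhdp import HdpParams, MetricConfig, PairRecord, embedhdp_score, get_backend

backend = get_backend("stub", dim=64, seed=0)
cfg = MetricConfig(hdp=HdpParams(seed=42))
for s1, s2 in [("気分 訴え なし", "気分 訴え なし"),
               ("吐き気 あり 報告 入れる", "吐き気 訴え あり"),
               ("頻繁 な 少量 の 排尿", "排便 中量 あり")]:
    print(embedhdp_score(PairRecord(s1, s2, id="x"), cfg, backend).value)
```

prints `1.000` (identical), `0.741` (partial overlap), `0.474` (different
content).  The benchmark harness runs a whole panel against human scores:

```sh
embedhdp synth --n 200 --seed 1 --out pairs.csv
embedhdp benchmark --in pairs.csv --out report.json --markdown
```

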