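# abbrsense

One-to-all disambiguation of ambiguous clinical abbreviations.

Clinical notes are dense with abbreviations whose meaning depends on context:
"BK" may mean *below knee* in a surgical note and *BK (virus)* in a nephrology
report; "PM" may be *pacemaker*, *polymyositis*, or a time of day. The
traditional one-to-one (OTO) strategy trains a separate classifier per
abbreviation, which is accurate but unmaintainable at hospital scale. The
one-to-all (OTA) strategy implemented here uses a **single binary classifier
for all abbreviations**: each occurrence is expanded into one
*context-candidate pair* per admissible expansion, the classifier scores each
pair, and the predicted sense is the candidate with the highest class-1
probability.

## Method

For an abbreviation occurrence with context split positionally into
`left / target / right` and a sense inventory of *n* candidate expansions,
the pipeline builds *n* token sequences

```
[CLS] left target right [SEP] candidate_i [SEP]     label = 1 iff candidate_i is the gold sense
```

so each instance yields exactly one positive and *n − 1* negative training
examples. Sequences are truncated to the model token budget (default 512)
with a **FIFO rule**: the oldest context tokens are dropped first, and the
candidate segment is never trimmed. The classifier head is two linear layers
with a ReLU between them — pooled input → hidden width 50 → 2 logits — with a
softmax over the logits,

```
y = softmax(W₂ · max(0, W₁x + b₁) + b₂),     W₂ ∈ ℝ^(50×2)
```

and ranking uses `p(class = 1)`. Two interchangeable backends satisfy the
scorer contract: a deterministic logistic model over sparse lexical
co-occurrence features, and the head itself trained by seeded gradient
descent on hashed features (a pretrained bidirectional-encoder backend plugs
into the same contract by supplying its `[CLS]` vector).

Evaluation builds one confusion matrix per abbreviation and reports
per-abbreviation accuracy, **macroaccuracy** (unweighted mean over
abbreviations) and **microaccuracy** (pooled correct/total), on the percent
scale. Experiment protocols cover a coverage-constrained 9:1 split (every
(abbreviation, sense) class is screened into training at least once) and
cross-site **incremental learning**: train on a base corpus, add k ∈ {0, 5,
10} new-site documents, continue training, and evaluate on the remaining
new-site instances.

A seeded synthetic-corpus generator with per-sense signature vocabularies and
a tunable signal rate `p_sig` makes the whole pipeline testable end to end,
including a distribution-shifted second site with senses unseen in the base
corpus.

## Worked example

```python
from abbrsense import (AbbrevInstance, build_sense_inventory, generate_pairs,
                       WhitespaceTokenizer, SynthConfig, generate_corpus,
                       TrainConfig, SplitSpec, run_within_corpus)

inst = AbbrevInstance("1", "BK", "...He is status post a",
                      "amputation on the right side and...",
                      "below knee", ("BK(virus)",))
inv = build_sense_inventory([inst])
for p in generate_pairs(inst, inv, WhitespaceTokenizer(512)):
    print(p.label, p.candidate, "|", " ".join(p.tokens))

instances, inventory = generate_corpus(SynthConfig(seed=7, p_sig=0.8))
result = run_within_corpus(instances, inventory,
                           TrainConfig(backend="lexical", seed=7), SplitSpec(0.9, 7))
print(f"test instances: {len(result.test)}")
print(f"macroaccuracy:  {result.report.macro_accuracy:.2f}")
print(f"microaccuracy:  {result.report.micro_accuracy:.2f}")
```

prints

```
0 BK(virus) | [CLS] ...He is status post a BK amputation on the right side and... [SEP] BK(virus) [SEP]
1 below knee | [CLS] ...He is status post a BK amputation on the right side and... [SEP] below knee [SEP]
test instances: 50
macroaccuracy:  100.00
microaccuracy:  100.00
```

The two-candidate instance becomes two labelled sequences (one positive); a
separable synthetic corpus (strong lexical signal, `p_sig = 0.8`) is then
split 9:1 with sense coverage, the lexical backend is trained on the training
pairs only, and both corpus-level accuracies on the 50 held-out instances are
perfect — the expected outcome when context vocabulary fully determines the
sense.

The same pipeline is scriptable from the shell:

```bash
abbrsense simulate --seed 7 --out-dir run/
abbrsense pairs   --corpus run/corpus.tsv --out run/pairs.jsonl
abbrsense train   --pairs run/pairs.jsonl --seed 7 --out run/scorer
abbrsense predict --corpus run/corpus.tsv --scorer run/scorer --out run/pred.jsonl
abbrsense evaluate --predictions run/pred.jsonl --gold run/corpus.tsv --out run/report.json
```

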