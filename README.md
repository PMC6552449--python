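# chvmine

Semiautomatic **consumer health vocabulary (CHV) mining** from health-forum
text.  A CHV maps lay expressions ("having loose bowels") to professional
medical concepts ("diarrhea"); keeping one up to date means continuously
discovering the colloquialisms, abbreviations and typos consumers actually
use.  `chvmine` implements a complete mine-review-iterate pipeline for this
task, aimed at terminology curators and biomedical NLP researchers:

1. **Pretrain** word embeddings `E` (skip-gram / CBOW with negative
   sampling, GloVe, or a FastText-style subword variant) on a tokenized
   forum corpus.
2. **Fine-tune** a low-rank projection `S` (shape `s × e`, `s < e`) on a
   small set of verified professional↔consumer seed pairs, keeping `E`
   fixed.  The adapted representation of a word with one-hot vector `M` is
   `P = S · E · M`.
3. **Rank** candidate counterpart terms for each query term by cosine
   similarity in the adapted space, export them for manual review, and feed
   accepted pairs back into training.

## The core method

For a query word ω_v with labeled synonyms Syn(ω_v), each synonym ω_r has a
desired rank rank\*(ω_r) (its position in the labeled set) and a current
rank rank(ω_r) by cosine similarity over a candidate pool.  The ranking
loss

&nbsp;&nbsp;&nbsp;&nbsp;L = Σ_{ω_v} Σ_{ω_r ∈ Syn(ω_v)} | rank(ω_r) − rank\*(ω_r) |

is not differentiable, so `S` is trained on a similarity-value surrogate:
with f(ω_v) the descending similarities of the pool to ω_v,

&nbsp;&nbsp;&nbsp;&nbsp;ℓ(ω_v, ω_r) = ( f(ω_v)[rank\*(ω_r)] − cos(S·E ω_v, S·E ω_r) )²,

where the target value is a per-epoch constant.  Because every word passes
through the same projection, *all* embeddings adapt, not only the labeled
words.  Retrieval quality is measured by **mean reciprocal rank** (MRR):
the average over queries of 1/rank of the first relevant synonym.

Since real forum crawls cannot be redistributed, the package ships a
synthetic-corpus generator that plants the relevant structure — concepts
with professional and consumer tokens sharing context distributions,
Zipfian background noise, consumer-side "casual style" contamination,
typos, and orphan consumer terms with no professional partner.

## Worked example

```
chvmine --seed 1 synth --out-corpus corpus.txt --out-pairs pairs.tsv --out-terms terms.txt
chvmine --seed 1 embed --corpus corpus.txt --out vectors.txt --dim 50
chvmine --seed 1 evaluate --vectors vectors.txt --pairs pairs.tsv
chvmine --seed 1 finetune --vectors vectors.txt --corpus corpus.txt \
        --pairs pairs.tsv --out model/
chvmine --seed 1 rank --model model/ --query P000 --top 5
```

The final command prints a review-ready candidate list (on the synthetic
corpus, `C000_0`/`C000_1` are the planted consumer variants of the
professional term `P000`; `X…` are shared context words, `B…` background
words, and `C018_1` a consumer variant of a different concept):

```
Top 5 candidates for 'P000':
rank    candidate       similarity
1       C000_1  0.9852
2       C000_0  0.9835
3       X008    0.9488
4       C018_1  0.9393
5       B0259   0.9392
```

and `evaluate` on the raw vectors prints the pre-fine-tuning baseline:

```
MRR     0.7458
n_queries       20
mean_first_rank 1.65
```

i.e. over the 20 professional-term queries of the gold pair set a true
consumer variant already sits near the top before supervision (these are
training-set queries; fine-tuning's benefit is measured on *held-out*
concepts, which is what `scripts/acceptance.py` quantifies).

The same operations are available as library calls
(`chvmine.generate_corpus`, `train_embeddings`, `init_projection`, `fit`,
`rank_candidates`, `mrr`, …); see `docs/methods.md` for the model details
and design choices.

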