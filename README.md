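# m6age

Prediction of N6-methyladenosine (m6A) sites in RNA from sequence segments,
combining sequence-derived feature encoders with unsupervised graph
embeddings of a learned sample-similarity network.

m6A is the most prevalent internal mRNA modification and marks transcripts
for altered splicing, export, stability and translation. Experimental maps
(MeRIP-seq, miCLIP) are expensive, so classifiers that score candidate
adenosines directly from the surrounding sequence are widely used. The
input here is a set of fixed, odd-length RNA segments with the candidate A
at the center; positives carry experimentally annotated m6A sites.

## Method

Two feature families are fused into one matrix per sample:

**Sequence-derived encoders** (seven, each a named feature block):

| block  | content | width |
|--------|---------|-------|
| CTD    | composition, adjacent-pair transitions, occurrence-quantile distribution | 30 |
| PseKNC | k-mer frequencies plus λ sequence-order tiers θ_j from six dinucleotide physicochemical properties | 4^k + λ |
| NPS    | frequencies of ordered pairs n1{k}n2 with k = 1..3 intervening bases | 48 |
| NPPS   | position-specific contrast p_i = p_i⁺ − p_i⁻ of conditional pair probabilities estimated per class | L − k − 1 per k |
| NCP-ND | per-position chemical-property bits (ring, H-bond, functional group) + running density | 4L |
| EIIP   | electron–ion interaction pseudopotential of each base | L |
| BPB    | interleaved class-conditional positional base frequencies f_i,n⁺, f_i,n⁻ | 2L |

NPPS and BPB are fitted on training labels only, so held-out encodings are
leakage-free.

**Graph embeddings.** A sample-similarity network is learned by fast linear
neighborhood similarity: minimize ½‖X − (C∘W)X‖²_F subject to W ≥ 0 and
row sums of C∘W equal to 1, where C marks each sample's c nearest
neighbors; the multiplicative update W ← W ∘ (XXᵀ + μeeᵀ) ⁄ ((C∘W)XXᵀ +
μ(C∘W)eeᵀ) monotonically decreases the penalized objective. Thresholded,
binarized and symmetrized, W becomes an unweighted connected graph whose
nodes are embedded by

* **SocDim** — top eigenvectors of the modularity matrix B = A − ddᵀ/2|E|,
* **Node2Vec** — second-order biased random walks (p, q) + skip-gram with
  negative sampling,
* **GraRep** — truncated SVD of positive log k-step transition matrices.

A gradient-boosted decision-tree classifier (LightGBM backend by default,
scikit-learn gradient boosting as an alternative) is trained on the fused
matrix with class weights inversely proportional to class counts, and
evaluated on a held-out split by ACC, MCC, SEN, SPE, F1 and AUC.

## Worked example

`examples/03_train_and_evaluate.py` runs the full pipeline on a synthetic
RRACH-motif benchmark (500 + 500 segments, L = 41):

```
held-out metrics: ACC=88.00%  MCC=0.7624  SEN=84.00%  SPE=92.00%  F1=0.8750  AUC=0.9613

top 10 features by importance:
   4440.29  NPPS_xi1_p24
    694.72  NCP_ND_pos20_ring
    675.58  NCP_ND_pos19_ring
    430.68  NPPS_xi1_p22
    265.42  GraRep_k2_2
    ...
graph embeddings hold 20% of the top-20 features
```

ACC/SEN/SPE are percentages over the 200 held-out segments; MCC is the
Matthews correlation; AUC is the probability that a random positive
outscores a random negative. The top-ranked columns sit at positions
+1/+2 relative to the central A (`NPPS_xi1_p24` is the spaced-pair
contrast ending at position 24 of 41) — exactly where the RRACH consensus
places its information — and graph-embedding columns such as `GraRep_k2_2`
supplement them.

The other examples cover encoding (`01`), similarity-graph learning and
embeddings (`02`), and imbalanced, class-weighted training plus a no-graph
ablation (`04`).

## Command line

```bash
m6age synth --n-pos 1000 --n-neg 1000 --length 41 --strength 0.9 --seed 7 --out pos.fa neg.fa
m6age split --pos pos.fa --neg neg.fa --train-frac 0.8 --seed 42 --out-dir splits/
m6age run --preset H41 --seed 1 --out-dir run/      # synthetic preset
m6age run --pos pos.fa --neg neg.fa --seed 1 --out-dir run/
m6age replay --manifest run/manifest.json            # bit-identical re-run
```

`m6age presets` lists the four named configurations (A101, A25, S21, H41)
pairing each segment length with its published feature-block choice.

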