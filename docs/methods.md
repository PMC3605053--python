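# Methods

## The model

`ddinet` predicts pharmacodynamic drug-drug interactions (PD DDIs) — one
drug modulating another's effect without changing its concentration — from
the premise that such interactions arise when two drugs perturb tightly
connected regions of the protein-protein-interaction (PPI) network.

**Edge weighting.** Every PPI edge is weighted by the Pearson correlation
coefficient (PCC) of its two genes' expression profiles across tissues
(sample covariance and SDs, n−1 denominator). Edges whose genes lack
expression data, or whose profile has zero variance, keep their place in
the graph topology but carry no weight: they are excluded from the
background statistics and from S-score edge collection, because topology
and coexpression enter the pipeline as separate evidence. The background
mean μ_bg and SD σ_bg are taken over all defined edge weights.

**Target-centered systems.** A drug's system is its in-network targets
plus their first-step neighbors. Targets absent from the network are
dropped (logged); a drug with no in-network target has an empty system and
an undefined S-score.

**S-score.** For a drug pair, collect the defined weights of every edge
with one endpoint in each system (each physical edge once, even when both
endpoints lie in both systems), then append one artificial entry of
exactly 1.0 per gene shared by the two systems. With μ, σ, n the mean,
sample SD and count of that list,

    S = (μ − μ_bg) / (σ / √n),

a one-sample t-type statistic: large S means the two systems are connected
by many, strongly coexpressed edges relative to a random stretch of the
network. When σ = 0 (notably n = 1, a single shared gene) σ_bg stands in,
so single-contact pairs get a finite, comparable score; n = 0 is undefined
— no evidence, not zero evidence. Undefined scores sort below all defined
scores in rankings.

**P-score.** Side-effect similarity: P(a,b) = Σ_t w(t) over shared terms,
with w(t) = −log2(f(t)) and f(t) the fraction of drugs annotated with the
term. Rare shared effects dominate; a term present in every drug
contributes nothing. A drug absent from the side-effect corpus makes the
P-score undefined (tri-state: evidence missing ≠ disjoint profiles). The
downstream model consumes P only through rank bins, so any similarity that
is monotone in "rare shared effects" is equivalent here.

**Evidence integration.** Each evidence is converted to a likelihood ratio
by quantile-binning its scores over gold-standard positives (GSP) and
negatives (GSN): LR(bin) = P(bin|GSP)/P(bin|GSN), with a dedicated bin for
undefined scores and additive pseudo-counts keeping every ratio finite and
positive. Bins are right-open [lo, hi); out-of-range scores clamp to the
extreme bins. Under naive-Bayes independence the per-evidence LRs
multiply; posterior odds = prior odds (|GSP|/|GSN|) × combined LR. A pair
with both evidences uses LR(S)·LR(P), with exactly one evidence that
single LR, with neither it is never predicted. The prediction threshold is
strict: combined LR > 2.

**Evaluation.** GSNs are sampled uniformly (seeded) from non-GSP drug
pairs, equal-size or five-fold. Metrics over GSP ∪ GSN: ROC/AUC per
evidence and combined (AUC = Mann-Whitney concordance, ties ½, undefined
scores ranked last); rank-binned fold enrichment (m/n)/(M/N); confusion
counts at the LR threshold with accuracy = (TP+TN)/total, recall =
TP/(TP+FN) and precision = TP/(TP+FP) all reported (accuracy conventions
differ across the literature, so both accuracy and precision are always
emitted); and GSP hit rate / cumulative coverage per minimum target
distance. Target distances are unweighted hop counts (BFS — Dijkstra with
unit weights), 0 iff the drugs share an in-network target.

**DDI classification.** Free-text interaction descriptions are split into
pharmaceutical / PK / PD-like by ordered keyword rules (pharmaceutical
checked first): pharmaceutical = {physicochemical, non-absorbable,
solution}; PK = {CYP, absorption, distribution, metabolism, excretion,
concentration, level, metabolite, metabolized, enzyme inducer, clearance};
everything else PD-like. Matching is by substring, case-insensitive except
all-uppercase keywords (CYP), which match case-sensitively so the pattern
cannot fire inside ordinary lowercase words. The rules are overridable via
a plain-text config (`class: kw, kw` per line). PD-like DDIs are the
positives for evaluation.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `n_bins` | 20 | quantile bins per LR model; quantile edges keep bins populated |
| `pseudo` | 0.5 | additive smoothing count per bin (incl. the undefined bin) |
| `gsn_multiplier` | 1 | GSN size = 1× or 5× |GSP| |
| `threshold` | 2 | strict combined-LR cutoff for prediction |
| `enrichment_bin_size` | 100 | pairs per rank bin in the enrichment table |

The number of bins in the pseudo-count normalization includes the
undefined bin, so the per-class bin probabilities sum to one; the ratio in
any one bin is unchanged by this convention because the totals cancel.

## The synthetic benchmark

The generator emulates the statistical structure the method assumes, not
any real database:

- **Network**: planted-partition graph, 300 genes in 6 modules, edge
  probability 0.15 within / 0.01 between. Modular, but without the heavy-
  tailed degree distribution of real PPI networks.
- **Expression**: 40 tissues; gene x = √ρ·latent(module) + √(1−ρ)·σ_n·ε,
  so two same-module genes have expected PCC ρ/(ρ + (1−ρ)σ_n²) = ρ at the
  default σ_n = 1 (default ρ = 0.7). Real expression is heteroskedastic,
  non-Gaussian and tissue-autocorrelated; none of that is modeled.
- **Drugs**: 60 drugs, 3 targets each. The first 40 form 20 planted
  interacting pairs; both drugs of a pair draw targets from one shared
  module (round-robin over modules), the remaining 20 draw targets
  uniformly. 20 planted pairs (not 30) so that a genuine background drug
  population exists alongside the planted one.
- **Side effects**: 150-term vocabulary, 8 terms per drug, plus 4 extra
  shared terms per planted pair.
- **DDIs**: planted pairs with a keyword-free description, so they
  classify PD-like.

One `numpy` generator seeded by a single integer drives all five tables;
equal config + seed ⇒ byte-identical output files.

Passing on this benchmark shows the pipeline recovers planted proximity /
coexpression / side-effect-overlap signal and is calibrated when that
signal is absent. It says nothing about performance on real DrugBank/HPRD
data, whose degree structure, target multiplicities and annotation biases
the generator does not emulate. One subtlety: switching the signal off
(p_within = p_between, ρ = 0, no side-effect boost) leaves a residual
target-overlap signal, because planted drugs still draw targets from a
shared 50-gene pool; the null AUC therefore sits slightly above 0.5 while
remaining within the calibration band checked by the tests.

## Numerical and degenerate-input choices

- PCCs are clipped to [−1, 1] against floating-point drift; zero-variance
  profiles give undefined weights rather than NaN.
- Background stats require ≥ 2 defined edge weights (error otherwise).
- Quantile binning deduplicates tied edges; if all scores are identical
  the model collapses to a single bin with LR = 1 (warning).
- `fit_lr` with `pseudo = 0` raises on empty bins rather than emitting
  infinite ratios.
- Ranking ties are broken by canonical (lexicographically sorted) pair
  order everywhere, making every output file deterministic.
- Pairs are keyed order-independently throughout: lookup(a,b) =
  lookup(b,a).
- Score tables print floats at 6 significant digits; round-trips are
  exact at that precision.

## Known limitations

- The S-score treats connecting-edge PCCs as an i.i.d. sample against a
  fixed background; edges sharing endpoints are in fact dependent, so S is
  a ranking statistic, not a calibrated t-test p-value.
- The P-score is a documented inverse-frequency variant, not the
  Campillos term-similarity kernel; its absolute values are not comparable
  to side-effect similarities computed by that method.
- Naive-Bayes multiplication ignores S/P dependence; with correlated
  evidence the combined LR is overconfident, though ranking is usually
  preserved.
- LR models are fitted on GSP ∪ GSN and applied to all pairs; prevalence
  shifts between that universe and all possible pairs move the prior, not
  the per-bin ratios.
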