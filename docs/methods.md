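# Methods

This note documents the models implemented in `haploleak`, the choices
behind the synthetic study conditions, and what the test suite does and
does not establish about behaviour on real data.

## 1. The imputation engine

Imputation is modelled as a haploid Li–Stephens hidden Markov model. The
hidden state at panel site *i* is the index of the reference haplotype
being copied, with state space `{1..n}` for a panel of *n* haplotypes.
Over an interval of genetic length *d* cM the chain switches to a
uniformly drawn haplotype with probability `1 − exp(−ρ·d)` (`recomb_scale
= ρ`), and a typed site emits the copied haplotype's allele flipped with
probability `error_rate`. The per-site posterior ALT probability is the
reported dosage; the discrete genotype is ALT iff dosage > 0.5 (a tie at
exactly 0.5 yields REF — an arbitrary but deterministic and documented
convention).

Because uniform switching composes exactly (the product of two such
transition kernels is the kernel of the summed distance), the
forward–backward recursion is evaluated only at the typed sites and
propagated into the gaps in closed form. This is exact, not an
approximation — the unit tests verify equality with an exhaustive sum
over all `n^L` hidden paths to 1e-9 — and it makes whole-chunk dosage
output a handful of matrix–vector products, so conformation batches of
128 queries impute in ~0.1 s on one core.

Parameter defaults and why:

| parameter | default | rationale |
| --- | --- | --- |
| `error_rate` | 0.01 | small allele-mismatch penalty; one mismatching site costs a likelihood factor of ~100, so exact matches dominate, the behaviour the reconstruction attack exploits |
| `recomb_scale` | 0.02 /cM | ~2 expected copying switches per 100 cM chromosome; with a short query the posterior stays locked on an exact match across a whole chunk, reproducing full-chunk recovery and the dosage stripe patterns |
| `min_state_prob` | 1e-6 | forward pruning floor relative to the per-site maximum, analogous to production engines' minimum state-probability ratio; the oracle tests disable it |
| chunking | 20 Mbp | imputation servers process 20-Mbp chunks independently; output is restricted to the chunk containing the query |

The emission/transition constants of production imputation software are
not published; the engine is calibrated behaviourally — unique-match
full-chunk recovery with extreme dosages, and dosage stripes at
multiples of 1/n for n-match queries — rather than to bit-level
equivalence with any specific tool. Queries in a batch are imputed
independently (cross-query effects in real engines are known to be
small, and independence makes runs exactly reproducible). An adapter
that accepts a panel VCF and query VCF and returns an imputed VCF is the
CLI `impute` subcommand; external engines could be substituted behind
the same file interface.

## 2. Synthetic panels: the mosaic-of-founders generator

`simulate_panel` draws per-variant population frequencies from a
Beta(0.2, 0.2) spectrum truncated to (0, 1) — U-shaped, so both rare
(<0.005) and common (>0.2) variants exist in quantity, which seed
construction requires — then samples founder haplotypes per site and
builds the remaining haplotypes as founder mosaics with switch points at
`switch_rate` per cM plus per-site mutation flips. This creates the two
properties the attack exploits: short-range linkage disequilibrium
(founder blocks) and haplotype uniqueness (switches and mutations). A
full coalescent simulation would add demographic realism the attack does
not consume.

The **attack-panel** study conditions (200 haplotypes × 20,000 variants
over 20 Mbp) are deliberately scaled down from a production panel
(~25× fewer haplotypes, ~17× sparser variants in bp than deeply
sequenced chromosome 20 data). Two scale-consistency choices follow:

* **Map rate 0.06 cM/Mb.** Seed spacing constraints are stated in
  genetic distance (0.001–0.0035 cM between consecutive set variants).
  At 17× reduced variant density, a realistic 1.13 cM/Mb map would leave
  essentially no variant pairs inside the spacing window; compressing
  the map by the same factor preserves the per-variant genetic spacing
  distribution of a full-density panel, so the published spacing
  parameters remain meaningful.
* **Founder blocks of ~0.07 cM** (`switch_rate` 15/cM, 40 founders,
  mutation 1e-4). Real LD blocks span roughly 0.02–0.06 cM; the chosen
  block scale keeps the 8-variant seed span (≤0.025 cM) inside a block
  (the strong-LD premise behind the spacing rule) while letting
  haplotypes diverge within the discrete-attack extension window.
  Mutations supply singleton alleles — the anchors that yield unique
  matches.

Panel size interacts with the rare-variant cutoff: no column mean of a
200-haplotype panel is strictly below 0.005, so the seed builder
consults an allele-frequency table supplied by the caller — the
generator's founder probabilities by default — mirroring an attacker
using population-scale external frequencies rather than the hidden
panel's own. A consequence of the small panel is that most rare anchors
have zero panel carriers; such seeds waste queries but are correctly
discarded by the sieve, exactly as blind anchor selection behaves in
practice.

## 3. The seed–sieve–extend attack

Defaults follow the published attack settings: 8-variant sets (one
anchor with external allele frequency < 0.005 fixed to ALT, seven
flankers with MAF > 0.2), consecutive genetic spacing within
[0.001, 0.0035] cM, sets placed in the middle 80% of the chromosome,
128-query conformation batches, extension tolerance 0.025 around 1/n,
and a correctness cutoff of 100 mismatches. Seed placement retries are
bounded (50 retried placements per random position, 10,000 positions).

The sieve classifier is a 75-tree random forest over 21 dosage-bucket
counts: end buckets [0, 0.1) and [0.9, 1], nine width-0.02 buckets
centred on the stripe dosages expected for 2–5 matches
({1/5, 1/4, 1/3, 2/5, 1/2, 3/5, 2/3, 3/4, 4/5} — the 0- and 1-stripes
live inside the end buckets and 2/4 coincides with 1/2; this is the only
layout reaching 21 buckets), and ten gap buckets. Buckets are half-open,
lower-inclusive, with dosage exactly 1.0 in the top end bucket. Training
uses 100 planted queries per class (1–5 and Other, the latter pooling
zero and ≥6 matches) with match counts verified by direct panel scan;
training is a one-off setup cost not charged to the attack's query
budget. The classifier is trained on the attacked panel by default; a
held-out panel can be passed instead.

Extension splits an n-match query on a site whose output dosage lies
within 0.025 of 1/n (nearest such site to the seed), typing it ALT in
one new query (isolating the single ALT carrier) and REF in the other;
the REF branch re-enters imputation, is classified as n−1 matches, and
is split again — recursion depth capped at 4, i.e. from 5 matches down
to 1. Every query submitted — conformation batches, extensions,
discrete rounds — counts against the query budget.

The discrete-genotype attack extends each query with one in-window
variant per round, typed with the query's *own* first-round output, and
filters queries whose re-imputed output changes anywhere in the chunk;
survivors after k = 15 rounds are declared unique matches. The window is
specified as 50 kb on real maps (~0.057 cM); on the compressed fixture
map the same genetic reach is ~950 kb, which `attack_config_for`
computes. Without that scaling the window sits inside a single founder
block where near-matching haplotypes are locally identical, and
extensions cannot discriminate them.

One behaviour deserves emphasis: a zero-match query whose conformation
happens to coincide with a flanker pattern carried by exactly one panel
haplotype imputes — correctly — to that haplotype, with a fully
self-consistent output that survives any number of extension rounds.
These survivors are successful reconstructions under the 100-mismatch
correctness rule, not attack errors; at 200-haplotype scale they are
common (~10–15% of zero-match conformations) because patterns often have
single carriers. The quantity the round count k actually controls is the
rate of *incorrect* reconstructions among survivors, which the tests
measure at ~0–1% at k = 15 and verify is monotone non-increasing in k.

## 4. IBD detection and semi-kinship

The semi-kinship coefficient compares a haploid chunk with a diploid
sample: SK = k₁/2, where k₁ is the fraction of the chunk's genetic
length covered by the *union* of IBD segments to either haplotype of the
diploid (a region IBD to both sides counts once — the union reading of
"shared with either haplotype"). SK therefore lies in [0, 0.5]; a
domain of [0, 1] sometimes quoted for the observed matrix is attainable
only by k₁ itself, and this implementation follows the definition.

Detection is exact-match run detection on phased data after a MAF ≥
0.01 filter, with minimum segment length 2.5 cM — the settings of
haploid-mode IBD detectors used for this task. Hash-seeded extension
and error tolerance are unnecessary because the simulator injects no
genotyping error by default; an optional `max_errors` bridges isolated
mismatches when error is injected. Segments are detected chromosome-wide
and apportioned to 20-Mbp chunks, so a segment crossing a chunk boundary
credits both chunks. Chunk intervals are half-open `[k·20 Mbp + 1,
(k+1)·20 Mbp + 1)` with cM endpoints interpolated from the map.

## 5. Pedigree simulation

Meioses are simulated as Poisson crossover processes at 1 per Morgan
without interference, on labelled genome segments, so IBD ground truth
is exact transmission bookkeeping rather than post-hoc inference. A
degree-d pair is realized as a lineal chain of d meioses from a diploid
ancestor (the relative), each intermediate gamete pairing with a fresh
founder haplotype. The lineage haplotype's expected IBD coverage with
the relative is 2^(1−d) of the genome — the same coverage law as the
collateral relationship of equal degree (half-siblings, avuncular,
cousins), which is the statistic semi-kinship and linking consume; the
segment-count distribution differs slightly from couple-ancestor
topologies, which is immaterial at 2.5 cM detection scale.

The **pedigree-cohort** conditions for linking experiments: four
chromosomes of 100 Mbp at 1 cM/Mb (20 chunks of 20 Mbp per individual),
1,500 array-like sites per chromosome drawn with a *uniform* allele
frequency spectrum. Uniform (not U-shaped) frequencies keep per-site
chance agreement at ~2/3, so 2.5 cM exact runs essentially never arise
between unrelated haplotypes at 15 sites/cM; with the heavy-tailed panel
spectrum, near-monomorphic sites produce spurious segments at this
density (real relative sets are array data dominated by common
variants, so this is the realistic choice, not a concession). Founder
haplotypes are consumed without replacement across pairs so distinct
pairs are genuinely unrelated.

## 6. Haplotype linking

The generative model: each target individual j and relative ℓ has a
latent relatedness degree r ∈ {∅, 1, 2, 3+} with prior p(∅) = 0.9 and
the remainder uniform; given an assignment of haplotype rows to
individuals, each observed SK value is drawn from p(s | r). EM
alternates the posterior update over r (prior × product of assigned
rows' likelihoods) with a maximum-weight assignment step solved as
minimum-cost network flow: one unit source per haplotype row, per
(individual, chromosome-segment) sinks of capacity 2, an uncapacitated
no-match column, edge cost −π_{i,j} where π is the posterior-expected
log-likelihood. In chunk mode the capacity-2 slot is the (chromosome,
chunk) position — the chunk-level generalization of the two-haplotypes-
per-chromosome constraint. The no-match column of π uses Σ log p_∅(s);
the formula-as-printed variant without the log is available behind
`null_log=False` but is inconsistent with a log-likelihood objective and
is off by default.

Numerical choices: likelihoods are floored at 1e-12 before logs
(histogram bins can be empty); flow costs are scaled to integers at 1e9
relative precision, and the M-step keeps the incumbent assignment
whenever the rounded flow solution scores no better under exact π, so
the EM objective (the evidence lower bound, tracked by `em_objective`)
is non-decreasing by construction, not merely to rounding precision.
Flow optima on integral capacities are integral; the rounding step
exists only as a safety net. T is set to the number of groups implicated
after pre-filtering — any sufficiently large value works because of the
no-match state.

SK likelihoods are estimated from a *held-out* labelled simulated cohort
(never the cohort being linked) as histograms with 25 equal bins on
(0, 1] plus a zero bin; degrees 3–5 are pooled into 3+. The unrelated
distribution is a point mass at zero (weight 0.95) plus a Gaussian at
the empirical mean with sd 0.1 at chunk level; at chromosome level all
distributions are Gaussians with empirical moments (unrelated sd
0.0175) and no point mass, where SK values are closer to Gaussian.
Chunk-level runs use a single EM iteration, chromosome-level runs ten
with an output filter p(∅) ≤ 0.99, matching the regimes in which each
converges.

The initial solution: (1) chain adjacent chunks by imputing each chunk
against the relative set over a region one chunk wider each direction
and scoring, in a ±500 kb boundary window, the number of variants where
the imputed dosage differs from the neighbour chunk's genotype by more
than 0.5 — mutual sole-best pairs with symmetric score ≤ 5 link, chains
are the transitive closure (the two directional scores are summed; the
source description is directional and silent on the combination); (2)
group rows with identical thresholded relatedness patterns, first at
2^(−9/2), then re-thresholding ungrouped rows at 2^(−13/2) (expected
lower bounds for 3rd- and 5th-degree SK), dropping groups under 5 rows
at each pass and capping each group at two rows per chunk by SK to the
group's strongest relative; (3) assign each chain to a group when a
strict majority of its chunks lie in it. Pre-filtering keeps rows with
SK ≥ 2^(−13/2) to a relative that relates to at least two distinct
chunks ("related to other target haplotypes" is read as ≥2 distinct
chunks). Duplicate reconstructed chunks, if present, should be collapsed
exactly before linking. At the fixture's 15 sites/Mb the chaining window
holds ~15 variants, so occasional chance links between unrelated chunks
appear; they fail the majority rule and are absorbed by the no-match
state (at production density the window holds hundreds of variants and
chance links vanish).

## 7. The relative-availability model

A monogamous Wright–Fisher population: N couples in the current
generation, Poisson(r) offspring per couple (r = 2.5), so the population
g generations back has size N(g) = N (r/2)^(−g). The database holds a
proportion q of the two most recent generations; the target is in the
current one; relationships more than one generation apart are excluded
(their members fall outside the database window, and omitting them only
understates risk). Under monogamy there are no half-siblings, so the
inventory is: degree 1 — two parents plus Poisson(r) siblings (the
size-biased family of an existing child, minus the child, is again
Poisson(r)); degree 2 — aunts/uncles, Poisson(2r); degree 3 — first
cousins (compound Poisson); degree 4 — parents' first cousins; degree 5
— second cousins.

Detectability of a relative separated by d meioses with a ancestral
haplotype sources uses the classical recombination model: segment count
Poisson with mean a(dL + C)/2^(d−1) (L = 35.9 Morgans by default, C = 22
autosomes, lengths proportional to standard map lengths), segment
lengths Exp(d), detection requiring ≥ s = 2 segments of ≥ m = 0.06
Morgans. P(≥1 detectable relative of a degree in the database) combines
the per-type generating functions, e.g. degree 3:
1 − exp(−2r(1 − e^{−r·q·p_det})). The exact derivations behind the
published analysis are not reproduced here; the implementation is
derived from the stated assumptions and *gated by a Monte-Carlo oracle*:
a pedigree simulator with explicit crossover-level meioses and
union-merged diploid IBD, run for 2000 replicates, whose 95% confidence
intervals must contain the closed forms for degrees 1–3 across database
proportions 0.001–0.01 (they do; the tests recompute this). Probabilities
depend on q only, not on N and R separately.

Curve synthesis: P(closest relative has degree d) =
P(detectable at d) × Π_{d'<d}(1 − P(detectable at d')); per-degree
distributions of linked genome fraction are smoothed with a
reflection-corrected Gaussian kernel density on [0, 1] (a boundary
substitute for boundary-kernel estimators; Silverman bandwidth, floored
at 1e-3; fewer than 3 samples fall back to the empirical step function),
converted to survival functions S_d(g), and combined as
p(g) = Σ_d P(closest = d) · S_d(g).

## 8. Problem sizes and what the tests show

The default suite runs the attack with a 20,000-query budget on the
200-haplotype panel, links a cohort of 20 pairs per degree 1–4 plus 20
unrelated on a 4-chromosome genome, and validates the relative model at
2000 Monte-Carlo replicates — sizes chosen so the whole suite completes
in minutes on one core while every mechanism (unique-match recovery,
stripes, sieving, extension, filtering, SK separation by degree, EM/flow
optimization, closest-relative weighting) is exercised against ground
truth or an independent oracle.

What passing does **not** show: reconstruction rates, linking counts and
availability probabilities on production-scale panels are not
reproduced — they require million-query budgets and access-controlled
data, and the synthetic generator does not model demographic structure,
phasing error (which in real panels *helps* diploid linking), genotyping
error, or gene conversion. The mosaic generator reproduces the LD and
uniqueness structure the attack needs, not the site-frequency spectrum
or haplotype-sharing tails of any real population. Conclusions supported
are mechanistic: the attack logic, the statistics, and the optimization
are correct as specified, and their qualitative behaviour (stripes,
degree ordering, filter monotonicity, model/oracle agreement) matches
the published account.
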