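# haploleak

**How much of a hidden reference panel leaks through a genotype
imputation service?** Imputation servers let researchers impute their
samples against access-controlled panels of deeply sequenced genomes,
returning per-site genotype predictions and dosages. Because imputation
copies from the closest-matching reference haplotypes, its output
necessarily reveals something about them. `haploleak` is a self-contained
toolkit for studying exactly how much, entirely on synthetic data: it
implements the imputation engine, the reconstruction attack against it,
the haplotype-linking algorithm that reassembles the stolen pieces, and
the population-genetic model of when linking is feasible.

The package is aimed at genomic-privacy researchers and imputation-service
operators who want to reproduce and probe the attack mechanics without
touching real servers or controlled data.

## What is implemented

* **Imputation engine** (`haploleak.engine`) — a haploid Li–Stephens
  copying HMM over a phased panel: hidden state = reference haplotype
  index, switch probability `1 − e^(−ρd)` over `d` cM, emission error
  `ε = 0.01`; forward–backward run at the typed sites and propagated into
  gaps in closed form (exact for this transition family). Dosage = the
  posterior ALT probability; 20-Mbp chunk semantics as on public servers.
* **Seed–sieve–extend attack** (`haploleak.attack`) — builds 8-variant
  query sets (one rare anchor fixed to ALT, seven common flankers spaced
  0.001–0.0035 cM apart), submits all 2⁷ = 128 conformations, classifies
  each output's 21-bucket dosage histogram into a match count (1–5 or
  Other) with a 75-tree random forest, saves single matches as
  reconstructed haplotypes, and splits n-match queries on a site with
  dosage ≈ 1/n. A discrete-genotype variant extends queries with their
  own output and filters on changed re-imputation (k = 15 rounds).
* **Semi-kinship** (`haploleak.kinship`) — exact-match IBD detection
  (min 2.5 cM, MAF ≥ 0.01) between haploid target chunks and diploid
  relatives; SK = k₁/2 with k₁ the union coverage of the chunk.
* **Linking** (`haploleak.linking`) — EM over latent relatedness degrees
  {∅, 1, 2, 3+} with a minimum-cost network-flow assignment step
  (≤ 2 haplotypes per individual per chromosome segment), initialized by
  imputation-based chunk chaining plus relatedness-pattern grouping.
* **Relative availability** (`haploleak.relatives`) — a monogamous
  Wright–Fisher model (`N(g) = N(r/2)^(−g)`, r = 2.5) of the probability
  that a database holding a fraction of the population contains a
  detectable relative (≥ 2 IBD segments ≥ 6 cM), validated against a
  Monte-Carlo meiosis oracle, plus the synthesis into
  (samples linked, genome fraction) curves.
* **Synthetic data** (`haploleak.popgen`, `haploleak.fixtures`) — phased
  panels from a mosaic-of-founders process with tunable allele-frequency
  spectrum and LD, genetic maps, and pedigree relatives of degrees 1–5
  with exact transmission-level IBD ground truth.

`docs/methods.md` documents the models, parameter choices, and the
limits of what the synthetic experiments show.

## Worked example

Reconstruct haplotypes from a simulated 200-haplotype panel through the
imputation interface alone:

```python
import numpy as np
from haploleak.fixtures import attack_panel, attack_config_for
from haploleak.engine import ImputationEngine
from haploleak.attack import run_sse_attack, evaluate_reconstruction

panel = attack_panel(seed=1)                  # 200 haplotypes x 20k variants, 20 Mbp
config = attack_config_for(panel)             # published attack settings, map-scaled
engine = ImputationEngine(panel)

report = run_sse_attack(engine, panel.pop_allele_freqs, config,
                        query_budget=5000, seed=42)
correct, incorrect, dup = evaluate_reconstruction(
    report.reconstructed, panel.genotypes[:, report.site_idx],
    config.correctness_cutoff)
print(f"queries used: {report.queries_used}")
print(f"reconstructed: {len(report.reconstructed)} "
      f"(correct {correct}, incorrect {incorrect}, duplicates {dup})")
```

Output:

```
queries used: 5000
reconstructed: 1831 (correct 200, incorrect 0, duplicates 1631)
```

Reading: with 5,000 queries the attack emitted 1,831 haplotype
reconstructions covering all 200 panel haplotypes (each recovered with
≤ 100 mismatches over 20,000 variants — in fact almost all exactly);
none of the emitted sequences was wrong, and the remaining 1,631 were
repeat recoveries of already-reconstructed haplotypes — the
diminishing-returns pattern of blind seed selection. The same pipeline is scriptable from the shell:

```bash
haploleak simulate-panel --seed 1 --out panel/
haploleak attack --panel panel/panel.vcf --map panel/panel.map \
    --pop-afs panel/pop_afs.txt --budget 5000 --seed 42 --out attack/
haploleak relative-model --db-proportion 0.005 --out model/
```

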