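"""Deterministic study fixtures used by the tests, docs and CLI examples.

The fixtures encode the package's study conditions:

* ``tiny-panel`` — a 4 x 10 toy panel for format round-trips and oracle
  tests.
* ``attack-panel`` — 200 haplotypes x ~20k variants over 20 Mbp. The map
  runs at 0.06 cM/Mb so that per-variant genetic spacing matches a
  full-density sequencing panel (the fixture is ~17x sparser in bp than a
  real deep panel); the founder mosaic (40 founders, 15 switches/cM,
  mutation 1e-4) gives LD-block genetic lengths of ~0.07 cM, rare
  variants with 1-10 carriers, and haplotype uniqueness — the structure
  the reconstruction attack exploits. Population (founder) allele
  frequencies accompany the panel, playing the role of an external
  frequency database.
* ``pedigree-cohort`` — target/relative diploid pairs at degrees 1-5
  with exact IBD ground truth, on a multi-chromosome genome with
  array-like (uniform-MAF) sites at 1 cM/Mb.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .attack import AttackConfig
from .popgen import ConfigurationError, HaplotypePanel, RelativeCohort, simulate_panel, simulate_relatives
from .vcfio import write_genetic_map, write_vcf

__all__ = [
    "tiny_panel",
    "attack_panel",
    "attack_config_for",
    "pedigree_founders",
    "combined_cohort",
    "make_fixture",
]

REFERENCE_CM_PER_MB = 1.13  # genome-wide average human recombination rate


def tiny_panel(seed: int = 1) -> HaplotypePanel:
    return simulate_panel(
        n_hap=4, n_var=10, n_founders=4, mut_rate=0.0, seed=seed, length_bp=100_000
    )


def attack_panel(seed: int = 1, n_hap: int = 200, n_var: int = 20_000) -> HaplotypePanel:
    return simulate_panel(
        n_hap=n_hap,
        n_var=n_var,
        n_founders=40,
        switch_rate=15.0,
        mut_rate=1e-4,
        seed=seed,
        length_bp=20_000_000,
        cm_per_mb=0.06,
        chrom="20",
    )


def attack_config_for(panel: HaplotypePanel, **overrides) -> AttackConfig:
    """Attack defaults with bp-valued settings scaled to the panel's map.

    The discrete-extension window is defined in base pairs on real maps
    (50 kb ~ 0.057 cM); on a compressed fixture map the same genetic
    reach requires proportionally more base pairs.
    """
    rate = (panel.cm[-1] - panel.cm[0]) / (panel.positions[-1] - panel.positions[0]) * 1e6
    base = AttackConfig()
    window = int(round(base.ext_window_bp * REFERENCE_CM_PER_MB / max(rate, 1e-9)))
    overrides.setdefault("ext_window_bp", window)
    return AttackConfig(**overrides)


def pedigree_founders(
    seed: int = 1,
    n_hap: int = 800,
    n_chrom: int = 4,
    n_var: int = 1500,
    length_bp: int = 100_000_000,
) -> list[HaplotypePanel]:
    """Independent founder haplotypes on a multi-chromosome genome.

    Sites mimic an array: uniform allele-frequency spectrum, ~15 sites
    per cM at 1 cM/Mb — ample for exact-match IBD detection at 2.5 cM
    while keeping cohorts desk-scale.
    """
    return [
        simulate_panel(
            n_hap=n_hap,
            n_var=n_var,
            seed=seed * 101 + c,
            length_bp=length_bp,
            cm_per_mb=1.0,
            mut_rate=0.0,
            af_spectrum=(1.0, 1.0),
            chrom=str(c + 1),
        )
        for c in range(n_chrom)
    ]


def combined_cohort(
    founders: list[HaplotypePanel],
    degrees: list,
    n_pairs: int,
    seed: int = 1,
) -> RelativeCohort:
    """Concatenate per-degree cohorts built on disjoint founder rows.

    Pair p's relative is relative p; using disjoint founders keeps pairs
    mutually unrelated.
    """
    from dataclasses import replace as _replace

    cohorts = []
    offset = 0
    true_ibd = []
    rng = np.random.default_rng(seed)
    for gi, d in enumerate(degrees):
        need = (4 if d == "unrelated" else 3 + int(d)) * n_pairs
        if offset + need > founders[0].n_hap:
            raise ConfigurationError("founder panel too small for the requested cohort")
        idx = np.arange(offset, offset + need)
        offset += need
        sub = [p.subset_haps(idx) for p in founders]
        coh = simulate_relatives(sub, d, n_pairs, seed=int(rng.integers(2**31)))
        true_ibd.extend(_replace(r, pair=r.pair + gi * n_pairs) for r in coh.true_ibd)
        cohorts.append(coh)
    chroms = cohorts[0].chroms
    base = cohorts[0]
    return RelativeCohort(
        targets={c: np.concatenate([coh.targets[c] for coh in cohorts]) for c in chroms},
        relatives={c: np.concatenate([coh.relatives[c] for coh in cohorts]) for c in chroms},
        degrees=sum((coh.degrees for coh in cohorts), []),
        true_ibd=true_ibd,
        site_cm=base.site_cm,
        positions=base.positions,
        allele_freqs={c: founders[i].allele_freqs for i, c in enumerate(chroms)},
        gmaps=base.gmaps,
    )


def make_fixture(name: str, seed: int, out_dir) -> dict[str, Path]:
    """Write a named fixture to ``out_dir``; deterministic given the seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if name == "tiny-panel":
        panel = tiny_panel(seed)
        paths["panel"] = out / "tiny_panel.vcf"
        paths["map"] = out / "tiny_panel.map"
        write_vcf(panel, paths["panel"])
        write_genetic_map(panel.gmap, paths["map"])
    elif name == "attack-panel":
        panel = attack_panel(seed)
        paths["panel"] = out / "attack_panel.vcf"
        paths["map"] = out / "attack_panel.map"
        paths["pop_afs"] = out / "attack_panel.pop_afs.txt"
        write_vcf(panel, paths["panel"])
        write_genetic_map(panel.gmap, paths["map"])
        np.savetxt(paths["pop_afs"], panel.pop_allele_freqs)
    elif name == "pedigree-cohort":
        founders = pedigree_founders(seed, n_hap=200, n_chrom=2)
        cohort = combined_cohort(founders, [1, 2, 3, 4, 5], 5, seed=seed)
        for c in cohort.chroms:
            tg = cohort.targets[c].reshape(-1, cohort.targets[c].shape[-1])
            rel = cohort.relatives[c].reshape(-1, cohort.relatives[c].shape[-1])
            base = founders[int(c) - 1]
            for tag, g in (("targets", tg), ("relatives", rel)):
                p = out / f"cohort_chr{c}_{tag}.vcf"
                write_vcf(
                    HaplotypePanel(genotypes=g, positions=base.positions, gmap=base.gmap, chrom=c),
                    p,
                )
                paths[f"{tag}_chr{c}"] = p
        ibd_path = out / "cohort_true_ibd.tsv"
        with open(ibd_path, "w") as fh:
            fh.write("pair\ttarget_side\trelative_side\tchrom\tstart_cm\tend_cm\tdegree\n")
            for r in cohort.true_ibd:
                fh.write(
                    f"{r.pair}\t{r.target_side}\t{r.relative_side}\t{r.chrom}"
                    f"\t{r.start_cm:.6f}\t{r.end_cm:.6f}\t{cohort.degrees[r.pair]}\n"
                )
        paths["true_ibd"] = ibd_path
    else:
        raise ConfigurationError(f"unknown fixture: {name}")
    return paths
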