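"""VCF and genetic-map readers/writers.

Phased panels are exchanged as uncompressed VCF with '|'-separated GT
(and optional per-haplotype DS); genetic maps as two-column whitespace
"position cM" text. Reading goes through cyvcf2; only biallelic records
are kept (multiallelic records are skipped and counted).
"""

from __future__ import annotations

import logging

import numpy as np
from cyvcf2 import VCF

from .popgen import ConfigurationError, GeneticMap, HaplotypePanel, uniform_map

__all__ = ["read_vcf", "write_vcf", "read_genetic_map", "write_genetic_map"]

log = logging.getLogger(__name__)


def write_vcf(
    panel: HaplotypePanel,
    path,
    dosages: np.ndarray | None = None,
    haploid: bool = False,
) -> None:
    """Write a panel as phased VCF; 2k/2k+1 haplotypes pair into samples.

    With ``haploid=True`` (or an odd haplotype count) each haplotype
    becomes its own single-allele sample column. ``dosages`` (same shape
    as the genotypes) adds a DS entry per haplotype.
    """
    pos = panel.positions
    if np.unique(pos).size != pos.size:
        raise ConfigurationError("position collision: duplicate variant positions")
    order = np.argsort(pos)
    haploid = haploid or panel.n_hap % 2 == 1
    if haploid:
        samples = [f"H{k}" for k in range(panel.n_hap)]
    else:
        samples = panel.sample_ids or [f"S{k}" for k in range(panel.n_hap // 2)]
    fmt = "GT" if dosages is None else "GT:DS"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if dosages is not None:
            fh.write(
                '##FORMAT=<ID=DS,Number=A,Type=Float,Description="Dosage per haplotype">\n'
            )
        fh.write(f"##contig=<ID={panel.chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples)
            + "\n"
        )
        G = panel.genotypes
        for j in order:
            cells = []
            if haploid:
                for h in range(panel.n_hap):
                    gt = str(int(G[h, j]))
                    if dosages is not None:
                        gt += f":{_fmt_float(dosages[h, j])}"
                    cells.append(gt)
            else:
                for k in range(panel.n_hap // 2):
                    gt = f"{int(G[2 * k, j])}|{int(G[2 * k + 1, j])}"
                    if dosages is not None:
                        gt += f":{_fmt_float(dosages[2 * k, j])},{_fmt_float(dosages[2 * k + 1, j])}"
                    cells.append(gt)
            fh.write(
                f"{panel.chrom}\t{pos[j]}\t{panel.variant_ids[j]}\t{panel.ref[j]}\t"
                f"{panel.alt[j]}\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )


def _fmt_float(x: float) -> str:
    return np.format_float_positional(float(x), trim="-")


def read_vcf(
    path,
    gmap: GeneticMap | None = None,
    require_phased: bool = True,
    cm_per_mb: float = 1.0,
) -> HaplotypePanel:
    """Read a phased VCF into a HaplotypePanel.

    Multiallelic records are skipped (count logged). Unphased genotypes
    raise in panel mode (``require_phased``). When no genetic map is
    given, a constant-rate map spanning the observed positions is
    attached.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[np.ndarray] = []
    positions: list[int] = []
    ids: list[str] = []
    ref: list[str] = []
    alt: list[str] = []
    chrom = None
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        chrom = var.CHROM
        gts = var.genotypes  # [a0, a1, phased] per sample (a1 may be absent)
        alleles: list[int] = []
        for g in gts:
            *calls, phased = g
            if require_phased and len(calls) > 1 and not phased:
                raise ConfigurationError(
                    f"unphased genotype at {var.CHROM}:{var.POS} in panel mode"
                )
            for a in calls:
                if a < 0:
                    raise ConfigurationError(f"missing allele at {var.CHROM}:{var.POS}")
                alleles.append(int(a))
        rows.append(np.asarray(alleles, dtype=np.uint8))
        positions.append(var.POS)
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        ref.append(var.REF)
        alt.append(var.ALT[0])
    if skipped:
        log.info("read_vcf: skipped %d multiallelic records", skipped)
    if not rows:
        raise ConfigurationError(f"no biallelic records in {path}")
    genotypes = np.stack(rows, axis=1)
    pos_arr = np.asarray(positions, dtype=np.int64)
    if gmap is None:
        gmap = uniform_map(int(pos_arr[0]), int(pos_arr[-1]) + 1, cm_per_mb)
    n_hap = genotypes.shape[0]
    sample_ids = samples if n_hap == 2 * len(samples) else None
    return HaplotypePanel(
        genotypes=genotypes,
        positions=pos_arr,
        gmap=gmap,
        chrom=chrom or "1",
        variant_ids=np.asarray(ids, dtype=object),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        sample_ids=sample_ids,
    )


def write_genetic_map(gmap: GeneticMap, path) -> None:
    with open(path, "w") as fh:
        for p, c in zip(gmap.positions, gmap.cm_values):
            fh.write(f"{int(p)} {np.format_float_positional(c, trim='-')}\n")


def read_genetic_map(path) -> GeneticMap:
    data = np.loadtxt(path, ndmin=2)
    if data.size == 0:
        raise ConfigurationError(f"empty genetic map: {path}")
    return GeneticMap(data[:, 0].astype(np.int64), data[:, 1])
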