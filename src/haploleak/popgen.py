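"""Synthetic phased panels, genetic maps, and pedigree relatives.

Everything downstream (the imputation engine, the reconstruction attack,
semi-kinship scoring, the linking algorithm and the relative-availability
model) is exercised on data produced here, so the generators aim for the
two properties real panels have that those components exploit:

* haplotype near-uniqueness plus short-range linkage disequilibrium,
  obtained from a mosaic-of-founders copying process with per-site
  mutation; and
* pedigree relatives whose identity-by-descent (IBD) segments are known
  exactly, obtained by simulating meioses as a Poisson crossover process
  (one crossover per Morgan, no interference) with full transmission
  bookkeeping.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneticMap",
    "HaplotypePanel",
    "IBDRecord",
    "RelativeCohort",
    "interpolate_cm",
    "uniform_map",
    "simulate_panel",
    "simulate_relatives",
    "meiosis_segments",
]


class ConfigurationError(ValueError):
    """Raised when an operation is called with unusable inputs."""


# ---------------------------------------------------------------------------
# Genetic map


@dataclass(frozen=True)
class GeneticMap:
    """Piecewise-linear bp -> cM map for one chromosome.

    positions are 1-based base-pair coordinates, strictly increasing;
    cm_values are cumulative centimorgans, non-decreasing.
    """

    positions: np.ndarray
    cm_values: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=np.int64)
        cm = np.asarray(self.cm_values, dtype=np.float64)
        if pos.size == 0:
            raise ConfigurationError("genetic map is empty")
        if pos.size != cm.size:
            raise ConfigurationError("map positions/cM lengths differ")
        if np.any(np.diff(pos) <= 0):
            raise ConfigurationError("map positions must be strictly increasing")
        if np.any(np.diff(cm) < 0):
            raise ConfigurationError("map cM values must be non-decreasing")
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "cm_values", cm)

    def interpolate(self, bp) -> np.ndarray | float:
        """cM at bp: linear between map points, constant beyond the ends."""
        return np.interp(bp, self.positions, self.cm_values)

    @property
    def length_cm(self) -> float:
        return float(self.cm_values[-1] - self.cm_values[0])


def interpolate_cm(gmap: GeneticMap, bp) -> np.ndarray | float:
    """Genetic position (cM) at base-pair coordinate(s) ``bp``."""
    return gmap.interpolate(bp)


def uniform_map(start_bp: int, end_bp: int, cm_per_mb: float, n_points: int = 2) -> GeneticMap:
    """A constant-rate map spanning [start_bp, end_bp]."""
    pos = np.linspace(start_bp, end_bp, n_points).astype(np.int64)
    cm = (pos - pos[0]) * (cm_per_mb / 1e6)
    return GeneticMap(pos, cm)


# ---------------------------------------------------------------------------
# Haplotype panel


@dataclass
class HaplotypePanel:
    """Phased binary haplotype matrix with variant metadata.

    genotypes is (n_hap, n_var) over {0, 1}; haplotypes 2k and 2k+1 form
    the diploid sample ``sample_ids[k]``. ``allele_freqs`` is the in-panel
    ALT frequency (column mean). ``pop_allele_freqs``, when present, holds
    the generating population frequencies and plays the role an external
    frequency resource (e.g. a population database) plays for an attacker
    who cannot see the panel itself.
    """

    genotypes: np.ndarray
    positions: np.ndarray
    gmap: GeneticMap
    chrom: str = "1"
    variant_ids: np.ndarray | None = None
    ref: np.ndarray | None = None
    alt: np.ndarray | None = None
    sample_ids: list[str] | None = None
    pop_allele_freqs: np.ndarray | None = None
    cm: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.genotypes = np.ascontiguousarray(self.genotypes, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.genotypes.ndim != 2:
            raise ConfigurationError("genotypes must be 2-D (n_hap, n_var)")
        if self.genotypes.shape[1] != self.positions.size:
            raise ConfigurationError("positions length != variant count")
        if self.variant_ids is None:
            self.variant_ids = np.array(
                [f"{self.chrom}:{p}" for p in self.positions], dtype=object
            )
        if self.ref is None:
            self.ref = np.full(self.n_var, "A", dtype=object)
        if self.alt is None:
            self.alt = np.full(self.n_var, "G", dtype=object)
        if self.sample_ids is None and self.n_hap % 2 == 0:
            self.sample_ids = [f"S{k}" for k in range(self.n_hap // 2)]
        self.cm = np.asarray(self.gmap.interpolate(self.positions), dtype=np.float64)

    @property
    def n_hap(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_var(self) -> int:
        return self.genotypes.shape[1]

    @property
    def allele_freqs(self) -> np.ndarray:
        return self.genotypes.mean(axis=0)

    def subset_haps(self, idx: np.ndarray) -> "HaplotypePanel":
        idx = np.asarray(idx)
        return HaplotypePanel(
            genotypes=self.genotypes[idx],
            positions=self.positions,
            gmap=self.gmap,
            chrom=self.chrom,
            variant_ids=self.variant_ids,
            ref=self.ref,
            alt=self.alt,
            sample_ids=None,
            pop_allele_freqs=self.pop_allele_freqs,
        )

    def subset_sites(self, idx: np.ndarray) -> "HaplotypePanel":
        idx = np.asarray(idx)
        return HaplotypePanel(
            genotypes=self.genotypes[:, idx],
            positions=self.positions[idx],
            gmap=self.gmap,
            chrom=self.chrom,
            variant_ids=np.asarray(self.variant_ids, dtype=object)[idx],
            ref=np.asarray(self.ref, dtype=object)[idx],
            alt=np.asarray(self.alt, dtype=object)[idx],
            sample_ids=self.sample_ids,
            pop_allele_freqs=None
            if self.pop_allele_freqs is None
            else self.pop_allele_freqs[idx],
        )


# ---------------------------------------------------------------------------
# Panel simulation


def simulate_panel(
    n_hap: int,
    n_var: int,
    n_founders: int | None = None,
    switch_rate: float = 1.0,
    mut_rate: float = 1e-4,
    af_spectrum: tuple[float, float] = (0.2, 0.2),
    seed: int = 0,
    length_bp: int = 20_000_000,
    start_bp: int = 1,
    cm_per_mb: float = 1.0,
    chrom: str = "1",
) -> HaplotypePanel:
    """Simulate a phased reference panel as a mosaic of founders.

    Founder haplotypes are drawn per site from Bernoulli(p_v) with
    p_v ~ Beta(af_spectrum) truncated to (0, 1); the remaining haplotypes
    copy founders with switch points at ``switch_rate`` per cM along the
    map and per-site flips at ``mut_rate``.  The Beta(0.2, 0.2) default is
    U-shaped, so the panel carries both rare (MAF < 0.005) and common
    (MAF > 0.2) variants in quantity, which seed construction requires.
    """
    if n_var <= 0:
        raise ConfigurationError("n_var must be positive")
    if n_hap <= 0:
        raise ConfigurationError("n_hap must be positive")
    if n_founders is None:
        n_founders = n_hap
    if n_founders > n_hap:
        raise ConfigurationError("n_founders must be <= n_hap")
    if switch_rate < 0 or mut_rate < 0:
        raise ConfigurationError("rates must be non-negative")

    rng = np.random.default_rng(seed)
    positions = np.sort(
        rng.choice(np.arange(start_bp, start_bp + length_bp), size=n_var, replace=False)
    ).astype(np.int64)
    gmap = uniform_map(start_bp, start_bp + length_bp, cm_per_mb)
    cm = np.asarray(gmap.interpolate(positions))

    a, b = af_spectrum
    eps = 1e-4
    pop_af = np.clip(rng.beta(a, b, size=n_var), eps, 1 - eps)
    founders = (rng.random((n_founders, n_var)) < pop_af).astype(np.uint8)

    haps = np.empty((n_hap, n_var), dtype=np.uint8)
    haps[:n_founders] = founders
    n_copies = n_hap - n_founders
    if n_copies > 0:
        # mosaic source per (haplotype, site): piecewise-constant founder
        # index with switch points from a Poisson process along the map
        gaps = np.diff(cm, prepend=cm[0])
        p_switch = 1.0 - np.exp(-switch_rate * gaps)
        switch = rng.random((n_copies, n_var)) < p_switch
        switch[:, 0] = True
        draw = rng.integers(0, n_founders, size=(n_copies, n_var))
        # forward-fill founder index between switch points
        idx = np.where(switch, np.arange(n_var), 0)
        idx = np.maximum.accumulate(idx, axis=1)
        src = np.take_along_axis(draw, idx, axis=1)
        haps[n_founders:] = founders[src, np.arange(n_var)]
    if mut_rate > 0:
        flips = rng.random((n_hap, n_var)) < mut_rate
        haps ^= flips.astype(np.uint8)

    return HaplotypePanel(
        genotypes=haps,
        positions=positions,
        gmap=gmap,
        chrom=chrom,
        pop_allele_freqs=pop_af,
    )


# ---------------------------------------------------------------------------
# Meiosis on labelled segments

Segments = list[tuple[float, float, int]]  # (start cM, end cM, source label)


def meiosis_segments(
    hap0: Segments, hap1: Segments, length_cm: float, rng: np.random.Generator
) -> Segments:
    """One meiosis over a labelled diploid, returning the gamete's segments.

    Crossovers are a Poisson process at 1 per Morgan (length_cm / 100
    expected events), no interference; the starting haplotype is fair.
    """
    n_x = rng.poisson(length_cm / 100.0)
    cuts = np.sort(rng.uniform(0.0, length_cm, size=n_x))
    bounds = np.concatenate([[0.0], cuts, [length_cm]])
    cur = int(rng.integers(2))
    out: Segments = []
    for k in range(len(bounds) - 1):
        lo, hi = float(bounds[k]), float(bounds[k + 1])
        if hi <= lo:
            continue
        source = hap0 if (cur + k) % 2 == 0 else hap1
        for s, e, lab in source:
            a, b = max(s, lo), min(e, hi)
            if b > a:
                out.append((a, b, lab))
    # merge touching segments with equal labels
    out.sort()
    merged: Segments = []
    for seg in out:
        if merged and merged[-1][2] == seg[2] and abs(merged[-1][1] - seg[0]) < 1e-12:
            merged[-1] = (merged[-1][0], seg[1], seg[2])
        else:
            merged.append(list(seg))  # type: ignore[arg-type]
    return [tuple(s) for s in merged]  # type: ignore[misc]


def _whole(label: int, length_cm: float) -> Segments:
    return [(0.0, length_cm, label)]


def _realize(segments: Segments, cm_sites: np.ndarray, source_haps: np.ndarray) -> np.ndarray:
    """Fill a sequence from labelled segments; sites on [start, end)."""
    out = np.empty(cm_sites.size, dtype=np.uint8)
    filled = np.zeros(cm_sites.size, dtype=bool)
    for s, e, lab in segments:
        m = (cm_sites >= s) & (cm_sites < e)
        out[m] = source_haps[lab][m]
        filled |= m
    if not filled.all():  # sites exactly at the chromosome end
        last = segments[-1]
        out[~filled] = source_haps[last[2]][~filled]
    return out


# ---------------------------------------------------------------------------
# Relative cohorts


@dataclass(frozen=True)
class IBDRecord:
    """Ground-truth IBD segment between a target haplotype and a relative."""

    pair: int
    target_side: int
    relative_side: int
    chrom: str
    start_cm: float
    end_cm: float

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm


@dataclass
class RelativeCohort:
    """Simulated target/relative diploid pairs with exact IBD bookkeeping.

    ``targets`` and ``relatives`` are (n_pairs, 2, n_var) arrays per
    chromosome (dict keyed by chromosome name); target haplotype side 0 is
    the lineage haplotype descending from the relative.
    """

    targets: dict[str, np.ndarray]
    relatives: dict[str, np.ndarray]
    degrees: list[int | str]
    true_ibd: list[IBDRecord]
    site_cm: dict[str, np.ndarray]
    positions: dict[str, np.ndarray]
    allele_freqs: dict[str, np.ndarray]
    gmaps: dict[str, GeneticMap]

    @property
    def n_pairs(self) -> int:
        return len(self.degrees)

    @property
    def chroms(self) -> list[str]:
        return list(self.targets)


def simulate_relatives(
    founder_panel: HaplotypePanel | list[HaplotypePanel],
    degree: int | str,
    n_pairs: int,
    seed: int = 0,
) -> RelativeCohort:
    """Simulate ``n_pairs`` (target, relative) diploid pairs of one degree.

    The relative is a diploid ancestor and the target descends from it via
    a chain of ``degree`` meioses; each intervening gamete pairs with a
    fresh founder haplotype, so the lineage haplotype of the target covers
    an expected fraction 2^(1-d) of the genome IBD with the relative (the
    same coverage law as the collateral relationships of equal degree).
    ``degree='unrelated'`` draws two independent diploid founders.

    Founder haplotypes are consumed without replacement across pairs so
    that distinct pairs are genuinely unrelated.
    """
    panels = founder_panel if isinstance(founder_panel, list) else [founder_panel]
    unrelated = degree == "unrelated"
    if not unrelated and degree not in (1, 2, 3, 4, 5):
        raise ConfigurationError(f"unsupported degree: {degree!r}")
    d = 0 if unrelated else int(degree)
    per_pair = 4 if unrelated else 3 + d  # relative 2 + chain spouses + target other side
    n_needed = per_pair * n_pairs
    if panels[0].n_hap < n_needed:
        raise ConfigurationError(
            f"founder panel too small: need {n_needed} haplotypes, have {panels[0].n_hap}"
        )
    rng = np.random.default_rng(seed)
    founder_order = rng.permutation(panels[0].n_hap)

    chroms = [p.chrom for p in panels]
    targets = {p.chrom: np.empty((n_pairs, 2, p.n_var), dtype=np.uint8) for p in panels}
    relatives = {p.chrom: np.empty((n_pairs, 2, p.n_var), dtype=np.uint8) for p in panels}
    true_ibd: list[IBDRecord] = []

    for pair in range(n_pairs):
        fids = founder_order[pair * per_pair : (pair + 1) * per_pair]
        for p in panels:
            L = p.gmap.length_cm
            cm0 = float(p.gmap.cm_values[0])
            sites = p.cm - cm0
            src = p.genotypes[fids]  # local founder library for this pair
            if unrelated:
                targets[p.chrom][pair, 0] = src[0]
                targets[p.chrom][pair, 1] = src[1]
                relatives[p.chrom][pair, 0] = src[2]
                relatives[p.chrom][pair, 1] = src[3]
                continue
            # labels 0,1 = the relative's two haplotypes; 2.. = fresh founders
            hap0, hap1 = _whole(0, L), _whole(1, L)
            next_founder = 2
            lineage = None
            for _ in range(d):
                lineage = meiosis_segments(hap0, hap1, L, rng)
                hap0, hap1 = lineage, _whole(next_founder, L)
                next_founder += 1
            assert lineage is not None
            relatives[p.chrom][pair, 0] = src[0]
            relatives[p.chrom][pair, 1] = src[1]
            targets[p.chrom][pair, 0] = _realize(lineage, sites, src)
            targets[p.chrom][pair, 1] = src[next_founder]
            for s, e, lab in lineage:
                if lab in (0, 1):
                    true_ibd.append(
                        IBDRecord(pair, 0, lab, p.chrom, s + cm0, e + cm0)
                    )
    label = "unrelated" if unrelated else int(degree)
    return RelativeCohort(
        targets=targets,
        relatives=relatives,
        degrees=[label] * n_pairs,
        true_ibd=true_ibd,
        site_cm={p.chrom: p.cm for p in panels},
        positions={p.chrom: p.positions for p in panels},
        allele_freqs={p.chrom: p.allele_freqs for p in panels},
        gmaps={p.chrom: p.gmap for p in panels},
    )
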