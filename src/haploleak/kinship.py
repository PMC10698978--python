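"""IBD detection between haploid targets and diploid relatives; semi-kinship.

The semi-kinship (SK) coefficient compares a haploid sample (a
reconstructed haplotype chunk) to a diploid sample: it is the probability
that an allele from the haploid sample and a randomly chosen allele from
the diploid sample at the same locus are identical by descent,
SK = k1 / 2 where k1 is the fraction of the chunk covered by IBD segments
to *either* haplotype of the diploid (union, not sum, so a region IBD to
both sides counts once). SK therefore lives in [0, 0.5].

IBD segments are found by exact-match run detection on phased data after
a minor-allele-frequency filter, with a minimum genetic length (defaults
mirror common haploid IBD-detector settings: 2.5 cM, MAF 0.01). The
simulator injects no genotyping error by default, so error-tolerant
extension is unnecessary; ``max_errors`` allows isolated mismatches to be
bridged when error is injected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .popgen import ConfigurationError, RelativeCohort

__all__ = ["IBDSegment", "SKMatrix", "detect_ibd", "semi_kinship", "sk_matrix", "cohort_sk_matrix"]

CHUNK_BP = 20_000_000


@dataclass(frozen=True)
class IBDSegment:
    target_id: int
    relative_id: int
    relative_side: int
    start_bp: int
    end_bp: int
    start_cm: float
    end_cm: float

    @property
    def length_cm(self) -> float:
        return self.end_cm - self.start_cm


@dataclass
class SKMatrix:
    """values[i, l]: SK between target-haplotype chunk i and relative l.

    Row metadata identifies the source haplotype, chromosome and chunk of
    each row, which the linking algorithm needs for its per-chromosome
    assignment constraint.
    """

    values: np.ndarray  # (N, M) in [0, 0.5]
    hap_id: np.ndarray  # (N,) source target-haplotype index
    chrom: np.ndarray  # (N,) chromosome label per row
    chunk: np.ndarray  # (N,) chunk index within chromosome

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_relatives(self) -> int:
        return self.values.shape[1]


def _match_runs(agree: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as (first index, last index) pairs."""
    if agree.all():
        return [(0, agree.size - 1)]
    padded = np.concatenate([[False], agree, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.where(d == 1)[0]
    ends = np.where(d == -1)[0] - 1
    return list(zip(starts.tolist(), ends.tolist()))


def detect_ibd(
    target_hap: np.ndarray,
    relative_diplotype: np.ndarray,
    site_cm: np.ndarray,
    site_bp: np.ndarray | None = None,
    afs: np.ndarray | None = None,
    min_cm: float = 2.5,
    maf_filter: float = 0.01,
    max_errors: int = 0,
    target_id: int = 0,
    relative_id: int = 0,
) -> list[IBDSegment]:
    """Exact-match IBD segments of a haploid target against each relative side.

    Sites with MAF below ``maf_filter`` are excluded before matching;
    maximal agreement runs shorter than ``min_cm`` are discarded. With
    ``max_errors`` > 0, runs separated by that many isolated mismatching
    sites are merged before the length filter.
    """
    target_hap = np.asarray(target_hap)
    rel = np.asarray(relative_diplotype)
    if target_hap.size != rel.shape[-1] or target_hap.size != site_cm.size:
        raise ConfigurationError("target/relative/site arrays disagree in length")
    keep = np.ones(target_hap.size, dtype=bool)
    if afs is not None and maf_filter > 0:
        maf = np.minimum(afs, 1 - afs)
        keep = maf >= maf_filter
    if not keep.any():
        raise ConfigurationError("no shared sites after the MAF filter")
    cm = site_cm[keep]
    bp = site_bp[keep] if site_bp is not None else np.zeros(keep.sum(), dtype=np.int64)
    t = target_hap[keep]

    out: list[IBDSegment] = []
    for side in (0, 1):
        agree = t == rel[side][keep]
        runs = _match_runs(agree)
        if max_errors > 0 and len(runs) > 1:
            merged = [runs[0]]
            for s, e in runs[1:]:
                ps, pe = merged[-1]
                if s - pe - 1 <= max_errors:
                    merged[-1] = (ps, e)
                else:
                    merged.append((s, e))
            runs = merged
        for s, e in runs:
            if cm[e] - cm[s] >= min_cm:
                out.append(
                    IBDSegment(
                        target_id,
                        relative_id,
                        side,
                        int(bp[s]),
                        int(bp[e]),
                        float(cm[s]),
                        float(cm[e]),
                    )
                )
    return out


def semi_kinship(segments: list[IBDSegment], chunk_start_cm: float, chunk_end_cm: float) -> float:
    """SK = k1/2, k1 = union coverage of the chunk by the segments.

    Segments are clipped to the chunk; overlap across the two relative
    haplotype sides is counted once (union).
    """
    chunk_cm = chunk_end_cm - chunk_start_cm
    if chunk_cm <= 0:
        raise ConfigurationError("chunk has non-positive genetic length")
    ivals = sorted(
        (max(s.start_cm, chunk_start_cm), min(s.end_cm, chunk_end_cm)) for s in segments
    )
    covered = 0.0
    cur_lo = cur_hi = None
    for lo, hi in ivals:
        if hi <= lo:
            continue
        if cur_lo is None:
            cur_lo, cur_hi = lo, hi
        elif lo <= cur_hi:
            cur_hi = max(cur_hi, hi)
        else:
            covered += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
    if cur_lo is not None:
        covered += cur_hi - cur_lo
    k1 = covered / chunk_cm
    return 0.5 * k1


def _chunk_grid(positions: np.ndarray, gmap, chunk_bp: int) -> list[tuple[float, float]]:
    """Chunk boundaries in cM for the half-open bp grid [k*C+1, (k+1)*C+1)."""
    first = int((positions[0] - 1) // chunk_bp)
    last = int((positions[-1] - 1) // chunk_bp)
    out = []
    for k in range(first, last + 1):
        lo_bp = k * chunk_bp + 1
        hi_bp = (k + 1) * chunk_bp + 1
        out.append((float(gmap.interpolate(lo_bp)), float(gmap.interpolate(hi_bp))))
    return out


def sk_matrix(
    target_haps: np.ndarray,
    relative_dips: np.ndarray,
    site_cm: np.ndarray,
    positions: np.ndarray,
    gmap,
    afs: np.ndarray | None = None,
    chrom: str = "1",
    chunk_bp: int | None = CHUNK_BP,
    min_cm: float = 2.5,
    maf_filter: float = 0.01,
    hap_offset: int = 0,
) -> SKMatrix:
    """SK values for every (target haplotype chunk, relative diplotype) pair.

    ``target_haps`` is (N_hap, n_var); ``relative_dips`` is (M, 2, n_var).
    IBD is detected once per (haplotype, relative) over the whole
    chromosome and then apportioned to 20-Mbp chunks (``chunk_bp=None``
    treats the chromosome as a single chunk).
    """
    target_haps = np.atleast_2d(np.asarray(target_haps))
    relative_dips = np.asarray(relative_dips)
    N, M = target_haps.shape[0], relative_dips.shape[0]
    if chunk_bp:
        chunks = _chunk_grid(positions, gmap, chunk_bp)
    else:
        chunks = [(float(site_cm[0]), float(gmap.cm_values[-1]))]
    values = np.zeros((N * len(chunks), M))
    hap_id = np.repeat(np.arange(N) + hap_offset, len(chunks))
    chunk_id = np.tile(np.arange(len(chunks)), N)
    for i in range(N):
        for l in range(M):
            segs = detect_ibd(
                target_haps[i],
                relative_dips[l],
                site_cm,
                site_bp=positions,
                afs=afs,
                min_cm=min_cm,
                maf_filter=maf_filter,
                target_id=i,
                relative_id=l,
            )
            if not segs:
                continue
            for c, (lo, hi) in enumerate(chunks):
                values[i * len(chunks) + c, l] = semi_kinship(segs, lo, hi)
    return SKMatrix(
        values=values,
        hap_id=hap_id,
        chrom=np.full(N * len(chunks), chrom, dtype=object),
        chunk=chunk_id,
    )


def cohort_sk_matrix(
    cohort: RelativeCohort,
    chunk_bp: int | None = CHUNK_BP,
    min_cm: float = 2.5,
    maf_filter: float = 0.01,
) -> SKMatrix:
    """SK matrix of all cohort target haplotypes against all relatives.

    Target haplotype 2*p + s is side s of pair p; relative l is the
    diploid partner of pair l, so ground truth links haplotype rows to
    relative columns with matching pair index.
    """
    blocks = []
    for chrom in cohort.chroms:
        th = cohort.targets[chrom].reshape(-1, cohort.targets[chrom].shape[-1])
        sk = sk_matrix(
            th,
            cohort.relatives[chrom],
            cohort.site_cm[chrom],
            cohort.positions[chrom],
            cohort.gmaps[chrom],
            afs=cohort.allele_freqs[chrom],
            chrom=chrom,
            chunk_bp=chunk_bp,
            min_cm=min_cm,
            maf_filter=maf_filter,
        )
        blocks.append(sk)
    return SKMatrix(
        values=np.vstack([b.values for b in blocks]),
        hap_id=np.concatenate([b.hap_id for b in blocks]),
        chrom=np.concatenate([b.chrom for b in blocks]),
        chunk=np.concatenate([b.chunk for b in blocks]),
    )
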