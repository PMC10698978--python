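"""Wright-Fisher model of relative availability and linkable-genome curves.

How likely is it that an adversary's auxiliary database contains a
detectable relative of a reference-panel individual? The model is a
monogamous Wright-Fisher population: N couples in the current
generation, each couple with Poisson(r) offspring, so the population g
generations back has size N(g) = N (r/2)^{-g}. The database holds a
proportion q of the two most recent generations, the target belongs to
the current one, and relationships more than one generation apart are
ignored. A relative is *detectable* when the diploid-diploid comparison
yields at least s IBD segments of length >= m Morgans.

Detection uses the classical recombination model: for a relationship
with ``a`` common ancestor haplotype sources and ``d`` meioses of
separation, the number of shared segments is Poisson with mean
a (dL + C) / 2^{d-1} (L the genome length in Morgans, C the number of
chromosomes) and segment lengths are Exp(d) Morgans. The closed forms
are validated against a Monte-Carlo oracle that simulates the same
branching pedigree with explicit crossover-level meioses.

Relationship inventory (one-generation window, monogamy, target in the
newest generation): degree 1 = parents + full siblings; degree 2 =
aunts/uncles; degree 3 = first cousins; degree 4 = parents' first
cousins; degree 5 = second cousins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .popgen import ConfigurationError, meiosis_segments

__all__ = [
    "WFParams",
    "LinkableCurve",
    "generation_size",
    "prob_detectable_relative",
    "mc_prob_detectable",
    "closest_relative_distribution",
    "smooth_linked_fraction",
    "linkable_curve",
]

# autosome genetic lengths (Morgans), proportions of a standard female-male
# averaged map; rescaled so they sum to genome_morgans
_AUTOSOME_MORGANS = np.array(
    [2.86, 2.69, 2.23, 2.14, 2.04, 1.92, 1.87, 1.68, 1.66, 1.81, 1.58, 1.75,
     1.26, 1.19, 1.41, 1.34, 1.28, 1.17, 1.07, 1.08, 0.62, 0.72]
)


@dataclass
class WFParams:
    r: float = 2.5  # offspring per couple
    m: float = 0.06  # minimum detectable segment length, Morgans
    s: int = 2  # minimum number of detected segments
    db_proportion: float = 0.0  # fraction of the two recent generations in the DB
    genome_morgans: float = 35.9

    def __post_init__(self) -> None:
        if self.r <= 0 or self.m <= 0 or self.s < 1:
            raise ConfigurationError("need r > 0, m > 0, s >= 1")
        if not 0.0 <= self.db_proportion <= 1.0:
            raise ConfigurationError("db_proportion must be in [0, 1]")

    @property
    def chrom_morgans(self) -> np.ndarray:
        return _AUTOSOME_MORGANS * (self.genome_morgans / _AUTOSOME_MORGANS.sum())

    @property
    def n_chrom(self) -> int:
        return _AUTOSOME_MORGANS.size


@dataclass
class LinkableCurve:
    """(p, g) pairs: proportion g of the genome linkable for proportion p
    of reference-panel samples; g is non-increasing in p."""

    p: np.ndarray
    g: np.ndarray


def generation_size(N: float, r: float, g: int) -> float:
    """Population size g generations before the current one: N (r/2)^{-g}."""
    if g < 0:
        raise ConfigurationError("g must be >= 0")
    return N * (r / 2.0) ** (-g)


def _p_detect(d_meioses: int, a_ancestors: int, params: WFParams) -> float:
    """P(>= s segments of >= m Morgans) under the Poisson/Exp segment model."""
    L, C = params.genome_morgans, params.n_chrom
    lam = a_ancestors * (d_meioses * L + C) / 2.0 ** (d_meioses - 1)
    lam_det = lam * np.exp(-d_meioses * params.m)
    return float(stats.poisson.sf(params.s - 1, lam_det))


# per degree: closed-form P(no detectable relative of each type in the DB),
# combined by independence. w_d = q * p_detect for the relevant meioses.


def prob_detectable_relative(degree: int, params: WFParams) -> float:
    """P(>= 1 detectable relative of the given degree in the database).

    Uses generating functions of the Poisson branching counts: siblings
    of any lineage member are Poisson(r) (size-biased family minus the
    member), aunts/uncles Poisson(2r), and cousin-type counts are
    compound Poisson.
    """
    q = params.db_proportion
    if q == 0.0:
        return 0.0
    r = params.r
    if degree == 1:
        w_pc = q * _p_detect(1, 1, params)
        w_sib = q * _p_detect(2, 2, params)
        p_none = (1.0 - w_pc) ** 2 * np.exp(-r * w_sib)
    elif degree == 2:
        w = q * _p_detect(3, 2, params)
        p_none = np.exp(-2.0 * r * w)
    elif degree == 3:
        w = q * _p_detect(4, 2, params)
        p_none = np.exp(-2.0 * r * (1.0 - np.exp(-r * w)))
    elif degree == 4:
        w = q * _p_detect(5, 2, params)
        p_none = np.exp(-4.0 * r * (1.0 - np.exp(-r * w)))
    elif degree == 5:
        w = q * _p_detect(6, 2, params)
        inner = 1.0 - np.exp(-r * (1.0 - np.exp(-r * w)))
        p_none = np.exp(-4.0 * r * inner)
    else:
        raise ConfigurationError("degree must be 1..5")
    return float(1.0 - p_none)


# ---------------------------------------------------------------------------
# Monte-Carlo meiosis oracle


def _founder(label: int, L: float):
    return [(0.0, L, label)]


def _diploid_ibd_lengths(dipA, dipB, lengths: np.ndarray) -> list[float]:
    """Lengths (Morgans) of merged IBD segments between two diplotypes.

    Haplotypes are per-chromosome labelled segment lists; two samples are
    IBD wherever any haplotype pair carries the same founder label over
    the same interval. Overlapping hits are merged before measuring.
    """
    out: list[float] = []
    for c in range(lengths.size):
        hits: list[tuple[float, float]] = []
        for ha in dipA:
            for hb in dipB:
                by_label: dict[int, list[tuple[float, float]]] = {}
                for s, e, lab in ha[c]:
                    by_label.setdefault(lab, []).append((s, e))
                for s, e, lab in hb[c]:
                    for s2, e2 in by_label.get(lab, ()):
                        lo, hi = max(s, s2), min(e, e2)
                        if hi > lo:
                            hits.append((lo, hi))
        hits.sort()
        cur = None
        for lo, hi in hits:
            if cur is None:
                cur = [lo, hi]
            elif lo <= cur[1] + 1e-12:
                cur[1] = max(cur[1], hi)
            else:
                out.append(cur[1] - cur[0])
                cur = [lo, hi]
        if cur is not None:
            out.append(cur[1] - cur[0])
    return out


def _detected(dipA, dipB, params: WFParams) -> bool:
    lens = _diploid_ibd_lengths(dipA, dipB, params.chrom_morgans * 100.0)
    n_ok = sum(1 for x in lens if x >= params.m * 100.0)
    return n_ok >= params.s


def _meiose_genome(dip, lengths_cm: np.ndarray, rng) -> list:
    return [
        meiosis_segments(dip[0][c], dip[1][c], float(lengths_cm[c]), rng)
        for c in range(lengths_cm.size)
    ]


def mc_prob_detectable(
    degree: int,
    params: WFParams,
    n_reps: int = 2000,
    seed: int = 0,
    db_proportions: tuple[float, ...] | None = None,
):
    """Monte-Carlo estimate of prob_detectable_relative, with 95% CIs.

    Each replicate simulates the target's pedigree neighbourhood for the
    requested degree (explicit meioses on 22 chromosomes), counts the
    relatives passing the (m, s) detection rule, and evaluates
    P(>= 1 in DB) = E[1 - (1-q)^D] for each database proportion q.
    Returns {q: (estimate, lo95, hi95)}.
    """
    if degree not in (1, 2, 3):
        raise ConfigurationError("the Monte-Carlo oracle covers degrees 1-3")
    qs = db_proportions or (params.db_proportion,)
    rng = np.random.default_rng(seed)
    cm = params.chrom_morgans * 100.0
    nC = cm.size
    D = np.zeros(n_reps, dtype=int)

    for rep in range(n_reps):
        lab = iter(range(10_000))
        # grandparent couples provide the founder labels for degrees 2-3
        gpp = [[ _founder(next(lab), cm[c]) for c in range(nC)] for _ in range(2)]
        gpm = [[ _founder(next(lab), cm[c]) for c in range(nC)] for _ in range(2)]
        father = [_meiose_genome(gpp, cm, rng),
                  [_founder(next(lab), cm[c]) for c in range(nC)]]
        mother = [_meiose_genome(gpm, cm, rng),
                  [_founder(next(lab), cm[c]) for c in range(nC)]]
        target = [_meiose_genome(father, cm, rng), _meiose_genome(mother, cm, rng)]
        count = 0
        if degree == 1:
            count += 2  # parents: whole-genome IBD, always detectable
            for _ in range(rng.poisson(params.r)):  # full siblings
                sib = [_meiose_genome(father, cm, rng), _meiose_genome(mother, cm, rng)]
                count += _detected(target, sib, params)
        elif degree == 2:
            for gp in (gpp, gpm):  # aunts/uncles on each side
                for _ in range(rng.poisson(params.r)):
                    avunc = [_meiose_genome(gp, cm, rng),
                             [_founder(next(lab), cm[c]) for c in range(nC)]]
                    count += _detected(target, avunc, params)
        else:  # first cousins
            for gp in (gpp, gpm):
                for _ in range(rng.poisson(params.r)):
                    avunc = [_meiose_genome(gp, cm, rng),
                             [_founder(next(lab), cm[c]) for c in range(nC)]]
                    for _ in range(rng.poisson(params.r)):
                        cousin = [_meiose_genome(avunc, cm, rng),
                                  [_founder(next(lab), cm[c]) for c in range(nC)]]
                        count += _detected(target, cousin, params)
        D[rep] = count

    out = {}
    for q in qs:
        vals = 1.0 - (1.0 - q) ** D
        est = float(vals.mean())
        se = float(vals.std(ddof=1) / np.sqrt(n_reps))
        out[q] = (est, est - 1.96 * se, est + 1.96 * se)
    return out


# ---------------------------------------------------------------------------
# Curve synthesis


def closest_relative_distribution(params: WFParams) -> dict[int, float]:
    """P(closest detectable relative has each degree), assuming independence.

    P(closest = d) = P(detectable at d) * prod_{d' < d} (1 - P(detectable at d')).
    """
    probs = {d: prob_detectable_relative(d, params) for d in range(1, 6)}
    out = {}
    none_closer = 1.0
    for d in range(1, 6):
        out[d] = probs[d] * none_closer
        none_closer *= 1.0 - probs[d]
    return out


def smooth_linked_fraction(samples: np.ndarray, grid_n: int = 201):
    """Boundary-corrected density on [0, 1] and its survival function.

    A Gaussian kernel density with reflection at both boundaries (a
    substitute for a boundary-kernel estimator); with fewer than three
    samples, the degenerate empirical step function is returned.
    Returns (grid, pdf, survival) with survival(g) = P(fraction >= g).
    """
    x = np.asarray(samples, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ConfigurationError("samples must lie in [0, 1]")
    grid = np.linspace(0.0, 1.0, grid_n)
    if x.size < 3 or np.std(x) < 1e-12:
        pdf = np.zeros(grid_n)
        surv = np.array([(x >= g).mean() if x.size else 0.0 for g in grid])
        return grid, pdf, surv
    bw = 1.06 * np.std(x) * x.size ** (-1 / 5)
    bw = max(bw, 1e-3)
    pts = np.concatenate([x, -x, 2 - x])  # reflection at 0 and 1
    diff = (grid[:, None] - pts[None, :]) / bw
    pdf = np.exp(-0.5 * diff**2).sum(axis=1) / (x.size * bw * np.sqrt(2 * np.pi))
    pdf /= np.trapezoid(pdf, grid)  # renormalize on [0, 1]
    cdf = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))])
    surv = 1.0 - cdf
    return grid, pdf, np.clip(surv, 0.0, 1.0)


def linkable_curve(
    closest_dist: dict[int, float],
    per_degree_survival: dict[int, tuple[np.ndarray, np.ndarray]],
) -> LinkableCurve:
    """Combine the closest-relative distribution with per-degree survival.

    ``per_degree_survival[d] = (grid, survival)`` gives, for degree d,
    the probability of linking at least proportion g of the genome. The
    curve reports p(g) = sum_d P(closest = d) * S_d(g) over a shared grid.
    """
    grids = [g for g, _ in per_degree_survival.values()]
    grid = grids[0]
    p = np.zeros_like(grid)
    for d, w in closest_dist.items():
        if d in per_degree_survival:
            gd, sd = per_degree_survival[d]
            p += w * np.interp(grid, gd, sd)
    return LinkableCurve(p=p, g=grid)
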