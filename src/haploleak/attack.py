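"""Seed-sieve-extend reconstruction of reference-panel haplotypes.

The attack interrogates an imputation engine with adversarially built
queries and reads reference haplotypes out of the answers:

* **seed** — build small variant sets (one rare anchor fixed to ALT plus
  high-MAF flankers under genetic-distance spacing constraints) and submit
  every genotype conformation, so that some conformation is guaranteed to
  match whatever haplotypes carry the rare allele;
* **sieve** — classify each output's dosage histogram (21 buckets: wide
  end buckets, narrow buckets on the expected dosage "stripes" at
  multiples of 1/n, and the gaps) into a predicted match count 1-5 or
  Other, keeping single matches as reconstructed haplotypes;
* **extend** — split a query matching n haplotypes into two longer
  queries using a site whose dosage sits near 1/n, isolating the one
  carrier of ALT there from the remaining n-1.

A discrete-genotype variant extends each query with its own imputed
output and filters queries whose re-imputation changes, which identifies
unique matches without dosages.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .engine import ImputationEngine, ImputationOutput, Query
from .popgen import ConfigurationError, HaplotypePanel

__all__ = [
    "AttackConfig",
    "SeedSet",
    "ReconstructionReport",
    "AttackInfeasibleError",
    "build_seed_set",
    "enumerate_conformations",
    "bucket_edges",
    "bucketize",
    "plant_query",
    "train_match_classifier",
    "sieve",
    "extend_queries",
    "run_sse_attack",
    "run_discrete_attack",
    "evaluate_reconstruction",
]


class AttackInfeasibleError(RuntimeError):
    """The panel/frequency table cannot support seed construction."""


@dataclass
class AttackConfig:
    set_size: int = 8
    low_maf_cutoff: float = 0.005
    high_maf_cutoff: float = 0.2
    min_spacing_cm: float = 0.001
    max_spacing_cm: float = 0.0035
    middle_fraction: float = 0.8
    extension_af_tol: float = 0.025
    ext_maf_cap: float = 0.6
    ext_window_bp: int = 50_000
    k_rounds: int = 15
    correctness_cutoff: int = 100
    max_positions: int = 10_000
    max_retries_per_position: int = 50
    max_extension_depth: int = 4

    def __post_init__(self) -> None:
        if not self.low_maf_cutoff < self.high_maf_cutoff:
            raise ConfigurationError("low_maf_cutoff must be < high_maf_cutoff")
        if not self.min_spacing_cm < self.max_spacing_cm:
            raise ConfigurationError("min_spacing_cm must be < max_spacing_cm")


@dataclass(frozen=True)
class SeedSet:
    """An anchor (rare, fixed to ALT) plus high-MAF flankers."""

    anchor: int
    flankers: np.ndarray
    chrom: str = "1"

    @property
    def site_idx(self) -> np.ndarray:
        return np.sort(np.append(self.flankers, self.anchor))

    @property
    def set_size(self) -> int:
        return self.flankers.size + 1


@dataclass
class ReconstructionReport:
    reconstructed: list[np.ndarray] = field(default_factory=list)
    provenance: list[str] = field(default_factory=list)
    site_idx: np.ndarray | None = None
    queries_used: int = 0
    trajectory: list[tuple[int, int]] = field(default_factory=list)
    correct_count: int | None = None
    incorrect_count: int | None = None
    duplicate_count: int | None = None


# ---------------------------------------------------------------------------
# Step 1: seed


def build_seed_set(
    panel: HaplotypePanel,
    attack_afs: np.ndarray | None,
    config: AttackConfig,
    rng: np.random.Generator,
) -> SeedSet | None:
    """Build one variant set around a random position, retrying on failure.

    ``attack_afs`` is the ALT-frequency table the adversary consults (for
    example population frequencies); it defaults to the panel's own
    frequencies. Returns None if no set could be placed within the retry
    budget; raises AttackInfeasibleError if no anchor exists at all.
    """
    afs = panel.allele_freqs if attack_afs is None else np.asarray(attack_afs)
    cm = panel.cm
    maf = np.minimum(afs, 1.0 - afs)
    anchor_ok = afs < config.low_maf_cutoff
    flank_ok = maf > config.high_maf_cutoff

    span = panel.positions[-1] - panel.positions[0]
    margin = (1.0 - config.middle_fraction) / 2.0
    bp_lo = panel.positions[0] + margin * span
    bp_hi = panel.positions[-1] - margin * span
    in_middle = (panel.positions >= bp_lo) & (panel.positions <= bp_hi)

    anchors = np.where(anchor_ok & in_middle)[0]
    if not np.any(anchor_ok):
        raise AttackInfeasibleError("no variant below the low-MAF cutoff")
    if anchors.size == 0:
        return None
    flank_pool = np.where(flank_ok & in_middle)[0]
    flank_cm = cm[flank_pool]

    n_flank = config.set_size - 1
    for _ in range(config.max_positions):
        pos = rng.uniform(bp_lo, bp_hi)
        anchor = int(anchors[np.argmin(np.abs(panel.positions[anchors] - pos))])
        for _ in range(config.max_retries_per_position):
            left_edge = right_edge = cm[anchor]
            chosen: list[int] = []
            ok = True
            for _ in range(n_flank):
                iR0 = np.searchsorted(flank_cm, right_edge + config.min_spacing_cm)
                iR1 = np.searchsorted(flank_cm, right_edge + config.max_spacing_cm, "right")
                iL0 = np.searchsorted(flank_cm, left_edge - config.max_spacing_cm)
                iL1 = np.searchsorted(flank_cm, left_edge - config.min_spacing_cm, "right")
                sides = []
                if iR1 > iR0:
                    sides.append("R")
                if iL1 > iL0:
                    sides.append("L")
                if not sides:
                    ok = False
                    break
                side = sides[rng.integers(len(sides))]
                if side == "R":
                    pick = flank_pool[rng.integers(iR0, iR1)]
                    right_edge = cm[pick]
                else:
                    pick = flank_pool[rng.integers(iL0, iL1)]
                    left_edge = cm[pick]
                chosen.append(int(pick))
            if ok:
                return SeedSet(anchor, np.array(sorted(chosen)), chrom=panel.chrom)
    return None


def enumerate_conformations(seed: SeedSet) -> list[Query]:
    """All genotype conformations with the anchor fixed to ALT: 2^(k-1)."""
    sites = seed.site_idx
    a_pos = int(np.where(sites == seed.anchor)[0][0])
    queries = []
    for conf in itertools.product((0, 1), repeat=sites.size - 1):
        alleles = np.empty(sites.size, dtype=np.uint8)
        alleles[np.arange(sites.size) != a_pos] = conf
        alleles[a_pos] = 1
        queries.append(Query(sites, alleles))
    return queries


# ---------------------------------------------------------------------------
# Step 2: sieve


_STRIPE_CENTERS = (1 / 5, 1 / 4, 1 / 3, 2 / 5, 1 / 2, 3 / 5, 2 / 3, 3 / 4, 4 / 5)


def bucket_edges(alpha: float = 0.1, beta: float = 0.02) -> np.ndarray:
    """The 22 edges of the 21 dosage buckets.

    Two end buckets of width ``alpha``, nine stripe buckets of width
    ``beta`` centered on the dosages expected for 2-5 matches (stripes for
    0 and 1 fall inside the end buckets; 2/4 coincides with 1/2), and ten
    gap buckets covering the rest of [0, 1].
    """
    edges = [0.0, alpha]
    for c in _STRIPE_CENTERS:
        edges.extend((c - beta / 2, c + beta / 2))
    edges.extend((1.0 - alpha, 1.0))
    return np.asarray(edges)


_EDGES = bucket_edges()


def bucketize(output: ImputationOutput) -> np.ndarray:
    """Counts of output dosages per bucket (lower-inclusive; 1.0 on top)."""
    if output.dosages is None:
        raise ConfigurationError("bucketize requires dosage-mode output")
    d = output.dosages
    if np.any(d < 0) or np.any(d > 1):
        raise ConfigurationError("dosages outside [0, 1]")
    idx = np.searchsorted(_EDGES[1:-1], d, side="right")
    return np.bincount(idx, minlength=21)


def _scan_matches(panel: HaplotypePanel, sites: np.ndarray, alleles: np.ndarray) -> np.ndarray:
    """Indices of panel haplotypes exactly matching a query (direct scan)."""
    return np.where((panel.genotypes[:, sites] == alleles).all(axis=1))[0]


def plant_query(
    panel: HaplotypePanel,
    n_matches: int,
    config: AttackConfig,
    rng: np.random.Generator,
    max_tries: int = 400,
) -> Query | None:
    """Construct a query verified by direct scan to match exactly n_matches.

    Used to label classifier training data and for planted-truth tests.
    ``n_matches`` may be 0 (no matching haplotype) or >= 1; queries are
    built like seeds (one rare-ish anchor plus nearby flankers), with
    flankers chosen on which the intended carriers agree and, where
    needed, the unintended ones do not.
    """
    counts = panel.genotypes.sum(axis=0)
    cm = panel.cm
    maf = np.minimum(panel.allele_freqs, 1 - panel.allele_freqs)
    flank_ok = maf > config.high_maf_cutoff

    if n_matches == 0:
        # a random rare-anchored conformation that happens to match nothing
        for _ in range(max_tries):
            s = build_seed_set(panel, panel.pop_allele_freqs, config, rng)
            if s is None:
                return None
            sites = s.site_idx
            for _ in range(20):
                alleles = rng.integers(0, 2, size=sites.size).astype(np.uint8)
                alleles[sites == s.anchor] = 1
                if _scan_matches(panel, sites, alleles).size == 0:
                    return Query(sites, alleles)
        return None

    anchors = np.where(counts >= n_matches)[0] if n_matches >= 6 else np.where(
        counts == n_matches
    )[0]
    if anchors.size == 0:
        anchors = np.where((counts >= n_matches) & (counts <= n_matches + 5))[0]
    if anchors.size == 0:
        return None
    window = config.max_spacing_cm
    for _ in range(max_tries):
        v = int(anchors[rng.integers(anchors.size)])
        carriers = np.where(panel.genotypes[:, v] == 1)[0]
        chosen = rng.choice(carriers, size=min(n_matches, carriers.size), replace=False)
        sites = [v]
        lo_edge = hi_edge = cm[v]
        ok = True
        for _ in range(config.set_size - 1):
            cand = np.where(
                flank_ok
                & (
                    ((cm > hi_edge + config.min_spacing_cm) & (cm < hi_edge + window))
                    | ((cm < lo_edge - config.min_spacing_cm) & (cm > lo_edge - window))
                )
            )[0]
            cand = cand[
                (panel.genotypes[np.ix_(chosen, cand)] == panel.genotypes[chosen[0], cand]).all(
                    axis=0
                )
            ]
            if cand.size == 0:
                ok = False
                break
            pick = int(cand[rng.integers(cand.size)])
            sites.append(pick)
            lo_edge, hi_edge = min(lo_edge, cm[pick]), max(hi_edge, cm[pick])
        if not ok:
            continue
        sites_arr = np.sort(np.array(sites))
        alleles = panel.genotypes[chosen[0], sites_arr]
        m = _scan_matches(panel, sites_arr, alleles)
        if (n_matches >= 6 and m.size >= 6) or m.size == n_matches:
            return Query(sites_arr, alleles)
    return None


def train_match_classifier(
    engine: ImputationEngine,
    config: AttackConfig,
    n_per_class: int = 100,
    seed: int = 0,
    n_trees: int = 75,
):
    """Random forest over dosage-bucket counts predicting match count.

    Labels are 1-5 and 0 for "Other" (no match, or six or more matches);
    training examples are planted queries with scan-verified match counts,
    imputed through the engine being attacked.
    """
    rng = np.random.default_rng(seed)
    X, y = [], []
    panel = engine.panel
    for label in (1, 2, 3, 4, 5):
        got = 0
        while got < n_per_class:
            q = plant_query(panel, label, config, rng)
            if q is None:
                raise ConfigurationError(f"cannot plant training queries for class {label}")
            out = engine.impute([q], output_mode="dosage")[0]
            X.append(bucketize(out))
            y.append(label)
            got += 1
    got = 0
    while got < n_per_class:
        target = 0 if got % 2 == 0 else 6
        q = plant_query(panel, target, config, rng)
        if q is None:
            raise ConfigurationError("cannot plant 'Other' training queries")
        out = engine.impute([q], output_mode="dosage")[0]
        X.append(bucketize(out))
        y.append(0)
        got += 1
    clf = RandomForestClassifier(n_estimators=n_trees, random_state=int(seed) % (2**31))
    clf.fit(np.asarray(X), np.asarray(y))
    return clf


def sieve(classifier, outputs: list[ImputationOutput]) -> np.ndarray:
    """Predicted match count per output; 0 means Other (discard)."""
    if not outputs:
        return np.empty(0, dtype=int)
    X = np.stack([bucketize(o) for o in outputs])
    return classifier.predict(X).astype(int)


# ---------------------------------------------------------------------------
# Step 3: extend


def extend_queries(
    query: Query,
    output: ImputationOutput,
    n_matches: int,
    config: AttackConfig,
) -> tuple[Query, Query] | None:
    """Split an n-match query on a site whose dosage is near 1/n.

    Returns (query_alt, query_ref): the ALT extension is expected to match
    the single haplotype carrying ALT there; the REF extension is expected
    to match the remaining n-1 and re-enters the sieve/extend loop. None
    when no candidate dosage is in range (branch abandoned).
    """
    if not 2 <= n_matches <= 5:
        raise ConfigurationError("extension requires 2 <= n_matches <= 5")
    if output.dosages is None:
        raise ConfigurationError("extension requires dosage-mode output")
    target = 1.0 / n_matches
    cand = np.where(np.abs(output.dosages - target) <= config.extension_af_tol)[0]
    cand_sites = output.site_idx[cand]
    cand_sites = cand_sites[~np.isin(cand_sites, query.site_idx)]
    if cand_sites.size == 0:
        return None
    center = output.site_idx[0] + np.median(query.site_idx - output.site_idx[0])
    pick = int(cand_sites[np.argmin(np.abs(cand_sites - center))])
    return query.extend(pick, 1), query.extend(pick, 0)


# ---------------------------------------------------------------------------
# Full attacks


def run_sse_attack(
    engine: ImputationEngine,
    attack_afs: np.ndarray | None,
    config: AttackConfig,
    query_budget: int,
    seed: int = 0,
    classifier=None,
    batch_size: int = 128,
) -> ReconstructionReport:
    """Seed -> impute -> sieve -> extend until the query budget is spent.

    Every query submitted to the engine (conformation batches and
    extension queries alike) is charged against ``query_budget``; training
    the sieve classifier is a one-off setup cost outside the budget.
    """
    if query_budget <= 0:
        raise ConfigurationError("query_budget must be positive")
    rng = np.random.default_rng(seed)
    if classifier is None:
        classifier = train_match_classifier(engine, config, seed=seed + 1)

    report = ReconstructionReport()
    pending: list[tuple[Query, int]] = []  # (query, extension depth)
    conf_batch = 2 ** (config.set_size - 1)

    while True:
        if pending:
            take = min(batch_size, len(pending), query_budget - report.queries_used)
            if take == 0:
                break
            batch, pending = pending[:take], pending[take:]
        else:
            if report.queries_used + conf_batch > query_budget:
                break
            seed_set = build_seed_set(engine.panel, attack_afs, config, rng)
            if seed_set is None:
                break
            batch = [(q, 0) for q in enumerate_conformations(seed_set)]
        outs = engine.impute([q for q, _ in batch], output_mode="dosage")
        report.queries_used += len(batch)
        labels = sieve(classifier, outs)
        for (q, depth), out, label in zip(batch, outs, labels):
            if label == 1:
                report.reconstructed.append(out.genotypes.copy())
                report.provenance.append(f"depth={depth},sites={q.site_idx.size}")
                if report.site_idx is None:
                    report.site_idx = out.site_idx
            elif 2 <= label <= 5 and depth < config.max_extension_depth:
                ext = extend_queries(q, out, int(label), config)
                if ext is not None:
                    pending.append((ext[0], depth + 1))
                    pending.append((ext[1], depth + 1))
        report.trajectory.append((report.queries_used, len(report.reconstructed)))
    return report


def discrete_filter(
    engine: ImputationEngine,
    queries: list[Query],
    anchor: int,
    config: AttackConfig,
    charge=None,
    base_outs: list[ImputationOutput] | None = None,
) -> tuple[np.ndarray, list[int]]:
    """The discrete-output sieving mechanism: extend-and-compare rounds.

    Each round extends every surviving query's *original* sites with one
    new in-window variant, typed with the query's own first-round output
    genotype, and drops queries whose re-imputed output differs anywhere.
    Returns (survivor mask, surviving count after each round).
    """
    panel = engine.panel
    afs = panel.allele_freqs if panel.pop_allele_freqs is None else panel.pop_allele_freqs
    pos = panel.positions
    in_window = np.where(
        (np.abs(pos - pos[anchor]) <= config.ext_window_bp) & (afs < config.ext_maf_cap)
    )[0]
    in_window = in_window[~np.isin(in_window, queries[0].site_idx)]
    order = in_window[np.argsort(-afs[in_window])]  # highest AF first

    if base_outs is None:
        base_outs = engine.impute(queries, output_mode="discrete")
        if charge is not None:
            charge(len(queries))
    alive = np.ones(len(queries), dtype=bool)
    per_round: list[int] = []
    for r in range(config.k_rounds):
        if r >= order.size:  # no unused in-window variant left: retire all
            alive[:] = False
            per_round.append(0)
            continue
        v = int(order[r])
        idx = np.where(alive)[0]
        if idx.size == 0:
            per_round.append(0)
            continue
        ext = [
            queries[i].extend(v, int(base_outs[i].genotypes[v - base_outs[i].site_idx[0]]))
            for i in idx
        ]
        outs = engine.impute(ext, output_mode="discrete")
        if charge is not None:
            charge(len(ext))
        for i, out in zip(idx, outs):
            if not np.array_equal(out.genotypes, base_outs[i].genotypes):
                alive[i] = False
        per_round.append(int(alive.sum()))
    return alive, per_round


def run_discrete_attack(
    engine: ImputationEngine,
    attack_afs: np.ndarray | None,
    config: AttackConfig,
    seed: int = 0,
    n_seed_sets: int = 10,
) -> ReconstructionReport:
    """Discrete-genotype reconstruction: seed, then extend-and-filter.

    Queries surviving all ``k_rounds`` extension rounds are declared
    unique matches and their first-round output genotypes recorded.
    """
    if engine.params.output_mode != "discrete":
        raise ConfigurationError("discrete attack requires an engine in discrete mode")
    rng = np.random.default_rng(seed)
    report = ReconstructionReport()

    def charge(k: int) -> None:
        report.queries_used += k

    for _ in range(n_seed_sets):
        seed_set = build_seed_set(engine.panel, attack_afs, config, rng)
        if seed_set is None:
            break
        queries = enumerate_conformations(seed_set)
        base_outs = engine.impute(queries, output_mode="discrete")
        charge(len(queries))
        alive, _ = discrete_filter(
            engine, queries, seed_set.anchor, config, charge=charge, base_outs=base_outs
        )
        for i in np.where(alive)[0]:
            report.reconstructed.append(base_outs[i].genotypes.copy())
            report.provenance.append("discrete-survivor")
            if report.site_idx is None:
                report.site_idx = base_outs[i].site_idx
        report.trajectory.append((report.queries_used, len(report.reconstructed)))
    return report


# ---------------------------------------------------------------------------
# Accounting


def evaluate_reconstruction(
    reconstructed: list[np.ndarray] | np.ndarray,
    truth_panel: np.ndarray,
    cutoff: int = 100,
) -> tuple[int, int, int]:
    """Classify reconstructions as correct / incorrect / duplicate.

    A sequence is *correct* if it is within ``cutoff`` mismatches of some
    panel haplotype (nearest by Hamming distance, ties to the lowest
    index) that has not already been reconstructed correctly; *incorrect*
    if it is more than ``cutoff`` from every panel haplotype and more than
    ``cutoff`` from every previously counted incorrect sequence; anything
    else is a duplicate.
    """
    truth = np.asarray(truth_panel, dtype=np.uint8)
    correct = incorrect = duplicates = 0
    seen: set[int] = set()
    prior_incorrect: list[np.ndarray] = []
    for rec in reconstructed:
        rec = np.asarray(rec, dtype=np.uint8)
        if rec.size != truth.shape[1]:
            raise ConfigurationError("reconstruction length != panel site count")
        dists = (truth != rec[None, :]).sum(axis=1)
        nearest = int(np.argmin(dists))
        if dists[nearest] <= cutoff:
            if nearest in seen:
                duplicates += 1
            else:
                seen.add(nearest)
                correct += 1
        else:
            if all((p != rec).sum() > cutoff for p in prior_incorrect):
                incorrect += 1
                prior_incorrect.append(rec)
            else:
                duplicates += 1
    return correct, incorrect, duplicates
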