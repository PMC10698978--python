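"""Probabilistic linking of haplotype chunks via shared relatedness.

Reconstructed haplotype chunks from the same individual show the same
relatedness pattern against an external panel of potential relatives.
Linking is cast as maximum-likelihood assignment of N haplotype rows to
T putative individuals (plus a no-match state): the latent degree of
relatedness r_{j,l} in {unrelated, 1, 2, 3+} between individual j and
relative l generates the observed semi-kinship value s_{i,l} of each
haplotype i assigned to j, and EM alternates between

* E-step: posterior over r_{j,l} proportional to prior * product of
  per-haplotype SK likelihoods, and
* M-step: a minimum-cost network-flow assignment maximizing
  sum_i pi_{i, g(i)} subject to one individual per haplotype and at most
  two haplotypes per (individual, chromosome).

The initial assignment combines imputation-based chaining of adjacent
chunks with grouping of identical thresholded relatedness patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .engine import ImputationEngine, Query
from .kinship import SKMatrix
from .popgen import ConfigurationError

__all__ = [
    "DEGREES",
    "LinkingConfig",
    "SKLikelihoods",
    "fit_sk_likelihoods",
    "e_step",
    "compute_pi",
    "m_step_assign",
    "em_objective",
    "group_by_pattern",
    "chain_adjacent_chunks",
    "combine_initial",
    "link_haplotypes",
    "evaluate_linking",
]

DEGREES = ("unrelated", "1", "2", "3+")  # the degree alphabet (4 states)
_N_BINS = 26  # zero bin + 25 equal bins on (0, 1]
_FLOOR = 1e-12


@dataclass
class LinkingConfig:
    prior_unrelated: float = 0.9  # remainder uniform over {1, 2, 3+}
    thr_hi: float = 2.0 ** (-9 / 2)  # expected lower bound, 3rd degree
    thr_lo: float = 2.0 ** (-13 / 2)  # expected lower bound, 5th degree
    min_group_size: int = 5
    em_iters: int = 1  # 1 chunk-level, 10 chromosome-level
    null_posterior_cap: float = 0.99  # chromosome-level output filter
    null_log: bool = True  # log p_0 in the no-match column of pi
    # step-1 chaining
    chain_window_bp: int = 500_000
    chain_dosage_gap: float = 0.5
    chain_score_max: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.thr_lo < self.thr_hi < 0.5:
            raise ConfigurationError("need 0 < thr_lo < thr_hi < 0.5")

    @property
    def prior(self) -> np.ndarray:
        rest = (1.0 - self.prior_unrelated) / 3.0
        return np.array([self.prior_unrelated, rest, rest, rest])


@dataclass
class SKLikelihoods:
    """p(s | r) for the four degree states, on a shared discretization.

    Chunk mode: histogram masses over a zero bin plus 25 equal bins on
    (0, 1], with the unrelated state a point mass at zero (weight 0.95)
    plus a truncated Gaussian. Chromosome mode: Gaussian densities with
    empirical moments evaluated on the same grid (no point mass).
    All rows are floored and normalized.
    """

    table: np.ndarray  # (4, 26) likelihood per (degree state, bin)
    mode: str = "chunk"

    def bin_of(self, s: np.ndarray) -> np.ndarray:
        s = np.asarray(s)
        b = np.ceil(np.clip(s, 0.0, 1.0) * 25).astype(int)
        return np.where(s <= 0, 0, b)

    def loglik(self, s: np.ndarray) -> np.ndarray:
        """log p(s | r) for every degree state: shape s.shape + (4,)."""
        return np.log(self.table.T[self.bin_of(s)])


def _bin_centers() -> np.ndarray:
    centers = np.concatenate([[0.0], (np.arange(25) + 0.5) / 25.0])
    return centers


def fit_sk_likelihoods(
    sk_by_degree: dict[str, np.ndarray],
    mode: str = "chunk",
    point_mass: float = 0.95,
    null_sd: float | None = None,
) -> SKLikelihoods:
    """Estimate p(s|r) from labelled SK samples.

    ``sk_by_degree`` maps each degree state ('1', '2', '3+', 'unrelated')
    to SK samples from a labelled cohort; degrees 3-5 should be pooled
    into '3+' by the caller. The unrelated state uses a point mass at
    zero plus a Gaussian at the empirical mean (sd 0.1) at chunk level,
    and a pure Gaussian (sd 0.0175) at chromosome level.
    """
    if null_sd is None:
        null_sd = 0.1 if mode == "chunk" else 0.0175
    if mode == "chromosome":
        point_mass = 0.0
    centers = _bin_centers()
    table = np.empty((4, _N_BINS))
    for k, deg in enumerate(DEGREES):
        s = np.asarray(sk_by_degree[deg], dtype=float)
        if deg == "unrelated":
            mean = float(s[s >= 0].mean()) if s.size else 0.0
            gauss = np.exp(-0.5 * ((centers - mean) / null_sd) ** 2)
            gauss = gauss / gauss.sum()
            row = (1.0 - point_mass) * gauss
            row[0] += point_mass
        elif mode == "chunk":
            b = np.ceil(np.clip(s, 0, 1) * 25).astype(int)
            b = np.where(s <= 0, 0, b)
            row = np.bincount(b, minlength=_N_BINS).astype(float)
            row = row / max(row.sum(), 1.0)
        else:
            mu, sd = float(s.mean()), float(max(s.std(), 1e-3))
            row = np.exp(-0.5 * ((centers - mu) / sd) ** 2)
            row = row / row.sum()
        table[k] = np.maximum(row, _FLOOR)
    return SKLikelihoods(table=table, mode=mode)


# ---------------------------------------------------------------------------
# EM pieces


def e_step(
    assign: np.ndarray, S: np.ndarray, prior: np.ndarray, lik: SKLikelihoods, T: int
) -> np.ndarray:
    """Posterior p(r_{j,l} | S, Theta): shape (T, M, 4).

    ``assign`` maps each haplotype row to an individual in [0, T) or T
    for no-match. An individual with no assigned haplotypes keeps the
    prior (empty product).
    """
    M = S.shape[1]
    ll = lik.loglik(S)  # (N, M, 4)
    logpost = np.tile(np.log(prior), (T, M, 1))
    for j in range(T):
        rows = np.where(assign == j)[0]
        if rows.size:
            logpost[j] += ll[rows].sum(axis=0)
    logpost -= logpost.max(axis=2, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=2, keepdims=True)
    return post


def compute_pi(
    posteriors: np.ndarray, S: np.ndarray, lik: SKLikelihoods, null_log: bool = True
) -> np.ndarray:
    """pi[i, j]: expected log-likelihood of row i under individual j.

    Column T (no-match) is sum_l log p_0(s_{i,l}); with
    ``null_log=False`` the log is omitted there, reproducing the
    formula-as-printed variant.
    """
    ll = lik.loglik(S)  # (N, M, 4)
    pi_t = np.einsum("nmr,tmr->nt", ll, posteriors)
    if null_log:
        null_col = ll[:, :, 0].sum(axis=1)
    else:
        null_col = np.exp(ll[:, :, 0]).sum(axis=1)
    return np.concatenate([pi_t, null_col[:, None]], axis=1)


def m_step_assign(
    pi: np.ndarray, chr_labels: np.ndarray, T: int, incumbent: np.ndarray | None = None
) -> np.ndarray:
    """Maximize sum_i pi[i, assign(i)] by minimum-cost network flow.

    Constraints: every haplotype row is assigned exactly once; each
    (individual, chromosome) receives at most two rows; the no-match
    column T is uncapacitated. Costs are scaled to integers for the flow
    solver; the flow optimum is integral. If an ``incumbent`` assignment
    scores at least as well under the exact (unrounded) objective, it is
    kept, so EM updates can never decrease the objective through cost
    rounding.
    """
    N = pi.shape[0]
    if not np.all(np.isfinite(pi)):
        raise ConfigurationError("pi must be finite (floor the likelihoods)")
    scale = 1e9 / max(1.0, np.abs(pi).max())
    cost = np.round(-pi * scale).astype(np.int64)

    G = nx.DiGraph()
    chroms = {}
    for i in range(N):
        G.add_node(("h", i), demand=-1)
        c = chr_labels[i]
        chroms.setdefault(c, []).append(i)
    G.add_node("sink", demand=N)
    for c, rows in chroms.items():
        for j in range(T + 1):
            node = ("s", j, c)
            G.add_node(node)
            cap = len(rows) if j == T else 2
            G.add_edge(node, "sink", capacity=cap, weight=0)
            for i in rows:
                G.add_edge(("h", i), node, capacity=1, weight=int(cost[i, j]))
    flow = nx.min_cost_flow(G)
    assign = np.full(N, T, dtype=int)
    for i in range(N):
        for node, f in flow[("h", i)].items():
            if f > 0:
                assign[i] = node[1]
                break
    if incumbent is not None and _feasible(incumbent, chr_labels, T):
        rows = np.arange(N)
        if pi[rows, incumbent].sum() >= pi[rows, assign].sum():
            return np.asarray(incumbent).copy()
    return assign


def _feasible(assign: np.ndarray, chr_labels: np.ndarray, T: int) -> bool:
    counts: dict[tuple, int] = {}
    for i, j in enumerate(assign):
        if j >= T:
            continue
        key = (int(j), chr_labels[i])
        counts[key] = counts.get(key, 0) + 1
        if counts[key] > 2:
            return False
    return True


def em_objective(
    assign: np.ndarray,
    posteriors: np.ndarray,
    S: np.ndarray,
    prior: np.ndarray,
    lik: SKLikelihoods,
    T: int,
) -> float:
    """Evidence lower bound: E_q[log p(S, R; Theta)] + H(q).

    Non-decreasing across alternating E- and M-steps; used by the
    monotonicity tests.
    """
    pi = compute_pi(posteriors, S, lik, null_log=True)
    data_term = float(pi[np.arange(len(assign)), assign].sum())
    q = np.clip(posteriors, _FLOOR, 1.0)
    prior_term = float((posteriors * np.log(prior)[None, None, :]).sum())
    entropy = float(-(posteriors * np.log(q)).sum())
    return data_term + prior_term + entropy


# ---------------------------------------------------------------------------
# Initial solution


def group_by_pattern(S: SKMatrix, config: LinkingConfig) -> list[np.ndarray]:
    """Group rows with identical thresholded relatedness patterns.

    Two passes: binarize at thr_hi and group identical non-zero rows
    (dropping groups below min_group_size), then re-threshold the
    ungrouped rows at thr_lo, adding to existing groups or forming new
    ones, dropping undersized new groups. Each group is finally capped to
    at most two haplotypes per chunk, keeping the rows with the highest
    SK to the group's strongest relative.
    """
    groups: dict[bytes, list[int]] = {}
    taken = np.zeros(S.n_rows, dtype=bool)
    for thr in (config.thr_hi, config.thr_lo):
        pat = (S.values >= thr).astype(np.uint8)
        new: dict[bytes, list[int]] = {}
        for i in range(S.n_rows):
            if taken[i] or not pat[i].any():
                continue
            key = pat[i].tobytes()
            if key in groups:
                groups[key].append(i)
                taken[i] = True
            else:
                new.setdefault(key, []).append(i)
        for key, rows in new.items():
            if len(rows) >= config.min_group_size:
                groups[key] = rows
                taken[np.asarray(rows)] = True
    out = []
    for rows in groups.values():
        rows = np.asarray(rows)
        # cap: at most two rows per (chromosome, chunk), by SK to the
        # group's strongest relative
        best_rel = int(np.argmax(S.values[rows].max(axis=0)))
        keep = []
        by_chunk: dict[tuple, list[int]] = {}
        for i in rows:
            by_chunk.setdefault((S.chrom[i], S.chunk[i]), []).append(i)
        for members in by_chunk.values():
            members = sorted(members, key=lambda i: -S.values[i, best_rel])
            keep.extend(members[:2])
        out.append(np.sort(np.asarray(keep)))
    return out


def chain_adjacent_chunks(
    engine: ImputationEngine,
    target_chunks: dict[tuple, dict[int, np.ndarray]],
    chunk_bounds: dict[tuple, tuple[int, int]],
    config: LinkingConfig,
    thin: int = 1,
) -> list[list[tuple]]:
    """Chain chunks whose imputed extension predicts the neighbour.

    ``target_chunks[(chrom, c)][row] = genotypes`` over that chunk's panel
    sites (``engine.panel`` must be the relative set for that chromosome's
    sites); ``chunk_bounds[(chrom, c)]`` are the chunk's bp bounds. Each
    chunk is imputed against the relative set over a region one chunk
    wider in each direction; at each boundary, a pair's score is the
    number of window variants whose dosage differs from the neighbour's
    genotype by more than ``chain_dosage_gap``, summed over both
    directions. Mutual sole-best pairs with score <= chain_score_max are
    linked, and chains are the transitive closure.
    """
    pos = engine.panel.positions
    keys = sorted(chunk_bounds, key=lambda k: (str(k[0]), k[1]))
    site_range = {
        k: (np.searchsorted(pos, chunk_bounds[k][0]), np.searchsorted(pos, chunk_bounds[k][1]))
    for k in keys}
    # impute every chunk row over the widened region
    dosages: dict[tuple, dict[int, tuple[np.ndarray, int]]] = {k: {} for k in keys}
    for k in keys:
        lo_s, hi_s = site_range[k]
        if hi_s <= lo_s or not target_chunks.get(k):
            continue
        lo_bp = max(int(pos[0]), chunk_bounds[k][0] - (chunk_bounds[k][1] - chunk_bounds[k][0]))
        hi_bp = min(int(pos[-1]) + 1, chunk_bounds[k][1] + (chunk_bounds[k][1] - chunk_bounds[k][0]))
        rows = list(target_chunks[k])
        queries = []
        sites = np.arange(lo_s, hi_s)[::thin]
        for r in rows:
            queries.append(Query(sites, target_chunks[k][r][::thin]))
        outs = engine.impute(queries, region=(lo_bp, hi_bp), output_mode="dosage")
        for r, out in zip(rows, outs):
            dosages[k][r] = (out.dosages, int(np.searchsorted(pos, lo_bp)))

    links: list[tuple[tuple, tuple]] = []  # ((key, row), (key, row))
    for a, b in zip(keys[:-1], keys[1:]):
        if a[0] != b[0] or b[1] != a[1] + 1:
            continue  # not adjacent on the same chromosome
        boundary = chunk_bounds[a][1]
        w_lo, w_hi = boundary - config.chain_window_bp, boundary + config.chain_window_bp
        s_lo, s_hi = np.searchsorted(pos, w_lo), np.searchsorted(pos, w_hi)
        if s_hi <= s_lo:
            continue
        rows_a, rows_b = list(dosages[a]), list(dosages[b])
        if not rows_a or not rows_b:
            continue
        score = np.zeros((len(rows_a), len(rows_b)))
        win = np.arange(s_lo, s_hi)
        a_lo, a_hi = site_range[a]
        b_lo, b_hi = site_range[b]
        for ia, ra in enumerate(rows_a):
            dos_a, off_a = dosages[a][ra]
            da = dos_a[win - off_a]
            for ib, rb in enumerate(rows_b):
                dos_b, off_b = dosages[b][rb]
                db = dos_b[win - off_b]
                # genotypes of each chunk in the window (clipped to its own span)
                in_b = (win >= b_lo) & (win < b_hi)
                in_a = (win >= a_lo) & (win < a_hi)
                g_b = target_chunks[b][rb][(win[in_b] - b_lo)]
                g_a = target_chunks[a][ra][(win[in_a] - a_lo)]
                s = (np.abs(da[in_b] - g_b) > config.chain_dosage_gap).sum()
                s += (np.abs(db[in_a] - g_a) > config.chain_dosage_gap).sum()
                score[ia, ib] = s
        best_b = score.argmin(axis=1)
        best_a = score.argmin(axis=0)
        for ia, ib in enumerate(best_b):
            if best_a[ib] != ia:
                continue
            if (score[ia] == score[ia, ib]).sum() > 1:
                continue  # not the sole best
            if (score[:, ib] == score[ia, ib]).sum() > 1:
                continue
            if score[ia, ib] <= config.chain_score_max:
                links.append(((a, rows_a[ia]), (b, rows_b[ib])))

    # transitive closure over shared chunk instances
    parent: dict[tuple, tuple] = {}

    def find(x):
        while parent.get(x, x) != x:
            parent[x] = parent.get(parent[x], parent[x])
            x = parent[x]
        return x

    for u, v in links:
        parent.setdefault(u, u)
        parent.setdefault(v, v)
        parent[find(u)] = find(v)
    chains: dict[tuple, list[tuple]] = {}
    for u in parent:
        chains.setdefault(find(u), []).append(u)
    return [sorted(c) for c in chains.values() if len(c) >= 2]


def combine_initial(
    chains: list[list[tuple]],
    groups: list[np.ndarray],
    row_of: dict[tuple, int],
    n_rows: int,
) -> np.ndarray:
    """Initial assignment: a chain joins a group if a strict majority of
    its chunks are in that group; everything else starts unassigned.

    Returns assign: (n_rows,) with group index or len(groups) (no match).
    ``row_of`` maps a chain element (chunk key, row id) to its SK row.
    """
    T = len(groups)
    assign = np.full(n_rows, T, dtype=int)
    member = np.full(n_rows, -1, dtype=int)
    for gi, rows in enumerate(groups):
        member[rows] = gi
    for gi, rows in enumerate(groups):
        assign[rows] = gi
    for chain in chains:
        rows = [row_of[x] for x in chain if x in row_of]
        if not rows:
            continue
        votes = member[rows]
        votes = votes[votes >= 0]
        if votes.size == 0:
            continue
        counts = np.bincount(votes, minlength=T)
        top = int(counts.argmax())
        if counts[top] * 2 > len(chain):  # strictly more than half the chain
            assign[np.asarray(rows)] = top
    return assign


# ---------------------------------------------------------------------------
# Orchestration


@dataclass
class LinkedGroup:
    individual: int
    rows: np.ndarray
    null_posterior: float


def link_haplotypes(
    S: SKMatrix,
    lik: SKLikelihoods,
    config: LinkingConfig | None = None,
    engine: ImputationEngine | None = None,
    target_chunks: dict | None = None,
    chunk_bounds: dict | None = None,
) -> tuple[list[LinkedGroup], np.ndarray]:
    """Full linking: pre-filter, initial solution, EM, output filtering.

    Rows are pre-filtered to those with SK >= thr_lo to a relative that
    relates (>= thr_lo) to at least two distinct chunks. When ``engine``
    (imputing against the relative set) and the chunk data are given,
    step-1 chaining refines the initial grouping. Returns the surviving
    groups (>= min_group_size rows; chromosome mode additionally requires
    a no-match posterior <= null_posterior_cap against some relative) and
    the full assignment vector.
    """
    config = config or LinkingConfig()
    if S.n_relatives == 0:
        return [], np.zeros(S.n_rows, dtype=int)

    hot = S.values >= config.thr_lo
    chunk_key = np.array([hash((c, k)) for c, k in zip(S.chrom, S.chunk)])
    rel_ok = np.zeros(S.n_relatives, dtype=bool)
    for l in range(S.n_relatives):
        if len(set(chunk_key[hot[:, l]])) >= 2:
            rel_ok[l] = True
    keep = np.where((hot & rel_ok[None, :]).any(axis=1))[0]
    if keep.size == 0:
        return [], np.full(S.n_rows, 0, dtype=int)

    sub = SKMatrix(S.values[keep], S.hap_id[keep], S.chrom[keep], S.chunk[keep])
    groups = group_by_pattern(sub, config)
    chains: list[list[tuple]] = []
    row_of: dict[tuple, int] = {}
    if engine is not None and target_chunks is not None and chunk_bounds is not None:
        sub_chunks: dict[tuple, dict[int, np.ndarray]] = {}
        for r in range(sub.n_rows):
            key = (sub.chrom[r], int(sub.chunk[r]))
            hap = int(sub.hap_id[r])
            if key in target_chunks and hap in target_chunks[key]:
                sub_chunks.setdefault(key, {})[hap] = target_chunks[key][hap]
                row_of[(key, hap)] = r
        chains = chain_adjacent_chunks(engine, sub_chunks, chunk_bounds, config)
    T = max(len(groups), 1)
    assign = combine_initial(chains, groups, row_of, sub.n_rows)

    prior = config.prior
    post = None
    # capacity slot: two haplotypes per chromosome segment per individual
    # (per chunk position in chunk mode, per chromosome otherwise)
    slots = np.array([f"{c}:{k}" for c, k in zip(sub.chrom, sub.chunk)], dtype=object)
    for _ in range(max(config.em_iters, 1)):
        post = e_step(assign, sub.values, prior, lik, T)
        pi = compute_pi(post, sub.values, lik, null_log=config.null_log)
        assign = m_step_assign(pi, slots, T, incumbent=assign)

    out: list[LinkedGroup] = []
    for j in range(T):
        rows = np.where(assign == j)[0]
        if rows.size < config.min_group_size:
            continue
        null_p = float(post[j, :, 0].min()) if post is not None else 1.0
        if lik.mode == "chromosome" and null_p > config.null_posterior_cap:
            continue
        out.append(LinkedGroup(individual=j, rows=keep[rows], null_posterior=null_p))
    full_assign = np.full(S.n_rows, T, dtype=int)
    full_assign[keep] = assign
    return out, full_assign


def evaluate_linking(
    groups: list[LinkedGroup], truth_individual: np.ndarray
) -> list[dict]:
    """Attribute each group to the strict-majority individual.

    Returns one record per group: attributed individual (or None for an
    unassigned set without a strict majority), correct and incorrect row
    counts.
    """
    out = []
    for g in groups:
        owners = truth_individual[g.rows]
        vals, counts = np.unique(owners, return_counts=True)
        top = counts.argmax()
        if counts[top] * 2 > len(owners):
            out.append(
                {
                    "individual": vals[top],
                    "correct": int(counts[top]),
                    "incorrect": int(len(owners) - counts[top]),
                    "unassigned": False,
                }
            )
        else:
            out.append(
                {"individual": None, "correct": 0, "incorrect": 0, "unassigned": True}
            )
    return out
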