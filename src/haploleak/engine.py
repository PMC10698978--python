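"""Haploid Li-Stephens HMM imputation over a reference panel.

The hidden state at each panel site is the index of the reference
haplotype being copied (state space {1..n}); transitions over an interval
of genetic length d cM switch to a uniformly chosen haplotype with
probability 1 - exp(-recomb_scale * d), and observations at typed sites
are noisy copies of the copied haplotype's allele (mismatch probability
``error_rate``). The forward-backward recursion is run over the typed
sites only and propagated analytically into the gaps, which is exact for
this transition family (uniform switching composes: the product of two
such kernels is the kernel of the summed genetic distance). Per-site
posteriors are normalized, and the dosage is the posterior ALT
probability.

Output mirrors an imputation server: per-site dosages in [0, 1] and/or
discrete genotypes (ALT iff dosage > 0.5; a tie at exactly 0.5 yields
REF), restricted to the 20-Mbp chunk containing the query when chunking
is on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .popgen import ConfigurationError, HaplotypePanel

__all__ = [
    "Query",
    "EngineParams",
    "ImputationOutput",
    "ImputationEngine",
    "forward_backward",
    "CHUNK_BP",
]

CHUNK_BP = 20_000_000


@dataclass(frozen=True)
class Query:
    """Typed sites (panel variant indices, sorted, unique) with alleles."""

    site_idx: np.ndarray
    alleles: np.ndarray
    haploid: bool = True

    def __post_init__(self) -> None:
        idx = np.asarray(self.site_idx, dtype=np.int64)
        al = np.asarray(self.alleles, dtype=np.uint8)
        if idx.size == 0:
            raise ConfigurationError("query has no typed sites")
        if idx.size != al.size:
            raise ConfigurationError("site/allele lengths differ")
        if np.any(np.diff(idx) <= 0):
            raise ConfigurationError("query sites must be sorted and unique")
        object.__setattr__(self, "site_idx", idx)
        object.__setattr__(self, "alleles", al)

    def extend(self, site: int, allele: int) -> "Query":
        """New query with one extra typed site."""
        idx = np.append(self.site_idx, site)
        al = np.append(self.alleles, allele)
        order = np.argsort(idx)
        return Query(idx[order], al[order])

    def key(self) -> tuple:
        return tuple(self.site_idx.tolist())


@dataclass
class EngineParams:
    error_rate: float = 0.01
    recomb_scale: float = 0.02  # per cM; a few expected switches per chromosome
    min_state_prob: float = 1e-6  # forward pruning floor relative to the max
    output_mode: str = "dosage"  # "dosage" | "discrete"

    def __post_init__(self) -> None:
        if not 0.0 < self.error_rate < 0.5:
            raise ConfigurationError("error_rate must be in (0, 0.5)")
        if self.min_state_prob < 0:
            raise ConfigurationError("min_state_prob must be >= 0")
        if self.output_mode not in ("dosage", "discrete"):
            raise ConfigurationError("output_mode must be 'dosage' or 'discrete'")


@dataclass
class ImputationOutput:
    """Imputed genotypes (and dosages unless discrete) over a site range."""

    site_idx: np.ndarray  # panel variant indices covered by the region
    genotypes: np.ndarray  # uint8 per site
    dosages: np.ndarray | None  # None in discrete output mode
    region: tuple[int, int]  # bp interval [start, end)


def _typed_forward_backward(
    panel: HaplotypePanel, queries: list[Query], params: EngineParams
):
    """Scaled forward-backward at the shared typed sites of a query batch."""
    tidx = queries[0].site_idx
    obs = np.stack([q.alleles for q in queries])  # (B, K)
    n = panel.n_hap
    B, K = obs.shape
    e = params.error_rate
    G_t = panel.genotypes[:, tidx]  # (n, K)
    match = obs[:, None, :] == G_t[None, :, :]  # (B, n, K)
    emis = np.where(match, 1.0 - e, e).transpose(0, 2, 1)  # (B, K, n)

    tcm = panel.cm[tidx]
    rho = 1.0 - np.exp(-params.recomb_scale * np.diff(tcm))  # (K-1,)

    f = np.empty((B, K, n))
    cur = emis[:, 0, :] / n
    cur = cur / cur.sum(axis=1, keepdims=True)
    f[:, 0] = cur
    for k in range(1, K):
        cur = (1.0 - rho[k - 1]) * cur + rho[k - 1] / n
        cur = cur * emis[:, k, :]
        if params.min_state_prob > 0:
            cur[cur < params.min_state_prob * cur.max(axis=1, keepdims=True)] = 0.0
        cur = cur / cur.sum(axis=1, keepdims=True)
        f[:, k] = cur

    b = np.empty((B, K, n))
    b[:, K - 1] = 1.0 / n
    cur = b[:, K - 1]
    for k in range(K - 2, -1, -1):
        v = emis[:, k + 1, :] * cur
        cur = (1.0 - rho[k]) * v + rho[k] * v.mean(axis=1, keepdims=True)
        cur = cur / cur.sum(axis=1, keepdims=True)
        b[:, k] = cur

    gamma = f * b
    gamma = gamma / gamma.sum(axis=2, keepdims=True)
    return tidx, tcm, f, b, emis, gamma


def _batch_dosages(
    panel: HaplotypePanel,
    queries: list[Query],
    params: EngineParams,
    lo: int,
    hi: int,
) -> np.ndarray:
    """ALT posterior for each query at panel sites [lo, hi).

    Queries must share an identical typed-site set. In the gap between
    typed anchors k and k+1 the state posterior factorizes as

        p_t  propto  (a f_k + (1-a)/n) * (c v_{k+1} + (1-c) sum(v)/n)

    with a = exp(-scale * d_left), c = exp(-scale * d_right) and
    v_{k+1} = emission_{k+1} * backward_{k+1}; one-sided beyond the
    outermost typed sites. Dosages then need only G^T-matvecs of a few
    per-query vectors per gap, so whole-chunk output is cheap.
    """
    tidx, tcm, f, b, emis, gamma = _typed_forward_backward(panel, queries, params)
    n = panel.n_hap
    B, K = f.shape[0], f.shape[1]
    scale = params.recomb_scale

    site_cm = panel.cm[lo:hi]
    Gu = panel.genotypes[:, lo:hi]
    freqs = Gu.mean(axis=0)
    right = np.searchsorted(tcm, site_cm, side="left")  # gap index in [0, K]

    v_all = emis * b  # (B, K, n)
    sv = v_all.sum(axis=2)

    dos = np.empty((B, hi - lo))
    for g in range(K + 1):
        cols = np.where(right == g)[0]
        if cols.size == 0:
            continue
        Gg = Gu[:, cols].astype(np.float64)  # (n, Lg)
        fg = freqs[cols][None, :]
        cmg = site_cm[cols]
        if g == 0:  # before the first typed site: backward only
            c = np.exp(-scale * (tcm[0] - cmg))[None, :]
            vG = v_all[:, 0] @ Gg
            svk = sv[:, 0][:, None]
            dos[:, cols] = (c * vG + (1.0 - c) * svk * fg) / svk
        elif g == K:  # after the last typed site: forward only
            a = np.exp(-scale * (cmg - tcm[K - 1]))[None, :]
            fG = f[:, K - 1] @ Gg
            dos[:, cols] = a * fG + (1.0 - a) * fg
        else:
            a = np.exp(-scale * (cmg - tcm[g - 1]))[None, :]
            c = np.exp(-scale * (tcm[g] - cmg))[None, :]
            fk, vk = f[:, g - 1], v_all[:, g]
            fv = fk * vk
            fG, vG, fvG = fk @ Gg, vk @ Gg, fv @ Gg
            svk = sv[:, g][:, None]
            sfv = fv.sum(axis=1)[:, None]
            num = (
                a * c * fvG
                + a * (1.0 - c) * (svk / n) * fG
                + c * (1.0 - a) / n * vG
                + (1.0 - a) * (1.0 - c) * (svk / n) * fg
            )
            den = (
                a * c * sfv
                + a * (1.0 - c) * svk / n
                + c * (1.0 - a) * svk / n
                + (1.0 - a) * (1.0 - c) * svk / n
            )
            dos[:, cols] = num / den

    # exact posterior at the typed sites themselves
    t_in = np.where((tidx >= lo) & (tidx < hi))[0]
    if t_in.size:
        gg = panel.genotypes[:, tidx[t_in]].astype(np.float64)
        dos[:, tidx[t_in] - lo] = np.einsum("bkh,hk->bk", gamma[:, t_in, :], gg)
    return np.clip(dos, 0.0, 1.0)


def forward_backward(
    panel: HaplotypePanel, query: Query, params: EngineParams | None = None
) -> np.ndarray:
    """Per-site posterior ALT probability over the whole panel region."""
    params = params or EngineParams()
    if query.site_idx[-1] >= panel.n_var or query.site_idx[0] < 0:
        raise ConfigurationError("query site outside the panel site universe")
    return _batch_dosages(panel, [query], params, 0, panel.n_var)[0]


def state_posteriors(
    panel: HaplotypePanel, query: Query, params: EngineParams | None = None
) -> np.ndarray:
    """Full (n_var, n_hap) posterior over copied haplotypes (diagnostics).

    Materializes the per-site state distribution the dosage computation
    marginalizes; intended for small panels.
    """
    params = params or EngineParams()
    tidx, tcm, f, b, emis, gamma = _typed_forward_backward(panel, [query], params)
    n, K = panel.n_hap, tidx.size
    scale = params.recomb_scale
    v_all = (emis * b)[0]
    f0 = f[0]
    out = np.empty((panel.n_var, n))
    right = np.searchsorted(tcm, panel.cm, side="left")
    for t in range(panel.n_var):
        g = right[t]
        if g == 0:
            c = np.exp(-scale * (tcm[0] - panel.cm[t]))
            p = c * v_all[0] + (1 - c) * v_all[0].sum() / n
        elif g == K:
            a = np.exp(-scale * (panel.cm[t] - tcm[K - 1]))
            p = a * f0[K - 1] + (1 - a) / n
        else:
            a = np.exp(-scale * (panel.cm[t] - tcm[g - 1]))
            c = np.exp(-scale * (tcm[g] - panel.cm[t]))
            alpha = a * f0[g - 1] + (1 - a) / n
            beta = c * v_all[g] + (1 - c) * v_all[g].sum() / n
            p = alpha * beta
        out[t] = p / p.sum()
    t_in = np.where((tidx >= 0) & (tidx < panel.n_var))[0]
    out[tidx[t_in]] = gamma[0, t_in]
    return out


class ImputationEngine:
    """An imputation-server-style service over one reference panel.

    The engine is the in-repo stand-in for an imputation server: callers
    submit batches of queries and receive per-site dosages and/or discrete
    genotypes over the chunk (or explicit region) being imputed. It also
    counts every query it has answered, which the attack modules use for
    budget accounting.
    """

    def __init__(
        self,
        panel: HaplotypePanel,
        params: EngineParams | None = None,
        chunk_mb: float = 20.0,
    ):
        self.panel = panel
        self.params = params or EngineParams()
        self.chunk_mb = chunk_mb
        self.queries_answered = 0

    def _region_bounds(self, queries: list[Query], region: tuple[int, int] | None):
        pos = self.panel.positions
        if region is not None:
            lo = int(np.searchsorted(pos, region[0], side="left"))
            hi = int(np.searchsorted(pos, region[1], side="left"))
            if hi <= lo:
                raise ConfigurationError("region contains no panel sites")
            return lo, hi, (int(region[0]), int(region[1]))
        if self.chunk_mb and self.chunk_mb > 0:
            anchor_bp = int(pos[queries[0].site_idx[0]])
            size = int(self.chunk_mb * 1e6)
            start = ((anchor_bp - 1) // size) * size + 1
            lo = int(np.searchsorted(pos, start, side="left"))
            hi = int(np.searchsorted(pos, start + size, side="left"))
            return lo, hi, (start, start + size)
        return 0, self.panel.n_var, (int(pos[0]), int(pos[-1]) + 1)

    def impute(
        self,
        queries: list[Query],
        region: tuple[int, int] | None = None,
        output_mode: str | None = None,
    ) -> list[ImputationOutput]:
        """Impute a batch of queries; each query is processed independently.

        Queries are internally grouped by their typed-site signature so
        conformation batches vectorize, but no information flows between
        queries.
        """
        if not queries:
            return []
        mode = output_mode or self.params.output_mode
        for q in queries:
            if q.site_idx[-1] >= self.panel.n_var or q.site_idx[0] < 0:
                raise ConfigurationError("query site outside the panel site universe")
        self.queries_answered += len(queries)

        groups: dict[tuple, list[int]] = {}
        for i, q in enumerate(queries):
            groups.setdefault(q.key(), []).append(i)

        out: list[ImputationOutput | None] = [None] * len(queries)
        for members in groups.values():
            batch = [queries[i] for i in members]
            lo, hi, reg = self._region_bounds(batch, region)
            dos = _batch_dosages(self.panel, batch, self.params, lo, hi)
            site_idx = np.arange(lo, hi)
            for row, i in enumerate(members):
                d = dos[row]
                out[i] = ImputationOutput(
                    site_idx=site_idx,
                    genotypes=(d > 0.5).astype(np.uint8),
                    dosages=None if mode == "discrete" else d.copy(),
                    region=reg,
                )
        return out  # type: ignore[return-value]
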