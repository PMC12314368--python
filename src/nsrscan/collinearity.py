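"""Collinear-block detection between two scaffolds from gene order + hits.

The chaining recurrence scores a chain of anchor pairs with a fixed match
reward per anchor and a linear penalty on skipped gene ranks on both axes:

    score(j) = match_score + max_i { score(i) + gap_penalty * (da-1 + db-1) }

over predecessors i with 0 < da = index_a(j) - index_a(i) <= max_gaps and
the matching strictly monotone index_b constraint (increasing for parallel
chains, decreasing for antiparallel ones, searched via a mirrored axis).
Chains are extracted greedily best-first; anchors of an accepted chain are
removed and anchors within ``overlap_window`` ranks of them may no longer
seed new chains.  Chains shorter than ``match_size`` or with a block
e-value above the cut are discarded.

The block e-value is a Poisson approximation: with anchors scattered
uniformly over the gene-rank grid, lambda is the expected anchor count in
the block's rank rectangle and

    e = P(Poisson(lambda) >= m) / m!

where m is the chain length; the 1/m! factor is the probability that m
exchangeable points in the rectangle are jointly monotone.  This is a
documented stand-in for the (unpublished) MCScanX formula; native
``.collinearity`` files can be imported instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.special import gammaln
from scipy.stats import poisson

from .kaks import KaKsResult, classify_homologous
from .model import GeneModel, HitRecord


@dataclass(frozen=True, slots=True)
class AnchorPair:
    index_a: int
    index_b: int
    gene_a: str
    gene_b: str
    hit_evalue: float


@dataclass(frozen=True, slots=True)
class CollinearParams:
    match_score: float = 50.0
    gap_penalty: float = -1.0
    match_size: int = 10
    max_gaps: int = 25
    overlap_window: int = 5
    e_value_cut: float = 1e-5

    def __post_init__(self) -> None:
        if self.match_size < 2:
            raise ValueError("match_size must be >= 2")
        if self.max_gaps < 0:
            raise ValueError("max_gaps must be >= 0")


@dataclass(frozen=True)
class CollinearBlock:
    anchors: tuple[AnchorPair, ...]
    orientation: str  # {parallel, antiparallel}
    score: float
    e_value: float
    scaffold_a: str = ""
    scaffold_b: str = ""
    validate: bool = True

    def __post_init__(self) -> None:
        if self.validate:
            _validate_block(self)

    @property
    def span_a(self) -> int:
        ia = [a.index_a for a in self.anchors]
        return max(ia) - min(ia) + 1

    @property
    def span_b(self) -> int:
        ib = [a.index_b for a in self.anchors]
        return max(ib) - min(ib) + 1


def _validate_block(block: CollinearBlock, max_gaps: int | None = None) -> None:
    anchors = block.anchors
    if not anchors:
        raise ValueError("empty block")
    sign = 1 if block.orientation == "parallel" else -1
    for prev, cur in zip(anchors, anchors[1:]):
        da = cur.index_a - prev.index_a
        db = sign * (cur.index_b - prev.index_b)
        if da <= 0 or db <= 0:
            raise ValueError(
                f"block violates monotonicity at anchors {prev.gene_a}->{cur.gene_a}"
            )
        if max_gaps is not None and (da > max_gaps or db > max_gaps):
            raise ValueError("block violates max_gaps")


def build_anchors(
    hits: list[HitRecord],
    genes_a: list[GeneModel],
    genes_b: list[GeneModel],
    e_value_cut: float = 1e-5,
) -> list[AnchorPair]:
    """Map hits to gene-rank index pairs.

    Genes are ranked by start position (strand-agnostic).  Hits above the
    e-value cut are dropped; duplicate (a, b) pairs keep the best e-value.
    Hits naming genes absent from either gene list raise KeyError.
    """
    rank_a = {g.gene_id: i for i, g in enumerate(sorted(genes_a, key=lambda g: (g.start, g.gene_id)))}
    rank_b = {g.gene_id: i for i, g in enumerate(sorted(genes_b, key=lambda g: (g.start, g.gene_id)))}
    best: dict[tuple[str, str], HitRecord] = {}
    for h in hits:
        if h.e_value > e_value_cut:
            continue
        if h.query_id not in rank_a:
            raise KeyError(f"hit query {h.query_id!r} not among scaffold A genes")
        if h.subject_id not in rank_b:
            raise KeyError(f"hit subject {h.subject_id!r} not among scaffold B genes")
        key = (h.query_id, h.subject_id)
        if key not in best or h.e_value < best[key].e_value:
            best[key] = h
    anchors = [
        AnchorPair(rank_a[q], rank_b[s], q, s, h.e_value)
        for (q, s), h in best.items()
    ]
    anchors.sort(key=lambda a: (a.index_a, a.index_b))
    return anchors


def collapse_tandem_anchors(anchors: list[AnchorPair]) -> list[AnchorPair]:
    """Collapse runs of consecutive same-axis genes hitting one partner gene.

    Consecutive (rank-adjacent) anchors on A sharing gene_b — a tandem array
    shadowing a single partner — are reduced to the lowest-e-value member,
    and symmetrically for runs on B sharing gene_a.  Prevents tandem
    clusters from simulating synteny.
    """

    def _collapse(items: list[AnchorPair], axis: str) -> list[AnchorPair]:
        if axis == "a":
            items = sorted(items, key=lambda x: (x.gene_b, x.index_a))
            same = lambda p, c: c.gene_b == p.gene_b and c.index_a - p.index_a == 1
        else:
            items = sorted(items, key=lambda x: (x.gene_a, x.index_b))
            same = lambda p, c: c.gene_a == p.gene_a and c.index_b - p.index_b == 1
        out: list[AnchorPair] = []
        run: list[AnchorPair] = []
        for anc in items:
            if run and same(run[-1], anc):
                run.append(anc)
            else:
                if run:
                    out.append(min(run, key=lambda x: (x.hit_evalue, x.index_a, x.index_b)))
                run = [anc]
        if run:
            out.append(min(run, key=lambda x: (x.hit_evalue, x.index_a, x.index_b)))
        return out

    collapsed = _collapse(_collapse(anchors, "a"), "b")
    collapsed.sort(key=lambda a: (a.index_a, a.index_b))
    return collapsed


def block_evalue(
    n_block_anchors: int,
    span_a: int,
    span_b: int,
    n_anchors_total: int,
    n_genes_a: int,
    n_genes_b: int,
) -> float:
    """Poisson chain e-value (see module docstring); monotone decreasing in
    the anchor count at a fixed rank rectangle."""
    if n_block_anchors < 1:
        raise ValueError("block must contain at least one anchor")
    if n_genes_a <= 0 or n_genes_b <= 0 or span_a <= 0 or span_b <= 0:
        raise ValueError("zero-size gene space or rank rectangle")
    lam = n_anchors_total * (span_a * span_b) / (n_genes_a * n_genes_b)
    m = n_block_anchors
    log_e = poisson.logsf(m - 1, lam) - gammaln(m + 1)
    return float(math.exp(log_e))


def _chain_dp(
    anchors: list[AnchorPair],
    params: CollinearParams,
    mirror: bool,
    can_seed: set[int],
) -> tuple[list[float], list[int]]:
    """One DP pass over sorted anchors; returns (score, predecessor) arrays.

    ``mirror`` negates index_b to search antiparallel chains.  Anchors not
    in ``can_seed`` may only appear with a predecessor.
    """
    n = len(anchors)
    NEG = -math.inf
    score = [NEG] * n
    pred = [-1] * n
    ib = [(-a.index_b if mirror else a.index_b) for a in anchors]
    for j in range(n):
        aj = anchors[j]
        best = params.match_score if j in can_seed else NEG
        best_pred = -1
        for i in range(j - 1, -1, -1):
            da = aj.index_a - anchors[i].index_a
            if da > params.max_gaps:
                break  # anchors sorted by index_a
            if da <= 0 or score[i] == NEG:
                continue
            db = ib[j] - ib[i]
            if db <= 0 or db > params.max_gaps:
                continue
            cand = score[i] + params.match_score + params.gap_penalty * ((da - 1) + (db - 1))
            # tie-break: prefer the predecessor with lowest index_a, then index_b;
            # scanning right-to-left, '>=' keeps the leftmost equal-score predecessor
            if cand > best or (cand == best and best_pred != -1):
                if cand > best:
                    best = cand
                    best_pred = i
                else:
                    pi, pj = anchors[i], anchors[best_pred]
                    if (pi.index_a, pi.index_b) < (pj.index_a, pj.index_b):
                        best_pred = i
        score[j] = best
        pred[j] = best_pred
    return score, pred


def chain_anchors(
    anchors: list[AnchorPair],
    params: CollinearParams = CollinearParams(),
    n_genes_a: int | None = None,
    n_genes_b: int | None = None,
    scaffold_a: str = "",
    scaffold_b: str = "",
    collapse_tandem: bool = True,
) -> list[CollinearBlock]:
    """Extract collinear blocks greedily best-first (both orientations)."""
    if not anchors:
        return []
    work = sorted(anchors, key=lambda a: (a.index_a, a.index_b))
    if collapse_tandem:
        work = collapse_tandem_anchors(work)
    if n_genes_a is None:
        n_genes_a = max(a.index_a for a in work) + 1
    if n_genes_b is None:
        n_genes_b = max(a.index_b for a in work) + 1
    n_total = len(work)

    blocks: list[CollinearBlock] = []
    available = list(range(len(work)))
    shadowed: set[int] = set()

    while True:
        idx_map = [k for k in available]
        sub = [work[k] for k in idx_map]
        if len(sub) < params.match_size:
            break
        best_chain: list[int] | None = None
        best_score = -math.inf
        best_orient = "parallel"
        for mirror in (False, True):
            can_seed = {
                j for j, k in enumerate(idx_map) if k not in shadowed
            }
            score, pred = _chain_dp(sub, params, mirror, can_seed)
            if not score:
                continue
            j_best = max(
                range(len(sub)),
                key=lambda j: (score[j], -sub[j].index_a, -sub[j].index_b),
            )
            if score[j_best] == -math.inf:
                continue
            if score[j_best] > best_score:
                chain = []
                j = j_best
                while j != -1:
                    chain.append(j)
                    j = pred[j]
                chain.reverse()
                best_score = score[j_best]
                best_chain = [idx_map[j] for j in chain]
                best_orient = "antiparallel" if mirror else "parallel"
        if best_chain is None or len(best_chain) < params.match_size:
            break
        chain_anchors_ = [work[k] for k in best_chain]
        ia = [a.index_a for a in chain_anchors_]
        ib_ = [a.index_b for a in chain_anchors_]
        ev = block_evalue(
            len(chain_anchors_),
            max(ia) - min(ia) + 1,
            max(ib_) - min(ib_) + 1,
            n_total,
            n_genes_a,
            n_genes_b,
        )
        accepted = ev <= params.e_value_cut
        if accepted:
            blocks.append(
                CollinearBlock(
                    anchors=tuple(chain_anchors_),
                    orientation=best_orient,
                    score=best_score,
                    e_value=ev,
                    scaffold_a=scaffold_a,
                    scaffold_b=scaffold_b,
                )
            )
        used = set(best_chain)
        available = [k for k in available if k not in used]
        if accepted and params.overlap_window > 0:
            for k in available:
                a = work[k]
                for c in chain_anchors_:
                    if (
                        abs(a.index_a - c.index_a) <= params.overlap_window
                        and abs(a.index_b - c.index_b) <= params.overlap_window
                    ):
                        shadowed.add(k)
                        break
        if not accepted:
            # chain too weak: nothing better remains in this region; removing
            # its anchors guarantees progress
            continue
    return blocks


def homologous_gene_flags(
    blocks: list[CollinearBlock],
    kaks_results: dict[tuple[str, str], KaKsResult],
    threshold: float = 0.3,
    metric: str = "ks",
) -> dict[str, bool]:
    """Per-gene homology flag: a gene is homologous iff it sits on at least
    one retained block anchor whose pair passes the divergence threshold.

    Only genes appearing in some block are present in the returned mapping;
    absent genes are non-homologous by definition.
    """
    missing = []
    flags: dict[str, bool] = {}
    for block in blocks:
        for a in block.anchors:
            res = kaks_results.get((a.gene_a, a.gene_b)) or kaks_results.get(
                (a.gene_b, a.gene_a)
            )
            if res is None:
                missing.append((a.gene_a, a.gene_b))
                continue
            ok = classify_homologous(res, threshold=threshold, metric=metric)
            for g in (a.gene_a, a.gene_b):
                flags[g] = flags.get(g, False) or ok
    if missing:
        raise KeyError(f"missing Ka/Ks results for anchor pairs: {missing[:10]}")
    return flags
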