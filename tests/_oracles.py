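"""Independent brute-force oracles used by the test suite.

Each oracle is deliberately written as a direct enumeration / simulation,
sharing no code with the implementation paths it checks.
"""

from __future__ import annotations

import itertools
import math
from itertools import combinations, permutations

from Bio.Seq import Seq

_NT = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def ng86_oracle(codons_a, codons_b):
    """NG86 quantities by exhaustive enumeration.

    Sites: per position, the fraction of the 3 possible changes that are
    synonymous (changes into stops count as nonsynonymous).  Differences:
    average over all orderings of the differing positions, dropping
    orderings that visit a stop codon unless all do.
    Returns (S, N, sd, nd).
    """
    S = N = sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        for codon in (ca, cb):
            syn_frac = 0.0
            for pos in range(3):
                n_syn = 0
                for nt in _NT:
                    if nt == codon[pos]:
                        continue
                    mut = codon[:pos] + nt + codon[pos + 1 :]
                    if mut not in _STOPS and _aa(mut) == _aa(codon):
                        n_syn += 1
                syn_frac += n_syn / 3.0
            S += syn_frac / 2.0
            N += (3.0 - syn_frac) / 2.0
        positions = [i for i in range(3) if ca[i] != cb[i]]
        if not positions:
            continue
        paths = []
        for order in permutations(positions):
            cur = ca
            s = n = 0
            ok = True
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if nxt in _STOPS:
                    ok = False
                if _aa(nxt) == _aa(cur):
                    s += 1
                else:
                    n += 1
                cur = nxt
            paths.append((s, n, ok))
        keep = [p for p in paths if p[2]] or paths
        sd += sum(p[0] for p in keep) / len(keep)
        nd += sum(p[1] for p in keep) / len(keep)
    return S, N, sd, nd


def hypergeom_tail_enum(k: int, n: int, K: int, N: int, tail: str) -> float:
    """Exact tail probability by enumerating every C(N, n) draw."""
    marked = set(range(K))
    total = hits = 0
    for draw in combinations(range(N), n):
        total += 1
        x = sum(1 for item in draw if item in marked)
        if (tail == "lower" and x <= k) or (tail == "upper" and x >= k):
            hits += 1
    return hits / total


def best_chain_score_oracle(anchors, match_score, gap_penalty, max_gaps) -> float:
    """Best chain score over both orientations via memoised recursion on the
    anchor-compatibility DAG (exhaustive over all chains)."""

    def solve_clean(points):
        pts = sorted(points)
        memo = {}

        def best_from(i):
            if i in memo:
                return memo[i]
            xa, xb = pts[i]
            best = match_score
            for j in range(len(pts)):
                da = pts[j][0] - xa
                db = pts[j][1] - xb
                if 0 < da <= max_gaps and 0 < db <= max_gaps:
                    cand = match_score + gap_penalty * ((da - 1) + (db - 1)) + best_from(j)
                    best = max(best, cand)
            memo[i] = best
            return best

        return max((best_from(i) for i in range(len(pts))), default=0.0)

    forward = solve_clean([(a.index_a, a.index_b) for a in anchors])
    mirrored = solve_clean([(a.index_a, -a.index_b) for a in anchors])
    return max(forward, mirrored)


def longest_monotone_chain(points, max_gaps=None) -> int:
    """Length of the longest strictly-increasing chain (both axes), with an
    optional per-step rank-gap cap; O(n^2) DP used as a Monte-Carlo helper."""
    pts = sorted(points)
    n = len(pts)
    best = [1] * n
    for j in range(n):
        for i in range(j):
            da = pts[j][0] - pts[i][0]
            db = pts[j][1] - pts[i][1]
            if da > 0 and db > 0 and (max_gaps is None or (da <= max_gaps and db <= max_gaps)):
                best[j] = max(best[j], best[i] + 1)
    return max(best, default=0)


def tdg_pairs_bruteforce(genes, group_of):
    """O(n^2) scan for tandem pairs: same group, rank distance <= 2,
    intervening gene (if any) in a different group."""
    by_scaffold = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold_id, []).append(g)
    found = set()
    for scf, glist in by_scaffold.items():
        glist = sorted(glist, key=lambda g: (g.start, g.gene_id))
        for i in range(len(glist)):
            for j in range(len(glist)):
                if i >= j:
                    continue
                gi, gj = glist[i], glist[j]
                grp = group_of.get(gi.gene_id)
                if grp is None or group_of.get(gj.gene_id) != grp:
                    continue
                if j - i == 1:
                    found.add((gi.gene_id, gj.gene_id))
                elif j - i == 2 and group_of.get(glist[i + 1].gene_id) != grp:
                    found.add((gi.gene_id, gj.gene_id))
    return found


def interval_union_bases(spans):
    """Union of [start, end) spans as an explicit base set."""
    bases = set()
    for s, e in spans:
        bases.update(range(s, e))
    return bases


def bases_to_intervals(bases):
    """Back-convert a base set to sorted disjoint intervals."""
    out = []
    for b in sorted(bases):
        if out and b == out[-1][1]:
            out[-1][1] = b + 1
        else:
            out.append([b, b + 1])
    return [tuple(iv) for iv in out]
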