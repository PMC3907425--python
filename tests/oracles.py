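"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle restates a rule from first principles, without sharing code with
the implementation it checks.
"""

from __future__ import annotations

import networkx as nx

MIN_UNITS = {2: 6, 3: 5, 4: 4}
_ACGT = set("ACGT")


# ---------------------------------------------------------------------------
# Island clustering: all-pairs overlap graph + connected components
# ---------------------------------------------------------------------------

def island_partition_bruteforce(intervals, min_overlap):
    """Partition (id, start, end) tuples into islands via an explicit overlap
    graph; returns a set of frozensets of ids."""
    g = nx.Graph()
    for rid, _s, _e in intervals:
        g.add_node(rid)
    for i, (ri, si, ei) in enumerate(intervals):
        for rj, sj, ej in intervals[i + 1 :]:
            if min(ei, ej) - max(si, sj) >= min_overlap:
                g.add_edge(ri, rj)
    return {frozenset(c) for c in nx.connected_components(g)}


# ---------------------------------------------------------------------------
# SSR mining: forward-reachability over every admissible parse
# ---------------------------------------------------------------------------

def _near_copies(m):
    """All strings reachable from motif m by one substitution, and all by one
    single-base deletion."""
    subs = set()
    for j in range(len(m)):
        for b in "ACGT":
            if b != m[j]:
                subs.add(m[:j] + b + m[j + 1 :])
    dels = {m[:j] + m[j + 1 :] for j in range(len(m))}
    return subs, dels


def longest_run_bruteforce(s, i, k):
    """Longest valid run end for the motif starting at position i (or None).

    A valid run is P I P I ... P: blocks of perfect motif copies separated by
    isolated single-base imperfections (substituted unit, unit with a deleted
    base, or an inserted base), starting and ending with a perfect copy, with
    at most floor(n_units / 10) imperfections. Explored as breadth-first
    reachability over (position, n_units, n_imperfections) states.
    """
    m = s[i : i + k]
    if len(m) < k or set(m) - _ACGT:
        return None
    if any(len(m) % d == 0 and m == m[: d] * (len(m) // d) for d in range(1, k)):
        return None
    subs, dels = _near_copies(m)
    states = {(i + k, 1, 0)}
    seen = set()
    best = None
    while states:
        pos, n, e = states.pop()
        if (pos, n, e) in seen:
            continue
        seen.add((pos, n, e))
        if n >= MIN_UNITS[k] and e <= n // 10:
            if best is None or (pos, n) > (best[0], best[1]):
                best = (pos, n, e)
        if s[pos : pos + k] == m:
            states.add((pos + k, n + 1, e))
        if s[pos : pos + k] in subs and s[pos + k : pos + 2 * k] == m:
            states.add((pos + 2 * k, n + 2, e + 1))
        if s[pos : pos + k - 1] in dels and s[pos + k - 1 : pos + 2 * k - 1] == m:
            states.add((pos + 2 * k - 1, n + 2, e + 1))
        if pos < len(s) and s[pos] in _ACGT and s[pos + 1 : pos + 1 + k] == m:
            states.add((pos + 1 + k, n + 1, e + 1))
    return best


def find_ssrs_bruteforce(s):
    """Exhaustive-substring SSR call set: {(start, end, unit_len, n_units,
    n_imperfections)} after same-unit-length containment suppression."""
    s = s.upper()
    out = set()
    for k in (2, 3, 4):
        cands = []
        for i in range(0, max(0, len(s) - 2 * k + 1)):
            hit = longest_run_bruteforce(s, i, k)
            if hit is not None:
                end, n, e = hit
                cands.append((i, end, n, e))
        cands.sort(key=lambda c: (-(c[1] - c[0]), c[0]))
        kept = []
        for c in cands:
            if not any(ks <= c[0] and c[1] <= ke for ks, ke, *_ in kept):
                kept.append(c)
        out.update((i, end, k, n, e) for i, end, n, e in kept)
    return out


# ---------------------------------------------------------------------------
# SNP calling: naive per-column counter
# ---------------------------------------------------------------------------

def call_snps_bruteforce(pileup, min_support=2, max_depth=30):
    """(position, allele_a, allele_b) triples from explicit column counting;
    alleles ordered by (support desc, base)."""
    out = []
    for pos in range(len(pileup.consensus)):
        col = pileup.column(pos)
        if len(col) > max_depth:
            continue
        counts = {}
        for _rid, base in col:
            if base in "ACGT":
                counts[base] = counts.get(base, 0) + 1
        supported = sorted(
            (b for b, c in counts.items() if c >= min_support),
            key=lambda b: (-counts[b], b),
        )
        if len(supported) >= 2:
            out.append((pos, supported[0], supported[1]))
    return out
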