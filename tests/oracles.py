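"""Independent brute-force oracles, kept free of the implementation paths.

Each function re-derives an expected result by direct enumeration so the
production code can be checked against it on small random inputs.
"""

from __future__ import annotations

from itertools import permutations


def mott_bruteforce(quals: list[int], cutoff: int) -> int:
    """Optimal truncation point for 3' quality trimming, by enumeration.

    Considers every suffix, scores it as sum(cutoff - q) over the removed
    bases, and returns the kept-prefix length maximizing that gain;
    a non-positive best gain keeps the whole read.  Ties retain more bases.
    """
    best_gain = 0
    best_cut = len(quals)
    for cut in range(len(quals) - 1, -1, -1):  # descending: ties keep larger cut
        gain = sum(cutoff - q for q in quals[cut:])
        if gain > best_gain:
            best_gain = gain
            best_cut = cut
    return best_cut


def overlap_components(kmers: list[str]) -> list[list[str]]:
    """Connected components of the (k-1) suffix-prefix overlap graph."""
    parent = {s: s for s in kmers}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in kmers:
        for b in kmers:
            if a != b and a[1:] == b[:-1]:
                parent[find(a)] = find(b)
    comps: dict[str, list[str]] = {}
    for s in kmers:
        comps.setdefault(find(s), []).append(s)
    return list(comps.values())


def is_path_shaped(kmers: list[str]) -> bool:
    """True when the overlap graph is a disjoint union of simple paths."""
    for s in kmers:
        out_deg = sum(1 for t in kmers if t != s and s[1:] == t[:-1])
        in_deg = sum(1 for t in kmers if t != s and t[1:] == s[:-1])
        if out_deg > 1 or in_deg > 1:
            return False
    # no in/out degree above 1; a cycle would make some component have
    # as many edges as nodes
    for comp in overlap_components(kmers):
        edges = sum(
            1 for a in comp for b in comp if a != b and a[1:] == b[:-1]
        )
        if edges >= len(comp) and len(comp) > 1:
            return False
    return True


def chain_merges_bruteforce(kmers: list[str]) -> list[str]:
    """All maximal chain merges of a path-shaped k-mer set, by enumeration.

    For each overlap component, tries every ordering of its k-mers and
    keeps the ordering in which consecutive k-mers overlap by k-1; on a
    simple path exactly one complete ordering is valid and its merge is
    the component's assembled sequence.
    """
    merges: list[str] = []
    for comp in overlap_components(kmers):
        valid = None
        for order in permutations(comp):
            if all(order[i][1:] == order[i + 1][:-1] for i in range(len(order) - 1)):
                valid = order
                break
        assert valid is not None, "component is not a simple path"
        merges.append(valid[0] + "".join(s[-1] for s in valid[1:]))
    return merges


def homopolymer_filter_bruteforce(counts: dict[str, int], k: int) -> dict[str, int]:
    """Direct re-statement of the low-complexity rule as a comprehension."""
    m = k // 2
    return {
        s: c
        for s, c in counts.items()
        if not any(base * m in s for base in "ACGT")
    }


def ratio_filter_bruteforce(counts: dict[str, int], ratio: float) -> dict[str, int]:
    """Direct re-statement of the frequency-ratio rule, using true division."""
    if not counts:
        return {}
    f_top = max(counts.values())
    return {s: c for s, c in counts.items() if f_top / c <= ratio}
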