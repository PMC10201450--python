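"""Independent brute-force enumerators used as test oracles.

The bulged-motif oracle enumerates every 12-subset of a sequence's guanine
positions and checks the grammar and filters directly on the subset; it
shares no code with the scanner's stem-chaining algorithm.
"""

from itertools import combinations

INSERTION_ALPHABET = set("ACT")


def _classify(n_intact, n_bulges, n_bulged_stems):
    if n_intact == 3 and n_bulges == 1:
        return "G3B1"
    if n_intact == 3 and n_bulges == 2 and n_bulged_stems == 1:
        return "G3B2"
    if n_intact == 2 and n_bulges == 2 and n_bulged_stems == 2:
        return "G2B2"
    return None


def _layout_ok(seq, g, bulge_max, loop_min, loop_max):
    """Is this ordered 12-tuple of guanine positions an accepted match?"""
    n_bulges = 0
    n_bulged_stems = 0
    # stems: consecutive triples
    for k in range(4):
        p1, p2, p3 = g[3 * k], g[3 * k + 1], g[3 * k + 2]
        stem_bulges = 0
        for a, b in ((p1, p2), (p2, p3)):
            gap = seq[a + 1 : b]
            if len(gap) > bulge_max:
                return None
            if gap:
                if not set(gap) <= INSERTION_ALPHABET:
                    return None
                stem_bulges += 1
        if stem_bulges:
            n_bulged_stems += 1
            n_bulges += stem_bulges
        if n_bulges > 2:
            return None
    # loops: between stem k's last G and stem k+1's first G
    for k in range(3):
        loop = seq[g[3 * k + 2] + 1 : g[3 * k + 3]]
        if not loop_min <= len(loop) <= loop_max:
            return None
        if "N" in loop or loop.count("G") > 1:
            return None
    model = _classify(4 - n_bulged_stems, n_bulges, n_bulged_stems)
    if model is None:
        return None
    if "CC" in seq[g[0] : g[11] + 1]:
        return None
    return model


def bulged_layouts(seq, bulge_max=3, loop_min=1, loop_max=3):
    """Accepted matches as {12-tuple of G positions: model}."""
    g_pos = [i for i, c in enumerate(seq) if c == "G"]
    out = {}
    for combo in combinations(g_pos, 12):
        # cheap span prune: max span of an accepted match
        if combo[-1] - combo[0] + 1 > 4 * 9 + 3 * loop_max:
            continue
        model = _layout_ok(seq, combo, bulge_max, loop_min, loop_max)
        if model is not None:
            out[combo] = model
    return out


def canonical_spans(seq, min_stem=3, loop_min=1, loop_max=7):
    """Accepted canonical matches as a set of (start, end) spans."""
    runs = []
    i = 0
    while i < len(seq):
        if seq[i] == "G":
            j = i
            while j < len(seq) and seq[j] == "G":
                j += 1
            if j - i >= min_stem:
                runs.append((i, j))
            i = j
        else:
            i += 1
    out = set()
    for i in range(len(runs) - 3):
        w = runs[i : i + 4]
        if all(
            loop_min <= w[k + 1][0] - w[k][1] <= loop_max
            and "N" not in seq[w[k][1] : w[k + 1][0]]
            for k in range(3)
        ):
            out.add((w[0][0], w[3][1]))
    return out
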