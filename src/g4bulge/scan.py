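"""Motif scanners for canonical and bulged G-quadruplex-forming sequences.

Two sequence grammars are implemented:

* the canonical motif ``G3+ N1-7 G3+ N1-7 G3+ N1-7 G3+`` (four uninterrupted
  G-tracts of three or more guanines separated by loops of any base, 1-7 nt);
* the bulged motif ``G Ix G Ix G  Ny  (x4)`` in which each of the four stems
  contributes exactly three tetrad guanines that may be interrupted by up to
  two insertions ("bulges") of 1-3 non-G bases (I in {A, C, T}), with loops
  (N, any base) of 1-3 nt between stems.

Accepted bulged matches are restricted to three structural models with
experimental support for stable quadruplex formation — G3B1 (three intact
stems, one bulge), G3B2 (three intact stems, two bulges in the same stem)
and G2B2 (two intact stems, one bulge in each of two stems) — and must pass
additional stability filters: no loop may contain more than one guanine and
the match core must not contain contiguous cytosines (``CC``), which favour
duplex formation over quadruplex folding.

N never matches any motif position.
"""

from __future__ import annotations

import re
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .core import ACCEPTED_BS_MODELS, MODEL_PREFERENCE, revcomp

_G_RUN = re.compile(r"G+")
_INSERTION_ALPHABET = set("ACT")


@dataclass(frozen=True)
class StemMatch:
    """One G-stem of a match, in scanned-sequence coordinates.

    ``g_offsets`` are the positions of the tetrad guanines (exactly three for
    bulged-model stems, possibly more for canonical stems); ``insertions``
    records each non-empty bulge as ``(slot, sequence)`` where slot 0 lies
    between the first and second guanine and slot 1 between the second and
    third.
    """

    start: int
    end: int
    g_offsets: Tuple[int, ...]
    insertions: Tuple[Tuple[int, str], ...] = ()

    @property
    def intact(self) -> bool:
        return not self.insertions

    @property
    def n_insertions(self) -> int:
        return len(self.insertions)


@dataclass(frozen=True)
class MotifHit:
    """A scanned G4-like match.

    ``start``/``end`` are genomic (forward-strand) coordinates; for hits on
    the minus strand, ``stems``/``loops``/``core_seq`` describe the motif as
    read on its own strand (i.e. on the reverse complement).
    """

    chrom: str
    start: int
    end: int
    strand: str
    model: str
    stems: Tuple[StemMatch, ...]
    loops: Tuple[str, ...]
    core_seq: str

    @property
    def name(self) -> str:  # BED name column
        return self.model

    @property
    def score(self):
        return None

    @property
    def n_intact_stems(self) -> int:
        return sum(1 for s in self.stems if s.intact)

    @property
    def n_bulges(self) -> int:
        return sum(s.n_insertions for s in self.stems)

    @property
    def bulge_seqs(self) -> Tuple[str, ...]:
        return tuple(ins for s in self.stems for _, ins in s.insertions)

    def __len__(self) -> int:
        return self.end - self.start


def classify_model(hit: MotifHit) -> Optional[str]:
    """Model label implied by a match's intact-stem and bulge counts.

    Returns ``"CANONICAL"`` for four intact stems without insertions (such a
    match is never a bulged model), one of G3B1/G3B2/G2B2 for the accepted
    bulged layouts, and ``None`` for layouts outside the accepted models
    (e.g. three or more bulges, or fewer than two intact stems).
    """
    return _classify(
        hit.n_intact_stems,
        hit.n_bulges,
        sum(1 for s in hit.stems if not s.intact),
    )


def _classify(n_intact: int, n_bulges: int, n_bulged_stems: int) -> Optional[str]:
    if n_intact == 4 and n_bulges == 0:
        return "CANONICAL"
    if n_intact == 3 and n_bulges == 1:
        return "G3B1"
    if n_intact == 3 and n_bulges == 2 and n_bulged_stems == 1:
        return "G3B2"
    if n_intact == 2 and n_bulges == 2 and n_bulged_stems == 2:
        return "G2B2"
    return None


def apply_bs_filters(
    hit: MotifHit,
    bulge_max: int = 3,
    loop_min: int = 1,
    loop_max: int = 3,
) -> Tuple[bool, Optional[str]]:
    """Stability filters for a candidate bulged match.

    Returns ``(accepted, reason)`` with a machine-readable rejection reason:
    ``too_many_bulges`` (more than two insertions in total),
    ``too_few_intact_stems`` (fewer than two uninterrupted stems),
    ``loop_g_linker`` (a loop with more than a single guanine),
    ``contiguous_cytosines`` (``CC`` within the match core),
    ``bad_insertion_length`` / ``bad_loop_length`` (outside the allowed
    ranges), ``invalid_base`` (N in any motif position).
    """
    if hit.n_bulges > 2:
        return False, "too_many_bulges"
    if hit.n_intact_stems < 2:
        return False, "too_few_intact_stems"
    for stem in hit.stems:
        for _, ins in stem.insertions:
            if not 1 <= len(ins) <= bulge_max:
                return False, "bad_insertion_length"
            if not set(ins) <= _INSERTION_ALPHABET:
                return False, "invalid_base"
    for loop in hit.loops:
        if not loop_min <= len(loop) <= loop_max:
            return False, "bad_loop_length"
        if "N" in loop:
            return False, "invalid_base"
        if loop.count("G") > 1:
            return False, "loop_g_linker"
    if "CC" in hit.core_seq:
        return False, "contiguous_cytosines"
    return True, None


def hit_from_layout(
    sequence: str,
    g_positions: Sequence[int],
    chrom: str = "",
    strand: str = "+",
) -> MotifHit:
    """Build a bulged-model MotifHit from the positions of its 12 guanines.

    The twelve positions (sorted, within ``sequence``) are grouped in order
    into four stems of three guanines each; intervening bases within a stem
    are insertions, bases between stems are loops. No filter is applied here.
    """
    g = sorted(g_positions)
    if len(g) != 12:
        raise ValueError("a bulged-model layout has exactly 12 guanines")
    stems = []
    for k in range(4):
        p1, p2, p3 = g[3 * k : 3 * k + 3]
        ins = []
        if p2 > p1 + 1:
            ins.append((0, sequence[p1 + 1 : p2]))
        if p3 > p2 + 1:
            ins.append((1, sequence[p2 + 1 : p3]))
        stems.append(StemMatch(p1, p3 + 1, (p1, p2, p3), tuple(ins)))
    loops = tuple(
        sequence[stems[k].end : stems[k + 1].start] for k in range(3)
    )
    start, end = stems[0].start, stems[3].end
    hit = MotifHit(
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        model="",
        stems=tuple(stems),
        loops=loops,
        core_seq=sequence[start:end],
    )
    model = classify_model(hit)
    return MotifHit(
        chrom, start, end, strand, model or "REJECTED", hit.stems, loops,
        hit.core_seq,
    )


def _candidate_stems(
    sequence: str, bulge_max: int
) -> Dict[int, List[Tuple[int, int, int, int]]]:
    """All stems of exactly three guanines with 0-2 insertions.

    Returns a map from stem start position to ``(p1, p2, p3, n_insertions)``
    tuples; insertion slots hold 1-``bulge_max`` bases over {A, C, T}.
    """
    s = sequence
    n = len(s)
    by_start: Dict[int, List[Tuple[int, int, int, int]]] = defaultdict(list)
    # precompute, per position, whether s[i:j] is a legal insertion
    for p1 in range(n - 2):
        if s[p1] != "G":
            continue
        for gap1 in range(bulge_max + 1):
            p2 = p1 + 1 + gap1
            if p2 >= n or s[p2] != "G":
                continue
            if gap1 and not set(s[p1 + 1 : p2]) <= _INSERTION_ALPHABET:
                continue
            for gap2 in range(bulge_max + 1):
                p3 = p2 + 1 + gap2
                if p3 >= n or s[p3] != "G":
                    continue
                if gap2 and not set(s[p2 + 1 : p3]) <= _INSERTION_ALPHABET:
                    continue
                by_start[p1].append(
                    (p1, p2, p3, (gap1 > 0) + (gap2 > 0))
                )
    return by_start


def scan_bulged(
    sequence: str,
    bulge_max: int = 3,
    loop_min: int = 1,
    loop_max: int = 3,
    chrom: str = "",
    strand: str = "+",
) -> List[MotifHit]:
    """Enumerate all accepted bulged-model matches in a sequence.

    Every distinct placement (stem/bulge layout) is reported, so matches may
    share up to three of their four G-tracts; overlapping matches are later
    collapsed by region merging. Output is sorted by coordinates.
    """
    s = sequence.upper()
    stems_by_start = _candidate_stems(s, bulge_max)
    hits: List[MotifHit] = []

    def extend(chain: List[Tuple[int, int, int, int]], bulges: int) -> None:
        if len(chain) == 4:
            g = [p for st in chain for p in st[:3]]
            hit = hit_from_layout(s, g, chrom=chrom, strand=strand)
            if hit.model in ACCEPTED_BS_MODELS:
                ok, _ = apply_bs_filters(hit, bulge_max, loop_min, loop_max)
                if ok:
                    hits.append(hit)
            return
        last_end = chain[-1][2] + 1
        for loop_len in range(loop_min, loop_max + 1):
            nxt = last_end + loop_len
            loop = s[last_end:nxt]
            if "N" in loop or loop.count("G") > 1:
                continue
            for stem in stems_by_start.get(nxt, ()):
                nb = bulges + stem[3]
                if nb > 2:
                    continue
                chain.append(stem)
                extend(chain, nb)
                chain.pop()

    for start in sorted(stems_by_start):
        for stem in stems_by_start[start]:
            if stem[3] <= 2:
                extend([stem], stem[3])

    hits.sort(key=lambda h: (h.start, h.end, tuple(s.g_offsets for s in h.stems)))
    return hits


def scan_canonical(
    sequence: str,
    min_stem: int = 3,
    loop_min: int = 1,
    loop_max: int = 7,
    chrom: str = "",
    strand: str = "+",
) -> List[MotifHit]:
    """Enumerate canonical matches: four maximal G-runs of ``min_stem``+
    guanines separated by loops of 1-7 bases.

    All windows of four consecutive candidate runs are enumerated, so runs
    may be shared between matches (a region with five runs yields two
    matches). Loops containing N are rejected.
    """
    s = sequence.upper()
    runs = [
        (m.start(), m.end())
        for m in _G_RUN.finditer(s)
        if m.end() - m.start() >= min_stem
    ]
    hits: List[MotifHit] = []
    for i in range(len(runs) - 3):
        window = runs[i : i + 4]
        ok = True
        loops = []
        for (s0, e0), (s1, _) in zip(window, window[1:]):
            loop = s[e0:s1]
            if not loop_min <= len(loop) <= loop_max or "N" in loop:
                ok = False
                break
            loops.append(loop)
        if not ok:
            continue
        stems = tuple(
            StemMatch(a, b, tuple(range(a, b))) for a, b in window
        )
        start, end = window[0][0], window[3][1]
        hits.append(
            MotifHit(
                chrom, start, end, strand, "CANONICAL", stems, tuple(loops),
                s[start:end],
            )
        )
    return hits


def _mirror(hit: MotifHit, length: int) -> MotifHit:
    """Map a hit found on the reverse complement to forward coordinates."""
    return MotifHit(
        chrom=hit.chrom,
        start=length - hit.end,
        end=length - hit.start,
        strand="-",
        model=hit.model,
        stems=hit.stems,
        loops=hit.loops,
        core_seq=hit.core_seq,
    )


def scan_genome(genome: Dict[str, str], which: str = "BS", **kwargs) -> List[MotifHit]:
    """Scan every chromosome on both strands.

    ``which`` selects the bulged (``"BS"``) or canonical (``"CS"``) grammar.
    Minus-strand matches are found on the reverse complement and reported in
    forward genomic coordinates with strand ``-``. Output is sorted.
    """
    scanner = {"BS": scan_bulged, "CS": scan_canonical}[which.upper()]
    hits: List[MotifHit] = []
    for chrom, seq in genome.items():
        hits.extend(scanner(seq, chrom=chrom, strand="+", **kwargs))
        hits.extend(
            _mirror(h, len(seq))
            for h in scanner(revcomp(seq), chrom=chrom, strand="+", **kwargs)
        )
    hits.sort(key=lambda h: (h.chrom, h.start, h.end, h.strand))
    return hits


def best_hit(hits: Iterable[MotifHit]) -> Optional[MotifHit]:
    """The preferred match among alternatives: fewest bulges / most intact
    stems (G3B1 > G3B2 > G2B2), then longest span, then leftmost."""
    ranked = sorted(
        hits,
        key=lambda h: (
            MODEL_PREFERENCE.get(h.model, 99),
            -(h.end - h.start),
            h.start,
        ),
    )
    return ranked[0] if ranked else None


def hits_to_dataframe(hits: Sequence[MotifHit]):
    """Tabulate hits (chrom, start, end, strand, model, stem/bulge columns)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [h.chrom for h in hits],
            "start": [h.start for h in hits],
            "end": [h.end for h in hits],
            "strand": [h.strand for h in hits],
            "model": [h.model for h in hits],
            "n_intact_stems": [h.n_intact_stems for h in hits],
            "n_bulges": [h.n_bulges for h in hits],
            "bulge_seqs": [",".join(h.bulge_seqs) for h in hits],
            "loops": [",".join(h.loops) for h in hits],
            "core_seq": [h.core_seq for h in hits],
        }
    )
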