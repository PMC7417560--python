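"""Perfect-complementarity off-target scanning and seed-site counting.

"Complementary" means contiguous perfect Watson-Crick pairing with no gaps
and no G:U wobble, i.e. a hit is an exact common substring between the
target-sense sequence (reverse complement of the guide) and a transcript.
The production scanner uses a k-mer seed-and-extend; an O(n*m) dynamic
programming routine (:func:`longest_complementary_stretch`) is kept as an
independent oracle.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from circscreen.annotation_io import revcomp
from circscreen.junction_design import ShRNADesign

DEFAULT_MIN_MATCH = 12  # published putative off-target threshold, nt

_ACGT = frozenset("ACGT")


@dataclass(frozen=True)
class OffTargetHit:
    """A maximal perfect-complementarity stretch between a guide and a transcript.

    ``guide_offset`` is the 0-based start of the matched region on the
    target-sense sequence (revcomp of the guide); ``transcript_offset`` the
    0-based start on the transcript.
    """

    guide_id: str
    transcript_id: str
    gene_id: str
    match_length: int
    guide_offset: int
    transcript_offset: int


@dataclass(frozen=True)
class SeedSpec:
    """A 7-nt seed (strand positions 2-8) and the UTR site it recognizes."""

    source: str  # "guide" | "star"
    seed: str
    site: str

    def __post_init__(self) -> None:
        if self.site != revcomp(self.seed):
            raise ValueError("site must be the reverse complement of seed")


def scan_offtargets(
    guide: str,
    transcripts: Iterable[Tuple[str, str]],
    min_len: int = DEFAULT_MIN_MATCH,
    guide_id: str = "guide",
    gene_ids: Optional[Mapping[str, str]] = None,
) -> List[OffTargetHit]:
    """Report every maximal complementary stretch of >= ``min_len`` nt.

    Per transcript, all distinct maximal matches are reported, longest first.
    ``gene_ids`` optionally maps transcript_id -> gene_id (default: identity).
    """
    if not guide:
        raise ValueError("empty guide")
    if min_len > len(guide):
        raise ValueError(f"min_len {min_len} > guide length {len(guide)}")
    if min_len < 8:
        _warnings.warn(
            f"min_len {min_len} < 8 nt makes the scan expensive and noisy",
            stacklevel=2,
        )
    target = revcomp(guide)
    k = min_len
    seeds: Dict[str, List[int]] = {}
    for i in range(len(target) - k + 1):
        kmer = target[i : i + k]
        if set(kmer) <= _ACGT:
            seeds.setdefault(kmer, []).append(i)

    hits: List[OffTargetHit] = []
    for tx_id, seq in transcripts:
        found: set[Tuple[int, int, int]] = set()
        for j in range(len(seq) - k + 1):
            positions = seeds.get(seq[j : j + k])
            if not positions:
                continue
            for i in positions:
                li, lj = i, j
                while li > 0 and lj > 0 and target[li - 1] == seq[lj - 1] and (
                    target[li - 1] in _ACGT
                ):
                    li -= 1
                    lj -= 1
                ri, rj = i + k, j + k
                while (
                    ri < len(target)
                    and rj < len(seq)
                    and target[ri] == seq[rj]
                    and target[ri] in _ACGT
                ):
                    ri += 1
                    rj += 1
                found.add((li, lj, ri - li))
        gene = gene_ids.get(tx_id, tx_id) if gene_ids else tx_id
        for li, lj, length in sorted(found, key=lambda t: (-t[2], t[1], t[0])):
            hits.append(
                OffTargetHit(
                    guide_id=guide_id,
                    transcript_id=tx_id,
                    gene_id=gene,
                    match_length=length,
                    guide_offset=li,
                    transcript_offset=lj,
                )
            )
    return hits


def longest_complementary_stretch(guide: str, transcript: str) -> int:
    """Length of the longest contiguous perfect-complementarity stretch.

    Exact longest-common-substring dynamic programming between
    ``revcomp(guide)`` and the transcript; serves as the scan oracle.
    """
    if not guide or not transcript:
        raise ValueError("guide and transcript must be non-empty")
    target = revcomp(guide)
    t = np.frombuffer(transcript.encode("ascii"), dtype="S1")
    valid = np.isin(t, np.frombuffer(b"ACGT", dtype="S1"))
    best = 0
    prev = np.zeros(len(t), dtype=np.int64)
    cur = np.empty_like(prev)
    for ch in target:
        if ch not in _ACGT:
            prev[:] = 0
            continue
        match = (t == ch.encode("ascii")) & valid
        cur[0] = 1 if match[0] else 0
        np.multiply(prev[:-1] + 1, match[1:], out=cur[1:])
        best = max(best, int(cur.max()))
        prev, cur = cur, prev
    return best


def extract_seeds(d: ShRNADesign, seed_length: int = 7) -> List[SeedSpec]:
    """Guide and star (passenger) seeds: strand positions 2..(1 + seed_length)."""
    if len(d.guide) < 1 + seed_length:
        raise ValueError(
            f"guide too short ({len(d.guide)} nt) for a {seed_length}-nt seed"
        )
    guide_seed = d.guide[1 : 1 + seed_length]
    star_seed = d.passenger[1 : 1 + seed_length]
    return [
        SeedSpec(source="guide", seed=guide_seed, site=revcomp(guide_seed)),
        SeedSpec(source="star", seed=star_seed, site=revcomp(star_seed)),
    ]


def count_overlapping(haystack: str, needle: str) -> int:
    """Sliding-window occurrence count (overlaps included)."""
    if not needle:
        raise ValueError("empty needle")
    n, i = 0, haystack.find(needle)
    while i != -1:
        n += 1
        i = haystack.find(needle, i + 1)
    return n


def count_seed_matches(
    specs: Sequence[SeedSpec], utrs: Mapping[str, str]
) -> Dict[SeedSpec, Dict[str, int]]:
    """Per seed spec and gene, the number of site occurrences in the 3' UTR."""
    return {
        spec: {gene: count_overlapping(utr, spec.site) for gene, utr in utrs.items()}
        for spec in specs
    }
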