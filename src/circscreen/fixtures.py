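"""Deterministic synthetic-data generators for every pipeline stage.

Each generator is a pure function of a :class:`FixtureSpec`: the same spec
(and hence the same ``rng_seed``) always produces byte-identical output.
All randomness flows through per-generator ``numpy.random.default_rng``
streams derived from the single spec seed; no global RNG state is touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from circscreen.annotation_io import (
    CircRNAModel,
    GenomeSequence,
    TranscriptModel,
    revcomp,
)
from circscreen.offtarget_scan import DEFAULT_MIN_MATCH, longest_complementary_stretch

_ALPHABET = np.array(list("ACGT"))
_RETRY_BUDGET = 500

# independent complement table so recorded truths do not share code with the
# production reverse-complement path
_TRUTH_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _truth_revcomp(seq: str) -> str:
    return "".join(_TRUTH_COMPLEMENT[ch] for ch in reversed(seq))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(_ALPHABET[rng.integers(0, 4, size=n)])


@dataclass(frozen=True)
class CircLayout:
    """Shape of the synthetic circRNA locus."""

    exon_lengths: Tuple[int, ...] = (200,)
    strand: str = "+"
    intron_length: int = 60
    flank: int = 300

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if not self.exon_lengths or any(l <= 0 for l in self.exon_lengths):
            raise ValueError("exon_lengths must be positive")
        if self.flank < 150:
            raise ValueError("flank must be >= 150 to fit the host transcript")


@dataclass(frozen=True)
class PlantedOffTarget:
    """A transcript that shares a complementary stretch with the guide.

    ``log2fc``/``padj`` are the exact values the DE-table generator plants
    for this gene; ``padj=None`` yields an NA entry (not testable).
    """

    match_length: int
    log2fc: float = 0.0
    padj: Optional[float] = 1.0


@dataclass(frozen=True)
class SeedPlant:
    """Seed-site planting rates for ranked-enrichment fixtures."""

    top_n: int
    rate_top: float
    rate_background: float

    def __post_init__(self) -> None:
        for rate in (self.rate_top, self.rate_background):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("planting rates must lie in [0, 1]")


@dataclass(frozen=True)
class FixtureSpec:
    rng_seed: int = 0
    n_genes: int = 100
    utr_length: Tuple[int, int] = (100, 300)
    tx_length: int = 500
    planted_offtargets: Tuple[PlantedOffTarget, ...] = ()
    planted_seed_enrichment: Optional[SeedPlant] = None
    circ_layout: CircLayout = field(default_factory=CircLayout)

    def __post_init__(self) -> None:
        if self.utr_length[0] > self.utr_length[1] or self.utr_length[0] <= 0:
            raise ValueError("utr_length bounds must be positive and ordered")
        # normalize tuples passed as (match_length, log2fc[, padj])
        planted = tuple(
            p if isinstance(p, PlantedOffTarget) else PlantedOffTarget(*p)
            for p in self.planted_offtargets
        )
        object.__setattr__(self, "planted_offtargets", planted)


@dataclass(frozen=True)
class SynthLocus:
    genome: GenomeSequence
    transcripts: Tuple[TranscriptModel, ...]
    circs: Tuple[CircRNAModel, ...]
    truth: Dict[str, str]  # circ_id -> mature circle sequence, ground truth


def synth_locus(spec: FixtureSpec) -> SynthLocus:
    """A toy chromosome carrying one circRNA locus and its host transcript.

    The recorded truth is the mature circle sequence (5'->3' from the
    back-splice acceptor), assembled independently of the production
    splicing code.
    """
    layout = spec.circ_layout
    rng = np.random.default_rng([spec.rng_seed, 0])
    n_exons = len(layout.exon_lengths)
    total = (
        2 * layout.flank
        + sum(layout.exon_lengths)
        + layout.intron_length * (n_exons - 1)
    )
    chrom_seq = _random_dna(rng, total)
    chrom = "chrS"

    exons = []
    pos = layout.flank
    for length in layout.exon_lengths:
        exons.append((pos, pos + length))
        pos += length + layout.intron_length
    circ = CircRNAModel(
        circ_id="circS",
        chrom=chrom,
        strand=layout.strand,
        start=exons[0][0],
        end=exons[-1][1],
        exons=tuple(exons),
    )

    host_exons = [list(iv) for iv in exons]
    host_exons[0][0] -= 100
    host_exons[-1][1] += 100
    if layout.strand == "+":
        cds_end = host_exons[-1][1] - 80
    else:
        cds_end = host_exons[0][0] + 80
    host = TranscriptModel(
        transcript_id="tx_host",
        gene_id="g_host",
        chrom=chrom,
        strand=layout.strand,
        exons=tuple(tuple(iv) for iv in host_exons),
        cds_end=cds_end,
    )

    plus = "".join(chrom_seq[s:e] for s, e in exons)
    circle_seq = plus if layout.strand == "+" else _truth_revcomp(plus)

    return SynthLocus(
        genome=GenomeSequence({chrom: chrom_seq}),
        transcripts=(host,),
        circs=(circ,),
        truth={"circS": circle_seq},
    )


def synth_transcriptome(
    spec: FixtureSpec, guide: str
) -> Tuple[List[Tuple[str, str]], List[dict]]:
    """Transcripts with planted complementary stretches plus clean background.

    Returns ``(records, truth)`` where truth lists, per planted transcript,
    the exact stretch length, its position, and the DE effect to plant.
    Backgrounds (and planted flanks) are rejection-sampled until the DP
    oracle confirms the longest stretch is exactly the intended one
    (< 12 nt for backgrounds).
    """
    rng = np.random.default_rng([spec.rng_seed, 1])
    target = revcomp(guide)
    records: List[Tuple[str, str]] = []
    truth: List[dict] = []

    for i, planted in enumerate(spec.planted_offtargets):
        length = planted.match_length
        if length > len(guide):
            raise ValueError(
                f"planted match_length {length} exceeds guide length {len(guide)}"
            )
        tx_id = f"ot{i}_len{length}"
        for _ in range(_RETRY_BUDGET):
            bg = _random_dna(rng, spec.tx_length)
            pos = int(rng.integers(0, spec.tx_length - length + 1))
            start = int(rng.integers(0, len(target) - length + 1))
            seq = bg[:pos] + target[start : start + length] + bg[pos + length :]
            if longest_complementary_stretch(guide, seq) == length:
                break
        else:
            raise RuntimeError(
                f"retry budget exceeded planting a {length}-nt stretch"
            )
        records.append((tx_id, seq))
        truth.append(
            {
                "transcript_id": tx_id,
                "gene_id": tx_id,
                "match_length": length,
                "transcript_offset": pos,
                "log2fc": planted.log2fc,
                "padj": planted.padj,
            }
        )

    n_background = max(0, spec.n_genes - len(spec.planted_offtargets))
    for j in range(n_background):
        for _ in range(_RETRY_BUDGET):
            seq = _random_dna(rng, spec.tx_length)
            if longest_complementary_stretch(guide, seq) < DEFAULT_MIN_MATCH:
                break
        else:
            raise RuntimeError("retry budget exceeded sampling clean background")
        records.append((f"bg{j}", seq))
    return records, truth


def synth_de_table(spec: FixtureSpec) -> pd.DataFrame:
    """DE table with exact planted effects and null background genes.

    Null genes draw log2fc ~ Normal(0, 0.2) and p ~ Uniform(0, 1) (padj set
    equal to p); planted off-target genes carry their specified values
    verbatim, with ``padj=None`` emitted as NA.
    """
    rng = np.random.default_rng([spec.rng_seed, 2])
    rows = []
    for i, planted in enumerate(spec.planted_offtargets):
        rows.append(
            {
                "gene_id": f"ot{i}_len{planted.match_length}",
                "log2fc": planted.log2fc,
                "pvalue": planted.padj,
                "padj": planted.padj,
            }
        )
    n_background = max(0, spec.n_genes - len(spec.planted_offtargets))
    for j in range(n_background):
        p = float(rng.uniform())
        rows.append(
            {
                "gene_id": f"bg{j}",
                "log2fc": float(rng.normal(0.0, 0.2)),
                "pvalue": p,
                "padj": p,
            }
        )
    df = pd.DataFrame(rows, columns=["gene_id", "log2fc", "pvalue", "padj"])
    df["pvalue"] = pd.to_numeric(df["pvalue"])
    df["padj"] = pd.to_numeric(df["padj"])
    return df


def synth_ranked_enrichment(
    spec: FixtureSpec, seed_site: str
) -> Tuple["RankedGeneList", Dict[str, str]]:
    """A ranked gene list plus UTRs with the site planted at two rates.

    The site is planted with probability ``rate_top`` in the ``top_n``
    most-downregulated genes and ``rate_background`` elsewhere; log2
    fold changes span [-4, 4] so about half the list is downregulated.
    """
    from circscreen.seed_enrichment import RankedGeneList

    plant = spec.planted_seed_enrichment
    if plant is None:
        raise ValueError("spec.planted_seed_enrichment is required")
    if plant.top_n > spec.n_genes:
        raise ValueError("top_n exceeds n_genes")
    if len(seed_site) > spec.utr_length[0]:
        raise ValueError("seed site longer than the shortest UTR")

    rng = np.random.default_rng([spec.rng_seed, 3])
    n = spec.n_genes
    genes = [f"g{i:05d}" for i in range(n)]
    log2fc = np.linspace(-4.0, 4.0, n)
    utrs: Dict[str, str] = {}
    for i, gene in enumerate(genes):
        length = int(rng.integers(spec.utr_length[0], spec.utr_length[1] + 1))
        utr = _random_dna(rng, length)
        rate = plant.rate_top if i < plant.top_n else plant.rate_background
        if rng.uniform() < rate:
            pos = int(rng.integers(0, length - len(seed_site) + 1))
            utr = utr[:pos] + seed_site + utr[pos + len(seed_site) :]
        utrs[gene] = utr
    ranked = RankedGeneList(
        genes=tuple(genes), n_down=int((log2fc < 0).sum()), n_dropped=0
    )
    return ranked, utrs
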