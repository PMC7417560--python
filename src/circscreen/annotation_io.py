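"""Input readers and strand-aware sequence extraction.

Coordinate conventions
----------------------
BED inputs are 0-based half-open; GTF inputs are 1-based closed.  Both are
converted on the way in, and **all internal arithmetic is 0-based half-open**.
RNA-world sequences are stored as DNA (U is converted to T on input) in the
uppercase alphabet ``ACGTN``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd

PathLike = Union[str, Path]

_ALPHABET = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DE_COLUMNS = ("gene_id", "log2fc", "pvalue", "padj")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string over ``ACGTN``."""
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation inputs."""


# ---------------------------------------------------------------------------
# Genome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeSequence:
    """Mapping chromosome name -> uppercase DNA string (alphabet ACGTN)."""

    sequences: Mapping[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise AnnotationError(f"empty sequence for chromosome {name!r}")
            bad = set(seq) - _ALPHABET
            if bad:
                raise AnnotationError(
                    f"chromosome {name!r} contains characters outside ACGTN: "
                    f"{sorted(bad)}"
                )

    def __getitem__(self, chrom: str) -> str:
        try:
            return self.sequences[chrom]
        except KeyError:
            raise AnnotationError(f"chromosome {chrom!r} absent from genome") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def __len__(self) -> int:
        return len(self.sequences)

    @property
    def chroms(self) -> Tuple[str, ...]:
        return tuple(self.sequences)


def read_genome(path: PathLike) -> GenomeSequence:
    """Read a FASTA genome, uppercasing and converting U to T.

    A strict parser is used so errors carry the offending line number;
    duplicate headers and characters outside ``ACGUTN`` are rejected.
    """
    sequences: Dict[str, List[str]] = {}
    current: Optional[str] = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0] if line[1:].strip() else ""
                if not name:
                    raise AnnotationError(f"{path}:{lineno}: empty FASTA header")
                if name in sequences:
                    raise AnnotationError(
                        f"{path}:{lineno}: duplicate FASTA header {name!r}"
                    )
                sequences[name] = []
                current = name
            else:
                if current is None:
                    raise AnnotationError(
                        f"{path}:{lineno}: sequence data before first FASTA header"
                    )
                chunk = line.upper().replace("U", "T")
                bad = set(chunk) - _ALPHABET
                if bad:
                    raise AnnotationError(
                        f"{path}:{lineno}: invalid sequence characters {sorted(bad)}"
                    )
                sequences[current].append(chunk)
    if not sequences:
        raise AnnotationError(f"{path}: no FASTA records found")
    return GenomeSequence({name: "".join(parts) for name, parts in sequences.items()})


def read_fasta_sequences(path: PathLike) -> Dict[str, str]:
    """Read any FASTA (transcriptome, UTRs) with the same normalization rules."""
    return dict(read_genome(path).sequences)


def write_fasta(records: Mapping[str, str], path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Transcripts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptModel:
    """A spliced transcript on the genome.

    ``exons`` are 0-based half-open genomic intervals sorted by start.
    ``cds_end`` is the genomic boundary delimiting the 3' UTR: for plus-strand
    transcripts the half-open end of the stop codon (UTR bases have genomic
    position >= cds_end); for minus-strand the 0-based start of the stop codon
    (UTR bases have genomic position < cds_end).  ``None`` means no annotated
    CDS; such transcripts contribute their full sequence to UTR scans and are
    flagged by :func:`three_prime_utr_sequence`.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: Tuple[Tuple[int, int], ...]
    cds_end: Optional[int] = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"{self.transcript_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not self.exons:
            raise AnnotationError(f"{self.transcript_id}: empty exon list")
        prev_end = None
        for start, end in self.exons:
            if end <= start:
                raise AnnotationError(
                    f"{self.transcript_id}: degenerate exon [{start}, {end})"
                )
            if prev_end is not None and start < prev_end:
                raise AnnotationError(
                    f"{self.transcript_id}: exons overlap or are unsorted"
                )
            prev_end = end

    @property
    def span(self) -> Tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def spliced_length(self) -> int:
        return sum(end - start for start, end in self.exons)


def spliced_sequence(t: TranscriptModel, g: GenomeSequence) -> str:
    """Spliced transcript sequence, 5'->3' in transcript orientation."""
    chrom_seq = g[t.chrom]
    if t.span[1] > len(chrom_seq):
        raise AnnotationError(
            f"{t.transcript_id}: exons exceed chromosome {t.chrom} "
            f"(length {len(chrom_seq)})"
        )
    plus = "".join(chrom_seq[start:end] for start, end in t.exons)
    return plus if t.strand == "+" else revcomp(plus)


def three_prime_utr_sequence(
    t: TranscriptModel, g: GenomeSequence
) -> Tuple[str, bool]:
    """3' UTR of a transcript as ``(sequence, flagged)``.

    When the transcript has no CDS boundary the full spliced sequence is
    returned with ``flagged=True`` so callers can log the approximation.
    """
    seq = spliced_sequence(t, g)
    if t.cds_end is None:
        return seq, True
    if t.strand == "+":
        utr_len = sum(
            max(0, end - max(start, t.cds_end)) for start, end in t.exons
        )
    else:
        utr_len = sum(
            max(0, min(end, t.cds_end) - start) for start, end in t.exons
        )
    return (seq[len(seq) - utr_len :] if utr_len else ""), False


def read_transcripts(path: PathLike) -> List[TranscriptModel]:
    """Read transcript models from a GTF2.2 / GFF3 file via :mod:`gffutils`.

    The 3' UTR boundary is taken, in order of preference, from explicit
    ``three_prime_utr`` features, ``stop_codon`` features, or the CDS end.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    exons: Dict[str, List[Tuple[int, int]]] = {}
    meta: Dict[str, Tuple[str, str, str]] = {}  # tx -> (gene, chrom, strand)
    cds: Dict[str, List[Tuple[int, int]]] = {}
    stops: Dict[str, List[Tuple[int, int]]] = {}
    utr3: Dict[str, List[Tuple[int, int]]] = {}

    buckets = {
        "exon": exons,
        "CDS": cds,
        "stop_codon": stops,
        "three_prime_utr": utr3,
        "three_prime_UTR": utr3,
    }
    for ftype, bucket in buckets.items():
        for feat in db.features_of_type(ftype):
            tx_ids = feat.attributes.get("transcript_id") or feat.attributes.get(
                "Parent"
            )
            if not tx_ids:
                raise AnnotationError(
                    f"{path}: {ftype} feature without transcript_id/Parent"
                )
            gene = (feat.attributes.get("gene_id") or tx_ids)[0]
            for tx in tx_ids:
                bucket.setdefault(tx, []).append((feat.start - 1, feat.end))
                meta.setdefault(tx, (gene, feat.seqid, feat.strand))

    models = []
    for tx, ivals in exons.items():
        gene, chrom, strand = meta[tx]
        cds_end: Optional[int] = None
        if tx in utr3:
            if strand == "+":
                cds_end = min(s for s, _ in utr3[tx])
            else:
                cds_end = max(e for _, e in utr3[tx])
        elif tx in stops:
            cds_end = (
                max(e for _, e in stops[tx])
                if strand == "+"
                else min(s for s, _ in stops[tx])
            )
        elif tx in cds:
            cds_end = (
                max(e for _, e in cds[tx])
                if strand == "+"
                else min(s for s, _ in cds[tx])
            )
        models.append(
            TranscriptModel(
                transcript_id=tx,
                gene_id=gene,
                chrom=chrom,
                strand=strand,
                exons=tuple(sorted(ivals)),
                cds_end=cds_end,
            )
        )
    models.sort(key=lambda m: m.transcript_id)
    return models


def write_transcripts_gtf(models: Sequence[TranscriptModel], path: PathLike) -> None:
    """Write transcript exon (and derived stop_codon boundary) features as GTF."""
    with open(path, "w") as fh:
        for t in models:
            attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
            for start, end in t.exons:
                fh.write(
                    f"{t.chrom}\tcircscreen\texon\t{start + 1}\t{end}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )
            if t.cds_end is not None:
                # re-encode the UTR boundary as a 1-nt stop_codon anchor
                if t.strand == "+":
                    s, e = t.cds_end - 1, t.cds_end
                else:
                    s, e = t.cds_end, t.cds_end + 1
                fh.write(
                    f"{t.chrom}\tcircscreen\tstop_codon\t{s + 1}\t{e}\t.\t"
                    f"{t.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# circRNAs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CircRNAModel:
    """Genomic definition of a circRNA.

    ``start``/``end`` delimit the back-splice span (0-based half-open, as in
    BED): ``start`` is the back-splice acceptor, ``end`` the donor boundary.
    ``exons`` are sub-intervals of the span in genomic order; by default the
    whole span is a single exon.
    """

    circ_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: Tuple[Tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"{self.circ_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.end <= self.start:
            raise AnnotationError(
                f"{self.circ_id}: degenerate span [{self.start}, {self.end})"
            )
        if not self.exons:
            object.__setattr__(self, "exons", ((self.start, self.end),))
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise AnnotationError(f"{self.circ_id}: degenerate exon [{s}, {e})")
            if s < self.start or e > self.end:
                raise AnnotationError(
                    f"{self.circ_id}: exon [{s}, {e}) outside span "
                    f"[{self.start}, {self.end})"
                )
            if prev_end is not None and s < prev_end:
                raise AnnotationError(f"{self.circ_id}: exons overlap or are unsorted")
            prev_end = e
        if self.exons[0][0] != self.start or self.exons[-1][1] != self.end:
            raise AnnotationError(
                f"{self.circ_id}: first exon must start at span start and "
                "last exon end at span end"
            )

    @property
    def mature_length(self) -> int:
        return sum(e - s for s, e in self.exons)


def circular_sequence(c: CircRNAModel, g: GenomeSequence) -> str:
    """Mature circle sequence read 5'->3' from the back-splice acceptor.

    Position 0 of the returned string is the first base after the junction
    (the acceptor-side base); the last position is the donor-side base.
    """
    t = TranscriptModel(
        transcript_id=c.circ_id,
        gene_id=c.circ_id,
        chrom=c.chrom,
        strand=c.strand,
        exons=c.exons,
    )
    return spliced_sequence(t, g)


def read_circrnas(source: PathLike) -> List[CircRNAModel]:
    """Read circRNA definitions from BED6 (one exon) or BED12 (blocked)."""
    circs = []
    with open(source) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise AnnotationError(
                    f"{source}:{lineno}: need at least BED6 (got {len(fields)} fields)"
                )
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            start, end = int(start_s), int(end_s)
            if strand not in ("+", "-"):
                raise AnnotationError(
                    f"{source}:{lineno}: missing or invalid strand {strand!r}"
                )
            if end <= start:
                raise AnnotationError(
                    f"{source}:{lineno}: end {end} <= start {start}"
                )
            exons: Tuple[Tuple[int, int], ...] = ()
            if len(fields) >= 12:
                n_blocks = int(fields[9])
                sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                starts = [int(x) for x in fields[11].rstrip(",").split(",")]
                if len(sizes) != n_blocks or len(starts) != n_blocks:
                    raise AnnotationError(
                        f"{source}:{lineno}: blockCount does not match block lists"
                    )
                exons = tuple(
                    (start + off, start + off + size)
                    for off, size in zip(starts, sizes)
                )
            circs.append(
                CircRNAModel(
                    circ_id=name,
                    chrom=chrom,
                    strand=strand,
                    start=start,
                    end=end,
                    exons=exons,
                )
            )
    return circs


def write_circrnas(circs: Sequence[CircRNAModel], path: PathLike) -> None:
    """Write circRNA models as BED12 (round-trips through read_circrnas)."""
    with open(path, "w") as fh:
        for c in circs:
            sizes = ",".join(str(e - s) for s, e in c.exons)
            starts = ",".join(str(s - c.start) for s, e in c.exons)
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{c.circ_id}\t0\t{c.strand}\t"
                f"{c.start}\t{c.end}\t0\t{len(c.exons)}\t{sizes}\t{starts}\n"
            )


# ---------------------------------------------------------------------------
# Differential-expression tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DERecord:
    """One row of a differential-expression result table."""

    gene_id: str
    log2fc: float
    pvalue: Optional[float] = None
    padj: Optional[float] = None


def read_de_table(source: Union[PathLike, io.TextIOBase]) -> pd.DataFrame:
    """Read a DE TSV with header ``gene_id, log2fc, pvalue, padj``.

    "NA" (or empty) marks missing p values.  Returns a DataFrame with exactly
    those columns; gene_ids must be unique and p values must lie in [0, 1].
    """
    df = pd.read_csv(
        source,
        sep="\t",
        dtype={"gene_id": str},
        na_values=["NA", "nan", "NaN", ""],
    )
    missing = set(DE_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(f"DE table missing columns: {sorted(missing)}")
    df = df.loc[:, list(DE_COLUMNS)].copy()
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise AnnotationError(f"duplicate gene_ids in DE table: {dups[:5]}")
    for col in ("log2fc", "pvalue", "padj"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    for col in ("pvalue", "padj"):
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise AnnotationError(f"{col} outside [0, 1] in DE table")
    return df
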