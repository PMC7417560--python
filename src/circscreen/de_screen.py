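"""Differential-expression filtering, cross-strain exclusion and off-target verdicts.

Two separate threshold sets are used deliberately: transcriptome
characterization keeps genes with linear fold change > 1.5 (in magnitude)
and raw p < 0.05, while putative off-target calls use |log2fc| > 1 and
adjusted p < 0.05.  Genes whose adjusted p is missing (DE tool outliers /
low expression) are surfaced as ``not_testable`` rather than dropped.
All inequalities are strict, as published.
"""

from __future__ import annotations

import math
import warnings as _warnings
from collections import Counter
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set

import pandas as pd

from circscreen.junction_design import ShRNADesign
from circscreen.offtarget_scan import OffTargetHit
from circscreen.seed_enrichment import SeedVerdict

STATUSES = ("unchanged", "changed", "not_testable", "not_detected")


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for significance filtering and off-target calls."""

    fc_threshold: float = 1.5  # linear fold change, transcriptome filter
    p_threshold: float = 0.05  # raw p, transcriptome filter
    ot_log2fc_threshold: float = 1.0  # |log2fc|, off-target calls
    ot_padj_threshold: float = 0.05  # adjusted p, off-target calls

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0 or self.ot_log2fc_threshold <= 0:
            raise ValueError("fold-change thresholds must be positive")
        if not (0 < self.p_threshold <= 1) or not (0 < self.ot_padj_threshold <= 1):
            raise ValueError("p thresholds must lie in (0, 1]")


@dataclass(frozen=True)
class OffTargetVerdict:
    """DE-based call for one putative off-target gene."""

    gene_id: str
    status: str  # unchanged | changed | not_testable | not_detected
    log2fc: Optional[float]
    padj: Optional[float]
    evidence: str  # provenance of the hit, e.g. "complementarity:15"

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


def significant_genes(
    table: pd.DataFrame, fp: FilterParams = FilterParams()
) -> pd.DataFrame:
    """Genes with |log2fc| > log2(fc_threshold) and raw p < p_threshold.

    Magnitude interpretation: up- or downregulated genes both qualify.
    Rows with missing p cannot pass the threshold and are dropped.
    """
    log2_cut = math.log2(fp.fc_threshold)
    log2fc = pd.to_numeric(table["log2fc"], errors="coerce")
    pvalue = pd.to_numeric(table["pvalue"], errors="coerce")
    keep = (log2fc.abs() > log2_cut) & (pvalue < fp.p_threshold)
    return table.loc[keep.fillna(False)]


def exclude_ubiquitous(
    per_strain_significant: Mapping[str, Set[str]],
) -> Dict[str, Set[str]]:
    """Remove genes significant in *every* strain from all strains' sets."""
    strains = list(per_strain_significant)
    if len(strains) < 2:
        _warnings.warn(
            "exclude_ubiquitous needs >= 2 strains; returning sets unchanged",
            stacklevel=2,
        )
        return {s: set(g) for s, g in per_strain_significant.items()}
    ubiquitous = set.intersection(
        *(set(per_strain_significant[s]) for s in strains)
    )
    return {s: set(per_strain_significant[s]) - ubiquitous for s in strains}


def offtarget_verdicts(
    hits: Sequence[OffTargetHit],
    table: pd.DataFrame,
    fp: FilterParams = FilterParams(),
) -> List[OffTargetVerdict]:
    """One verdict per unique gene among the hits.

    changed       |log2fc| > ot_log2fc_threshold and padj < ot_padj_threshold
    not_testable  padj missing (outlier / too lowly expressed)
    not_detected  gene absent from the DE table
    unchanged     everything else
    """
    by_gene = table.set_index("gene_id") if len(table) else table
    best_hit: Dict[str, int] = {}
    order: List[str] = []
    for hit in hits:
        if hit.gene_id not in best_hit:
            order.append(hit.gene_id)
            best_hit[hit.gene_id] = hit.match_length
        else:
            best_hit[hit.gene_id] = max(best_hit[hit.gene_id], hit.match_length)

    verdicts = []
    for gene in order:
        evidence = f"complementarity:{best_hit[gene]}"
        if len(table) == 0 or gene not in by_gene.index:
            verdicts.append(
                OffTargetVerdict(gene, "not_detected", None, None, evidence)
            )
            continue
        row = by_gene.loc[gene]
        log2fc = float(row["log2fc"])
        padj = row["padj"]
        if pd.isna(padj):
            verdicts.append(
                OffTargetVerdict(gene, "not_testable", log2fc, None, evidence)
            )
            continue
        padj = float(padj)
        if abs(log2fc) > fp.ot_log2fc_threshold and padj < fp.ot_padj_threshold:
            status = "changed"
        else:
            status = "unchanged"
        verdicts.append(OffTargetVerdict(gene, status, log2fc, padj, evidence))
    return verdicts


def verdict_summary(verdicts: Iterable[OffTargetVerdict]) -> Dict[str, int]:
    counts = Counter(v.status for v in verdicts)
    return {status: counts.get(status, 0) for status in STATUSES}


def knockdown_report(
    designs: Sequence[ShRNADesign],
    hits: Sequence[OffTargetHit],
    verdicts_by_guide: Mapping[str, Sequence[OffTargetVerdict]],
    seed_verdicts_by_guide: Optional[Mapping[str, Mapping[str, SeedVerdict]]] = None,
) -> Dict[str, dict]:
    """Per-design specificity evidence bundle (JSON-serializable).

    A design is flagged ``no detectable off-targets`` when no verdict is
    ``changed`` and no seed is enriched; otherwise
    ``candidate off-target effect``.
    """
    known = {d.design_id for d in designs}
    for hit in hits:
        if hit.guide_id not in known:
            raise ValueError(f"hit references unknown design {hit.guide_id!r}")
    for gid in verdicts_by_guide:
        if gid not in known:
            raise ValueError(f"verdicts reference unknown design {gid!r}")
    if seed_verdicts_by_guide:
        for gid in seed_verdicts_by_guide:
            if gid not in known:
                raise ValueError(f"seed verdicts reference unknown design {gid!r}")

    report: Dict[str, dict] = {}
    for d in designs:
        verdicts = list(verdicts_by_guide.get(d.design_id, ()))
        counts = verdict_summary(verdicts)
        seeds = {}
        any_enriched = False
        if seed_verdicts_by_guide and d.design_id in seed_verdicts_by_guide:
            for word, sv in seed_verdicts_by_guide[d.design_id].items():
                seeds[word] = {
                    "enriched": sv.enriched,
                    "corrected_min_p": sv.corrected_min_p,
                    "best_bin": sv.best_bin,
                }
                any_enriched = any_enriched or sv.enriched
        clean = counts["changed"] == 0 and not any_enriched
        report[d.design_id] = {
            "circ_id": d.circ_id,
            "guide": d.guide,
            "warnings": list(d.warnings),
            "offtarget_counts": counts,
            "offtargets": [
                {
                    "gene_id": v.gene_id,
                    "status": v.status,
                    "log2fc": v.log2fc,
                    "padj": v.padj,
                    "evidence": v.evidence,
                }
                for v in verdicts
            ],
            "seed_enrichment": seeds,
            "flag": (
                "no detectable off-targets" if clean else "candidate off-target effect"
            ),
        }
    return report


def render_report(report: Mapping[str, dict]) -> str:
    """Human-readable rendering of :func:`knockdown_report` output."""
    lines = []
    for design_id, entry in report.items():
        lines.append(f"design {design_id} ({entry['circ_id']}): {entry['flag']}")
        lines.append(f"  guide: {entry['guide']}")
        if entry["warnings"]:
            lines.append(f"  warnings: {', '.join(entry['warnings'])}")
        counts = entry["offtarget_counts"]
        lines.append(
            "  off-targets: "
            + ", ".join(f"{status}={counts[status]}" for status in STATUSES)
        )
        for word, sv in entry["seed_enrichment"].items():
            state = "ENRICHED" if sv["enriched"] else "not enriched"
            lines.append(
                f"  seed {word}: {state} (corrected p = {sv['corrected_min_p']:.3g})"
            )
    return "\n".join(lines)
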