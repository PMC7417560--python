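"""Back-splice junction context and junction-spanning shRNA guide design.

The mature circle is read 5'->3'; the back-splice junction is the joint
between its last and first base.  A junction context of width ``w`` is the
string ``circle[-w:] + circle[:w]``, so the junction lies between indices
``w - 1`` and ``w``.  Guides are the exact reverse complement of a
``guide_length`` window of that context with at least ``min_overhang``
bases on each side of the junction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Tuple

from circscreen.annotation_io import CircRNAModel, GenomeSequence, circular_sequence, revcomp


class DesignError(ValueError):
    """Raised when design parameters are infeasible for a junction."""


@dataclass(frozen=True)
class DesignParams:
    """Parameters for junction-spanning guide design.

    ``shift`` moves the target window toward the target's 3' end when
    positive (the published alternate design uses +3).
    """

    guide_length: int = 21
    min_overhang: int = 5
    context_width: int = 30
    shift: int = 3

    def __post_init__(self) -> None:
        if self.guide_length < 2 * self.min_overhang:
            raise DesignError(
                f"guide_length {self.guide_length} < 2 x min_overhang "
                f"{self.min_overhang}"
            )
        if self.context_width < self.guide_length:
            raise DesignError(
                f"context_width {self.context_width} < guide_length "
                f"{self.guide_length}"
            )


@dataclass(frozen=True)
class JunctionContext:
    """Sequence context across a back-splice junction.

    ``sequence`` has length ``2 * context_width``; the junction lies between
    ``junction_index - 1`` and ``junction_index``.
    """

    circ_id: str
    sequence: str
    junction_index: int

    def __post_init__(self) -> None:
        if len(self.sequence) != 2 * self.junction_index:
            raise DesignError(
                f"{self.circ_id}: junction_index must be half the context length"
            )


@dataclass(frozen=True)
class ShRNADesign:
    """A junction-spanning guide and its provenance.

    ``window_start`` indexes the target window within the junction context;
    ``guide`` is the exact reverse complement of that window, ``passenger``
    the reverse complement of the guide (modeled as a blunt duplex).
    ``side_5p``/``side_3p`` count window bases upstream/downstream of the
    junction on the target.
    """

    circ_id: str
    design_id: str
    window_start: int
    target_window: str
    guide: str
    passenger: str
    side_5p: int
    side_3p: int
    warnings: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.side_5p + self.side_3p != len(self.guide):
            raise DesignError(f"{self.design_id}: side lengths do not sum to length")
        if revcomp(self.guide) != self.target_window:
            raise DesignError(f"{self.design_id}: guide is not revcomp of window")


def build_junction_context(
    c: CircRNAModel, g: GenomeSequence, p: DesignParams = DesignParams()
) -> JunctionContext:
    """Extract the junction context from the mature circular sequence."""
    circ = circular_sequence(c, g)
    w = p.context_width
    if len(circ) < 2 * w:
        raise DesignError(
            f"{c.circ_id}: circle length {len(circ)} < 2 x context_width {w}; "
            f"use context_width <= {len(circ) // 2}"
        )
    return JunctionContext(
        circ_id=c.circ_id, sequence=circ[-w:] + circ[:w], junction_index=w
    )


def _window_design(
    ctx: JunctionContext, p: DesignParams, start: int, design_id: str
) -> ShRNADesign:
    window = ctx.sequence[start : start + p.guide_length]
    side_5p = ctx.junction_index - start
    side_3p = start + p.guide_length - ctx.junction_index
    guide = revcomp(window)
    return ShRNADesign(
        circ_id=ctx.circ_id,
        design_id=design_id,
        window_start=start,
        target_window=window,
        guide=guide,
        passenger=revcomp(guide),
        side_5p=side_5p,
        side_3p=side_3p,
    )


def enumerate_guide_windows(
    ctx: JunctionContext, p: DesignParams = DesignParams()
) -> List[ShRNADesign]:
    """All guide windows satisfying the per-side junction overhang.

    Yields ``guide_length - 2 * min_overhang + 1`` designs when feasible.
    """
    designs = []
    lo = ctx.junction_index - (p.guide_length - p.min_overhang)
    hi = ctx.junction_index - p.min_overhang
    for start in range(max(lo, 0), hi + 1):
        if start + p.guide_length > len(ctx.sequence):
            break
        designs.append(
            _window_design(ctx, p, start, f"{ctx.circ_id}:w{start}")
        )
    return designs


def design_primary(
    ctx: JunctionContext, p: DesignParams = DesignParams()
) -> ShRNADesign:
    """The centered window; for odd lengths the extra base goes 5' of the junction."""
    side_5p = (p.guide_length + 1) // 2
    if side_5p < p.min_overhang or p.guide_length - side_5p < p.min_overhang:
        raise DesignError(
            f"{ctx.circ_id}: centered design infeasible for guide_length "
            f"{p.guide_length}, min_overhang {p.min_overhang}"
        )
    start = ctx.junction_index - side_5p
    return _window_design(ctx, p, start, f"{ctx.circ_id}:primary")


def design_shifted(ctx: JunctionContext, p: DesignParams) -> ShRNADesign:
    """Alternate design: the primary window shifted ``p.shift`` nt.

    Positive shifts move toward the target 3' side (the published alternate
    design is +3, giving sides (8, 13) from a (11, 10) primary).
    """
    primary = design_primary(ctx, p)
    s = p.shift
    max_pos = primary.side_5p - p.min_overhang
    max_neg = primary.side_3p - p.min_overhang
    if s > max_pos or s < -max_neg:
        raise DesignError(
            f"{ctx.circ_id}: shift {s:+d} violates min_overhang "
            f"{p.min_overhang}; feasible shifts are {-max_neg:+d}..{max_pos:+d}"
        )
    start = primary.window_start + s
    if start < 0 or start + p.guide_length > len(ctx.sequence):
        raise DesignError(f"{ctx.circ_id}: shifted window leaves the context")
    return _window_design(ctx, p, start, f"{ctx.circ_id}:shift{s:+d}")


def host_linear_safety(d: ShRNADesign, offtarget_min_len: int = 12) -> ShRNADesign:
    """Flag designs whose longer junction side alone reaches the off-target
    complementarity threshold against the linear host mRNA."""
    if max(d.side_5p, d.side_3p) >= offtarget_min_len and (
        "host_linear_risk" not in d.warnings
    ):
        return replace(d, warnings=d.warnings + ("host_linear_risk",))
    return d
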