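"""Genome-organization statistics: junction gaps, overlaps and spacers.

For adjacent features the signed gap is ``downstream.start - upstream.end
- 1``: negative values are overlaps, positive values intergenic spacers,
zero means contiguous genes.  On a circular genome the junction from the
last feature back to the first is reported too (flagged ``origin``) but is
excluded from overlap/spacer summaries, as are junctions flanking the
control region itself -- published spacer counts are quoted "in addition
to the control region".
"""

from __future__ import annotations

from dataclasses import dataclass, field

from mitocr.core import AnnotationError, GenomeAnnotation, NucSequence


@dataclass(frozen=True)
class JunctionGap:
    upstream: str
    downstream: str
    gap: int
    origin: bool = False
    touches_control_region: bool = False


@dataclass
class OrganizationSummary:
    n_overlap_junctions: int
    total_overlap_bp: int
    max_overlap: tuple[int, list[tuple[str, str]]]
    n_spacers: int
    total_spacer_bp: int
    spacer_range: tuple[int, int] | None

    def to_dict(self) -> dict:
        return {
            "n_overlap_junctions": self.n_overlap_junctions,
            "total_overlap_bp": self.total_overlap_bp,
            "max_overlap_bp": self.max_overlap[0],
            "max_overlap_pairs": [list(p) for p in self.max_overlap[1]],
            "n_spacers": self.n_spacers,
            "total_spacer_bp": self.total_spacer_bp,
            "spacer_range": list(self.spacer_range) if self.spacer_range else None,
        }


def junction_gaps(annotation: GenomeAnnotation) -> list[JunctionGap]:
    """Signed gap at every junction between position-adjacent features."""
    recs = annotation.records
    if [r.start for r in recs] != sorted(r.start for r in recs):
        raise AnnotationError("annotation must be sorted by start coordinate")
    gaps: list[JunctionGap] = []
    for up, down in zip(recs, recs[1:]):
        gaps.append(
            JunctionGap(
                upstream=up.qualified_name,
                downstream=down.qualified_name,
                gap=down.start - up.end - 1,
                touches_control_region=(up.kind == "control_region" or down.kind == "control_region"),
            )
        )
    if annotation.circular and len(recs) >= 2:
        last, first = recs[-1], recs[0]
        gaps.append(
            JunctionGap(
                upstream=last.qualified_name,
                downstream=first.qualified_name,
                gap=first.start + annotation.genome_length - last.end - 1,
                origin=True,
                touches_control_region=(last.kind == "control_region" or first.kind == "control_region"),
            )
        )
    return gaps


def organization_summary(
    gaps: list[JunctionGap], exclude_control_region: bool = True
) -> OrganizationSummary:
    """Overlap stats over negative gaps, spacer stats over positive gaps.

    The origin junction is always excluded; junctions touching the control
    region are excluded when ``exclude_control_region`` (the default).
    """
    kept = [
        g
        for g in gaps
        if not g.origin and not (exclude_control_region and g.touches_control_region)
    ]
    overlaps = [g for g in kept if g.gap < 0]
    spacers = [g for g in kept if g.gap > 0]
    if overlaps:
        worst = max(-g.gap for g in overlaps)
        pairs = [(g.upstream, g.downstream) for g in overlaps if -g.gap == worst]
    else:
        worst, pairs = 0, []
    return OrganizationSummary(
        n_overlap_junctions=len(overlaps),
        total_overlap_bp=sum(-g.gap for g in overlaps),
        max_overlap=(worst, pairs),
        n_spacers=len(spacers),
        total_spacer_bp=sum(g.gap for g in spacers),
        spacer_range=(min(g.gap for g in spacers), max(g.gap for g in spacers)) if spacers else None,
    )


def shared_overlap_motifs(
    annotation: GenomeAnnotation, genome: NucSequence | str
) -> list[tuple[tuple[str, str], str]]:
    """J-strand sequence of every overlap between adjacent features.

    Lets one spot junctions sharing the same overlap motif, such as the
    ATGATAA heptamer found at both the ATP8/ATP6 and ND4L/ND4 junctions of
    seed-bug mitogenomes.
    """
    seq = genome.seq if isinstance(genome, NucSequence) else genome
    out: list[tuple[tuple[str, str], str]] = []
    recs = annotation.records
    for up, down in zip(recs, recs[1:]):
        gap = down.start - up.end - 1
        if gap >= 0:
            continue
        if up.end > len(seq):
            raise AnnotationError(
                f"overlap {up.qualified_name}/{down.qualified_name} extends past sequence end"
            )
        out.append(((up.qualified_name, down.qualified_name), seq[down.start - 1 : up.end]))
    return out
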