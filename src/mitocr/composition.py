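"""Nucleotide composition, AT/GC skew, and codon usage.

Skew statistics follow the standard definitions

    AT skew = (A - T) / (A + T)        GC skew = (G - C) / (G + C)

computed over base counts of the strand under study.  Whole-genome values
are reported on the J-strand; per-gene values on the coding strand, so a
statement like "J-strand PCGs are AT-skewed" reads directly off the
output.  Ambiguous bases (N) are excluded from every numerator and
denominator.  Percentages are rounded only at report time; all internal
values are kept at full precision.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from Bio.Data import CodonTable

from mitocr.core import INVERTEBRATE_MITO_TABLE, SequenceError

_MITO_TABLE = CodonTable.unambiguous_dna_by_id[INVERTEBRATE_MITO_TABLE]


@dataclass(frozen=True)
class BaseComposition:
    a: float
    c: float
    g: float
    t: float
    n_counted: int

    @property
    def at(self) -> float:
        return self.a + self.t

    @property
    def gc(self) -> float:
        return self.g + self.c

    def as_dict(self) -> dict:
        return {"A": self.a, "C": self.c, "G": self.g, "T": self.t, "n_counted": self.n_counted}


@dataclass(frozen=True)
class SkewStats:
    at_skew: float | None
    gc_skew: float | None

    @property
    def at_defined(self) -> bool:
        return self.at_skew is not None

    @property
    def gc_defined(self) -> bool:
        return self.gc_skew is not None


def base_composition(seq: str) -> BaseComposition:
    """Base fractions over A/C/G/T; N is excluded from the denominator."""
    if not seq:
        raise SequenceError("cannot compute composition of an empty sequence")
    counts = Counter(seq.upper())
    n = counts["A"] + counts["C"] + counts["G"] + counts["T"]
    if n == 0:
        raise SequenceError("sequence contains no unambiguous bases")
    return BaseComposition(
        a=counts["A"] / n, c=counts["C"] / n, g=counts["G"] / n, t=counts["T"] / n, n_counted=n
    )


def skew(comp: BaseComposition) -> SkewStats:
    """AT and GC skew; a zero denominator yields a flagged None, never an
    exception."""
    at = (comp.a - comp.t) / (comp.a + comp.t) if comp.a + comp.t > 0 else None
    gc = (comp.g - comp.c) / (comp.g + comp.c) if comp.g + comp.c > 0 else None
    return SkewStats(at_skew=at, gc_skew=gc)


def _check_frame(cds: str, name: str) -> str:
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise SequenceError(f"{name}: CDS length {len(cds)} is not a multiple of 3")
    return cds


def at_content_by_codon_position(cds_list: list[str] | dict[str, str]) -> tuple[float, float, float]:
    """A+T fraction at codon positions 1-3, pooled over all coding
    sequences (coding-strand orientation, truncated stops already removed)."""
    items = cds_list.items() if isinstance(cds_list, dict) else [(f"cds{i}", s) for i, s in enumerate(cds_list)]
    at_counts = [0, 0, 0]
    totals = [0, 0, 0]
    for name, cds in items:
        cds = _check_frame(cds, name)
        for i, base in enumerate(cds):
            pos = i % 3
            if base in "ACGT":
                totals[pos] += 1
                if base in "AT":
                    at_counts[pos] += 1
    if any(t == 0 for t in totals):
        raise SequenceError("empty CDS set")
    return tuple(at_counts[i] / totals[i] for i in range(3))  # type: ignore[return-value]


@dataclass
class CodonUsageTable:
    counts: dict[str, int]
    n_codons: int
    n_skipped: int

    @property
    def percentages(self) -> dict[str, float]:
        if self.n_codons == 0:
            return {}
        return {c: 100.0 * k / self.n_codons for c, k in self.counts.items()}

    def amino_acid(self, codon: str) -> str:
        if codon in _MITO_TABLE.stop_codons:
            return "*"
        return _MITO_TABLE.forward_table[codon]

    def by_amino_acid(self) -> dict[str, int]:
        agg: dict[str, int] = {}
        for codon, k in self.counts.items():
            agg[self.amino_acid(codon)] = agg.get(self.amino_acid(codon), 0) + k
        return agg

    def top(self, n: int = 6) -> list[tuple[str, str, float]]:
        pct = self.percentages
        ranked = sorted(self.counts, key=lambda c: (-self.counts[c], c))
        return [(c, self.amino_acid(c), pct[c]) for c in ranked[:n]]


def codon_usage(cds_list: list[str] | dict[str, str], drop_terminal_stop: bool = True) -> CodonUsageTable:
    """Codon counts and percentages over a set of in-frame coding-strand
    CDS under the invertebrate mitochondrial code.

    Terminal stop codons are dropped by default (truncated terminators are
    not full codons and must already be absent); codons containing an
    ambiguous base are skipped and tallied in ``n_skipped``.
    """
    items = cds_list.items() if isinstance(cds_list, dict) else [(f"cds{i}", s) for i, s in enumerate(cds_list)]
    counts: Counter[str] = Counter()
    skipped = 0
    for name, cds in items:
        cds = _check_frame(cds, name)
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if drop_terminal_stop and codons and codons[-1] in _MITO_TABLE.stop_codons:
            codons = codons[:-1]
        for codon in codons:
            if set(codon) <= set("ACGT"):
                counts[codon] += 1
            else:
                skipped += 1
    return CodonUsageTable(counts=dict(counts), n_codons=sum(counts.values()), n_skipped=skipped)


def cds_from_annotation(annotation, genome, drop_truncated_stop: bool = True) -> dict[str, str]:
    """Coding-strand CDS for every protein-coding gene of an annotated
    genome, trimming incomplete terminators ('T-'/'TA') so each sequence
    is in frame."""
    out: dict[str, str] = {}
    for rec in annotation.by_kind("PCG"):
        s = annotation.feature_seq(rec, genome)
        if drop_truncated_stop and rec.truncated_stop_len:
            s = s[: len(s) - rec.truncated_stop_len]
        out[rec.qualified_name] = s
    return out
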