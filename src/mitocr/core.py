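"""Domain types and I/O for mitogenome annotation tables and sequences.

Coordinate convention
---------------------
All coordinates are 1-based and fully inclusive, matching the style of
published mitogenome organization tables (a tRNA spanning positions 1-65
has length 65).  Internal arithmetic uses this convention throughout; the
BED writer in :mod:`mitocr.control_region` converts to 0-based half-open
on output only.

Strand convention
-----------------
``J`` is the majority strand (most genes of an insect mitogenome are
transcribed from it), ``N`` the minority strand.  Stored sequences are
J-strand; N-strand feature sequences are extracted as the reverse
complement of the J-strand slice.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

VALID_BASES = frozenset("ACGTN")
GENE_KINDS = ("PCG", "tRNA", "rRNA", "control_region")

#: NCBI translation table id for the invertebrate mitochondrial code.
INVERTEBRATE_MITO_TABLE = 5


class AnnotationError(ValueError):
    """Raised for malformed or inconsistent annotation input."""


class SequenceError(ValueError):
    """Raised for sequences containing characters outside A/C/G/T/N."""


@dataclass(frozen=True)
class GeneRecord:
    """One annotated mitogenome feature.

    ``start``/``end`` are 1-based inclusive; ``end >= start`` always
    (features never wrap the origin -- the control region ends at the
    genome's final position).  Truncated stop codons are stored verbatim
    ("T-", "TA"); completion by polyadenylation is a transcript-level
    event and is never applied here.
    """

    name: str
    kind: str
    strand: str
    start: int
    end: int
    anticodon: str | None = None
    start_codon: str | None = None
    stop_codon: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in GENE_KINDS:
            raise AnnotationError(f"{self.name}: unknown feature kind {self.kind!r}")
        if self.strand not in ("J", "N"):
            raise AnnotationError(f"{self.name}: strand must be J or N, got {self.strand!r}")
        if self.start < 1:
            raise AnnotationError(f"{self.name}: start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise AnnotationError(
                f"{self.name}: end ({self.end}) < start ({self.start})"
            )

    @property
    def length(self) -> int:
        """Feature length in bp, computed from coordinates (the printed
        size column of published tables is never trusted)."""
        return self.end - self.start + 1

    @property
    def qualified_name(self) -> str:
        """Name disambiguated by anticodon (two tRNA-Ser, two tRNA-Leu)."""
        if self.anticodon:
            return f"{self.name}({self.anticodon})"
        return self.name

    @property
    def truncated_stop_len(self) -> int:
        """Number of bases of an incomplete terminator ('T-' -> 1, 'TA' -> 2)."""
        if self.stop_codon in ("T", "T-"):
            return 1
        if self.stop_codon == "TA":
            return 2
        return 0


@dataclass
class GenomeAnnotation:
    """An ordered, validated set of :class:`GeneRecord`."""

    records: list[GeneRecord]
    circular: bool = True
    genome_length: int = 0

    def __post_init__(self) -> None:
        if self.genome_length == 0 and self.records:
            self.genome_length = max(r.end for r in self.records)
        starts = [r.start for r in self.records]
        if starts != sorted(starts):
            raise AnnotationError("records are not sorted by start coordinate")
        names = [r.qualified_name for r in self.records]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise AnnotationError(f"duplicate qualified feature names: {dup}")

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def by_kind(self, kind: str) -> list[GeneRecord]:
        return [r for r in self.records if r.kind == kind]

    def get(self, qualified_name: str) -> GeneRecord:
        for r in self.records:
            if r.qualified_name == qualified_name or r.name == qualified_name:
                return r
        raise KeyError(qualified_name)

    def feature_seq(self, record: GeneRecord, genome: "NucSequence | str") -> str:
        """Coding-strand sequence of a feature (reverse complement for N)."""
        seq = genome.seq if isinstance(genome, NucSequence) else genome
        sl = seq[record.start - 1 : record.end]
        return reverse_complement(sl) if record.strand == "N" else sl


@dataclass
class NucSequence:
    """A named nucleotide sequence, uppercase over A/C/G/T/N (J-strand by
    convention for whole-genome records)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise SequenceError(
                f"{self.id}: invalid characters {sorted(bad)} (alphabet is A/C/G/T/N)"
            )

    def __len__(self) -> int:
        return len(self.seq)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over A/C/G/T/N; an involution."""
    s = seq.upper()
    bad = set(s) - VALID_BASES
    if bad:
        raise SequenceError(f"invalid characters for reverse complement: {sorted(bad)}")
    return s.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Annotation table I/O
# ---------------------------------------------------------------------------

_COLUMNS = ["name", "kind", "strand", "start", "end", "anticodon", "start_codon", "stop_codon"]


def _parse_coord(token: str, lineno: int, what: str) -> int:
    token = token.strip().replace(",", "")
    try:
        value = int(token)
    except ValueError:
        raise AnnotationError(f"line {lineno}: malformed {what} coordinate {token!r}") from None
    return value


def read_annotation_table(path: str | Path | io.TextIOBase) -> GenomeAnnotation:
    """Read a tab-separated feature table.

    Expected header columns: name, kind, strand, start, end, anticodon,
    start_codon, stop_codon (trailing empty columns may be omitted).
    Alternatively a single ``position`` column with "start-end" is
    accepted in place of start/end.
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
        src = "<stream>"
    else:
        lines = Path(path).read_text().splitlines()
        src = str(path)
    lines = [ln for ln in lines if ln.strip()]
    if not lines:
        raise AnnotationError(f"{src}: empty annotation table")
    header = [h.strip() for h in lines[0].split("\t")]
    if "name" not in header:
        raise AnnotationError(f"{src}: missing header line with a 'name' column")
    records: list[GeneRecord] = []
    for lineno, line in enumerate(lines[1:], start=2):
        fields = line.split("\t")
        row = {h: (fields[i].strip() if i < len(fields) else "") for i, h in enumerate(header)}
        if "position" in row and row.get("position"):
            pos = row["position"].replace("–", "-").replace("−", "-")
            parts = pos.split("-")
            if len(parts) != 2:
                raise AnnotationError(f"line {lineno}: malformed position {row['position']!r}")
            start = _parse_coord(parts[0], lineno, "start")
            end = _parse_coord(parts[1], lineno, "end")
        else:
            if not row.get("start") or not row.get("end"):
                raise AnnotationError(f"line {lineno}: missing start/end coordinates")
            start = _parse_coord(row["start"], lineno, "start")
            end = _parse_coord(row["end"], lineno, "end")
        records.append(
            GeneRecord(
                name=row["name"],
                kind=row.get("kind", "").strip() or "PCG",
                strand=row.get("strand", "").strip() or "J",
                start=start,
                end=end,
                anticodon=row.get("anticodon") or None,
                start_codon=row.get("start_codon") or None,
                stop_codon=row.get("stop_codon") or None,
            )
        )
    return GenomeAnnotation(records=records)


def write_annotation_table(annotation: GenomeAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_COLUMNS) + "\n")
        for r in annotation.records:
            fh.write(
                "\t".join(
                    [
                        r.name,
                        r.kind,
                        r.strand,
                        str(r.start),
                        str(r.end),
                        r.anticodon or "",
                        r.start_codon or "",
                        r.stop_codon or "",
                    ]
                )
                + "\n"
            )


def load_reference_annotation() -> GenomeAnnotation:
    """The packaged *Panaorus albomaculatus* organization table: 37 genes
    plus the control region of the 16,345-bp mitogenome."""
    ref = resources.files("mitocr.data").joinpath("panaorus_annotation.tsv")
    with resources.as_file(ref) as p:
        return read_annotation_table(p)


# ---------------------------------------------------------------------------
# FASTA I/O (delegated to Biopython; normalized to uppercase on read)
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> list[NucSequence]:
    seqs = [NucSequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    if not seqs:
        raise SequenceError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: Iterable[NucSequence], path: str | Path) -> None:
    records = [SeqRecord(Seq(s.seq), id=s.id, description="") for s in seqs]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(records)
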