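"""tRNA-family conservation profiling.

INP% is the percentage of identical nucleotide positions of a gene-family
multiple alignment: a column is *identical* only when every row carries
the same non-gap residue (a gapped column can never be identical), *ge80*
when the modal non-gap residue covers at least 80% of rows (gap rows
included in the denominator) without being identical, otherwise
*variable*.  The denominator of INP% is the alignment length; the
ungapped-consensus alternative can be selected with
``denominator="ungapped"``.

A small center-star progressive aligner is included as a convenience for
unaligned input (match +1 / mismatch -1 / gap -2, deterministic
tie-breaking); curated alignments from a dedicated aligner are preferred
when available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

TRNA_REGIONS = (
    "acceptor_stem",
    "DHU_stem",
    "DHU_loop",
    "anticodon_stem",
    "anticodon_loop",
    "variable_loop",
    "TpsiC_stem",
    "TpsiC_loop",
    "other",
)


@dataclass
class FamilyAlignment:
    family: str
    taxa: list[str]
    rows: list[str]  # equal-length aligned sequences, '-' for gaps

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError(f"{self.family}: alignment needs >= 2 rows")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError(f"{self.family}: aligned rows of unequal length")
        self.rows = [r.upper() for r in self.rows]

    @property
    def length(self) -> int:
        return len(self.rows[0])


@dataclass
class ConservationProfile:
    family: str
    classes: list[str]  # per column: identical | ge80 | variable
    inp_percent: float

    @property
    def n_identical(self) -> int:
        return sum(1 for c in self.classes if c == "identical")


def _column_class(column: list[str], ge80_fraction: float = 0.8) -> str:
    residues = [b for b in column if b != "-"]
    if residues and len(set(residues)) == 1 and len(residues) == len(column):
        return "identical"
    if residues:
        modal = max(set(residues), key=residues.count)
        if residues.count(modal) >= ge80_fraction * len(column):
            return "ge80"
    return "variable"


def inp_percent(alignment: FamilyAlignment, denominator: str = "alignment") -> ConservationProfile:
    """Per-column conservation classes and the identical-position
    percentage of a family alignment."""
    if denominator not in ("alignment", "ungapped"):
        raise ValueError("denominator must be 'alignment' or 'ungapped'")
    cols = [[row[j] for row in alignment.rows] for j in range(alignment.length)]
    classes = [_column_class(c) for c in cols]
    if denominator == "alignment":
        denom = alignment.length
    else:
        denom = sum(1 for c in cols if any(b != "-" for b in c))
    n_ident = sum(1 for k in classes if k == "identical")
    return ConservationProfile(
        family=alignment.family,
        classes=classes,
        inp_percent=100.0 * n_ident / denom if denom else 0.0,
    )


def region_conservation(
    alignment: FamilyAlignment, structure: list[str]
) -> dict[str, float]:
    """INP% per secondary-structure region (acceptor stem, DHU arm, ...).

    Regions with no annotated columns are omitted from the report.
    """
    if len(structure) != alignment.length:
        raise ValueError(
            f"structure annotation length {len(structure)} != alignment length {alignment.length}"
        )
    profile = inp_percent(alignment)
    out: dict[str, float] = {}
    for region in sorted(set(structure)):
        cols = [j for j, r in enumerate(structure) if r == region]
        ident = sum(1 for j in cols if profile.classes[j] == "identical")
        out[region] = 100.0 * ident / len(cols)
    return out


def strand_conservation_contrast(
    profiles: dict[str, ConservationProfile], strand_map: dict[str, str]
) -> dict:
    """Mean INP% per strand class with per-family values (descriptive
    contrast; no significance test)."""
    per_strand: dict[str, dict[str, float]] = {"J": {}, "N": {}}
    for fam, prof in profiles.items():
        if fam not in strand_map:
            raise KeyError(f"missing strand assignment for family {fam}")
        per_strand[strand_map[fam]][fam] = prof.inp_percent
    if not any(per_strand.values()):
        raise ValueError("no families supplied")
    return {
        strand: {
            "mean_inp_percent": float(np.mean(list(vals.values()))) if vals else None,
            "families": vals,
        }
        for strand, vals in per_strand.items()
    }


# ---------------------------------------------------------------------------
# Center-star alignment
# ---------------------------------------------------------------------------

MATCH, MISMATCH, GAP = 1, -1, -2


def _pairwise_align(a: str, b: str) -> tuple[str, str, int]:
    """Needleman-Wunsch under +1/-1/-2 with deterministic traceback
    (diagonal preferred, then up, then left)."""
    n, m = len(a), len(b)
    score = np.zeros((n + 1, m + 1), dtype=np.int64)
    score[:, 0] = GAP * np.arange(n + 1)
    score[0, :] = GAP * np.arange(m + 1)
    for i in range(1, n + 1):
        sub = np.where(np.frombuffer(b.encode(), dtype=np.uint8) == ord(a[i - 1]), MATCH, MISMATCH)
        for j in range(1, m + 1):
            score[i, j] = max(
                score[i - 1, j - 1] + sub[j - 1],
                score[i - 1, j] + GAP,
                score[i, j - 1] + GAP,
            )
    out_a, out_b = [], []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + (
            MATCH if a[i - 1] == b[j - 1] else MISMATCH
        ):
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and score[i, j] == score[i - 1, j] + GAP:
            out_a.append(a[i - 1])
            out_b.append("-")
            i -= 1
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            j -= 1
    return "".join(reversed(out_a)), "".join(reversed(out_b)), int(score[n, m])


def center_star_align(
    seqs: list[str], taxa: list[str] | None = None, family: str = "family"
) -> FamilyAlignment:
    """Center-star progressive multiple alignment.

    The center is the sequence maximizing the sum of pairwise alignment
    scores (first index wins ties); all others are merged against it with
    the usual once-a-gap-always-a-gap rule.
    """
    if not seqs:
        raise ValueError("no sequences to align")
    seqs = [s.upper() for s in seqs]
    taxa = taxa or [f"seq{i + 1}" for i in range(len(seqs))]
    if len(seqs) == 1:
        return FamilyAlignment(family=family, taxa=taxa, rows=seqs * 1)
    k = len(seqs)
    scores = np.zeros((k, k), dtype=np.int64)
    for i in range(k):
        for j in range(i + 1, k):
            _, _, s = _pairwise_align(seqs[i], seqs[j])
            scores[i, j] = scores[j, i] = s
    center = int(np.argmax(scores.sum(axis=1)))  # argmax returns first max
    ungapped_center = seqs[center]
    master = ungapped_center  # center row of the growing MSA
    aligned: dict[int, str] = {center: master}
    for idx in range(k):
        if idx == center:
            continue
        a_center, a_other, _ = _pairwise_align(ungapped_center, seqs[idx])
        # merge the pairwise alignment into the MSA, column by column,
        # synchronizing on the center's residues (once a gap, always a gap)
        old_rows = {key: row for key, row in aligned.items()}
        new_rows: dict[int, list[str]] = {key: [] for key in old_rows}
        new_rows[idx] = []
        i = j = 0  # i over master columns, j over pairwise columns
        while i < len(master) or j < len(a_center):
            if i < len(master) and master[i] == "-":
                for key, row in old_rows.items():
                    new_rows[key].append(row[i])
                new_rows[idx].append("-")
                i += 1
            elif j < len(a_center) and a_center[j] == "-":
                for key in old_rows:
                    new_rows[key].append("-")
                new_rows[idx].append(a_other[j])
                j += 1
            else:
                for key, row in old_rows.items():
                    new_rows[key].append(row[i])
                new_rows[idx].append(a_other[j])
                i += 1
                j += 1
        aligned = {key: "".join(v) for key, v in new_rows.items()}
        master = aligned[center]
    rows = [aligned[i] for i in range(k)]
    return FamilyAlignment(family=family, taxa=taxa, rows=rows)


def read_aligned_fasta(path) -> FamilyAlignment:
    """Read an aligned FASTA file as a family alignment."""
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty alignment")
    return FamilyAlignment(
        family=str(path),
        taxa=[r.id for r in records],
        rows=[str(r.seq).upper() for r in records],
    )
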