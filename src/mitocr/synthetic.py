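"""Seeded generators emulating the architecture of a seed-bug
mitochondrial control region and mitogenome, so every analysis stage runs
on synthetic data with known ground truth.

The default control-region layout mirrors the dissected architecture of
the *Panaorus albomaculatus* control region: a 321-bp block of elevated
(32.1%) G+C content, an (AATTT)x3 and a (TA)x5 microsatellite flanking an
8-bp poly-C tract, a 103-bp block of 90.3% A+T, an 8-bp poly-A tract, a
34-bp linker, a 949-bp tandem array of 52 full 18-bp units in four
variant types (copy counts 18/15/15/4, two variable sites) closed by a
13-bp terminal partial copy, a second 34-bp linker, and a stem-loop with
a 'TATA' element at its 5' end.  Only the 13-bp partial-copy sequence of
the Type I unit is known; the remaining 5 bases of the default unit
templates are synthetic, so the emitted sequences share the published
architecture but not the deposited sequence.

Fillers (GC/AT blocks, linkers) are built from deterministic composition
masks -- fixed positions reserved for G/C so that no sliding window can
cross the partition scanners' AT- or GC-content thresholds, with random
base identities in every slot -- and are additionally rejection-sampled
against the motif scanners so that the generated region contains exactly
the planted features.  Every generator is a pure function of
(config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Data import CodonTable

from mitocr import control_region as cr
from mitocr.core import (
    INVERTEBRATE_MITO_TABLE,
    GenomeAnnotation,
    NucSequence,
    load_reference_annotation,
    reverse_complement,
)

TYPE_NAMES = {1: "I", 2: "II", 3: "III", 4: "IV"}

# 13-bp published Type I prefix, extended by 5 synthetic bases to the
# 18-bp unit length; variable sites at 0-based positions 5 and 15.
_TYPE_I = "GAATTAGATTAAATCAAT"
_VARIABLE_SITES = (5, 15)


def _variant(base: str, site_residues: dict[int, str]) -> str:
    s = list(base)
    for pos, res in site_residues.items():
        s[pos] = res
    return "".join(s)


DEFAULT_UNIT_TEMPLATES = (
    _TYPE_I,  # Type I:  A at 5, A at 15
    _variant(_TYPE_I, {5: "G", 15: "T"}),  # Type II
    _variant(_TYPE_I, {15: "T"}),  # Type III
    _variant(_TYPE_I, {5: "G"}),  # Type IV = 5' of II joined to 3' of I
)


@dataclass(frozen=True)
class CRGeneratorConfig:
    gc_block_len: int = 321
    gc_content: float = 0.321
    microsat_1: tuple[str, int] = ("AATTT", 3)
    polyc_len: int = 8
    microsat_2: tuple[str, int] = ("TA", 5)
    at_block_len: int = 103
    at_content: float = 0.903
    polya_len: int = 8
    pre_array_linker: int = 34
    post_array_linker: int = 34
    unit_templates: tuple[str, ...] = DEFAULT_UNIT_TEMPLATES
    type_counts: tuple[int, ...] = (18, 15, 15, 4)
    partial_prefix_len: int = 13
    # arrangement rules (all observed in the published array)
    rule_start_with_type1: bool = True
    rule_iii_between_ii_and_i: bool = True
    rule_iv_followed_by_ii: bool = True
    hairpin_arm: str = "TGTAATAGATCT"  # 12 bp; 3' arm is its reverse complement
    hairpin_loop: str = "ATTATAAT"  # 8 bp
    tata_element: bool = True
    tail_len: int = 0  # extra neutral filler after the hairpin

    @property
    def n_full_units(self) -> int:
        return sum(self.type_counts)


@dataclass
class GroundTruth:
    """What the generator planted, for round-trip verification."""

    segments: list[tuple[str, int, int]] = field(default_factory=list)  # (kind, start, end) 1-based
    unit_labels: list[int] = field(default_factory=list)
    partial_label: int | None = None
    variable_sites: tuple[int, ...] = ()
    type_counts: dict[int, int] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


class UnsatisfiableArrangement(ValueError):
    """Raised when the requested type counts cannot satisfy the
    arrangement rules."""


# ---------------------------------------------------------------------------
# repeat array
# ---------------------------------------------------------------------------


def _sample_unit_order(config: CRGeneratorConfig, rng: np.random.Generator) -> list[int]:
    """Uniform sample over unit orders satisfying the arrangement rules.

    Under the full rule set every Type III sits in a II-III-I chain and
    every Type IV immediately precedes such a chain, so valid orders are
    exactly the shuffles of the blocks [IV II III I], [II III I] and [I];
    sampling blocks uniformly samples valid orders uniformly.
    """
    c1, c2, c3, c4 = (list(config.type_counts) + [0, 0, 0, 0])[:4]
    if not (config.rule_iii_between_ii_and_i or config.rule_iv_followed_by_ii):
        labels = [t + 1 for t, c in enumerate(config.type_counts) for _ in range(c)]
        rng.shuffle(labels)
        return labels
    if config.rule_iv_followed_by_ii and c4 > c2:
        raise UnsatisfiableArrangement(
            "rule 'every Type IV followed by Type II' needs at least as many Type II as Type IV"
        )
    if config.rule_iii_between_ii_and_i:
        if c3 != c2:
            raise UnsatisfiableArrangement(
                "rule 'Type III between Type II and Type I' requires equal Type II and "
                "Type III counts (every II opens a II-III-I chain)"
            )
        if c3 > c1:
            raise UnsatisfiableArrangement(
                "rule 'Type III between Type II and Type I' needs a Type I after every Type III"
            )
    blocks = (
        [[4, 2, 3, 1]] * c4
        + [[2, 3, 1]] * (c3 - c4)
        + [[1]] * (c1 - c3)
    )
    free_i = c1 - c3
    if config.rule_start_with_type1 and free_i < 1 and blocks and blocks[0] != [1]:
        raise UnsatisfiableArrangement(
            "rule 'array starts with Type I' needs a Type I copy outside the II-III-I chains"
        )
    if not blocks:
        return []
    order = list(range(len(blocks)))
    for _ in range(10_000):
        rng.shuffle(order)
        first = blocks[order[0]]
        if config.rule_start_with_type1 and first[0] != 1:
            continue
        if first[0] == 2:  # a bare chain start has no Type I predecessor
            continue
        return [lab for i in order for lab in blocks[i]]
    raise UnsatisfiableArrangement("no valid arrangement found within 10,000 tries")


def generate_repeat_array(
    config: CRGeneratorConfig | None = None, seed: int = 0
) -> tuple[str, GroundTruth]:
    """Emit a tandem array honoring the configured type counts and
    arrangement rules, plus a terminal partial (Type I prefix)."""
    cfg = config or CRGeneratorConfig()
    templates = cfg.unit_templates
    if len({len(t) for t in templates}) != 1:
        raise ValueError("unit templates must have equal length")
    rng = np.random.default_rng(seed)
    labels = _sample_unit_order(cfg, rng)
    seq = "".join(templates[lab - 1] for lab in labels)
    partial_label = None
    if cfg.partial_prefix_len:
        if cfg.partial_prefix_len >= len(templates[0]):
            raise ValueError("partial prefix must be shorter than the unit")
        seq += templates[0][: cfg.partial_prefix_len]
        partial_label = 1
    truth = GroundTruth(
        segments=[("tandem_array", 1, len(seq))],
        unit_labels=labels,
        partial_label=partial_label,
        variable_sites=_VARIABLE_SITES if templates == DEFAULT_UNIT_TEMPLATES else (),
        type_counts={t + 1: c for t, c in enumerate(cfg.type_counts) if c},
        extras={"period": len(templates[0]), "partial_len": cfg.partial_prefix_len},
    )
    return seq, truth


# ---------------------------------------------------------------------------
# composition-controlled fillers
# ---------------------------------------------------------------------------


def _random_bases(rng: np.random.Generator, n: int, alphabet: str) -> list[str]:
    return [alphabet[i] for i in rng.integers(0, len(alphabet), n)]


def _block_with_quota(
    rng: np.random.Generator, length: int, minor_fraction: float, minor: str, major: str, tile: int
) -> str:
    """Random block whose per-``tile`` minor-base (e.g. G/C) counts are as
    even as possible, so sliding-window content cannot stray far from the
    target fraction."""
    n_minor = round(length * minor_fraction)
    n_tiles = length // tile
    if n_tiles == 0:
        out = _random_bases(rng, length, major)
        for pos in rng.choice(length, size=min(n_minor, length), replace=False):
            out[pos] = rng.choice(list(minor))
        return "".join(out)
    base_q, extra = divmod(min(n_minor, n_tiles * tile), n_tiles)
    quotas = np.full(n_tiles, base_q)
    quotas[rng.choice(n_tiles, size=extra, replace=False)] += 1
    out: list[str] = []
    for q in quotas:
        tile_bases = _random_bases(rng, tile, major)
        for pos in rng.choice(tile, size=int(q), replace=False):
            tile_bases[pos] = str(rng.choice(list(minor)))
        out.extend(tile_bases)
    out.extend(_random_bases(rng, length - n_tiles * tile, major))
    return "".join(out)


# Fixed G/C slot masks for the 34-bp linkers.  Constraints: every 20-bp
# window holds 3-4 slots (so no window reaches 90% A+T or 25% G+C), and a
# boundary adjoining an all-A/T neighbor accumulates 3 slots within 9 bp
# (so A+T-window creep past the boundary stays below the minimum reported
# block fragment).
_PRE_LINKER_GC_SLOTS = (2, 5, 8, 15, 22, 28)  # 5' end abuts the poly-A tract
_POST_LINKER_GC_SLOTS = (2, 5, 8, 15, 22, 28, 32)  # 3' end abuts TATA + stem


def _masked_linker(rng: np.random.Generator, length: int, gc_slots: tuple[int, ...]) -> list[str]:
    out = _random_bases(rng, length, "AT")
    for pos in gc_slots:
        if pos < length:
            out[pos] = str(rng.choice(["G", "C"]))
    return out


def _tail_filler(rng: np.random.Generator, length: int) -> str:
    out = _random_bases(rng, length, "AT")
    for pos in range(6, length, 6):
        out[pos] = str(rng.choice(["G", "C"]))
    # the first two bases must not extend an upstream hairpin stem by
    # pairing against the TATA element ('TA' pairs with 'TA')
    if length >= 1:
        out[0] = "A"
    if length >= 2:
        out[1] = "T"
    return "".join(out)


def _segment_is_clean(
    seq: str, skip_at: bool = False, skip_gc: bool = False, check_array: bool = True
) -> bool:
    """True when the scanners find nothing in a filler segment."""
    pc = cr.PartitionConfig()
    if cr.find_homopolymers(seq, min_len=pc.poly_min_len) if len(seq) >= pc.poly_min_len else []:
        return False
    if cr.find_microsatellites(
        seq, pc.microsat_max_unit, pc.microsat_min_copies, pc.microsat_min_length
    ):
        return False
    if not skip_at and len(seq) >= pc.at_window:
        if content_hits := cr.content_blocks(seq, pc.at_window, pc.at_threshold, "AT"):
            return False
    if not skip_gc and len(seq) >= pc.gc_window:
        if cr.content_blocks(seq, pc.gc_window, pc.gc_threshold, "GC"):
            return False
    if check_array and cr.detect_tandem_array(
        seq, min_period=pc.microsat_max_unit + 1, min_copies=pc.array_min_copies,
        min_identity=pc.array_min_identity,
    ):
        return False
    return True


def _rejection_sample(make, clean, cap: int = 500) -> str:
    for _ in range(cap):
        s = make()
        if clean(s):
            return s
    raise RuntimeError("could not generate a clean filler segment (cap reached)")


# ---------------------------------------------------------------------------
# control region
# ---------------------------------------------------------------------------


def generate_control_region(
    config: CRGeneratorConfig | None = None, seed: int = 0
) -> tuple[str, GroundTruth]:
    """Assemble the full control region in published element order and
    record ground-truth coordinates for every planted feature.

    The assembly is validated against the tandem-array detector (exactly
    one array, at the planted period, must be recoverable) and resampled
    otherwise: random filler abutting the A-rich tracts can occasionally
    imitate a short tandem array across a segment boundary, and the
    generator's contract is that the emitted region contains exactly the
    planted features.
    """
    cfg = config or CRGeneratorConfig()
    rng = np.random.default_rng(seed)
    period = len(cfg.unit_templates[0])
    for _ in range(50):
        seq, truth = _assemble_control_region(cfg, rng)
        pc = cr.PartitionConfig()
        arrays = cr.detect_tandem_array(
            seq,
            min_period=max(pc.array_min_period, pc.microsat_max_unit + 1),
            max_period=pc.array_max_period,
            min_copies=pc.array_min_copies,
            min_identity=pc.array_min_identity,
        )
        if len(arrays) == 1 and arrays[0].period == period:
            return seq, truth
    raise RuntimeError("could not assemble a control region with a uniquely detectable array")


def _assemble_control_region(
    cfg: CRGeneratorConfig, rng: np.random.Generator
) -> tuple[str, GroundTruth]:
    parts: list[tuple[str, str]] = []  # (kind, sequence)

    gc_block = _rejection_sample(
        lambda: _block_with_quota(rng, cfg.gc_block_len, cfg.gc_content, "GC", "AT", tile=20),
        lambda s: _segment_is_clean(s, skip_gc=True),
    )
    parts.append(("gc_block", gc_block))
    parts.append(("microsatellite", cfg.microsat_1[0] * cfg.microsat_1[1]))
    parts.append(("poly_tract", "C" * cfg.polyc_len))
    parts.append(("microsatellite", cfg.microsat_2[0] * cfg.microsat_2[1]))
    at_block = _rejection_sample(
        lambda: _block_with_quota(rng, cfg.at_block_len, 1 - cfg.at_content, "GC", "AT", tile=10),
        lambda s: _segment_is_clean(s, skip_at=True),
    )
    parts.append(("at_block", at_block))
    parts.append(("poly_tract", "A" * cfg.polya_len))

    array_seq, array_truth = generate_repeat_array(cfg, seed=int(rng.integers(0, 2**31 - 1)))
    period = array_truth.extras["period"]
    consensus_like = cfg.unit_templates[0]

    def make_pre() -> str:
        link = _masked_linker(rng, cfg.pre_array_linker, _PRE_LINKER_GC_SLOTS)
        # the base just 5' of the array must not extend its periodicity
        forbidden = consensus_like[period - 1]
        if link[-1] == forbidden:
            link[-1] = "A" if forbidden != "A" else "T"
        return "".join(link)

    parts.append(("linker", _rejection_sample(make_pre, lambda s: _segment_is_clean(s, check_array=False))))
    parts.append(("tandem_array", array_seq))

    def make_post() -> str:
        link = _masked_linker(rng, cfg.post_array_linker, _POST_LINKER_GC_SLOTS)
        forbidden = consensus_like[cfg.partial_prefix_len % period]
        if link[0] == forbidden:
            link[0] = "A" if forbidden != "A" else "T"
        return "".join(link)

    parts.append(("linker", _rejection_sample(make_post, lambda s: _segment_is_clean(s, check_array=False))))
    if cfg.tata_element:
        parts.append(("tata", "TATA"))
    hairpin = cfg.hairpin_arm + cfg.hairpin_loop + reverse_complement(cfg.hairpin_arm)
    parts.append(("hairpin", hairpin))
    if cfg.tail_len:
        parts.append(
            ("tail", _rejection_sample(lambda: _tail_filler(rng, cfg.tail_len), _segment_is_clean))
        )

    seq = "".join(p[1] for p in parts)
    truth = GroundTruth(
        unit_labels=array_truth.unit_labels,
        partial_label=array_truth.partial_label,
        variable_sites=array_truth.variable_sites,
        type_counts=array_truth.type_counts,
        extras={"period": period, "partial_len": cfg.partial_prefix_len},
    )
    pos = 1
    for kind, s in parts:
        truth.segments.append((kind, pos, pos + len(s) - 1))
        pos += len(s)
    return seq, truth


def expected_partition_kinds(truth: GroundTruth) -> list[str]:
    """Segment kinds the partitioner should report for a generated
    control region: the TATA element is part of the pre-hairpin linker
    gap, and any tail is unassigned."""
    out: list[str] = []
    for kind, _, _ in truth.segments:
        if kind == "tata":
            continue  # absorbed into the preceding linker gap
        mapped = "unassigned" if kind == "tail" else kind
        out.append(mapped)
    return out


# ---------------------------------------------------------------------------
# whole mitogenome
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CompositionParams:
    """Per-strand base composition targets for random gene bodies."""

    at_content: float = 0.76
    at_skew: float = 0.0
    gc_skew: float = 0.0

    def probs(self) -> dict[str, float]:
        at, gc = self.at_content, 1 - self.at_content
        return {
            "A": at * (1 + self.at_skew) / 2,
            "T": at * (1 - self.at_skew) / 2,
            "G": gc * (1 + self.gc_skew) / 2,
            "C": gc * (1 - self.gc_skew) / 2,
        }


_MITO = CodonTable.unambiguous_dna_by_id[INVERTEBRATE_MITO_TABLE]
OVERLAP_MOTIF = "ATGATAA"
_MOTIF_JUNCTIONS = (("ATPase8", "ATPase6"), ("ND4", "ND4L"))  # (upstream, downstream)


def generate_mitogenome(
    annotation_template: GenomeAnnotation | None = None,
    composition_params: CompositionParams | None = None,
    seed: int = 0,
    cr_config: CRGeneratorConfig | None = None,
) -> tuple[NucSequence, GenomeAnnotation, GroundTruth]:
    """Random mitogenome matching a reference gene architecture.

    Gene bodies are drawn per-base from the coding-strand composition
    target (reverse-complemented onto the J-strand for N-strand genes);
    the shared ATGATAA overlap motif is planted on the J-strand at the
    ATP8/ATP6 and ND4L/ND4 junctions, annotated start codons and
    (complete or truncated) stop codons are planted where no overlap
    motif occupies the positions, and the control region is produced by
    :func:`generate_control_region` plus neutral tail filler.
    """
    ann = annotation_template or load_reference_annotation()
    comp = composition_params or CompositionParams()
    rng = np.random.default_rng(seed)
    n = ann.genome_length
    genome = np.full(n, "", dtype="U1")
    truth = GroundTruth(extras={"planted_motifs": []})

    probs_j = comp.probs()
    probs_n = {  # J-strand probabilities for an N-strand coding target
        "A": probs_j["T"], "T": probs_j["A"], "G": probs_j["C"], "C": probs_j["G"],
    }

    control = next(r for r in ann.records if r.kind == "control_region")
    cr_cfg = cr_config or CRGeneratorConfig()
    cr_core, cr_truth = generate_control_region(cr_cfg, seed=int(rng.integers(0, 2**31 - 1)))
    pad = control.length - len(cr_core)
    if pad < 0:
        raise ValueError("control-region slot shorter than the generated region")
    period = len(cr_cfg.unit_templates[0])
    for _ in range(50):  # the padded slot must keep exactly one detectable array
        cr_seq = cr_core + _tail_filler(rng, pad)
        arrays = cr.detect_tandem_array(cr_seq, min_period=7)
        if len(arrays) == 1 and arrays[0].period == period:
            break
    else:
        raise RuntimeError("could not pad the control region without a spurious array")
    genome[control.start - 1 : control.end] = list(cr_seq)
    truth.extras["control_region"] = {
        "start": control.start,
        "segments": [(k, s + control.start - 1, e + control.start - 1) for k, s, e in cr_truth.segments],
        "unit_labels": cr_truth.unit_labels,
    }

    # planted J-strand overlap motifs
    by_name = {r.name: r for r in ann.records}
    for up_name, down_name in _MOTIF_JUNCTIONS:
        up, down = by_name.get(up_name), by_name.get(down_name)
        if up is None or down is None:
            continue
        lo, hi = down.start, up.end  # overlap span, 1-based
        if hi - lo + 1 == len(OVERLAP_MOTIF):
            genome[lo - 1 : hi] = list(OVERLAP_MOTIF)
            truth.extras["planted_motifs"].append((up_name, down_name, OVERLAP_MOTIF, lo, hi))

    def plant(record, coding_offset: int, codon: str) -> None:
        """Write a coding-strand codon fragment at a coding offset,
        skipping genome positions already fixed."""
        for k, base in enumerate(codon):
            off = coding_offset + k
            j_pos = (record.start + off) if record.strand == "J" else (record.end - off)
            idx = j_pos - 1
            val = base if record.strand == "J" else reverse_complement(base)
            if genome[idx] == "":
                genome[idx] = val

    for rec in ann.records:
        if rec.kind == "control_region":
            continue
        if rec.kind == "PCG":
            if rec.start_codon:
                plant(rec, 0, rec.start_codon)
            if rec.stop_codon:
                stop = rec.stop_codon.replace("-", "")
                plant(rec, rec.length - len(stop), stop)
        probs = probs_j if rec.strand == "J" else probs_n
        bases = rng.choice(list("ATGC"), size=rec.length, p=[probs[b] for b in "ATGC"])
        span = slice(rec.start - 1, rec.end)
        empty = genome[span] == ""
        region = genome[span]
        region[empty] = bases[empty]
        genome[span] = region

    # non-coding gaps between genes
    empty = genome == ""
    if empty.any():
        fill = rng.choice(list("ATGC"), size=int(empty.sum()), p=[probs_j[b] for b in "ATGC"])
        genome[empty] = fill

    seq = NucSequence(id=f"synthetic_mitogenome_seed{seed}", seq="".join(genome))
    truth.extras["composition_target"] = comp
    return seq, ann, truth


# ---------------------------------------------------------------------------
# tRNA family alignments
# ---------------------------------------------------------------------------


def generate_family_alignment(
    n_taxa: int,
    length: int,
    identity_prob: float | None = 0.8,
    structure: list[str] | None = None,
    region_identity_probs: dict[str, float] | None = None,
    seed: int = 0,
    family: str = "synthetic-family",
):
    """Alignment whose columns are identical with the stated probability
    (optionally per structure region), plus per-column ground truth."""
    from mitocr.trna import FamilyAlignment

    rng = np.random.default_rng(seed)
    if structure is not None and len(structure) != length:
        raise ValueError("structure annotation length must equal alignment length")
    cols: list[list[str]] = []
    planted: list[bool] = []
    for j in range(length):
        p = identity_prob if identity_prob is not None else 0.8
        if structure is not None and region_identity_probs:
            p = region_identity_probs.get(structure[j], p)
        if rng.random() < p:
            base = str(rng.choice(list("ACGT")))
            cols.append([base] * n_taxa)
            planted.append(True)
        else:
            cols.append([str(b) for b in rng.choice(list("ACGT"), size=n_taxa)])
            planted.append(False)
    rows = ["".join(cols[j][i] for j in range(length)) for i in range(n_taxa)]
    aln = FamilyAlignment(family=family, taxa=[f"taxon{i + 1}" for i in range(n_taxa)], rows=rows)
    truth = GroundTruth(extras={"planted_identical": planted})
    return aln, truth


# ---------------------------------------------------------------------------
# CDS pairs for Ka/Ks recovery
# ---------------------------------------------------------------------------


def _codon_neighbors(codon: str) -> tuple[list[str], list[str]]:
    """(synonymous, nonsynonymous) non-stop single-nucleotide neighbors."""
    def aa(c):
        return "*" if c in _MITO.stop_codons else _MITO.forward_table[c]

    syn, nonsyn = [], []
    for pos in range(3):
        for b in "ACGT":
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if aa(alt) == "*":
                continue
            (syn if aa(alt) == aa(codon) else nonsyn).append(alt)
    return syn, nonsyn


_USABLE_CODONS = [
    c
    for c in sorted(_MITO.forward_table)
    if _codon_neighbors(c)[0] and _codon_neighbors(c)[1]
]


def generate_cds_pair(
    n_codons: int, syn_prob: float, nonsyn_prob: float, seed: int = 0,
    gc_weight: float = 1.0,
) -> tuple[str, str, GroundTruth]:
    """Ancestor/descendant CDS pair with at most one planted substitution
    per codon (synonymous with ``syn_prob``, else nonsynonymous with
    ``nonsyn_prob``), stop-free under the invertebrate mito code.

    ``gc_weight`` biases ancestral codon sampling: each codon's weight is
    ``gc_weight ** (G+C count)``, so values below 1 give AT-rich genes.
    """
    if syn_prob + nonsyn_prob > 1:
        raise ValueError("syn_prob + nonsyn_prob must be <= 1")
    rng = np.random.default_rng(seed)
    weights = np.array(
        [gc_weight ** sum(1 for b in c if b in "GC") for c in _USABLE_CODONS], dtype=float
    )
    weights /= weights.sum()
    anc: list[str] = []
    der: list[str] = []
    n_syn = n_nonsyn = 0
    for _ in range(n_codons):
        codon = _USABLE_CODONS[int(rng.choice(len(_USABLE_CODONS), p=weights))]
        anc.append(codon)
        u = rng.random()
        syn, nonsyn = _codon_neighbors(codon)
        if u < syn_prob:
            der.append(syn[int(rng.integers(0, len(syn)))])
            n_syn += 1
        elif u < syn_prob + nonsyn_prob:
            der.append(nonsyn[int(rng.integers(0, len(nonsyn)))])
            n_nonsyn += 1
        else:
            der.append(codon)
    truth = GroundTruth(extras={"n_syn": n_syn, "n_nonsyn": n_nonsyn})
    return "".join(anc), "".join(der), truth
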