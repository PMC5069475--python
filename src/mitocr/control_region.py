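"""Control-region dissection: tandem-array decomposition, repeat-unit
typing, adjacency rules, motif scanning, hairpin detection, and
partitioning of the region into labeled sections.

The tandem-array decomposer is a from-scratch period detector.  A
candidate period ``p`` is scored by the shifted self-match rate -- the
fraction of positions ``i`` with ``seq[i] == seq[i+p]``.  Maximal
high-match segments (true runs merged across short mismatch gaps, such as
the isolated mismatches produced by unit variants) define candidate
arrays; units are cut in phase from the array start so that a trailing
partial copy, if any, is terminal and prefix-aligned to the consensus.
Among overlapping candidates whose mean unit-to-consensus identity agrees
within 0.02, the smallest period wins (an 18-bp array must not be
reported at period 36); remaining conflicts are resolved longest first.

All coordinates here are 1-based inclusive (see :mod:`mitocr.core`); the
BED writer converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from mitocr.core import SequenceError

_BASE_ORDER = "ACGT"


# ---------------------------------------------------------------------------
# Tandem array detection
# ---------------------------------------------------------------------------


@dataclass
class RepeatArray:
    """A decomposed tandem array within the analyzed sequence."""

    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    period: int
    units: list[tuple[int, int, str]]  # (1-based offset, length, sequence)
    n_full: int
    n_partial: int
    consensus: str
    identity: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def full_units(self) -> list[str]:
        return [u[2] for u in self.units if u[1] == self.period]

    @property
    def partial_unit(self) -> str | None:
        if self.n_partial:
            return self.units[-1][2]
        return None

    def validate(self) -> None:
        assert sum(u[1] for u in self.units) == self.length, "unit lengths must tile the array"
        assert all(u[1] == self.period for u in self.units[: self.n_full])
        if self.n_partial:
            assert self.units[-1][1] < self.period


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, stop) pairs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    changes = np.flatnonzero(padded[1:] != padded[:-1])
    return list(zip(changes[::2], changes[1::2]))


def _merged_segments(mask: np.ndarray, max_gap: int, min_edge_run: int) -> list[tuple[int, int]]:
    """Merge true runs separated by <= max_gap falses; drop terminal runs
    shorter than min_edge_run so segments begin and end on solid matches."""
    runs = _true_runs(mask)
    merged: list[list[tuple[int, int]]] = []
    for run in runs:
        if merged and run[0] - merged[-1][-1][1] <= max_gap:
            merged[-1].append(run)
        else:
            merged.append([run])
    out = []
    for group in merged:
        while group and group[0][1] - group[0][0] < min_edge_run:
            group.pop(0)
        while group and group[-1][1] - group[-1][0] < min_edge_run:
            group.pop()
        if group:
            out.append((group[0][0], group[-1][1]))
    return out


def _consensus_of(units: list[str]) -> str:
    """Per-column majority; ties broken toward A<C<G<T for determinism."""
    p = len(units[0])
    cols = []
    for j in range(p):
        counts = {b: 0 for b in _BASE_ORDER}
        for u in units:
            if u[j] in counts:
                counts[u[j]] += 1
        cols.append(max(_BASE_ORDER, key=lambda b: (counts[b], -_BASE_ORDER.index(b))))
    return "".join(cols)


def _cut_array(seq: str, start0: int, length: int, period: int) -> RepeatArray:
    """Cut an array span into phase-anchored units and build its consensus."""
    start0, length, period = int(start0), int(length), int(period)
    n_full = length // period
    rem = length % period
    units: list[tuple[int, int, str]] = []
    for k in range(n_full):
        off = start0 + k * period
        units.append((off + 1, period, seq[off : off + period]))
    if rem:
        off = start0 + n_full * period
        units.append((off + 1, rem, seq[off : off + rem]))
    full = [u[2] for u in units[:n_full]]
    consensus = _consensus_of(full)
    ident = float(
        np.mean([sum(a == b for a, b in zip(u, consensus)) / period for u in full])
    )
    arr = RepeatArray(
        start=start0 + 1,
        end=start0 + length,
        period=period,
        units=units,
        n_full=n_full,
        n_partial=1 if rem else 0,
        consensus=consensus,
        identity=ident,
    )
    arr.validate()
    return arr


def _overlap_len(a: RepeatArray, b: RepeatArray) -> int:
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def detect_tandem_array(
    seq: str,
    min_period: int = 5,
    max_period: int = 250,
    min_copies: int = 3,
    min_identity: float = 0.8,
    period_tolerance: float = 0.02,
    max_gap: int = 2,
    min_edge_run: int = 3,
) -> list[RepeatArray]:
    """Detect and decompose tandem repeat arrays.

    Returns arrays sorted by start; an empty list when nothing qualifies.
    ``period_tolerance`` is the identity slack within which a smaller
    period is preferred over a larger one covering the same span.
    """
    seq = seq.upper()
    n = len(seq)
    if n < min_period * min_copies:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    candidates: list[RepeatArray] = []
    for p in range(min_period, min(max_period, n // 2) + 1):
        mask = arr[:-p] == arr[p:]
        for a, b in _merged_segments(mask, max_gap=max_gap, min_edge_run=min(min_edge_run, p)):
            length = (b - a) + p
            n_full = length // p
            if n_full < max(2, min_copies):  # a partial never counts toward min_copies
                continue
            cand = _cut_array(seq, a, length, p)
            if cand.identity < min_identity:
                continue
            if _minimal_period(cand.consensus) < min_period:
                continue  # microsatellite-scale repeat wearing a long period
            candidates.append(cand)
    if not candidates:
        return []
    # group candidates that cover essentially the same locus
    candidates.sort(key=lambda c: (-c.length, c.period, c.start))
    groups: list[list[RepeatArray]] = []
    for cand in candidates:
        for group in groups:
            ref = group[0]
            ov = _overlap_len(cand, ref)
            if ov >= 0.8 * cand.length and ov >= 0.8 * ref.length:
                group.append(cand)
                break
        else:
            groups.append([cand])
    # Within a group, prefer the smallest period.  A candidate is eligible
    # when its identity is within the tolerance of the group's best OR is
    # high in absolute terms: consensus identity inflates mechanically at
    # period multiples (fewer units vote per consensus column), so a
    # strongly supported short period must not lose to an incidental
    # longer near-periodicity of the unit arrangement.
    chosen: list[RepeatArray] = []
    for group in groups:
        best_ident = max(c.identity for c in group)
        floor = min(best_ident, 0.9)
        eligible = [
            c for c in group
            if c.identity >= best_ident - period_tolerance or c.identity >= floor
        ]
        eligible.sort(key=lambda c: (c.period, -c.length, c.start))
        chosen.append(eligible[0])
    # across groups: longest-array-first, drop candidates overlapping winners
    chosen.sort(key=lambda c: (-c.length, c.period, c.start))
    accepted: list[RepeatArray] = []
    for cand in chosen:
        if all(_overlap_len(cand, acc) < 0.3 * cand.length for acc in accepted):
            accepted.append(cand)
    accepted.sort(key=lambda c: c.start)
    return accepted


# ---------------------------------------------------------------------------
# Unit typing and adjacency
# ---------------------------------------------------------------------------


@dataclass
class UnitTypeAssignment:
    variable_sites: list[int]  # 0-based positions within the unit
    labels: list[int]  # per full unit, 1-based type ids by descending count
    type_definitions: dict[int, tuple[str, ...]]  # residues at variable sites
    counts: dict[int, int]
    adjacency: dict[int, dict[int, int]]
    partial_label: int | None

    def type_template(self, consensus: str, type_id: int) -> str:
        t = list(consensus)
        for site, res in zip(self.variable_sites, self.type_definitions[type_id]):
            t[site] = res
        return "".join(t)


def classify_units(array: RepeatArray, min_minor_count: int = 2) -> UnitTypeAssignment:
    """Type full repeat units by their residues at variable sites.

    A column is a variable site when at least two residues each occur in
    >= ``min_minor_count`` units.  Types are the residue combinations at
    the variable sites, numbered by descending copy count (ties broken by
    first occurrence); a combination rarer than ``min_minor_count`` is
    treated as a point mutation and merged into the nearest type by
    Hamming distance.  The terminal partial copy is labeled by best
    prefix match against the type templates and counted separately.
    """
    full = array.full_units
    if len(full) < 2:
        raise SequenceError("unit typing requires at least 2 full units")
    if len({len(u) for u in full}) != 1:
        raise SequenceError("full units of unequal length")
    p = array.period
    sites: list[int] = []
    for j in range(p):
        counts: dict[str, int] = {}
        for u in full:
            counts[u[j]] = counts.get(u[j], 0) + 1
        if sum(1 for v in counts.values() if v >= min_minor_count) >= 2:
            sites.append(j)
    combos = [tuple(u[j] for j in sites) for u in full]
    combo_counts: dict[tuple[str, ...], int] = {}
    first_seen: dict[tuple[str, ...], int] = {}
    for i, c in enumerate(combos):
        combo_counts[c] = combo_counts.get(c, 0) + 1
        first_seen.setdefault(c, i)
    major = [c for c in combo_counts if combo_counts[c] >= min_minor_count]
    if not major:  # degenerate: everything rare; keep the most common combo
        major = [max(combo_counts, key=lambda c: (combo_counts[c], -first_seen[c]))]
    major.sort(key=lambda c: (-combo_counts[c], first_seen[c]))
    type_of = {c: i + 1 for i, c in enumerate(major)}

    def nearest_type(combo: tuple[str, ...]) -> int:
        dists = [
            (sum(a != b for a, b in zip(combo, m)), type_of[m]) for m in major
        ]
        return min(dists)[1]

    labels = [type_of.get(c) or nearest_type(c) for c in combos]
    counts_by_type: dict[int, int] = {t: 0 for t in type_of.values()}
    for lab in labels:
        counts_by_type[lab] += 1
    adjacency: dict[int, dict[int, int]] = {}
    for a, b in zip(labels, labels[1:]):
        adjacency.setdefault(a, {}).setdefault(b, 0)
        adjacency[a][b] += 1
    partial_label = None
    if array.n_partial:
        partial = array.partial_unit or ""
        best = None
        for c in major:
            template = list(array.consensus)
            for site, res in zip(sites, c):
                template[site] = res
            score = sum(x == y for x, y in zip(partial, template))
            key = (-score, type_of[c])
            if best is None or key < best[0]:
                best = (key, type_of[c])
        partial_label = best[1] if best else None
    return UnitTypeAssignment(
        variable_sites=sites,
        labels=labels,
        type_definitions={v: k for k, v in type_of.items()},
        counts=counts_by_type,
        adjacency=adjacency,
        partial_label=partial_label,
    )


@dataclass
class AdjacencyReport:
    transitions: dict[int, dict[int, int]]
    labels: list[int]
    partial_label: int | None

    def always_followed_by(self, x: int, y: int) -> bool:
        """True iff type ``x`` occurs, every occurrence has a successor
        among the full units, and every successor is type ``y``."""
        if x not in self.labels:
            return False
        if self.labels and self.labels[-1] == x:
            return False  # terminal occurrence has no full-unit successor
        row = self.transitions.get(x, {})
        return set(row) == {y}


def adjacency_patterns(assignment: UnitTypeAssignment) -> AdjacencyReport:
    if len(assignment.labels) < 2:
        raise SequenceError("adjacency analysis requires at least 2 units")
    return AdjacencyReport(
        transitions=assignment.adjacency,
        labels=assignment.labels,
        partial_label=assignment.partial_label,
    )


# ---------------------------------------------------------------------------
# Motif scanners
# ---------------------------------------------------------------------------


@dataclass
class MotifHit:
    kind: str  # homopolymer | microsatellite | at_rich_block | gc_rich_block | hairpin
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    motif: str | None = None
    copies: int | None = None
    content: float | None = None
    extras: dict = field(default_factory=dict)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def find_homopolymers(seq: str, min_len: int = 8) -> list[MotifHit]:
    """Maximal single-base runs of length >= min_len (>= 3 required)."""
    if min_len < 3:
        raise ValueError("min_len must be >= 3")
    seq = seq.upper()
    hits = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        if j - i >= min_len and seq[i] in "ACGT":
            hits.append(
                MotifHit(kind="homopolymer", start=i + 1, end=j, motif=seq[i], copies=j - i)
            )
        i = j
    return hits


def _minimal_period(s: str) -> int:
    for d in range(1, len(s)):
        if len(s) % d == 0 and s == s[:d] * (len(s) // d):
            return d
    return len(s)


def find_microsatellites(
    seq: str, max_unit: int = 6, min_copies: int = 3, min_length: int = 0
) -> list[MotifHit]:
    """Maximal perfect tandem runs of unit length 2..max_unit.

    Runs reducible to a shorter period are reported only at the shortest
    period; single-base runs are the homopolymer scanner's business.
    """
    if max_unit > 6:
        raise ValueError("max_unit must be <= 6")
    seq = seq.upper()
    n = len(seq)
    hits: list[MotifHit] = []
    for k in range(2, max_unit + 1):
        i = 0
        while i + 2 * k <= n:
            j = i + k
            while j < n and seq[j] == seq[j - k]:
                j += 1
            run = j - i  # full periodic stretch, may include a partial copy
            copies = run // k
            if copies >= min_copies and run >= min_length:
                motif = seq[i : i + k]
                if _minimal_period(motif) == k and set(motif) <= set("ACGT"):
                    hits.append(
                        MotifHit(kind="microsatellite", start=i + 1, end=j, motif=motif, copies=copies)
                    )
                i = j
            else:
                i += 1
    hits.sort(key=lambda h: (h.start, h.end))
    # drop hits nested inside another reported run (shorter unit wins ties)
    out: list[MotifHit] = []
    for h in hits:
        if any(o.start <= h.start and h.end <= o.end and o is not h for o in hits):
            continue
        out.append(h)
    return out


def content_blocks(
    seq: str, window: int = 20, threshold: float = 0.9, mode: str = "AT"
) -> list[MotifHit]:
    """Maximal merged runs of windows whose A+T (or G+C) fraction meets
    ``threshold``; per-block content is recomputed on the merged slice."""
    if mode not in ("AT", "GC"):
        raise ValueError("mode must be 'AT' or 'GC'")
    seq = seq.upper()
    n = len(seq)
    if window > n:
        raise ValueError("window exceeds sequence length")
    pair = "AT" if mode == "AT" else "GC"
    ind = np.fromiter((1 if b in pair else 0 for b in seq), dtype=np.int64, count=n)
    csum = np.concatenate([[0], np.cumsum(ind)])
    win_content = (csum[window:] - csum[:-window]) / window
    passing = win_content >= threshold
    # coverage = union of passing windows; merge overlapping/abutting spans
    spans: list[list[int]] = []
    for a, b in _true_runs(passing):
        lo, hi = int(a), int(b - 1 + window - 1)  # 0-based inclusive
        if spans and lo <= spans[-1][1] + 1:
            spans[-1][1] = max(spans[-1][1], hi)
        else:
            spans.append([lo, hi])
    hits: list[MotifHit] = []
    for lo, hi in spans:
        content = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
        hits.append(
            MotifHit(
                kind="at_rich_block" if mode == "AT" else "gc_rich_block",
                start=lo + 1,
                end=hi + 1,
                content=float(content),
            )
        )
    return hits


_PAIR = {"A": "T", "T": "A", "G": "C", "C": "G"}


def find_hairpin(
    seq: str,
    min_stem: int = 6,
    max_loop: int = 12,
    max_mismatch: int = 1,
    min_loop: int = 3,
    tata_window: int = 10,
) -> list[MotifHit]:
    """Inverted-repeat (stem-loop) search.

    Two arms of equal length flank a loop of ``min_loop..max_loop`` bases;
    arm positions pair reverse-complementarily with at most
    ``max_mismatch`` mispairs, and the outermost and innermost pairs must
    be true pairs.  Hits record whether a 'TATA' element ends within
    ``tata_window`` bp upstream of the 5' arm.  Hits nested inside a
    longer-stemmed hit at the same locus are suppressed.
    """
    if min_stem < 4:
        raise ValueError("min_stem must be >= 4")
    seq = seq.upper()
    n = len(seq)
    raw: list[MotifHit] = []
    for loop_start in range(1, n):
        for loop_len in range(min_loop, max_loop + 1):
            left = loop_start - 1  # innermost base of 5' arm
            right = loop_start + loop_len  # innermost base of 3' arm
            if right >= n:
                continue
            if _PAIR.get(seq[left]) != seq[right]:
                continue  # innermost pair must be a true pair
            mism = 0
            best_arm = 0
            k = 0
            while left - k >= 0 and right + k < n:
                if _PAIR.get(seq[left - k]) == seq[right + k]:
                    best_arm = k + 1  # maximal arm ending on a true pair
                else:
                    mism += 1
                    if mism > max_mismatch:
                        break
                k += 1
            if best_arm >= min_stem:
                a = best_arm
                s0 = left - a + 1
                e0 = right + a - 1
                mismatches = sum(
                    1 for k in range(a) if _PAIR.get(seq[left - k]) != seq[right + k]
                )
                upstream = seq[max(0, s0 - tata_window - 3) : s0]
                raw.append(
                    MotifHit(
                        kind="hairpin",
                        start=s0 + 1,
                        end=e0 + 1,
                        motif=seq[s0 : left + 1],
                        extras={
                            "stem_len": a,
                            "loop_len": loop_len,
                            "mismatches": mismatches,
                            "tata_upstream": "TATA" in upstream,
                        },
                    )
                )
    raw.sort(key=lambda h: (-h.extras["stem_len"], h.extras["loop_len"], h.start))
    out: list[MotifHit] = []
    for h in raw:
        if any(o.start <= h.start and h.end <= o.end for o in out):
            continue
        out.append(h)
    out.sort(key=lambda h: h.start)
    return out


def best_hairpin(hits: list[MotifHit]) -> MotifHit | None:
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.extras["stem_len"], h.extras["mismatches"], h.extras["loop_len"], h.start))


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------


@dataclass
class Segment:
    kind: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    payload: object | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ControlRegionPartition:
    segments: list[Segment]
    arrays: list[RepeatArray]
    motifs: list[MotifHit]

    @property
    def kinds(self) -> list[str]:
        return [s.kind for s in self.segments]

    def validate(self, length: int) -> None:
        assert self.segments[0].start == 1
        assert self.segments[-1].end == length
        for a, b in zip(self.segments, self.segments[1:]):
            assert b.start == a.end + 1, "segments must tile without gaps or overlaps"


@dataclass
class PartitionConfig:
    """Scanner parameters for control-region partitioning.

    The tandem-array label is reserved for periods above the
    microsatellite ceiling (``microsat_max_unit``); shorter-period perfect
    repeats are the microsatellite scanner's domain.  The hairpin search
    is restricted to the subsequence downstream of the tandem array when
    one is found (stem-loops sit just downstream of the array in seed-bug
    control regions), overridable via ``hairpin_downstream_of_array``.
    """

    array_min_period: int = 7
    array_max_period: int = 250
    array_min_copies: int = 3
    array_min_identity: float = 0.8
    microsat_max_unit: int = 6
    microsat_min_copies: int = 3
    microsat_min_length: int = 10
    poly_min_len: int = 8
    at_window: int = 20
    at_threshold: float = 0.9
    gc_window: int = 20
    gc_threshold: float = 0.25
    hairpin_min_stem: int = 6
    hairpin_max_loop: int = 12
    hairpin_max_mismatch: int = 1
    hairpin_downstream_of_array: bool = True
    gap_absorb: int = 4
    min_block_fragment: int = 10


_PRECEDENCE = ["tandem_array", "hairpin", "microsatellite", "poly_tract", "gc_block", "at_block"]


def partition_control_region(
    seq: str, config: PartitionConfig | None = None
) -> ControlRegionPartition:
    """Run every scanner and resolve overlaps into an ordered, covering
    partition.  Precedence: tandem array > hairpin > microsatellite >
    poly tract > GC block > AT block; unlabeled interior gaps become
    linkers (gaps <= ``gap_absorb`` are absorbed into the preceding
    segment), unlabeled edge gaps are 'unassigned', and a sequence with no
    recognized feature is one unassigned segment.
    """
    cfg = config or PartitionConfig()
    seq = seq.upper()
    n = len(seq)
    arrays = detect_tandem_array(
        seq,
        min_period=max(cfg.array_min_period, cfg.microsat_max_unit + 1),
        max_period=cfg.array_max_period,
        min_copies=cfg.array_min_copies,
        min_identity=cfg.array_min_identity,
    )
    if cfg.hairpin_downstream_of_array:
        # stem-loops of interest sit just downstream of the tandem array;
        # with no array there is no search region (override via config)
        hp_off = arrays[-1].end if arrays else len(seq)
        hp_region = seq[hp_off:]
    else:
        hp_off = 0
        hp_region = seq
    hp_hits = (
        find_hairpin(
            hp_region,
            min_stem=cfg.hairpin_min_stem,
            max_loop=cfg.hairpin_max_loop,
            max_mismatch=cfg.hairpin_max_mismatch,
        )
        if len(hp_region) >= 2 * cfg.hairpin_min_stem + 3
        else []
    )
    for h in hp_hits:
        h.start += hp_off
        h.end += hp_off
    hairpin = best_hairpin(hp_hits)
    micro = find_microsatellites(
        seq,
        max_unit=cfg.microsat_max_unit,
        min_copies=cfg.microsat_min_copies,
        min_length=cfg.microsat_min_length,
    )
    polys = find_homopolymers(seq, min_len=cfg.poly_min_len)
    at_blocks = content_blocks(seq, cfg.at_window, cfg.at_threshold, "AT") if n >= cfg.at_window else []
    gc_blocks = content_blocks(seq, cfg.gc_window, cfg.gc_threshold, "GC") if n >= cfg.gc_window else []

    by_kind: dict[str, list[tuple[int, int, object]]] = {
        "tandem_array": [(a.start, a.end, a) for a in arrays],
        "hairpin": [(hairpin.start, hairpin.end, hairpin)] if hairpin else [],
        "microsatellite": [(h.start, h.end, h) for h in micro],
        "poly_tract": [(h.start, h.end, h) for h in polys],
        "gc_block": [(h.start, h.end, h) for h in gc_blocks],
        "at_block": [(h.start, h.end, h) for h in at_blocks],
    }
    claimed = np.zeros(n, dtype=bool)
    segments: list[Segment] = []
    for kind in _PRECEDENCE:
        min_frag = cfg.min_block_fragment if kind in ("gc_block", "at_block") else 1
        for s1, e1, payload in by_kind[kind]:
            lo, hi = s1 - 1, e1  # 0-based half-open
            free = ~claimed[lo:hi]
            for a, b in _true_runs(free):
                if b - a >= min_frag:
                    segments.append(
                        Segment(kind=kind, start=int(lo + a + 1), end=int(lo + b), payload=payload)
                    )
                    claimed[lo + a : lo + b] = True
    segments.sort(key=lambda s: s.start)
    merged: list[Segment] = []
    for seg in segments:  # fuse contiguous same-kind pieces
        if merged and seg.kind == merged[-1].kind and seg.start == merged[-1].end + 1:
            merged[-1].end = seg.end
        else:
            merged.append(seg)
    segments = merged
    if not segments:
        return ControlRegionPartition(
            segments=[Segment(kind="unassigned", start=1, end=n)] if n else [],
            arrays=arrays,
            motifs=micro + polys + at_blocks + gc_blocks + ([hairpin] if hairpin else []),
        )
    # fill gaps: absorb tiny ones, label the rest linker / unassigned
    filled: list[Segment] = []
    cursor = 1
    for seg in segments:
        if seg.start > cursor:
            gap_len = seg.start - cursor
            if filled and gap_len <= cfg.gap_absorb:
                filled[-1].end = seg.start - 1
            elif filled:
                filled.append(Segment(kind="linker", start=cursor, end=seg.start - 1))
            else:
                kind = "unassigned" if gap_len > cfg.gap_absorb else None
                if kind:
                    filled.append(Segment(kind="unassigned", start=cursor, end=seg.start - 1))
                else:
                    seg = Segment(kind=seg.kind, start=cursor, end=seg.end, payload=seg.payload)
        filled.append(seg)
        cursor = seg.end + 1
    if cursor <= n:
        gap_len = n - cursor + 1
        if gap_len <= cfg.gap_absorb:
            filled[-1].end = n
        else:
            filled.append(Segment(kind="unassigned", start=cursor, end=n))
    part = ControlRegionPartition(
        segments=filled,
        arrays=arrays,
        motifs=micro + polys + at_blocks + gc_blocks + ([hairpin] if hairpin else []),
    )
    part.validate(n)
    return part


def write_bed(partition: ControlRegionPartition, path: str | Path, chrom: str = "control_region") -> None:
    """Write the partition as BED (0-based half-open) for browser use."""
    with open(path, "w") as fh:
        for seg in partition.segments:
            fh.write(f"{chrom}\t{seg.start - 1}\t{seg.end}\t{seg.kind}\n")
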