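"""Pairwise Ka/Ks by the Nei-Gojobori (1986) counting method.

For each codon the number of synonymous sites is the fraction of the
three possible single-nucleotide changes at each position that leave the
amino acid unchanged under the invertebrate mitochondrial code; changes
producing a stop codon count as nonsynonymous.  Site counts are averaged
over the two sequences.  Observed differences in codons differing at
2-3 positions are averaged over all mutational pathways (orders of
substitution) with equal weight.  Proportions are corrected for multiple
hits with the Jukes-Cantor formula d = -3/4 ln(1 - 4p/3); p >= 3/4 makes
the correction undefined and is flagged rather than raised.

Ka/Ks < 1 indicates purifying selection.  The ratio is flagged undefined
(``None``) when Ks = 0; it is never reported as infinity.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

from mitocr.core import INVERTEBRATE_MITO_TABLE, SequenceError

_MITO = CodonTable.unambiguous_dna_by_id[INVERTEBRATE_MITO_TABLE]
_BASES = "ACGT"


def _translate(codon: str) -> str:
    """Amino acid for a codon, with '*' for stops."""
    if codon in _MITO.stop_codons:
        return "*"
    return _MITO.forward_table[codon]


def _syn_sites(codon: str) -> float:
    """Synonymous site count of one codon (nonsynonymous = 3 - this)."""
    aa = _translate(codon)
    syn = 0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if _translate(alt) != "*" and _translate(alt) == aa:
                syn += 1
    return syn / 3.0


def _pathway_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons,
    averaged over all substitution orders with equal weight."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    sd = nd = 0.0
    paths = list(itertools.permutations(diff_pos))
    w = 1.0 / len(paths)
    for path in paths:
        cur = c1
        for pos in path:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _translate(cur) == _translate(nxt):
                sd += w
            else:
                nd += w
            cur = nxt
    return sd, nd


@dataclass(frozen=True)
class KaKsResult:
    ka: float | None
    ks: float | None
    ratio: float | None
    n_sites: tuple[float, float]  # (nonsynonymous, synonymous)
    p_n: float
    p_s: float
    sd: float
    nd: float

    @property
    def ratio_defined(self) -> bool:
        return self.ratio is not None


def _codons(cds: str, label: str) -> list[str]:
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise SequenceError(f"{label}: length {len(cds)} not a multiple of 3")
    if "-" in cds:
        raise SequenceError(f"{label}: gapped codons are not supported; strip gap columns first")
    out = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    for i, c in enumerate(out[:-1]):
        if _translate(c) == "*":
            raise SequenceError(f"{label}: internal stop codon {c} at codon {i + 1}")
    if out and _translate(out[-1]) == "*":
        raise SequenceError(f"{label}: terminal stop codon must be removed before analysis")
    return out


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def ng86_kaks(cds_a: str, cds_b: str) -> KaKsResult:
    """Nei-Gojobori Ka/Ks for a pre-aligned, gap-free, in-frame CDS pair."""
    codons_a = _codons(cds_a, "cds_a")
    codons_b = _codons(cds_b, "cds_b")
    if len(codons_a) != len(codons_b):
        raise SequenceError(
            f"sequences differ in length ({len(cds_a)} vs {len(cds_b)}); align codons first"
        )
    if not codons_a:
        raise SequenceError("empty CDS pair")
    s_a = sum(_syn_sites(c) for c in codons_a)
    s_b = sum(_syn_sites(c) for c in codons_b)
    s_sites = (s_a + s_b) / 2.0
    n_sites = 3.0 * len(codons_a) - s_sites
    sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        ds, dn = _pathway_diffs(ca, cb)
        sd += ds
        nd += dn
    p_s = sd / s_sites if s_sites > 0 else 0.0
    p_n = nd / n_sites if n_sites > 0 else 0.0
    ks = _jukes_cantor(p_s)
    ka = _jukes_cantor(p_n)
    ratio = None
    if ka is not None and ks is not None and ks > 0:
        ratio = ka / ks
    return KaKsResult(
        ka=ka, ks=ks, ratio=ratio, n_sites=(n_sites, s_sites), p_n=p_n, p_s=p_s, sd=sd, nd=nd
    )


def mean_pairwise_kaks(cds_list: list[str]) -> dict:
    """Mean Ka, Ks and Ka/Ks over all unordered pairs of a gene's aligned
    CDS set, skipping pairs with undefined values."""
    kas, kss, ratios = [], [], []
    for a, b in itertools.combinations(cds_list, 2):
        r = ng86_kaks(a, b)
        if r.ka is not None:
            kas.append(r.ka)
        if r.ks is not None:
            kss.append(r.ks)
        if r.ratio is not None:
            ratios.append(r.ratio)
    return {
        "mean_ka": float(np.mean(kas)) if kas else None,
        "mean_ks": float(np.mean(kss)) if kss else None,
        "mean_ratio": float(np.mean(ratios)) if ratios else None,
        "n_pairs": len(kas),
    }


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float


def kaks_gc_regression(points: list[tuple[float, float]]) -> RegressionFit:
    """Ordinary least squares of Ka/Ks ratio on G+C fraction across genes.

    A negative slope with high R^2 reproduces the classic observation
    that GC-poor mitochondrial genes evolve with higher Ka/Ks.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 (gc, ka/ks) points for a regression")
    x = np.asarray([p[0] for p in points], dtype=float)
    y = np.asarray([p[1] for p in points], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in GC content; regression undefined")
    if np.allclose(y, y[0]):
        # constant response: slope 0, R^2 defined as 0
        return RegressionFit(slope=0.0, intercept=float(y[0]), r_squared=0.0)
    fit = stats.linregress(x, y)
    return RegressionFit(slope=float(fit.slope), intercept=float(fit.intercept), r_squared=float(fit.rvalue**2))
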