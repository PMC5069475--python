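"""Nei-Gojobori Ka/Ks against independent oracles, plus the Ka/Ks-GC
regression."""

import itertools
import math
import random
import warnings

import numpy as np
import pytest

from mitocr.core import SequenceError
from mitocr.evo_rates import kaks_gc_regression, mean_pairwise_kaks, ng86_kaks
from mitocr.synthetic import generate_cds_pair

# --------------------------------------------------------------------------
# Independent oracle: brute-force site counting and exhaustive pathway
# enumeration, written against the raw genetic-code table.
# --------------------------------------------------------------------------

from Bio.Data.CodonTable import unambiguous_dna_by_id

_T5 = unambiguous_dna_by_id[5]


def _aa(codon):
    return "*" if codon in _T5.stop_codons else _T5.forward_table[codon]


def oracle_sites(codon):
    """Synonymous-site count of a codon by direct enumeration."""
    syn = 0
    for pos, b in itertools.product(range(3), "ACGT"):
        if b == codon[pos]:
            continue
        alt = codon[:pos] + b + codon[pos + 1:]
        if _aa(alt) != "*" and _aa(alt) == _aa(codon):
            syn += 1
    return syn / 3


def oracle_diffs(c1, c2):
    """(syn, nonsyn) differences averaged over all substitution orders."""
    pos = [i for i in range(3) if c1[i] != c2[i]]
    if not pos:
        return 0.0, 0.0
    paths = list(itertools.permutations(pos))
    syn = nonsyn = 0.0
    for path in paths:
        cur = c1
        for p in path:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            if _aa(nxt) == _aa(cur):
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
    n = len(paths)
    return syn / n, nonsyn / n


def oracle_kaks(a, b):
    codons_a = [a[i:i + 3] for i in range(0, len(a), 3)]
    codons_b = [b[i:i + 3] for i in range(0, len(b), 3)]
    s_sites = (sum(map(oracle_sites, codons_a)) + sum(map(oracle_sites, codons_b))) / 2
    n_sites = 3 * len(codons_a) - s_sites
    sd = nd = 0.0
    for x, y in zip(codons_a, codons_b):
        s, n = oracle_diffs(x, y)
        sd += s
        nd += n
    def jc(p):
        return None if p >= 0.75 else -0.75 * math.log(1 - 4 * p / 3)
    return jc(nd / n_sites), jc(sd / s_sites), (n_sites, s_sites)


_NON_STOP = [c for c in sorted(_T5.forward_table)]


class TestNG86:
    def test_identical_sequences(self):
        r = ng86_kaks("ATGATT", "ATGATT")
        assert r.ka == 0.0 and r.ks == 0.0
        assert r.ratio is None and not r.ratio_defined

    def test_single_synonymous_leucine_change(self):
        # TTA -> TTG is synonymous (Leu); Gly padding keeps pS below 3/4
        r = ng86_kaks("TTAGGAGGA", "TTGGGAGGA")
        assert r.ka == 0.0
        assert r.ks > 0.0

    def test_sites_sum_to_three_per_codon(self):
        r = ng86_kaks("ATGATTCCA", "ATGATTCCA")
        assert sum(r.n_sites) == pytest.approx(9.0)

    def test_two_difference_codons_match_pathway_oracle(self):
        rng = random.Random(11)
        checked = 0
        while checked < 60:
            c1 = rng.choice(_NON_STOP)
            c2 = rng.choice(_NON_STOP)
            if sum(a != b for a, b in zip(c1, c2)) < 2:
                continue
            pad = rng.choice(_NON_STOP)
            a, b = c1 + pad, c2 + pad
            r = ng86_kaks(a, b)
            oka, oks, osites = oracle_kaks(a, b)
            assert r.n_sites == pytest.approx(osites)
            assert r.ka == pytest.approx(oka) if oka is not None else r.ka is None
            assert r.ks == pytest.approx(oks) if oks is not None else r.ks is None
            checked += 1

    def test_matches_independent_library_implementation(self):
        """Cross-check against Biopython's NG86 on a moderately diverged pair."""
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds
        a, b, _ = generate_cds_pair(300, 0.06, 0.03, seed=5)
        mine = ng86_kaks(a, b)
        dn, ds = cal_dn_ds(CodonSeq(a), CodonSeq(b), codon_table=_T5, method="NG86")
        assert mine.ka == pytest.approx(dn, abs=1e-12)
        assert mine.ks == pytest.approx(ds, abs=1e-12)

    def test_symmetry(self):
        a, b, _ = generate_cds_pair(120, 0.08, 0.05, seed=3)
        r1, r2 = ng86_kaks(a, b), ng86_kaks(b, a)
        assert r1.ka == pytest.approx(r2.ka) and r1.ks == pytest.approx(r2.ks)

    def test_synonymous_only_evolution_gives_zero_ka(self):
        a, b, _ = generate_cds_pair(200, 0.10, 0.0, seed=9)
        r = ng86_kaks(a, b)
        assert r.ka == 0.0 and r.ks > 0.0

    def test_internal_stop_rejected(self):
        with pytest.raises(SequenceError, match="stop"):
            ng86_kaks("ATGTAAATT", "ATGTAAATT")

    def test_length_mismatch_rejected(self):
        with pytest.raises(SequenceError):
            ng86_kaks("ATGATT", "ATG")

    def test_parameter_recovery_within_three_mc_standard_errors(self):
        n, syn_p, nonsyn_p = 500, 0.05, 0.02
        a, b, truth = generate_cds_pair(n, syn_p, nonsyn_p, seed=17)
        r = ng86_kaks(a, b)
        n_sites, s_sites = r.n_sites
        # planted substitution counts are exact (one change max per codon)
        assert r.nd == truth.extras["n_nonsyn"]
        assert r.sd == truth.extras["n_syn"]
        se_ka = math.sqrt(n * nonsyn_p * (1 - nonsyn_p)) / n_sites
        se_ks = math.sqrt(n * syn_p * (1 - syn_p)) / s_sites
        assert abs(r.ka - n * nonsyn_p / n_sites) <= 3 * se_ka
        assert abs(r.ks - n * syn_p / s_sites) <= 3 * se_ks

    def test_mean_pairwise_mode(self):
        # three related sequences: an ancestor, a derived copy, the ancestor again
        a, b, _ = generate_cds_pair(80, 0.05, 0.02, seed=4)
        out = mean_pairwise_kaks([a, b, a])
        assert out["n_pairs"] == 3
        assert out["mean_ka"] is not None and out["mean_ka"] >= 0


class TestRegression:
    def test_collinear_points(self):
        pts = [(0.1, 1.0), (0.2, 0.8), (0.3, 0.6), (0.4, 0.4)]
        fit = kaks_gc_regression(pts)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(-2.0)

    def test_constant_response(self):
        fit = kaks_gc_regression([(0.1, 0.5), (0.2, 0.5), (0.3, 0.5)])
        assert fit.r_squared == 0.0 and fit.slope == 0.0

    def test_matches_closed_form_normal_equations(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(0.2, 0.5, 10)
        y = -1.5 * x + 0.9 + rng.normal(0, 0.05, 10)
        fit = kaks_gc_regression(list(zip(x, y)))
        xm, ym = x.mean(), y.mean()
        slope = ((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum()
        intercept = ym - slope * xm
        ss_res = ((y - (slope * x + intercept)) ** 2).sum()
        r2 = 1 - ss_res / ((y - ym) ** 2).sum()
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)
        assert fit.r_squared == pytest.approx(r2, abs=1e-10)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            kaks_gc_regression([(0.1, 1.0), (0.2, 0.8)])
        with pytest.raises(ValueError, match="variance"):
            kaks_gc_regression([(0.3, 1.0), (0.3, 0.8), (0.3, 0.6)])
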