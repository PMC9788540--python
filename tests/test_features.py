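import functools
import itertools
import re

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from srnascape.features import (
    MIN_LOOP,
    _max_pairing,
    compare_feature_groups,
    correlate_gc_nmfe,
    count_gga_motifs,
    extract_site_windows,
    find_sorfs,
    fold_mfe,
    gc_content,
    motif_profile,
    nmfe,
)
from srnascape.io import GenomeRecord, reverse_complement
from srnascape.sites import SiteCall

import pandas as pd


# ---------------------------------------------------------------------------
# Independent oracles

_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def brute_max_pairs(seq):
    """Exhaustive maximum nested pairing by interval recursion."""
    @functools.lru_cache(maxsize=None)
    def best(i, j):
        if j - i < MIN_LOOP + 1:
            return 0
        top = best(i, j - 1)
        for k in range(i, j - MIN_LOOP):
            if (seq[k], seq[j]) in _PAIRS:
                left = best(i, k - 1) if k > i else 0
                top = max(top, left + 1 + best(k + 1, j - 1))
        return top

    return best(0, len(seq) - 1) if seq else 0


def regex_sorfs(seq, min_aa=20):
    """Frame-wise regex scan for AUG...stop ORFs, longest per stop."""
    found = []
    for frame in range(3):
        codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
        stops_used = set()
        for ci, codon in enumerate(codons):
            if codon != "AUG":
                continue
            for cj in range(ci + 1, len(codons)):
                if codons[cj] in ("UAA", "UAG", "UGA"):
                    if cj not in stops_used:
                        stops_used.add(cj)
                        aa = cj - ci
                        if aa >= min_aa:
                            found.append((frame, frame + 3 * ci, frame + 3 * cj + 2, aa))
                    break
    return sorted(found)


def manual_ranksum(x, y):
    """Normal-approximation rank-sum test, written independently of scipy."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    n1, n2 = len(x), len(y)
    combined = np.concatenate([x, y])
    order = combined.argsort(kind="mergesort")
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(1, n1 + n2 + 1)
    # average ties
    for v in np.unique(combined):
        mask = combined == v
        if mask.sum() > 1:
            ranks[mask] = ranks[mask].mean()
    w = ranks[:n1].sum()
    mu = n1 * (n1 + n2 + 1) / 2.0
    sigma = np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)
    z = (w - mu) / sigma
    from math import erf, sqrt

    p = 2 * (1 - 0.5 * (1 + erf(abs(z) / sqrt(2))))
    return z, p


# ---------------------------------------------------------------------------


class TestGc:
    @pytest.mark.parametrize("seq, expected", [("ACGT", 0.5), ("GGCC", 1.0), ("AATT", 0.0)])
    def test_examples(self, seq, expected):
        assert gc_content(seq) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")

    def test_ambiguous_counts_as_non_gc(self):
        assert gc_content("GGNN") == 0.5


class TestFolding:
    def test_unpairable_sequence_scores_zero(self):
        assert fold_mfe("AAAA") == 0.0

    def test_simple_hairpin(self):
        # four GC pairs around a 4-nt loop
        assert fold_mfe("GGGGAAAACCCC") == -4.0

    def test_matches_exhaustive_enumeration(self, rng):
        for _ in range(40):
            n = int(rng.integers(5, 26))
            seq = "".join(rng.choice(list("ACGU"), size=n))
            assert _max_pairing(seq) == brute_max_pairs(seq), seq

    @settings(deadline=None, max_examples=30)
    @given(st.text(alphabet="ACGU", min_size=6, max_size=18))
    def test_tandem_duplication_never_raises_nmfe(self, seq):
        single = fold_mfe(seq)
        double = fold_mfe(seq + seq)
        assert nmfe(double, 2 * len(seq)) <= nmfe(single, len(seq)) + 1e-12

    def test_unknown_backend_rejected(self):
        with pytest.raises(ValueError):
            fold_mfe("ACGU", backend="quantum")


class TestNmfe:
    @pytest.mark.parametrize("mfe_val, length, expected",
                             [(-10.0, 100, -0.1), (0.0, 50, 0.0), (-98.4, 205, -0.48)])
    def test_values(self, mfe_val, length, expected):
        assert nmfe(mfe_val, length) == pytest.approx(expected)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            nmfe(-1.0, 0)


class TestGroupStats:
    def test_identical_groups_null(self, rng):
        df = pd.DataFrame({"length": rng.normal(200, 10, 30),
                           "gc": rng.uniform(0.4, 0.6, 30),
                           "nmfe": rng.normal(-0.4, 0.05, 30)})
        out = compare_feature_groups({"a": df, "b": df.copy()})
        assert (out.pvalue > 0.99).all()

    def test_shifted_groups_detected(self, rng):
        a = pd.DataFrame({"length": rng.normal(200, 10, 50)})
        b = pd.DataFrame({"length": rng.normal(260, 10, 50)})
        out = compare_feature_groups({"a": a, "b": b}, features=["length"])
        assert out.pvalue.iloc[0] < 1e-6

    def test_matches_independent_ranksum(self, rng):
        for _ in range(20):
            a = rng.normal(0, 1, int(rng.integers(5, 40)))
            b = rng.normal(0.3, 1, int(rng.integers(5, 40)))
            stat, p = sps.ranksums(a, b)
            z, p2 = manual_ranksum(a, b)
            assert p == pytest.approx(p2, abs=1e-8)

    def test_small_group_excluded_with_warning(self, rng):
        a = pd.DataFrame({"length": rng.normal(200, 10, 30)})
        tiny = pd.DataFrame({"length": [1.0, 2.0]})
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                compare_feature_groups({"a": a, "tiny": tiny}, features=["length"])

    def test_spearman_sign_and_null(self, rng):
        gc = [0.4, 0.5, 0.6, 0.7, 0.8]
        mono = [-0.30, -0.35, -0.40, -0.45, -0.50]
        rho, p = correlate_gc_nmfe(gc, mono)
        assert rho == pytest.approx(-1.0)
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        rho2, p2 = correlate_gc_nmfe(list(x), list(y))
        assert abs(rho2) < 0.3
        rho_ref, p_ref = sps.spearmanr(x, y)
        assert rho2 == pytest.approx(float(rho_ref), abs=1e-12)
        with pytest.raises(ValueError):
            correlate_gc_nmfe([0.1, 0.2], [0.3, 0.4])


class TestMotifProfile:
    def _sites(self, positions, strand="+", kind="TSS"):
        return [SiteCall(p, strand, kind, 10.0, 5.0) for p in positions]

    def test_identical_windows_full_information(self):
        genome = GenomeRecord("g", "ACGT" * 100)
        sites = self._sites(range(50, 90, 4))  # every window identical (period 4)
        prof = motif_profile(sites, genome, "TSS", window=(-4, 4))
        assert np.allclose(prof.information, 2.0)
        assert (prof.frequencies.sum(axis=1) - 1).abs().max() < 1e-9

    def test_order_invariance(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        genome = GenomeRecord("g", seq)
        sites = self._sites(list(range(100, 1900, 137)))
        a = motif_profile(sites, genome, "TSS", window=(-5, 5))
        b = motif_profile(list(reversed(sites)), genome, "TSS", window=(-5, 5))
        assert a.consensus == b.consensus
        assert np.allclose(a.frequencies.values, b.frequencies.values)

    def test_minus_strand_profile_is_revcomp_of_plus(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        genome = GenomeRecord("g", seq)
        rc_genome = GenomeRecord("g_rc", reverse_complement(seq))
        n = len(seq)
        plus_positions = list(range(200, 2800, 173))
        plus = motif_profile(self._sites(plus_positions), genome, "TSS", (-6, 6))
        minus_positions = [n - p + 1 for p in plus_positions]
        minus = motif_profile(self._sites(minus_positions, strand="-"),
                              rc_genome, "TSS", (-6, 6))
        assert plus.consensus == minus.consensus
        assert np.allclose(plus.frequencies.values, minus.frequencies.values)

    def test_edge_sites_skipped(self):
        genome = GenomeRecord("g", "ACGT" * 30)
        sites = self._sites([2, 50, 54, 58, 62, 66, 70, 74, 78, 82, 86])
        with pytest.warns(UserWarning):
            prof = motif_profile(sites, genome, "TSS", window=(-10, 10))
        assert prof.n_sites == 10

    def test_too_few_sites_rejected(self):
        genome = GenomeRecord("g", "ACGT" * 30)
        with pytest.raises(ValueError):
            motif_profile(self._sites([50]), genome, "TSS")


class TestSorfs:
    def test_minimal_orf_counted(self):
        seq = "AUG" + "GCU" * 20 + "UAA"
        (orf,) = find_sorfs(seq)
        assert orf.aa_length == 21
        assert orf.start_offset == 0 and orf.end_offset == len(seq) - 1

    def test_no_start_no_orf(self):
        assert find_sorfs("GCU" * 30) == []

    def test_below_minimum_dropped(self):
        seq = "AUG" + "GCU" * 10 + "UAA"
        assert find_sorfs(seq) == []
        assert len(find_sorfs(seq, min_aa=5)) == 1

    def test_nested_starts_keep_longest(self):
        seq = "AUG" + "GCU" * 5 + "AUG" + "GCU" * 25 + "UGA"
        out = find_sorfs(seq, min_aa=20)
        assert len(out) == 1
        assert out[0].start_offset == 0  # earliest AUG wins the shared stop

    def test_matches_regex_oracle(self, rng):
        for _ in range(30):
            seq = "".join(rng.choice(list("ACGU"), size=400))
            mine = [(o.frame, o.start_offset, o.end_offset, o.aa_length)
                    for o in find_sorfs(seq, min_aa=5)]
            assert sorted(mine) == regex_sorfs(seq, min_aa=5)


class TestGgaMotifs:
    def test_single_unpaired(self):
        assert count_gga_motifs("GGA", "...") == {
            "unpaired": 1, "partially_paired": 0, "paired": 0}

    def test_partially_paired_pair(self):
        assert count_gga_motifs("GGAGGA", "((.)).") == {
            "unpaired": 0, "partially_paired": 2, "paired": 0}

    def test_overlapping_occurrences_counted(self):
        assert count_gga_motifs("GGGA", "....")["unpaired"] == 1
        assert count_gga_motifs("GGAGGAGGA", "." * 9)["unpaired"] == 3

    def test_unbalanced_structure_rejected(self):
        with pytest.raises(ValueError):
            count_gga_motifs("GGA", "((.")
        with pytest.raises(ValueError):
            count_gga_motifs("GGA", ".))")

    def test_matches_brute_scan(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 60))
            seq = "".join(rng.choice(list("ACGU"), size=n, p=[0.2, 0.2, 0.4, 0.2]))
            # random balanced structure: pair random disjoint positions
            struct = ["."] * n
            for _ in range(int(rng.integers(0, n // 4))):
                i, j = sorted(rng.choice(n, size=2, replace=False))
                if all(struct[k] == "." for k in (i, j)) and j > i:
                    struct[i], struct[j] = "(", ")"
            struct = "".join(struct)
            got = count_gga_motifs(seq, struct)
            expected = {"unpaired": 0, "partially_paired": 0, "paired": 0}
            for i in range(n - 2):
                if seq[i : i + 3] == "GGA":
                    u = struct[i : i + 3].count(".")
                    key = {3: "unpaired", 0: "paired"}.get(u, "partially_paired")
                    expected[key] += 1
            assert got == expected
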