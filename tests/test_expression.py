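import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from srnascape.expression import (
    DirectRelationCall,
    TargetParams,
    classify_direct_relations,
    compute_tpm,
    differential_expression,
    duplex_score,
    extract_gene_windows,
    predict_trans_targets,
    scan_csra_targets,
    top_expressed,
    tpm_table,
)
from srnascape.io import GeneAnnotation, GenomeRecord, reverse_complement
from srnascape.simulate import simulate_counts


class TestTpm:
    def test_hand_arithmetic(self):
        out = compute_tpm(np.array([10, 10]), np.array([100, 200]))
        assert out == pytest.approx([666666.6667, 333333.3333], rel=1e-6)

    def test_single_feature_gets_everything(self):
        assert compute_tpm(np.array([7]), np.array([123]))[0] == pytest.approx(1e6)

    def test_symmetry(self):
        out = compute_tpm(np.full(8, 3.0), np.full(8, 250.0))
        assert out == pytest.approx([1e6 / 8] * 8)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            compute_tpm(np.zeros(3), np.ones(3))

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.integers(0, 10_000), min_size=2, max_size=30))
    def test_sums_to_one_million(self, counts):
        counts = np.asarray(counts, float)
        if counts.sum() == 0:
            counts[0] = 1
        lengths = np.arange(1, len(counts) + 1) * 50.0
        assert compute_tpm(counts, lengths).sum() == pytest.approx(1e6, abs=1e-3)


class TestDifferentialExpression:
    def test_identical_replicates_all_ns(self):
        mat = pd.DataFrame(
            np.tile([[100.0], [50.0], [10.0]], (1, 6)),
            index=["a", "b", "c"],
            columns=[f"s{i}" for i in range(6)],
        )
        out = differential_expression(mat, ["A"] * 3 + ["B"] * 3)
        assert (out.status == "ns").all()
        assert out.log2fc.abs().max() == pytest.approx(0.0)

    def test_zero_feature_is_ns_with_p_one(self):
        mat = pd.DataFrame(
            np.vstack([np.zeros(6), np.full(6, 40.0) + np.arange(6)]),
            index=["zero", "ok"], columns=[f"s{i}" for i in range(6)],
        )
        out = differential_expression(mat, ["A"] * 3 + ["B"] * 3)
        assert out.loc["zero", "pvalue"] == 1.0
        assert out.loc["zero", "status"] == "ns"

    def test_planted_fold_change_recovered(self):
        # 4x up on a 10% minority so size factors stay anchored on the nulls
        lfc = np.zeros(300)
        lfc[:30] = 2.0
        counts, labels = simulate_counts(300, log2fc=lfc, seed=11)
        mat = pd.DataFrame(counts, index=[f"f{i}" for i in range(300)],
                           columns=[f"s{i}" for i in range(6)])
        out = differential_expression(mat, labels)
        planted = out.iloc[:30]
        assert np.median(planted.log2fc) == pytest.approx(2.0, abs=0.3)
        # planted features separate cleanly from the nulls in raw p
        assert np.median(planted.pvalue) < 0.05 < np.median(out.iloc[30:].pvalue)

    def test_bh_preserves_p_ordering(self):
        counts, labels = simulate_counts(100, log2fc=0.0, seed=3)
        mat = pd.DataFrame(counts, index=[f"f{i}" for i in range(100)],
                           columns=[f"s{i}" for i in range(6)])
        out = differential_expression(mat, labels)
        order = out.pvalue.argsort(kind="stable").to_numpy()
        padj_sorted = out.padj.to_numpy()[order]
        assert (np.diff(padj_sorted) >= -1e-12).all()

    def test_status_partition(self):
        counts, labels = simulate_counts(200, log2fc=1.5, seed=5)
        mat = pd.DataFrame(counts, index=[f"f{i}" for i in range(200)],
                           columns=[f"s{i}" for i in range(6)])
        out = differential_expression(mat, labels)
        assert set(out.status.unique()) <= {"up", "down", "ns"}
        up = (out.padj < 0.05) & (out.log2fc >= 1)
        assert ((out.status == "up") == up).all()

    def test_two_conditions_required(self):
        mat = pd.DataFrame(np.ones((3, 6)), columns=[f"s{i}" for i in range(6)])
        with pytest.raises(ValueError):
            differential_expression(mat, ["A"] * 6)


class TestTopExpressed:
    def _tpm(self, values):
        return pd.DataFrame(values, columns=["a1", "a2", "b1", "b2"])

    def test_identical_conditions_full_overlap(self):
        tpm = self._tpm(np.tile(np.arange(60, dtype=float)[:, None] + 1, (1, 4)))
        out = top_expressed(tpm, ["A", "A", "B", "B"], n=10)
        assert out["overlap_size"] == 10

    def test_disjoint_top_sets(self):
        values = np.zeros((40, 4))
        values[:20, :2] = 1000.0   # high in A only
        values[20:, 2:] = 1000.0   # high in B only
        tpm = self._tpm(values + 0.001)
        out = top_expressed(tpm, ["A", "A", "B", "B"], n=20)
        assert out["overlap_size"] == 0

    def test_row_order_never_matters(self, rng):
        values = rng.uniform(0, 100, size=(60, 4))
        tpm = self._tpm(values)
        tpm.index = [f"f{i}" for i in range(60)]
        out1 = top_expressed(tpm, ["A", "A", "B", "B"], n=15)
        shuffled = tpm.sample(frac=1.0, random_state=0)
        out2 = top_expressed(shuffled, ["A", "A", "B", "B"], n=15)
        assert out1["top"] == out2["top"]


class TestCsrAScan:
    def _genome_with_upstream(self, upstream):
        # gene CDS starts at position 101 on the + strand
        seq = "T" * (100 - len(upstream)) + upstream + "ATG" + "GCT" * 40 + "TAA"
        seq += "T" * 50
        genome = GenomeRecord("g", seq)
        ann = GeneAnnotation("gene1", "CDS", 101, 100 + 3 + 120 + 3, "+")
        return genome, [ann]

    def test_motif_at_minus_12_found(self):
        genome, anns = self._genome_with_upstream("C" * 8 + "AAGGA" + "C" * 12)
        df = scan_csra_targets(anns, genome)
        assert list(df.gene_id) == ["gene1"]
        assert df.motif_count.iloc[0] == 1

    def test_no_motif_no_candidate(self):
        genome, anns = self._genome_with_upstream("C" * 25)
        assert scan_csra_targets(anns, genome).empty

    def test_matches_regex_oracle_on_random_genes(self, rng):
        n = 20_000
        seq = "".join(rng.choice(list("ACGT"), size=n))
        genome = GenomeRecord("g", seq)
        anns = []
        for i in range(60):
            start = 200 + i * 300
            strand = "+" if i % 2 == 0 else "-"
            anns.append(GeneAnnotation(f"g{i}", "CDS", start, start + 150, strand))
        df = scan_csra_targets(anns, genome)
        got = dict(zip(df.gene_id, df.motif_count))
        pattern = re.compile("(?=A[ACGT]GGA)")
        for ann in anns:
            if ann.strand == "+":
                window = seq[ann.start - 26 : ann.start + 10]
            else:
                window = reverse_complement(seq[ann.end - 11 : ann.end + 25])
            expected = len(pattern.findall(window))
            assert got.get(ann.gene_id, 0) == expected, ann.gene_id


class TestDuplexScore:
    def test_perfect_complement_scores_by_pairs(self):
        # 10 GC + 10 AU pairs = 50; flanks cannot pair (A vs A)
        window = "A" + "G" * 10 + "U" * 10 + "A"
        srna = "U" + "A" * 10 + "C" * 10 + "U"  # revcomp of core, unpairable flanks?
        core_w = window[1:21]
        srna = "GG" + reverse_complement(core_w.replace("U", "T")).replace("T", "U") + "GG"
        hit = duplex_score(srna, window)
        assert hit is not None
        assert hit[0] == 50.0

    def test_poly_a_never_pairs(self):
        assert duplex_score("A" * 30, "A" * 50) is None

    def test_seed_length_enforced(self):
        # 6-pair duplex flanked by A:C mismatches on both sides
        window = "C" + "G" * 6 + "C" * 20
        srna = "A" + "C" * 6 + "A" * 3
        assert duplex_score(srna, window, TargetParams(seed_min=7)) is None
        assert duplex_score(srna, window, TargetParams(seed_min=5)) is not None

    def test_matches_brute_force(self, rng):
        params = TargetParams(seed_min=5)
        pair_score = {("A", "U"): 2.0, ("U", "A"): 2.0, ("G", "C"): 3.0,
                      ("C", "G"): 3.0, ("G", "U"): 1.0, ("U", "G"): 1.0}
        for _ in range(25):
            s = "".join(rng.choice(list("ACGU"), size=40))
            w = "".join(rng.choice(list("ACGU"), size=60))
            best = None
            for i in range(40):
                for j in range(60):
                    score, length = 0.0, 0
                    while i + length < 40 and j - length >= 0 and \
                            (s[i + length], w[j - length]) in pair_score:
                        score += pair_score[(s[i + length], w[j - length])]
                        length += 1
                    if length >= params.seed_min:
                        if best is None or score > best:
                            best = score
            got = duplex_score(s, w, params)
            assert (got[0] if got else None) == best

    def test_revcomp_exchange_symmetry(self, rng):
        params = TargetParams(seed_min=5)
        for _ in range(10):
            s = "".join(rng.choice(list("ACGU"), size=30))
            w = "".join(rng.choice(list("ACGU"), size=30))
            a = duplex_score(s, w, params)
            b = duplex_score(w, s, params)
            assert (a[0] if a else None) == (b[0] if b else None)


class TestTransTargets:
    def test_planted_target_ranks_first(self, rng):
        windows = {}
        for i in range(30):
            windows[f"g{i:02d}"] = "".join(rng.choice(list("ACGU"), size=100))
        target = windows["g07"]
        seg = target[40:60]
        srna = ("".join(rng.choice(list("ACGU"), size=20))
                + reverse_complement(seg.replace("U", "T")).replace("T", "U")
                + "".join(rng.choice(list("ACGU"), size=20)))
        preds = predict_trans_targets(srna, windows, "sX")
        assert preds[0].target_gene_id == "g07"
        assert preds[0].rank == 1
        ranks = [p.rank for p in preds]
        assert ranks == list(range(1, len(preds) + 1))

    def test_gene_window_extraction_strand_aware(self):
        seq = "A" * 300 + "ATGCCC" + "A" * 300
        genome = GenomeRecord("g", seq)
        ann_fwd = GeneAnnotation("f", "CDS", 301, 306, "+")
        ann_rev = GeneAnnotation("r", "CDS", 301, 306, "-")
        wins = extract_gene_windows([ann_fwd, ann_rev], genome, window=(-3, 3))
        # inclusive offsets -3..+3 around the first base of the start codon
        assert wins["f"] == "AAAAUGC"
        assert wins["r"] == "UUUGGGC"


class TestDirectRelations:
    class FakeSrna:
        def __init__(self, id, location_class, same=(), opposite=()):
            self.id = id
            self.location_class = location_class
            self.same_strand_gene_ids = same
            self.antisense_gene_ids = opposite

    def test_three_criteria(self):
        srnas = [
            self.FakeSrna("s1", "intra", same=("alkB1",)),
            self.FakeSrna("s2", "as", opposite=("alkB1",)),
            self.FakeSrna("s3", "inter"),
        ]
        from srnascape.expression import InteractionPrediction

        interactions = {
            "s3": [InteractionPrediction("s3", "alkB1", 40.0, (0, 10), (0, 10), rank=3)],
        }
        calls = classify_direct_relations(srnas, ["alkB1"], interactions)
        by_id = {c.srna_id: c.criteria for c in calls}
        assert by_id == {"s1": ("i",), "s2": ("ii",), "s3": ("iii",)}
        # tightening top_k drops criterion iii
        calls2 = classify_direct_relations(srnas, ["alkB1"], interactions, top_k=2)
        assert {c.srna_id for c in calls2} == {"s1", "s2"}

    def test_unknown_key_gene_rejected(self):
        with pytest.raises(ValueError):
            classify_direct_relations([], ["ghost"], {}, known_gene_ids=["real"])
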