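"""Sequence features: GC, folding, CAI, TOP score, uORFs, group statistics."""

import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from polytome.errors import ConfigurationError, DataError
from polytome.seqfeatures import (
    TOP_SCORE_VERSION,
    TranscriptRecord,
    cai,
    detect_top_motif,
    detect_uorfs,
    feature_group_stats,
    feature_table,
    fold_mfe_per_bp,
    gc_content,
    load_human_codon_usage,
    nussinov_max_pairs,
    select_representative_transcript,
    top_local_score,
    top_rna_overlap,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GCGC", 1.0), ("ATAT", 0.0), ("GCAT", 0.5), ("GCATN", 0.5)],
    )
    def test_examples(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_all_n_undefined(self):
        assert np.isnan(gc_content("NNN"))

    @given(dna)
    def test_reverse_and_complement_invariance(self, seq):
        assert gc_content(seq[::-1]) == pytest.approx(gc_content(seq))
        comp = seq.translate(str.maketrans("ACGT", "TGCA"))
        assert gc_content(comp) == pytest.approx(gc_content(seq))


def _brute_force_pairs(seq, min_loop=3, wobble=True):
    """Exhaustive enumeration of nested pairings (oracle for <=12-mers)."""
    pairs = {"AT", "TA", "GC", "CG"} | ({"GT", "TG"} if wobble else set())

    def best(i, j):
        if j - i < min_loop + 1:
            return 0
        score = best(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if seq[i] + seq[k] in pairs:
                score = max(score, 1 + best(i + 1, k - 1) + best(k + 1, j))
        return score

    return best(0, len(seq) - 1)


class TestFolding:
    def test_unpairable_sequence(self):
        assert fold_mfe_per_bp("AAAAAAAA") == pytest.approx(0.0)

    def test_simple_hairpin(self):
        # GGG AAAA CCC: three G-C pairs around a 4-nt loop
        assert nussinov_max_pairs("GGGAAAACCC") == 3
        assert fold_mfe_per_bp("GGGAAAACCC") == pytest.approx(-0.3)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(12)
        for n in (8, 10, 12):
            for _ in range(20):
                seq = "".join(rng.choice(list("ACGT"), n))
                assert nussinov_max_pairs(seq) == _brute_force_pairs(seq)

    def test_wc_only_mode_reverse_complement_symmetric(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), 10))
            rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
            assert nussinov_max_pairs(seq, wobble=False) == nussinov_max_pairs(rc, wobble=False)

    def test_too_short_rejected(self):
        with pytest.raises(DataError):
            fold_mfe_per_bp("ACG")

    def test_unknown_engine_rejected(self):
        with pytest.raises(ConfigurationError):
            fold_mfe_per_bp("ACGUACGU", engine="mfold")


class TestCai:
    def test_uniform_usage_gives_one(self):
        usage = {c: 1.0 for c in load_human_codon_usage()}
        assert cai("ATGGCTGCCTAA", usage) == pytest.approx(1.0)

    def test_two_codon_toy(self):
        usage = {"GCT": 0.8, "GCC": 0.2}
        assert cai("ATGGCTGCCTAA", usage) == pytest.approx(0.5)

    def test_maximal_codons_give_one(self):
        usage = load_human_codon_usage()
        # CTG and GAG are the most used codons of Leu and Glu
        assert cai("ATGCTGGAGTAA", usage) == pytest.approx(1.0)

    def test_internal_stop_warns_and_truncates(self):
        usage = {"GCT": 0.8, "GCC": 0.2}
        with pytest.warns(UserWarning, match="internal stop"):
            value = cai("ATGGCTTAAGCCGCCTAA", usage)
        assert value == pytest.approx(1.0)  # only GCT scored

    def test_synonymous_recoding_to_equal_w_invariant(self):
        usage = {"GCT": 0.5, "GCC": 0.5, "CTG": 1.0}
        assert cai("ATGGCTTAA", usage) == pytest.approx(cai("ATGGCCTAA", usage))

    def test_packaged_table_complete(self):
        usage = load_human_codon_usage()
        assert len(usage) == 64
        assert all(v > 0 for v in usage.values())


def _brute_top_score(seq, anchor_max=5, window=50):
    seq = seq[:window]
    vals = [1 if b in "CT" else -1 for b in seq]
    best = 0
    for s in range(min(anchor_max, len(seq))):
        for e in range(s + 1, len(seq) + 1):
            best = max(best, sum(vals[s:e]))
    return best


class TestTopScore:
    def test_pure_pyrimidine_run(self):
        assert top_local_score("CTTTTTCC" + "G" * 20) == 8

    def test_all_purines_floored_at_zero(self):
        assert top_local_score("G" * 30) == 0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), 50))
            assert top_local_score(seq) == _brute_top_score(seq)

    @given(dna.filter(lambda s: len(s) >= 10))
    def test_pyrimidine_substitution_never_decreases(self, seq):
        base = top_local_score(seq)
        idx = next((i for i, b in enumerate(seq[:50]) if b in "AG"), None)
        if idx is not None:
            improved = seq[:idx] + "C" + seq[idx + 1 :]
            assert top_local_score(improved) >= base


class TestTopMotif:
    @pytest.mark.parametrize(
        "seq,expected",
        [("CTTTTGAA", True), ("ACTTTTGG", False), ("CTTAGAAA", False),
         ("CCCCC", True), ("TTTTT", False)],
    )
    def test_examples(self, seq, expected):
        assert detect_top_motif(seq) is expected

    @given(dna.filter(lambda s: len(s) >= 5))
    def test_motif_implies_score_at_least_k(self, seq):
        if detect_top_motif(seq, min_run=5):
            assert top_local_score(seq) >= 5


_UORF_RE = re.compile(r"(?=(ATG(?:[ACGT]{3})*?(?:TAA|TAG|TGA)))")


def _brute_uorfs(seq, min_codons=3):
    out = []
    for m in _UORF_RE.finditer(seq):
        orf = m.group(1)
        if len(orf) // 3 >= min_codons:
            out.append((m.start(), m.start() + len(orf)))
    return out


class TestUorfs:
    def test_embedded_uorf(self):
        utr = "GGCC" + "ATGAAATAA" + "GGCC"
        assert detect_uorfs(utr) == [(4, 13)]

    def test_no_atg(self):
        assert detect_uorfs("CCTTTTGGGTTT") == []

    def test_orf_must_fit_in_utr(self):
        assert detect_uorfs("CCATGAAATA") == []  # stop codon truncated

    def test_min_codons_respected(self):
        assert detect_uorfs("ATGTAA", min_codons=3) == []
        assert detect_uorfs("ATGTAA", min_codons=2) == [(0, 6)]

    def test_matches_regex_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            seq = "".join(rng.choice(list("ACGT"), 200))
            assert detect_uorfs(seq) == _brute_uorfs(seq)

    def test_min_codons_validated(self):
        with pytest.raises(ConfigurationError):
            detect_uorfs("ATGTAA", min_codons=1)


class TestRepresentativeTranscript:
    @staticmethod
    def _rec(tid, cds_codons, level=1):
        return TranscriptRecord(tid, "G1", "CCAA", "ATG" + "GCT" * cds_codons + "TAA",
                                "AATT", annotation_level=level)

    def test_single_transcript(self):
        t = self._rec("t1", 5)
        assert select_representative_transcript([t]) is t

    def test_highest_abundance_wins(self):
        a, b = self._rec("t1", 5), self._rec("t2", 5)
        chosen = select_representative_transcript([a, b], {"t1": 5.0, "t2": 10.0})
        assert chosen is b

    def test_abundance_tie_breaks_on_cds_length(self):
        a, b = self._rec("t1", 100), self._rec("t2", 200)
        chosen = select_representative_transcript([a, b], {"t1": 10.0, "t2": 10.0})
        assert chosen is b

    def test_without_abundance_best_annotation_level(self):
        a, b = self._rec("t1", 100, level=2), self._rec("t2", 50, level=1)
        assert select_representative_transcript([a, b]) is b

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            select_representative_transcript([])


class TestFeatureTable:
    def test_row_contents(self):
        rec = TranscriptRecord(
            "t1", "G1",
            utr5="CTTTTTCC" + "ATGAAATAA" + "GCGCGCGCGC",
            cds="ATG" + "GCT" * 10 + "TAA",
            utr3="AT" * 30,
        )
        df = feature_table([rec], usage={"GCT": 1.0}, ires_genes=["G1"])
        row = df.loc["G1"]
        assert row["len5"] == 27 and row["len3"] == 60
        assert row["n_uorf"] == 1
        assert row["has_top_motif"] and row["has_ires"]
        assert row["top_local_score"] >= 8
        assert row["mfe3_bp"] <= 0
        assert row["engine"] == "nussinov"
        assert row["top_score_version"] == TOP_SCORE_VERSION


class TestGroupStats:
    @staticmethod
    def _features(values, labels):
        idx = [f"g{i}" for i in range(len(values))]
        feats = pd.DataFrame({"len5": values}, index=idx)
        return feats, pd.Series(labels, index=idx)

    def test_two_group_kw_equals_squared_ranksum_z(self):
        rng = np.random.default_rng(0)
        x = rng.permutation(np.arange(40, dtype=float))  # tie-free
        feats, groups = self._features(x, ["a"] * 20 + ["b"] * 20)
        out = feature_group_stats(feats, groups, feature_cols=["len5"])
        H = out["overall"]["H"].iloc[0]
        z = stats.ranksums(x[:20], x[20:]).statistic
        assert H == pytest.approx(z**2)
        # Dunn z on two groups agrees with the rank-sum z up to sign
        assert abs(out["pairwise"]["z"].iloc[0]) == pytest.approx(abs(z))

    def test_strong_shift_detected(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 1, 30), rng.normal(5, 1, 30)])
        feats, groups = self._features(x, ["a"] * 30 + ["b"] * 30)
        out = feature_group_stats(feats, groups)
        assert out["pairwise"]["p_adj"].iloc[0] < 1e-6

    def test_null_p_uniform_under_permutation(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, 45)
        ps = []
        for _ in range(200):
            labels = rng.permutation(["a"] * 15 + ["b"] * 15 + ["c"] * 15)
            feats, groups = self._features(x, labels)
            out = feature_group_stats(feats, groups)
            ps.append(out["overall"]["p"].iloc[0])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_feature_reported_na(self):
        feats, groups = self._features(np.ones(20), ["a"] * 10 + ["b"] * 10)
        out = feature_group_stats(feats, groups)
        assert np.isnan(out["overall"]["H"].iloc[0])

    def test_too_few_groups_rejected(self):
        feats, groups = self._features(np.arange(4), ["a"] * 4)
        with pytest.raises(DataError):
            feature_group_stats(feats, groups)


class TestTopRnaOverlap:
    def test_identical_sets(self):
        out = top_rna_overlap({"c1": {"a", "b"}}, {"a", "b"})
        row = out["table"].iloc[0]
        assert row["fraction_of_known"] == 1.0
        assert row["fraction_of_cluster"] == 1.0
        assert out["candidates"].empty

    def test_disjoint(self):
        out = top_rna_overlap({"c1": {"x"}}, {"a"})
        assert out["table"].iloc[0]["n_known_top"] == 0

    def test_candidates_ranked_by_score(self):
        out = top_rna_overlap(
            {"c1": {"a", "b", "known"}}, {"known"}, scores={"a": 3, "b": 9}
        )
        assert list(out["candidates"]["gene_id"]) == ["b", "a"]

    def test_empty_known_list_rejected(self):
        with pytest.raises(ConfigurationError):
            top_rna_overlap({"c1": {"a"}}, set())
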