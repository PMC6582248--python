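"""NG86 site counting, pathway-averaged differences and Ka/Ks estimation."""

import math
from itertools import permutations, product

import pytest
from Bio.Seq import Seq

from triadscope.errors import FormatError, ValidationError
from triadscope.kaks import (
    STANDARD_CODE,
    CodonAlignment,
    codon_differences,
    codon_sites,
    jukes_cantor,
    ng86,
    pair_kaks_table,
)

SENSE_CODONS = STANDARD_CODE.sense_codons


def oracle_translate(codon: str) -> str:
    """Independent translation route (Biopython Seq)."""
    return str(Seq(codon).translate())


def oracle_differences(c1: str, c2: str):
    """Brute-force pathway enumerator, independent of the implementation."""
    positions = [i for i in range(3) if c1[i] != c2[i]]
    results = []
    for order in permutations(positions):
        cur, sd, nd = c1, 0, 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if oracle_translate(nxt) == "*":
                blocked = True
                break
            if oracle_translate(nxt) == oracle_translate(cur):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if not blocked:
            results.append((sd, nd))
    if not results:
        return None
    return (
        sum(r[0] for r in results) / len(results),
        sum(r[1] for r in results) / len(results),
    )


class TestCodonSites:
    @pytest.mark.parametrize(
        "codon,s",
        [("GGG", 1.0), ("ATG", 0.0), ("AAA", 1 / 3)],
    )
    def test_hand_counted_examples(self, codon, s):
        got_s, got_n = codon_sites(codon)
        assert got_s == pytest.approx(s)
        assert got_n == pytest.approx(3.0 - s)

    def test_stop_and_ambiguous_codons_rejected(self):
        for bad in ("TAA", "TAG", "TGA", "ANA", "AC"):
            with pytest.raises(ValidationError):
                codon_sites(bad)

    def test_sites_sum_to_three_for_all_sense_codons(self):
        for codon in SENSE_CODONS:
            s, n = codon_sites(codon)
            assert s + n == pytest.approx(3.0)
            assert 0.0 <= s <= 3.0


class TestCodonDifferences:
    @pytest.mark.parametrize(
        "c1,c2,expected",
        [
            ("TTT", "TTT", (0.0, 0.0)),
            ("GGG", "GGA", (1.0, 0.0)),
            # two pathways: via GTT (1 syn, 1 nonsyn) and via TTA (0 syn, 2 nonsyn)
            ("TTT", "GTA", (0.5, 1.5)),
        ],
    )
    def test_hand_enumerated_examples(self, c1, c2, expected):
        assert codon_differences(c1, c2) == pytest.approx(expected)

    def test_symmetric_in_arguments(self):
        for c1, c2 in [("TTT", "GTA"), ("ATG", "CCC"), ("AAA", "AGG")]:
            assert codon_differences(c1, c2) == pytest.approx(
                codon_differences(c2, c1)
            )

    def test_matches_oracle_on_spot_checks(self):
        # the exhaustive 61x61 sweep lives in the acceptance suite
        pairs = [("TGG", "CGC"), ("TCA", "ATG"), ("AGA", "CGG"), ("TTA", "CAC")]
        for c1, c2 in pairs:
            expected = oracle_differences(c1, c2)
            assert codon_differences(c1, c2) == pytest.approx(expected)

    def test_sd_nd_sum_to_mismatch_count_when_unblocked(self):
        # none of these pairs has a stop codon on any mutational pathway
        for c1, c2 in [("AAA", "CCC"), ("ATG", "ATA"), ("GGG", "CCC")]:
            k = sum(a != b for a, b in zip(c1, c2))
            sd, nd = codon_differences(c1, c2)
            assert sd + nd == pytest.approx(k)


class TestJukesCantor:
    def test_closed_form_values(self):
        assert jukes_cantor(0.0) == 0.0
        assert jukes_cantor(0.5) == pytest.approx(-0.75 * math.log(1 / 3))

    def test_saturation_boundary(self):
        assert jukes_cantor(0.75) is None
        assert jukes_cantor(0.9) is None

    def test_domain_validation(self):
        for p in (-0.1, 1.5):
            with pytest.raises(ValidationError):
                jukes_cantor(p)

    def test_monotone_below_saturation(self):
        ps = [0.0, 0.1, 0.3, 0.5, 0.7]
        ds = [jukes_cantor(p) for p in ps]
        assert ds == sorted(ds)
        assert all(d >= p for p, d in zip(ps, ds))


class TestNg86:
    def test_identical_pair_is_all_zero_with_clear_flags(self):
        seq = "".join(SENSE_CODONS[i % 61] for i in range(300))
        res = ng86(CodonAlignment(seq, seq))
        assert (res.Ka, res.Ks) == (0.0, 0.0)
        assert res.ratio is None
        assert not (res.saturated_s or res.saturated_n or res.zero_ks)

    def test_two_codon_hand_example_saturates_synonymous(self):
        res = ng86(CodonAlignment("GGGAAA", "GGAAAA"))
        assert res.S == pytest.approx(4 / 3)
        assert res.N == pytest.approx(14 / 3)
        assert (res.Sd, res.Nd) == (1.0, 0.0)
        assert res.pS == pytest.approx(0.75)
        assert res.saturated_s and res.Ks is None

    def test_symmetric_under_sequence_swap(self):
        a = "ATGGCCAAATTTGGGCACGGA"
        b = "ATGGCAAAGTTCGGACATGGC"
        r1 = ng86(CodonAlignment(a, b))
        r2 = ng86(CodonAlignment(b, a))
        assert (r1.S, r1.N, r1.Sd, r1.Nd, r1.Ka, r1.Ks) == (
            r2.S, r2.N, r2.Sd, r2.Nd, r2.Ka, r2.Ks
        )

    def test_concatenation_consistency(self):
        p1 = CodonAlignment("ATGGCCAAA", "ATGGCAAAG")
        p2 = CodonAlignment("TTTGGGCAC", "TTCGGACAT")
        cat = CodonAlignment(p1.seq1 + p2.seq1, p1.seq2 + p2.seq2)
        r1, r2, rc = ng86(p1), ng86(p2), ng86(cat)
        assert rc.S == pytest.approx(r1.S + r2.S)
        assert rc.N == pytest.approx(r1.N + r2.N)
        assert rc.Sd == pytest.approx(r1.Sd + r2.Sd)
        assert rc.Nd == pytest.approx(r1.Nd + r2.Nd)

    def test_gapped_codons_skipped_pairwise(self):
        full = ng86(CodonAlignment("ATGGCC", "ATGGCA"))
        gapped = ng86(CodonAlignment("ATG---GCC", "ATGTTTGCA"))
        assert gapped.n_codons == 2
        assert (gapped.S, gapped.Sd) == (full.S, full.Sd)

    def test_sites_sum_to_compared_length(self):
        pair = CodonAlignment("ATGGCCAAATTT", "ATGGCAAAGTTC")
        res = ng86(pair)
        assert res.S + res.N == pytest.approx(3 * res.n_codons)

    @pytest.mark.parametrize(
        "s1,s2,msg",
        [
            ("ATGGC", "ATGGC", "divisible"),
            ("ATGGCC", "ATG", "mismatch"),
            ("ATGTAAGCC", "ATGGCAGCC", "stop"),
        ],
    )
    def test_alignment_validation(self, s1, s2, msg):
        with pytest.raises(ValidationError, match=msg):
            CodonAlignment(s1, s2)


class TestPairKaksTable:
    def _write(self, tmp_path, seqs, manifest_rows):
        fasta = tmp_path / "pairs.fasta"
        fasta.write_text("".join(f">{k}\n{v}\n" for k, v in seqs.items()))
        man = tmp_path / "pairs.tsv"
        man.write_text(
            "pair_id\tid1\tid2\tgroup\n"
            + "".join("\t".join(r) + "\n" for r in manifest_rows)
        )
        return fasta, man

    def test_identical_pairs_give_zero_rows(self, tmp_path):
        seq = "ATGGCCAAATTTGGGCAC"
        fasta, man = self._write(
            tmp_path,
            {"a1": seq, "a2": seq, "b1": seq, "b2": seq},
            [("p1", "a1", "a2", "g"), ("p2", "b1", "b2", "g")],
        )
        results, groups = pair_kaks_table(fasta, man)
        assert len(results) == 2
        assert (results[["Sd", "Nd", "Ka", "Ks"]] == 0).all().all()
        assert results["ratio"].isna().all()
        assert groups.loc[0, "n_undefined"] == 2

    def test_empty_manifest_gives_empty_table(self, tmp_path):
        fasta, man = self._write(tmp_path, {"a": "ATG"}, [])
        results, groups = pair_kaks_table(fasta, man)
        assert results.empty and groups.empty

    def test_unmatched_id_is_manifest_error(self, tmp_path):
        fasta, man = self._write(
            tmp_path, {"a1": "ATGGCC"}, [("p1", "a1", "missing", "g")]
        )
        with pytest.raises(FormatError, match="missing"):
            pair_kaks_table(fasta, man)
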