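import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bexplore.errors import ConfigError
from bexplore.io import GenomeIndex
from bexplore.offtarget import (OffTargetHit, cfd_score, default_cfd_table,
                                find_offtargets, load_cfd_table,
                                offtarget_feature, uniform_cfd_table)
from bexplore.screening import CandidateGuide
from bexplore._seq import revcomp

from ._oracles import brute_offtargets
from .conftest import random_genome

PROTO = "GATCAGTCCATGACGTTACC"


def _guide(genome: GenomeIndex, chrom="chr1", start=1) -> CandidateGuide:
    return CandidateGuide(f"{chrom}:{start}", "+", PROTO, "AGG",
                          start, start + len(PROTO) - 1, 5, chrom=chrom)


def _hit(seq: str, pam: str = "AGG", start: int = 100) -> OffTargetHit:
    return OffTargetHit("chr1", start, start + len(seq) - 1, "+", seq, pam,
                        sum(a != b for a, b in zip(seq, PROTO)))


class TestFindOfftargets:
    def test_exact_duplicate_found_on_target_excluded(self):
        seq = PROTO + "AGG" + "TTTT" + PROTO + "AGG"
        genome = GenomeIndex({"chr1": seq})
        guide = _guide(genome, start=1)
        hits = find_offtargets(guide, genome, max_mm=0, pam_policy="strict",
                               pam_pattern="NGG")
        assert len(hits) == 1
        assert (hits[0].start, hits[0].n_mismatches) == (28, 0)

    def test_mismatch_budget_is_respected(self):
        decoy = "TTTCAGTCCATGACGTTACG"      # 3 substitutions vs PROTO
        assert sum(a != b for a, b in zip(decoy, PROTO)) == 3
        genome = GenomeIndex({"chr1": PROTO + "AGG" + "AT" + decoy + "TGG"})
        guide = _guide(genome)
        assert find_offtargets(guide, genome, max_mm=2,
                               pam_pattern="NGG") == []
        hits = find_offtargets(guide, genome, max_mm=3, pam_pattern="NGG")
        assert len(hits) == 1 and hits[0].n_mismatches == 3

    def test_hits_match_bruteforce_scan_on_random_genome(self, rng):
        genome = random_genome(rng, 10_000)
        guide = _guide(genome)
        for policy, patterns in [("any", None), ("strict", ["NGG"]),
                                 ("relaxed", ["NGG", "NAG"])]:
            for max_mm in (0, 2, 4):
                hits = find_offtargets(guide, genome, max_mm=max_mm,
                                       pam_policy=policy, pam_pattern="NGG")
                got = {(h.chrom, h.start, h.end, h.strand, h.n_mismatches)
                       for h in hits}
                want = brute_offtargets(genome.sequences, PROTO, max_mm,
                                        patterns,
                                        exclude=("chr1", 1, 20, "+"))
                assert got == want

    def test_monotone_in_mismatch_budget(self, rng):
        genome = random_genome(rng, 8_000)
        guide = _guide(genome)
        previous: set = set()
        for max_mm in range(5):
            hits = {(h.start, h.end, h.strand)
                    for h in find_offtargets(guide, genome, max_mm=max_mm,
                                             pam_policy="any")}
            assert previous <= hits
            previous = hits

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_strand_symmetry(self, seed):
        """Reverse-complementing the genome mirrors the hit set."""
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=600))
        fwd = GenomeIndex({"chr1": seq})
        rev = GenomeIndex({"chr1": revcomp(seq)})
        guide = CandidateGuide("q", "+", PROTO, "AGG", 10**6, 10**6 + 19, 5,
                               chrom="chrQ")      # off-genome: nothing excluded
        n = len(seq)
        fwd_hits = {(n - h.end + 1, n - h.start + 1,
                     "-" if h.strand == "+" else "+")
                    for h in find_offtargets(guide, fwd, max_mm=4,
                                             pam_policy="any")}
        rev_hits = {(h.start, h.end, h.strand)
                    for h in find_offtargets(guide, rev, max_mm=4,
                                             pam_policy="any")}
        assert fwd_hits == rev_hits

    def test_empty_genome_no_hits(self):
        genome = GenomeIndex({"chr1": "ACGT"})
        assert find_offtargets(_guide(genome), genome, max_mm=4,
                               pam_policy="any") == []


class TestCfdScore:
    def test_perfect_match_canonical_pam_scores_one(self, uniform_table):
        assert cfd_score(PROTO, _hit(PROTO, "AGG"), uniform_table) == 1.0

    def test_single_mismatch_equals_table_entry(self, uniform_table):
        mutated = "T" + PROTO[1:]
        assert cfd_score(PROTO, _hit(mutated), uniform_table) == \
            pytest.approx(0.5)

    def test_two_mismatches_multiply(self, uniform_table):
        mutated = "T" + PROTO[1:10] + "A" + PROTO[11:]
        assert mutated[10] != PROTO[10]
        assert cfd_score(PROTO, _hit(mutated), uniform_table) == \
            pytest.approx(0.5 * 0.5)

    def test_default_table_position_specific_product(self):
        table = default_cfd_table()
        mutated = PROTO[:4] + ("A" if PROTO[4] != "A" else "G") + PROTO[5:]
        expected = table.mismatch(5, PROTO[4], mutated[4]) * table.pam("AGG")
        assert cfd_score(PROTO, _hit(mutated), table) == pytest.approx(expected)

    def test_missing_entry_is_config_error(self):
        table = uniform_cfd_table()
        table.mismatch_penalties.pop((1, "G", "T"))
        with pytest.raises(ConfigError, match="no entry"):
            cfd_score(PROTO, _hit("T" + PROTO[1:]), table)

    def test_table_file_roundtrip(self, tmp_path):
        table = default_cfd_table()
        lines = ["position\tquery_base\tgenomic_base\tmultiplier"]
        for (pos, q, g), m in table.mismatch_penalties.items():
            lines.append(f"{pos}\t{q}\t{g}\t{m}")
        for pam, m in table.pam_penalties.items():
            lines.append(f"0\t{pam}\t-\t{m}")
        p = tmp_path / "table.tsv"
        p.write_text("\n".join(lines) + "\n")
        reloaded = load_cfd_table(p)
        assert reloaded.mismatch_penalties == table.mismatch_penalties
        assert reloaded.pam_penalties == table.pam_penalties


class TestOfftargetFeature:
    def test_no_hits_scores_zero(self, uniform_table):
        genome = GenomeIndex({"chr1": PROTO + "AGG" + "T" * 30})
        guide = _guide(genome)
        assert offtarget_feature(guide, genome, table=uniform_table,
                                 pam_pattern="NGG") == 0.0

    def test_mean_of_hit_scores(self, uniform_table):
        one_mm = "T" + PROTO[1:]
        seq = PROTO + "AGG" + "TT" + PROTO + "AGG" + "TT" + one_mm + "AGG"
        genome = GenomeIndex({"chr1": seq})
        guide = _guide(genome)
        # hits: exact duplicate (1.0) and one-mismatch copy (0.5)
        assert offtarget_feature(guide, genome, max_mm=4, table=uniform_table,
                                 pam_pattern="NGG") == pytest.approx(0.75)
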