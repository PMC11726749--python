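import numpy as np
import pytest

from mrpipe.gwas_io import LDMatrix
from mrpipe.instruments import (
    InstrumentConfig,
    clump,
    compute_f_statistics,
    harmonize,
    select_by_pvalue,
)

from conftest import make_assoc

CFG = InstrumentConfig()


class TestSelectByPvalue:
    def test_boundary_is_inclusive(self):
        recs = [make_assoc(snp_id=f"rs{i}", pval=p)
                for i, p in enumerate([1e-6, 5e-5, 6e-5])]
        kept = select_by_pvalue(recs, CFG)
        assert [r.snp_id for r in kept] == ["rs0", "rs1"]

    def test_empty_input(self):
        assert select_by_pvalue([], CFG) == []

    def test_matches_brute_force_and_is_idempotent(self, rng):
        recs = [make_assoc(snp_id=f"rs{i}", pval=float(p))
                for i, p in enumerate(rng.uniform(1e-8, 1e-3, size=100))]
        kept = select_by_pvalue(recs, CFG)
        assert kept == [r for r in recs if r.pval <= 5e-5]
        assert select_by_pvalue(kept, CFG) == kept


def _ld(ids, pos, r2):
    return LDMatrix(snp_ids=tuple(ids), r2=np.asarray(r2, float),
                    pos=tuple(pos))


class TestClump:
    def test_more_significant_snp_dominates(self):
        a = make_assoc(snp_id="rs1", pos=1000, pval=1e-8)
        b = make_assoc(snp_id="rs2", pos=2000, pval=1e-6)
        ld = _ld(["rs1", "rs2"], [1000, 2000], [[1, 0.5], [0.5, 1]])
        kept = clump([a, b], ld, CFG)
        assert [r.snp_id for r in kept] == ["rs1"]

    def test_outside_window_both_retained(self):
        a = make_assoc(snp_id="rs1", pos=1000, pval=1e-8)
        b = make_assoc(snp_id="rs2", pos=1000 + 20_000_000, pval=1e-6)
        ld = _ld(["rs1", "rs2"], [a.pos, b.pos], [[1, 0.5], [0.5, 1]])
        assert len(clump([a, b], ld, CFG)) == 2

    def test_different_chromosome_not_clumped(self):
        a = make_assoc(snp_id="rs1", chrom="1", pos=1000, pval=1e-8)
        b = make_assoc(snp_id="rs2", chrom="2", pos=2000, pval=1e-6)
        ld = _ld(["rs1", "rs2"], [1000, 2000], [[1, 0.9], [0.9, 1]])
        assert len(clump([a, b], ld, CFG)) == 2

    def test_missing_snp_in_ld_raises(self):
        a = make_assoc(snp_id="rs1")
        ld = _ld(["rsX"], [1], [[1.0]])
        with pytest.raises(KeyError, match="rs1"):
            clump([a], ld, CFG)

    @staticmethod
    def _oracle(assocs, ld, cfg):
        """Independent exhaustive greedy re-implementation."""
        remaining = {a.snp_id: a for a in assocs}
        kept = []
        while remaining:
            idx = min(remaining.values(),
                      key=lambda r: (r.pval, r.chrom, r.pos, r.snp_id))
            kept.append(idx)
            del remaining[idx.snp_id]
            i = ld.snp_ids.index(idx.snp_id)
            for other in list(remaining.values()):
                j = ld.snp_ids.index(other.snp_id)
                close = (other.chrom == idx.chrom
                         and abs(other.pos - idx.pos) <= cfg.clump_window_kb * 1000)
                if close and ld.r2[i, j] > cfg.clump_r2:
                    del remaining[other.snp_id]
        return sorted(kept, key=lambda r: (r.chrom, r.pos, r.snp_id))

    def test_matches_exhaustive_greedy_oracle(self, rng):
        for trial in range(10):
            k = 10
            pos = np.sort(rng.integers(1, 30_000_000, size=k))
            a = rng.uniform(0, 1, size=(k, k))
            r2 = np.clip((a + a.T) / 2, 0, 0.999)
            np.fill_diagonal(r2, 1.0)
            recs = [make_assoc(snp_id=f"rs{i}", pos=int(pos[i]),
                               pval=float(rng.uniform(1e-9, 1e-4)))
                    for i in range(k)]
            ld = _ld([r.snp_id for r in recs], pos, r2)
            got = clump(recs, ld, CFG)
            assert got == self._oracle(recs, ld, CFG)

    def test_output_invariant_to_input_permutation(self, rng):
        k = 8
        pos = np.sort(rng.integers(1, 5_000_000, size=k))
        a = rng.uniform(0, 1, size=(k, k))
        r2 = np.clip((a + a.T) / 2, 0, 0.999)
        np.fill_diagonal(r2, 1.0)
        recs = [make_assoc(snp_id=f"rs{i}", pos=int(pos[i]),
                           pval=float(rng.uniform(1e-9, 1e-4)))
                for i in range(k)]
        ld = _ld([r.snp_id for r in recs], pos, r2)
        base = clump(recs, ld, CFG)
        perm = [recs[i] for i in rng.permutation(k)]
        assert clump(perm, ld, CFG) == base


class TestFStatistics:
    def test_arithmetic(self):
        strong = make_assoc(beta=0.1, se=0.01)
        rep = compute_f_statistics([strong], CFG)
        assert rep.f_per_snp[0] == pytest.approx(100.0)
        assert rep.strong

    def test_weak_instrument(self):
        weak = make_assoc(beta=0.01, se=0.01)
        rep = compute_f_statistics([weak], CFG)
        assert rep.f_per_snp[0] == pytest.approx(1.0)
        assert not rep.strong

    def test_mean_equals_arithmetic_oracle(self, rng):
        recs = [make_assoc(snp_id=f"rs{i}", beta=float(b), se=float(s))
                for i, (b, s) in enumerate(zip(rng.normal(0, 0.05, 20),
                                               rng.uniform(0.005, 0.02, 20)))]
        rep = compute_f_statistics(recs, CFG)
        assert rep.mean_f == pytest.approx(
            np.mean([(r.beta / r.se) ** 2 for r in recs]), rel=1e-12)


class TestHarmonize:
    def test_swapped_alleles_flip_sign(self):
        exp = make_assoc(snp_id="rs1", ea="A", oa="G", beta=0.10, eaf=0.3)
        out = make_assoc(snp_id="rs1", ea="G", oa="A", beta=0.05, eaf=0.7)
        h = harmonize([exp], [out], CFG)
        assert h.beta_out[0] == pytest.approx(-0.05)
        assert bool(h.flipped[0])

    def test_strand_complement_resolved(self):
        # outcome on opposite strand: A/G on + is T/C on -
        exp = make_assoc(snp_id="rs1", ea="A", oa="G", beta=0.10)
        out = make_assoc(snp_id="rs1", ea="T", oa="C", beta=0.05)
        h = harmonize([exp], [out], CFG)
        assert h.beta_out[0] == pytest.approx(0.05)
        assert not bool(h.flipped[0])

    def test_strand_complement_with_swap_flips_sign(self):
        # A/G vs C/T: complementing gives G/A, the swapped orientation
        exp = make_assoc(snp_id="rs1", ea="A", oa="G", beta=0.1)
        out = make_assoc(snp_id="rs1", ea="C", oa="T", beta=0.05)
        h = harmonize([exp], [out], CFG)
        assert h.beta_out[0] == pytest.approx(-0.05)
        assert bool(h.flipped[0])

    def test_incompatible_alleles_dropped(self):
        exp = make_assoc(snp_id="rs1", ea="A", oa="G")
        out = make_assoc(snp_id="rs1", ea="A", oa="C")  # no orientation fits
        other = make_assoc(snp_id="rs2")
        h = harmonize([exp, other], [out, other], CFG)
        assert ("rs1", "allele-mismatch") in h.dropped
        assert h.snp_ids == ["rs2"]

    def test_palindromic_near_half_frequency_dropped(self):
        exp = make_assoc(snp_id="rs1", ea="A", oa="T", eaf=0.50)
        out = make_assoc(snp_id="rs1", ea="A", oa="T", eaf=0.50)
        keeper = make_assoc(snp_id="rs2")
        h = harmonize([exp, keeper], [out, keeper], CFG)
        assert ("rs1", "palindromic-ambiguous") in h.dropped

    def test_palindromic_clear_frequency_inferred(self):
        exp = make_assoc(snp_id="rs1", ea="A", oa="T", eaf=0.2, beta=0.1)
        out_same = make_assoc(snp_id="rs1", ea="A", oa="T", eaf=0.22, beta=0.05)
        h = harmonize([exp], [out_same], CFG)
        assert h.beta_out[0] == pytest.approx(0.05)
        out_opp = make_assoc(snp_id="rs1", ea="A", oa="T", eaf=0.78, beta=0.05)
        h2 = harmonize([exp], [out_opp], CFG)
        assert h2.beta_out[0] == pytest.approx(-0.05)

    def test_missing_in_outcome_reported(self):
        exp = [make_assoc(snp_id="rs1"), make_assoc(snp_id="rs2")]
        out = [make_assoc(snp_id="rs2")]
        h = harmonize(exp, out, CFG)
        assert ("rs1", "missing-in-outcome") in h.dropped

    def test_no_survivors_is_hard_error(self):
        exp = [make_assoc(snp_id="rs1")]
        out = [make_assoc(snp_id="rsX")]
        with pytest.raises(ValueError, match="no usable instruments"):
            harmonize(exp, out, CFG)

    def test_involutive_on_aligned_data(self, rng):
        # once outcome alleles match the exposure's, re-harmonizing changes nothing
        exp = [make_assoc(snp_id=f"rs{i}", beta=float(rng.normal()))
               for i in range(5)]
        out = [make_assoc(snp_id=f"rs{i}", beta=float(rng.normal()))
               for i in range(5)]
        h1 = harmonize(exp, out, CFG)
        assert not h1.flipped.any()
        np.testing.assert_array_equal(h1.beta_out,
                                      np.array([o.beta for o in out]))
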