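"""ROH scanner and shared-region intersection vs brute-force oracles."""

import numpy as np
import pytest

from autozygmap.io import HET, HOM_A, HOM_B, MISSING, GenotypeMatrix, Marker
from autozygmap.roh import (ROHParams, call_roh, call_roh_all, intersect_shared,
                            region_span, window_hit_fractions)

from conftest import oracle_call_roh, oracle_window_fractions

STUDY = ROHParams()   # the study's scanner option set


def mk_markers(positions, chrom="1"):
    return [Marker(chrom, int(p), f"m{i}", "A", "C")
            for i, p in enumerate(positions)]


class TestWindowFractions:
    def test_all_homozygous_gives_one_everywhere(self):
        mk = mk_markers(range(1000, 1000 + 100 * 20000, 20000))
        fr = window_hit_fractions(np.zeros(100, dtype=np.int8), mk, STUDY)
        assert np.all(fr == 1.0)

    def test_alternating_het_gives_zero(self):
        codes = np.tile([0, 1], 50).astype(np.int8)
        mk = mk_markers(range(1000, 1000 + 100 * 20000, 20000))
        fr = window_hit_fractions(codes, mk, STUDY)
        assert np.all(fr == 0.0)

    def test_single_het_matches_window_enumeration(self):
        """One het at marker 50 of 100: fractions equal the brute-force
        count of qualifying windows over overlapping windows."""
        codes = np.zeros(100, dtype=np.int8)
        codes[49] = HET
        mk = mk_markers(range(1000, 1000 + 100 * 20000, 20000))
        fr = window_hit_fractions(codes, mk, STUDY)
        expect = oracle_window_fractions(codes, STUDY)
        np.testing.assert_allclose(fr, expect)
        assert fr[49] == 0.0           # every window containing the het fails

    def test_short_chromosome_shrinks_window(self):
        codes = np.array([0, 0, 2], dtype=np.int8)
        fr = window_hit_fractions(codes, mk_markers([100, 200, 300]), STUDY)
        assert fr.tolist() == [1.0, 1.0, 1.0]

    def test_empty_chromosome(self):
        assert window_hit_fractions(np.empty(0, dtype=np.int8), [], STUDY).size == 0


class TestCallROH:
    def test_single_maximal_run(self):
        # 40 homozygous markers, 26 kb apart: satisfies min_snps, min_kb and
        # the 30 kb/SNP density cap simultaneously
        mk = mk_markers(range(10_000, 10_000 + 40 * 26_000, 26_000))
        segs = call_roh("s", np.zeros(40, dtype=np.int8), mk, STUDY)
        assert len(segs) == 1
        s = segs[0]
        assert (s.start_bp, s.end_bp, s.n_snps) == (mk[0].pos_bp, mk[-1].pos_bp, 40)

    def test_large_gap_splits_run(self):
        left = list(range(10_000, 10_000 + 40 * 26_000, 26_000))
        right = [left[-1] + 1_500_000 + 26_000 * i for i in range(40)]
        mk = mk_markers(left + right)
        segs = call_roh("s", np.zeros(80, dtype=np.int8), mk, STUDY)
        assert len(segs) == 2
        assert segs[0].end_bp == left[-1] and segs[1].start_bp == right[0]

    def test_min_snps_boundary(self):
        """9 homozygous markers fail the >= 10 SNP rule; 10 pass."""
        for n, expected in [(9, 0), (10, 1)]:
            mk = mk_markers(range(10_000, 10_000 + n * 120_000, 120_000))
            params = ROHParams(max_density_kb_per_snp=150.0)
            segs = call_roh("s", np.zeros(n, dtype=np.int8), mk, params)
            assert len(segs) == expected

    def test_density_cap_rejects_sparse_run(self):
        mk = mk_markers(range(10_000, 10_000 + 40 * 50_000, 50_000))  # 50 kb/SNP
        assert call_roh("s", np.zeros(40, dtype=np.int8), mk, STUDY) == []

    @pytest.mark.parametrize("seed", range(30))
    def test_oracle_equivalence_random_chromosomes(self, seed):
        """Scanner output equals explicit window/run enumeration."""
        rng = np.random.default_rng(seed)
        m = int(rng.integers(5, 300))
        pos = np.sort(rng.choice(np.arange(1, 4_000_000), size=m, replace=False))
        # mostly-homozygous stretches with sprinkled het/missing
        codes = rng.choice([HOM_A, HOM_B, HET, MISSING], size=m,
                           p=[0.55, 0.35, 0.07, 0.03]).astype(np.int8)
        params = ROHParams(min_snps=int(rng.integers(2, 12)),
                           window_snps=int(rng.integers(2, 60)),
                           window_het=int(rng.integers(0, 2)),
                           window_missing=int(rng.integers(0, 2)),
                           min_kb=float(rng.choice([0, 100, 1000])),
                           max_gap_kb=float(rng.choice([100, 1000])),
                           max_density_kb_per_snp=float(rng.choice([30, 1000])))
        mk = mk_markers(pos)
        got = [(s.start_bp, s.end_bp, s.n_snps)
               for s in call_roh("s", codes, mk, params)]
        assert got == oracle_call_roh("s", codes, mk, params)

    def test_monotonicity_in_min_snps_and_window_het(self):
        rng = np.random.default_rng(5)
        m = 400
        pos = np.sort(rng.choice(np.arange(1, 8_000_000), size=m, replace=False))
        codes = rng.choice([HOM_A, HOM_B, HET], size=m,
                           p=[0.6, 0.35, 0.05]).astype(np.int8)
        mk = mk_markers(pos)
        n_prev = None
        for min_snps in (2, 5, 10, 20):
            n = len(call_roh("s", codes, mk,
                             ROHParams(min_snps=min_snps, min_kb=0,
                                       max_density_kb_per_snp=1e6)))
            if n_prev is not None:
                assert n <= n_prev
            n_prev = n
        f_prev = None
        for whet in (0, 1, 2):
            f = window_hit_fractions(codes, mk, ROHParams(window_het=whet))
            if f_prev is not None:
                assert np.all(f >= f_prev)
            f_prev = f


class TestRegionSpan:
    def test_study_region_sizes(self):
        assert region_span(74_306_245, 76_800_429) == 2_494_184
        assert region_span(66_668_989, 68_938_216) == 2_269_227

    def test_degenerate_and_error(self):
        assert region_span(5, 5) == 0
        with pytest.raises(ValueError):
            region_span(10, 9)


class TestIntersectShared:
    def _gm(self, codes_by_sample, positions, chrom="1"):
        samples = list(codes_by_sample)
        codes = np.array([codes_by_sample[s] for s in samples], dtype=np.int8)
        return GenotypeMatrix(samples, mk_markers(positions, chrom), codes)

    def test_interval_intersection(self):
        """[1-10 Mb] ∩ [5-15 Mb] = [5-10 Mb]."""
        from autozygmap.roh import ROHSegment
        pos = list(range(1_000_000, 15_000_001, 1_000_000))
        gm = self._gm({"a": [0] * 15, "b": [0] * 15}, pos)
        segs = {"a": [ROHSegment("a", "1", 1_000_000, 10_000_000, 10)],
                "b": [ROHSegment("b", "1", 5_000_000, 15_000_000, 11)]}
        regions = intersect_shared(segs, gm)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start_bp, r.end_bp) == (5_000_000, 10_000_000)
        assert r.span_bp == 5_000_000
        assert r.consensus_ok

    def test_consensus_fails_on_opposite_homozygotes(self):
        from autozygmap.roh import ROHSegment
        pos = [100, 200, 300]
        gm = self._gm({"a": [HOM_A, HOM_A, HOM_A], "b": [HOM_A, HOM_B, HOM_A]},
                      pos)
        segs = {s: [ROHSegment(s, "1", 100, 300, 3)] for s in ("a", "b")}
        regions = intersect_shared(segs, gm)
        assert regions[0].n_markers == 3
        assert not regions[0].consensus_ok

    def test_symmetric_and_idempotent(self, sim_clean):
        segs = call_roh_all(sim_clean.gmatrix, STUDY)
        fwd = intersect_shared(segs, sim_clean.gmatrix)
        rev = intersect_shared(dict(reversed(list(segs.items()))),
                               sim_clean.gmatrix)
        assert [(r.chrom, r.start_bp, r.end_bp, r.n_markers) for r in fwd] \
            == [(r.chrom, r.start_bp, r.end_bp, r.n_markers) for r in rev]
        # idempotence: intersecting the result regions with themselves
        from autozygmap.roh import ROHSegment
        again = {sid: [ROHSegment(sid, r.chrom, r.start_bp, r.end_bp, r.n_markers)
                       for r in fwd] for sid in segs}
        back = intersect_shared(again, sim_clean.gmatrix)
        assert [(r.chrom, r.start_bp, r.end_bp) for r in back] \
            == [(r.chrom, r.start_bp, r.end_bp) for r in fwd]

    def test_regions_contained_in_every_case_roh(self, sim_clean):
        segs = call_roh_all(sim_clean.gmatrix, STUDY)
        for r in intersect_shared(segs, sim_clean.gmatrix):
            for sid, ss in segs.items():
                assert any(s.chrom == r.chrom and s.start_bp <= r.start_bp
                           and s.end_bp >= r.end_bp for s in ss), \
                    f"region {r} not inside an ROH of {sid}"

    def test_planted_segment_recovered_with_consensus(self, sim_clean):
        """The gene-dropped autozygous haplotype around the causal locus is
        recovered as a consensus-true shared region, and the recovered marker
        set matches a direct all-case marker sweep."""
        gm, t = sim_clean.gmatrix, sim_clean.truth
        segs = call_roh_all(gm, STUDY)
        regions = intersect_shared(segs, gm)
        hit = [r for r in regions
               if r.chrom == t.causal_chrom
               and r.start_bp <= t.causal_pos <= r.end_bp]
        assert len(hit) == 1 and hit[0].consensus_ok

        # marker-sweep oracle: markers covered by an ROH of every case
        covered = set()
        for i, m in enumerate(gm.markers):
            if all(any(s.contains(m.chrom, m.pos_bp) for s in ss)
                   for ss in segs.values()):
                covered.add(m.id)
        in_regions = {mid for r in regions for i, m in enumerate(gm.markers)
                      if r.chrom == m.chrom and r.start_bp <= m.pos_bp <= r.end_bp
                      for mid in [m.id]}
        assert covered == in_regions

    def test_requires_two_cases(self, sim_clean):
        with pytest.raises(ValueError):
            intersect_shared({"a": []}, sim_clean.gmatrix)
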