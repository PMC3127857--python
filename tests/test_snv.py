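"""Error-matrix estimation, the LLR statistic, SNV calling and indel filters."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sgcseq import (
    CallerConfig,
    ErrorMatrix,
    GenomicInterval,
    StrandedPileup,
    call_snvs,
    concordance,
    concordance_percent,
    estimate_error_matrix,
    filter_indels,
    llr,
    simulate_pileup,
)
from sgcseq.indels import GappedReadRecord
from sgcseq.snv import llr_array

from conftest import random_dna

BASES = "ACGT"


def brute_force_llr(counts, P):
    """Oracle: multinomial log-pmf difference via scipy.

    The multinomial coefficient cancels between the heterozygous-mixture
    and homozygous models, leaving exactly the LLR statistic.
    """
    counts = np.asarray(counts)
    n = counts.sum()
    order = np.argsort(-counts, kind="stable")
    b1, b2 = order[0], order[1]
    mix = 0.5 * P[b1] + 0.5 * P[b2]
    l1 = stats.multinomial.logpmf(counts, n, mix)
    l0 = stats.multinomial.logpmf(counts, n, P[b1])
    return l1 - l0


def random_hom_genotypes(rng, n):
    return [BASES[i] for i in rng.integers(0, 4, size=n)]


class TestErrorMatrix:
    def test_rows_must_be_stochastic(self):
        bad = np.full((4, 4), 0.2)
        with pytest.raises(ValueError):
            ErrorMatrix(bad)

    def test_uniform_model(self):
        P = ErrorMatrix.uniform(0.01)
        assert np.allclose(P.p.sum(axis=1), 1.0)
        assert np.allclose(np.diag(P.p), 0.99)

    def test_error_free_estimate_is_identity_up_to_pseudocount(self):
        iv = GenomicInterval("c1", 0, 40)
        fwd = np.zeros((40, 4), dtype=int)
        for i in range(40):
            fwd[i, i % 4] = 500
        pu = StrandedPileup(iv, fwd, fwd.copy())
        P = estimate_error_matrix(pu, pseudocount=0.5)
        assert np.diag(P.p).min() > 0.999
        assert (P.p - np.eye(4)).max() < 1e-3

    def test_recovers_simulated_uniform_error(self, rng, uniform_p):
        gts = random_hom_genotypes(rng, 4_000)
        pu = simulate_pileup(gts, 150, uniform_p, seed=21)
        P = estimate_error_matrix(pu)
        off = P.p[~np.eye(4, dtype=bool)]
        assert off == pytest.approx(0.01 / 3, abs=4e-4)

    def test_excluding_hets_improves_recovery(self, rng, uniform_p):
        gts = random_hom_genotypes(rng, 800)
        het_positions = list(range(0, 800, 40))  # 2.5% contamination
        for p in het_positions:
            ref = gts[p]
            gts[p] = (ref, BASES[(BASES.index(ref) + 1) % 4])
        pu = simulate_pileup(gts, 200, uniform_p, seed=22)
        P_naive = estimate_error_matrix(pu)
        P_clean = estimate_error_matrix(pu, exclude_positions=het_positions)
        err_naive = np.abs(P_naive.p - uniform_p.p).max()
        err_clean = np.abs(P_clean.p - uniform_p.p).max()
        assert err_clean < err_naive

    def test_empty_pileup_rejected(self):
        pu = StrandedPileup.empty(GenomicInterval("c1", 0, 5))
        with pytest.raises(ValueError):
            estimate_error_matrix(pu)


class TestLLR:
    def test_pure_hom_counts_forced_negative(self, uniform_p):
        # all 100 reads agree: the het model pays ~log 2 per read
        value = llr([100, 0, 0, 0], uniform_p)
        assert value == pytest.approx(-100 * math.log(2), rel=0.02)

    def test_balanced_het_counts_positive_and_exact(self, uniform_p):
        value = llr([50, 50, 0, 0], uniform_p)
        assert value > 0
        assert value == pytest.approx(brute_force_llr([50, 50, 0, 0], uniform_p.p))

    def test_zero_depth_is_nan(self, uniform_p):
        assert math.isnan(llr([0, 0, 0, 0], uniform_p))

    def test_exhaustive_small_n_sweep_matches_multinomial_oracle(self, uniform_p):
        """All count vectors with N <= 8 plus random vectors up to N = 50."""
        from itertools import product

        P = uniform_p.p
        vectors = [
            c for c in product(range(9), repeat=4) if 0 < sum(c) <= 8
        ]
        rng = np.random.default_rng(33)
        for _ in range(200):
            n = int(rng.integers(1, 51))
            vectors.append(tuple(rng.multinomial(n, [0.4, 0.3, 0.2, 0.1])))
        mine = llr_array(np.array(vectors), uniform_p)
        oracle = np.array([brute_force_llr(v, P) for v in vectors])
        assert mine == pytest.approx(oracle)

    def test_base_label_permutation_symmetry(self, rng):
        """Permuting base labels in counts and P together leaves LLR unchanged."""
        p = np.array(
            [
                [0.96, 0.02, 0.01, 0.01],
                [0.02, 0.95, 0.02, 0.01],
                [0.01, 0.01, 0.97, 0.01],
                [0.02, 0.01, 0.01, 0.96],
            ]
        )
        counts = np.array([40, 35, 3, 2])
        base_value = llr(counts, ErrorMatrix(p))
        for _ in range(5):
            perm = rng.permutation(4)
            permuted = llr(counts[perm], ErrorMatrix(p[np.ix_(perm, perm)]))
            assert permuted == pytest.approx(base_value)

    def test_structural_zero_handled_by_pseudocount_convention(self):
        # a structural zero on an observed base drives the null to -inf,
        # hence estimation always applies a pseudocount; raw llr reports
        # the infinity rather than crashing
        P = np.array(
            [
                [1.0, 0.0, 0.0, 0.0],
                [0.0, 1.0, 0.0, 0.0],
                [0.0, 0.0, 1.0, 0.0],
                [0.0, 0.0, 0.0, 1.0],
            ]
        )
        value = llr([30, 5, 0, 0], ErrorMatrix(P))
        assert value == math.inf  # het explains data the null cannot


class TestCallSNVs:
    def _mixed_pileup(self, rng, uniform_p, n=1_500, het_every=150, depth=200, seed=40):
        gts = random_hom_genotypes(rng, n)
        het_positions = []
        for p in range(het_every // 2, n, het_every):
            ref = gts[p]
            alt = BASES[(BASES.index(ref) + 2) % 4]
            gts[p] = (ref, alt)
            het_positions.append(p)
        return simulate_pileup(gts, depth, uniform_p, seed=seed), het_positions

    def test_simulated_hets_called(self, rng, uniform_p):
        pu, het_positions = self._mixed_pileup(rng, uniform_p)
        P = estimate_error_matrix(pu)
        calls = call_snvs(pu, P, config=CallerConfig(threshold=10))
        assert sorted(c.position for c in calls) == het_positions

    def test_single_strand_signal_not_called(self, uniform_p, rng):
        gts = random_hom_genotypes(rng, 200)
        pu = simulate_pileup(gts, 200, uniform_p, seed=41)
        # inject a strong variant signal on the forward strand only
        i = 100
        ref_idx = BASES.index(gts[i] if isinstance(gts[i], str) else gts[i][0])
        alt_idx = (ref_idx + 1) % 4
        pu.fwd[i, alt_idx] = pu.fwd[i, ref_idx]
        P = estimate_error_matrix(pu)
        calls = call_snvs(pu, P, config=CallerConfig(threshold=10, iterate=False))
        assert i not in {c.position for c in calls}

    def test_het_inside_mask_suppressed(self, rng, uniform_p):
        pu, het_positions = self._mixed_pileup(rng, uniform_p, seed=42)
        mask = np.zeros(len(pu), dtype=bool)
        mask[het_positions[0]] = True
        P = estimate_error_matrix(pu)
        calls = call_snvs(pu, P, mask=mask, config=CallerConfig(threshold=10))
        called = {c.position for c in calls}
        assert het_positions[0] not in called
        assert set(het_positions[1:]) <= called

    def test_false_candidates_decrease_in_threshold(self, rng, uniform_p):
        """Calibration: on hom-only data the candidate count is monotonically
        non-increasing in the threshold c."""
        gts = random_hom_genotypes(rng, 3_000)
        pu = simulate_pileup(gts, 30, uniform_p, seed=43)  # low depth: noisier
        P = estimate_error_matrix(pu)
        counts = []
        for c in (-5.0, 0.0, 5.0, 10.0, 20.0):
            cfg = CallerConfig(threshold=c, min_depth=1,
                               min_second_fraction=0.0, iterate=False)
            counts.append(len(call_snvs(pu, P, config=cfg)))
        assert counts == sorted(counts, reverse=True)

    def test_second_allele_floor_enforced(self, uniform_p, rng):
        gts = random_hom_genotypes(rng, 100)
        pu = simulate_pileup(gts, 400, uniform_p, seed=44)
        i = 50
        ref_idx = BASES.index(gts[i])
        alt_idx = (ref_idx + 1) % 4
        # ~12.7% variant on both strands: clears the LLR threshold at this
        # depth but stays under the 13% second-allele floor
        pu.fwd[i, alt_idx] = 58
        pu.rev[i, alt_idx] = 58
        P = ErrorMatrix.uniform(0.01)
        cfg = CallerConfig(threshold=10, iterate=False)
        assert i not in {c.position for c in call_snvs(pu, P, config=cfg)}
        cfg_low = CallerConfig(threshold=10, min_second_fraction=0.05, iterate=False)
        assert i in {c.position for c in call_snvs(pu, P, config=cfg_low)}


class TestConcordance:
    @pytest.mark.parametrize(
        "hit,total,expected", [(13, 14, 92.9), (344, 345, 99.7), (5, 5, 100.0)]
    )
    def test_percentage_rounding(self, hit, total, expected):
        assert concordance_percent(hit, total) == expected

    def test_perfect_agreement(self, rng, uniform_p):
        gts = random_hom_genotypes(rng, 400)
        het_positions = [50, 150, 250]
        truth_rows = []
        for p in het_positions:
            ref = gts[p]
            alt = BASES[(BASES.index(ref) + 1) % 4]
            gts[p] = (ref, alt)
            truth_rows.append({"pos0": p, "genotype": "het", "alleles": ref + alt})
        for p in (10, 110, 210, 310):
            truth_rows.append({"pos0": p, "genotype": "hom",
                               "alleles": gts[p] if isinstance(gts[p], str) else gts[p][0]})
        pu = simulate_pileup(gts, 300, uniform_p, seed=50)
        P = estimate_error_matrix(pu)
        calls = call_snvs(pu, P)
        report = concordance(calls, pd.DataFrame(truth_rows))
        assert report["het_pct"] == 100.0
        assert report["hom_pct"] == 100.0
        assert report["diagnostic_odds_ratio"] == "Infinite"

    def test_missed_het_counted(self):
        truth = pd.DataFrame(
            [{"pos0": 5, "genotype": "het", "alleles": "AG"},
             {"pos0": 9, "genotype": "hom", "alleles": "C"}]
        )
        report = concordance([], truth)
        assert report["het_pct"] == 0.0
        assert report["hom_pct"] == 100.0


class TestIndelFilters:
    def _genome(self, rng):
        return {"c1": random_dna(rng, 3_000)}

    def _pileup(self, depth=100, length=3_000):
        iv = GenomicInterval("c1", 0, length)
        fwd = np.zeros((length, 4), dtype=int)
        fwd[:, 0] = depth // 2
        rev = np.zeros((length, 4), dtype=int)
        rev[:, 0] = depth - depth // 2
        return StrandedPileup(iv, fwd, rev)

    def _records(self, genome, pos=1_000, n_fwd=3, n_rev=3):
        seq = genome["c1"]
        recs = []
        for i in range(n_fwd):
            start = pos - 20 - i
            recs.append(GappedReadRecord(
                read_id=f"f{i}", breakpoint=start, strand="+",
                indel_pos=pos, indel_seq="TTG", is_insertion=True,
                read_seq=seq[start:pos] + "TTG" + seq[pos : start + 33],
            ))
        for i in range(n_rev):
            start = pos - 15 - 2 * i
            recs.append(GappedReadRecord(
                read_id=f"r{i}", breakpoint=start, strand="-",
                indel_pos=pos, indel_seq="TTG", is_insertion=True,
                read_seq=seq[start:pos] + "TTG" + seq[pos : start + 33],
            ))
        return recs

    def test_all_rules_met_accepted(self, rng):
        genome = self._genome(rng)
        calls = filter_indels(self._records(genome), self._pileup(), genome)
        assert len(calls) == 1
        assert calls[0].passes

    def test_single_forward_breakpoint_rejected(self, rng):
        genome = self._genome(rng)
        recs = self._records(genome, n_fwd=1, n_rev=3)
        calls = filter_indels(recs, self._pileup(), genome)
        assert not calls[0].passes
        assert "breakpoints" in calls[0].reasons

    def test_low_depth_rejected(self, rng):
        genome = self._genome(rng)
        calls = filter_indels(self._records(genome), self._pileup(depth=50), genome)
        assert not calls[0].passes
        assert "depth" in calls[0].reasons

    def test_near_perfect_alternative_placement_rejected(self, rng):
        """Reads matching a second locus with < 3 mismatches mark the indel
        as a likely off-target capture."""
        genome = self._genome(rng)
        recs = self._records(genome)
        # plant an alternative locus: a supporting read's sequence with 2
        # mismatches, far from the indel
        read = recs[0].read_seq
        corrupted = list(read)
        corrupted[5] = "A" if read[5] != "A" else "C"
        corrupted[20] = "A" if read[20] != "A" else "C"
        seq = genome["c1"]
        genome["c1"] = seq[:2_500] + "".join(corrupted) + seq[2_500 + len(read):]
        calls = filter_indels(recs, self._pileup(), genome)
        assert not calls[0].passes
        assert "alternative_placement" in calls[0].reasons

    def test_missing_strand_rejected(self):
        with pytest.raises(ValueError):
            GappedReadRecord("x", 0, "?", 10, "A", True, "ACGT")
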