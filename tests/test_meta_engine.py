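"""Fixed-effect combination, raw/INT pairing, loci and novelty."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from glycometa import meta_engine as me
from glycometa.cohort_engine import CohortScoreSet, compute_cohort_scores
from glycometa.formats_io import (AnnotationRecord, KnownLocus, VariantKey)


def _score_set(U, V, variants=None, cohort_id="C1", trait="FG",
               transform="INT", hwe_p=None, call_rate=None, eaf=None,
               n=None):
    k = len(U)
    if variants is None:
        variants = [VariantKey("1", 1000 + i, "A", "G") for i in range(k)]
    return CohortScoreSet(
        cohort_id=cohort_id, ancestry="EUR", trait=trait,
        transform=transform, variants=variants,
        U=np.asarray(U, float), V=np.asarray(V, float),
        n=np.asarray(n if n is not None else [100] * k, int),
        eaf=np.asarray(eaf if eaf is not None else [0.3] * k, float),
        call_rate=np.asarray(call_rate if call_rate is not None
                             else [1.0] * k, float),
        hwe_p=np.asarray(hwe_p if hwe_p is not None else [1.0] * k, float),
        monomorphic=np.zeros(k, bool))


class TestCombineScores:
    def test_single_cohort_identity(self):
        ss = _score_set([1.5, -2.0], [2.0, 3.0])
        meta = me.combine_scores([ss])
        assert np.array_equal(meta.U, ss.U)
        assert np.array_equal(meta.V, ss.V)
        assert np.array_equal(meta.n_cohorts, [1, 1])

    def test_two_cohort_closed_form(self):
        a = _score_set([1.0], [1.0], cohort_id="A")
        b = _score_set([1.0], [1.0], cohort_id="B")
        meta = me.combine_scores([a, b])
        z = meta.U[0] / np.sqrt(meta.V[0])
        p = 2 * me.stats.norm.sf(abs(z))
        assert meta.U[0] == 2.0 and meta.V[0] == 2.0
        assert z == pytest.approx(np.sqrt(2))
        assert p == pytest.approx(0.15730, abs=1e-5)

    @given(st.lists(st.integers(0, 2), min_size=3, max_size=7),
           st.integers(0, 2 ** 31 - 1))
    def test_associativity_over_random_partitions(self, groups, seed):
        """Within-group then across-group combination equals the one-stage
        combination for every partition of cohorts into ancestry groups."""
        rng = np.random.default_rng(seed)
        sets = [_score_set(rng.normal(size=4), rng.uniform(0.5, 3, 4),
                           cohort_id=f"C{i}") for i in range(len(groups))]
        one_stage = me.combine_scores(sets)
        staged = {}
        for g in set(groups):
            members = [s for s, lab in zip(sets, groups) if lab == g]
            staged[g] = me.combine_scores(members)
        # second stage: sum the per-group sums directly
        U2 = np.sum([m.U for m in staged.values()], axis=0)
        V2 = np.sum([m.V for m in staged.values()], axis=0)
        assert np.allclose(one_stage.U, U2, rtol=0, atol=1e-12)
        assert np.allclose(one_stage.V, V2, rtol=0, atol=1e-12)

    def test_equals_inverse_variance_weighted_meta(self, rng):
        """Score summation reproduces inverse-variance-weighted averaging
        of per-cohort effect estimates with weights V_j."""
        sets = [_score_set(rng.normal(size=5), rng.uniform(0.5, 4, 5),
                           cohort_id=f"C{i}") for i in range(4)]
        meta = me.combine_scores(sets)
        betas = np.array([s.U / s.V for s in sets])
        weights = np.array([s.V for s in sets])
        ivw = (betas * weights).sum(axis=0) / weights.sum(axis=0)
        assert np.allclose(meta.U / meta.V, ivw, rtol=1e-10)

    def test_qc_failures_dropped_per_variant(self):
        good = _score_set([1.0, 1.0], [1.0, 1.0], cohort_id="A")
        bad = _score_set([5.0, 1.0], [1.0, 1.0], cohort_id="B",
                         hwe_p=[1e-5, 1.0])
        meta = me.combine_scores([good, bad])
        assert meta.U[0] == 1.0       # failing entry not summed
        assert meta.U[1] == 2.0
        assert list(meta.n_cohorts) == [1, 2]

    def test_call_rate_boundary_is_kept(self):
        ss = _score_set([1.0], [1.0], call_rate=[0.99])
        meta = me.combine_scores([ss, _score_set([1.0], [1.0],
                                                 cohort_id="B")])
        assert meta.n_cohorts[0] == 2   # 0.99 is not < 0.99

    def test_swapped_alleles_flipped(self):
        v = VariantKey("1", 1000, "A", "G")
        v_swapped = VariantKey("1", 1000, "G", "A")
        a = _score_set([1.0], [1.0], variants=[v], cohort_id="A")
        b = _score_set([-1.0], [1.0], variants=[v_swapped], cohort_id="B",
                       eaf=[0.7])
        meta = me.combine_scores([a, b])
        assert meta.U[0] == pytest.approx(2.0)   # sign flipped on B
        assert meta.eaf[0] == pytest.approx(0.3)  # frequency complemented

    def test_mixed_traits_or_transforms_rejected(self):
        a = _score_set([1.0], [1.0], trait="FG")
        b = _score_set([1.0], [1.0], trait="FI", cohort_id="B")
        with pytest.raises(me.MetaInputError, match="trait"):
            me.combine_scores([a, b])
        c = _score_set([1.0], [1.0], transform="raw", cohort_id="C")
        with pytest.raises(me.MetaInputError, match="transform"):
            me.combine_scores([a, c])


class TestMergeRawInt:
    def test_identical_streams_consistent(self):
        raw = me.combine_scores([_score_set([2.0], [4.0],
                                            transform="raw")])
        int_ = me.combine_scores([_score_set([2.0], [4.0])])
        out = me.merge_raw_int(raw, int_)[0]
        z_raw = out.beta / out.se
        z_int = me.stats.norm.isf(out.p / 2)
        assert z_raw == pytest.approx(z_int, abs=1e-10)

    def test_raw_only_variant_dropped(self):
        v2 = [VariantKey("1", 1000, "A", "G"), VariantKey("1", 2000, "A", "G")]
        raw = me.combine_scores([_score_set([1.0, 1.0], [1.0, 1.0],
                                            variants=v2,
                                            transform="raw")])
        int_ = me.combine_scores([_score_set([1.0], [1.0],
                                             variants=v2[:1])])
        out = me.merge_raw_int(raw, int_)
        assert len(out) == 1
        assert out[0].key.pos == 1000

    def test_direction_concordance_on_skewed_trait(self, rng):
        """Raw-scale effect sign agrees with the INT-scale z direction for
        every variant of a simulated skewed-trait cohort."""
        n, m = 1500, 20
        g = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
        beta = rng.choice([-0.3, 0.0, 0.3], size=m)
        y = np.exp(rng.normal(size=n) * 0.8) + g @ beta   # skewed noise
        from glycometa.cohort_engine import fit_null_model, score_stats, \
            inverse_normal
        variants = [VariantKey("1", 1000 + 1_100_000 * i, "A", "G")
                    for i in range(m)]
        sets = {}
        for transform, yy in (("raw", y), ("INT", inverse_normal(y))):
            null = fit_null_model(yy)
            ss = score_stats(null, g)
            sets[transform] = _score_set(ss.U, ss.V, variants=variants,
                                         transform=transform)
        out = me.merge_raw_int(me.combine_scores([sets["raw"]]),
                               me.combine_scores([sets["INT"]]))
        int_z = sets["INT"].U / np.sqrt(sets["INT"].V)
        for r, z in zip(out, int_z):
            if abs(z) > 0.5:     # sign is meaningful away from zero
                assert np.sign(r.beta) == np.sign(z)


def _result(pos, p, chrom="1", consequence=None):
    key = VariantKey(chrom, pos, "A", "G")
    return me.MetaVariantResult(key=key, U_meta=1.0, V_meta=1.0, beta=0.1,
                                se=0.05, p=p, n=1000, eaf=0.2, n_cohorts=2)


def _annot(pos, consequence, chrom="1", gene="G1"):
    return AnnotationRecord(key=VariantKey(chrom, pos, "A", "G"),
                            gene=gene, consequence=consequence,
                            damaging_flags=(False,) * 5)


class TestSignificantCoding:
    def test_threshold_and_category_rules(self):
        results = [_result(100, 1e-8), _result(200, 1e-10),
                   _result(300, 2.2e-7), _result(400, 1e-9)]
        annotations = [_annot(100, "missense"), _annot(200, "synonymous"),
                       _annot(300, "missense")]
        out = me.significant_coding(results, annotations)
        positions = [r.key.pos for r in out]
        assert 100 in positions          # missense below threshold
        assert 200 not in positions      # synonymous never flagged
        assert 300 not in positions      # boundary: strict less-than
        assert 400 not in positions      # unannotated treated non-coding

    def test_any_coding_row_suffices(self):
        results = [_result(100, 1e-9)]
        annotations = [_annot(100, "synonymous", gene="A"),
                       _annot(100, "missense", gene="B")]
        assert len(me.significant_coding(results, annotations)) == 1


class TestClump:
    def test_nearby_variants_one_locus(self):
        out = me.clump([_result(1_000_000, 1e-9),
                        _result(1_400_000, 1e-8)])
        assert len(out) == 1
        assert out[0].lead.pos == 1_000_000

    def test_distant_variants_two_loci(self):
        out = me.clump([_result(1_000_000, 1e-9),
                        _result(1_600_000, 1e-8)])
        assert len(out) == 2

    def test_exact_window_joins(self):
        out = me.clump([_result(1_000_000, 1e-9),
                        _result(1_500_000, 1e-8)])
        assert len(out) == 1

    def _oracle(self, results, window=500_000):
        """Independent re-implementation: repeatedly pop the smallest-p
        remaining variant and remove its neighbourhood."""
        remaining = sorted(results,
                           key=lambda r: (r.p, r.key.sort_key()))
        loci = []
        while remaining:
            lead = remaining[0]
            members = frozenset(
                (r.key.chrom, r.key.pos) for r in remaining
                if r.key.chrom == lead.key.chrom
                and abs(r.key.pos - lead.key.pos) <= window)
            loci.append(((lead.key.chrom, lead.key.pos), members))
            remaining = [r for r in remaining
                         if (r.key.chrom, r.key.pos) not in members]
        return loci

    def test_matches_oracle_and_is_order_invariant(self, rng):
        results = [_result(int(pos), float(p), chrom=str(c))
                   for pos, p, c in zip(
                       rng.integers(1, 20_000_000, 50),
                       rng.uniform(1e-12, 1e-7, 50),
                       rng.integers(1, 4, 50))]
        expected = self._oracle(results)
        for order in (results, results[::-1],
                      list(rng.permutation(np.array(results,
                                                    dtype=object)))):
            got = me.clump(list(order))
            got_repr = [((l.lead.chrom, l.lead.pos),
                         frozenset((m.chrom, m.pos) for m in l.members))
                        for l in got]
            assert got_repr == expected
        # every variant in exactly one locus
        all_members = [m for l in me.clump(results) for m in l.members]
        assert len(all_members) == 50
        assert len(set((m.chrom, m.pos) for m in all_members)) == 50


class TestNovelty:
    def _locus(self, pos):
        key = VariantKey("1", pos, "A", "G")
        return me.Locus(lead=key, members=[key], trait="FG", lead_p=1e-9)

    def test_within_window_matches_known(self):
        known = [KnownLocus("FG", "1", 1_500_000, "KNOWN_A")]
        out = me.classify_novelty([self._locus(1_000_001)], known)
        assert out[0].novel is False
        assert out[0].matched_known == "KNOWN_A"

    def test_beyond_window_is_novel(self):
        known = [KnownLocus("FG", "1", 1_500_001, "KNOWN_A")]
        out = me.classify_novelty([self._locus(1_000_000)], known)
        assert out[0].novel is True

    def test_known_on_other_chromosome_only(self):
        known = [KnownLocus("FG", "2", 1_000_000, "KNOWN_A")]
        out = me.classify_novelty([self._locus(1_000_000)], known)
        assert out[0].novel is True

    def test_empty_known_list_all_novel(self):
        out = me.classify_novelty([self._locus(5)], [])
        assert out[0].novel is True


class TestEndToEndRecovery:
    def test_planted_effect_recovered_within_3se(self, small_cfg,
                                                 small_cohorts):
        """Meta-analysis of the synthetic consortium recovers the planted
        per-allele effect of the causal gene within +/-3 SE."""
        sets = [compute_cohort_scores(c, "FG", "raw")
                for c in small_cohorts]
        meta = me.combine_scores(sets)
        truth = small_cohorts[0].truth["FG"].to_numpy()
        planted = np.nonzero(truth)[0]
        common = [j for j in planted if meta.eaf[j] > 0.05]
        assert common
        hits = 0
        for j in common:
            beta = meta.U[j] / meta.V[j]
            se = 1 / np.sqrt(meta.V[j])
            if abs(beta - truth[j]) <= 3 * se:
                hits += 1
        assert hits / len(common) >= 0.9
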