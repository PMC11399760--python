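"""Permutation gene-set enrichment: selection, null, FDR, clustering."""

import numpy as np
import pytest
from scipy import stats

from glycometa import gsea_engine as ge
from glycometa import synthetic_data as sd
from glycometa.formats_io import AnnotationRecord, VariantKey
from glycometa.meta_engine import MetaVariantResult


def _result(pos, p, chrom="1"):
    return MetaVariantResult(
        key=VariantKey(chrom, pos, "A", "G"), U_meta=1.0, V_meta=1.0,
        beta=0.1, se=0.05, p=p, n=1000, eaf=0.2, n_cohorts=2)


def _annot(pos, gene, consequence="missense", chrom="1"):
    return AnnotationRecord(
        key=VariantKey(chrom, pos, "A", "G"), gene=gene,
        consequence=consequence, damaging_flags=(True,) * 5)


class TestSelectInputGenes:
    def test_best_nonsynonymous_not_lead_is_used(self):
        results = [_result(1_000_000, 1e-9), _result(1_100_000, 1e-6)]
        annotations = [_annot(1_000_000, "SYN_GENE", "synonymous"),
                       _annot(1_100_000, "MIS_GENE", "missense")]
        assert ge.select_input_genes(results, annotations) == ["MIS_GENE"]

    def test_cutoff_is_strict(self):
        results = [_result(1_000_000, 1e-5)]
        annotations = [_annot(1_000_000, "G1")]
        assert ge.select_input_genes(results, annotations) == []

    def test_duplicate_genes_deduplicated(self):
        results = [_result(1_000_000, 1e-8),
                   _result(2_000_000, 1e-7, chrom="2")]
        annotations = [_annot(1_000_000, "G1"),
                       _annot(2_000_000, "G1", chrom="2")]
        assert ge.select_input_genes(results, annotations) == ["G1"]

    def test_locus_without_nonsynonymous_contributes_nothing(self):
        results = [_result(1_000_000, 1e-9)]
        annotations = [_annot(1_000_000, "G1", "synonymous")]
        assert ge.select_input_genes(results, annotations) == []


class TestFilterToPanel:
    def _panel(self, genes):
        return ge.PermutationPanel(studies=[list(genes)],
                                   panel_genes=set(genes), seeds=[0])

    def test_full_panel_removes_nothing(self):
        retained, removed = ge.filter_to_panel(
            ["A", "B"], self._panel(["A", "B", "C"]))
        assert retained == ["A", "B"] and removed == []

    def test_partial_overlap(self):
        retained, removed = ge.filter_to_panel(
            ["A", "B", "C"], self._panel(["A", "C"]))
        assert retained == ["A", "C"] and removed == ["B"]

    def test_all_removed_is_fatal(self):
        with pytest.raises(ge.GseaError):
            ge.filter_to_panel(["X"], self._panel(["A"]))

    def test_larger_panel_retains_at_least_as_many(self):
        small = self._panel(["A", "B"])
        large = self._panel(["A", "B", "C", "D"])
        genes = ["A", "C", "X"]
        kept_small, _ = ge.filter_to_panel(genes, small)
        kept_large, _ = ge.filter_to_panel(genes, large)
        assert set(kept_small) <= set(kept_large)


def _panel_fixture(n_genes=60, n_ind=500, seed=21):
    """One polymorphic missense variant per gene: per-gene best p is the
    per-variant p, so null calibration has a closed-form reference."""
    cfg = sd.SimConfig(
        n_cohorts_per_ancestry={"EUR": 1}, n_individuals=n_ind,
        n_variants=n_genes, n_genes=n_genes,
        maf_spectrum=(0.0, 0.3, 0.7), seed=seed)
    cohort = sd.simulate_cohort(cfg, "EUR_1", "EUR")
    annotations = [_annot_from(v, g) for v, g in
                   zip(cohort.variants, cohort.variant_genes)]
    return cohort, annotations


def _annot_from(key, gene):
    return AnnotationRecord(key=key, gene=gene, consequence="missense",
                            damaging_flags=(True,) * 5)


class TestPermutationPanel:
    def test_deterministic_and_counted(self):
        cohort, annotations = _panel_fixture()
        a = ge.build_permutation_panel(cohort, annotations, 60, seed=5)
        b = ge.build_permutation_panel(cohort, annotations, 60, seed=5)
        assert a.studies == b.studies and a.seeds == b.seeds
        assert len(a.studies) == 60

    def test_different_seed_differs(self):
        cohort, annotations = _panel_fixture()
        a = ge.build_permutation_panel(cohort, annotations, 10, seed=5)
        b = ge.build_permutation_panel(cohort, annotations, 10, seed=6)
        assert a.studies != b.studies

    def test_best_gene_p_follows_uniform_order_statistic(self):
        """With g independent null genes, the best per-study gene p is the
        minimum of g uniforms, i.e. Beta(1, g)."""
        cohort, annotations = _panel_fixture(n_genes=50, n_ind=400)
        dosages = np.nan_to_num(cohort.dosages)
        Gc = dosages - dosages.mean(axis=0)
        norms = np.sqrt((Gc ** 2).sum(axis=0))
        panel = ge.build_permutation_panel(cohort, annotations, 200,
                                           seed=7)
        best_ps = []
        for s in panel.seeds:
            y = np.random.default_rng(s).normal(size=cohort.dosages.shape[0])
            e = y - y.mean()
            sigma = np.sqrt(e @ e / (len(y) - 1))
            z = Gc.T @ e / (norms * sigma)
            best_ps.append(2 * stats.norm.sf(np.abs(z)).min())
        ks = stats.kstest(best_ps, stats.beta(1, 50).cdf)
        assert ks.pvalue > 0.01


def _gsm_for(cohort, n_sets=120, planted=(), seed=3):
    genes = sorted(set(cohort.variant_genes))
    return sd.simulate_geneset_matrix(genes, n_sets, planted=planted,
                                      seed=seed)


class TestEnrichment:
    def test_planted_set_detected(self):
        cohort, annotations = _panel_fixture()
        panel = ge.build_permutation_panel(cohort, annotations, 150,
                                           seed=1)
        input_genes = sorted(panel.panel_genes)[:20]
        planted = [sd.PlantedSet("SET00000", tuple(input_genes),
                                 z_mean=3.0)]
        gsm = _gsm_for(cohort, planted=planted)
        out = ge.enrichment(input_genes, gsm, panel.studies[:100])
        by_id = {r.set_id: r for r in out}
        assert by_id["SET00000"].p < 1e-4
        assert by_id["SET00000"].z_enrich > 3

    def test_null_input_p_uniform(self):
        """Using a held-out permuted study as the observed input, the
        enrichment p-values across sets are uniform."""
        cohort, annotations = _panel_fixture(n_genes=60)
        panel = ge.build_permutation_panel(cohort, annotations, 201,
                                           seed=2)
        gsm = _gsm_for(cohort, n_sets=300)
        pseudo_input = panel.studies[200][:15]
        out = ge.enrichment(pseudo_input, gsm, panel.studies[:200])
        ks = stats.kstest([r.p for r in out], "uniform")
        assert ks.pvalue > 0.01

    def test_zero_variance_set_excluded(self):
        cohort, annotations = _panel_fixture(n_genes=10)
        panel = ge.build_permutation_panel(cohort, annotations, 60,
                                           seed=3)
        gsm = _gsm_for(cohort, n_sets=3)
        gsm.z[:, 1] = 7.0    # constant column: every sum identical
        out = ge.enrichment(sorted(panel.panel_genes)[:4], gsm,
                            panel.studies[:50])
        assert {r.set_id for r in out} == {"SET00000", "SET00002"}


class TestEmpiricalFdr:
    def _observed(self, ps):
        return [ge.EnrichmentResult(set_id=f"S{i}", S_obs=0.0, mu_perm=0.0,
                                    sd_perm=1.0, z_enrich=0.0, p=p)
                for i, p in enumerate(ps)]

    def test_fdr_zero_when_observed_beats_every_null(self):
        cohort, annotations = _panel_fixture(n_genes=30)
        panel = ge.build_permutation_panel(cohort, annotations, 80,
                                           seed=4)
        input_genes = sorted(panel.panel_genes)[:10]
        planted = [sd.PlantedSet("SET00000", tuple(input_genes), 4.0)]
        gsm = _gsm_for(cohort, n_sets=50, planted=planted)
        out = ge.enrichment(input_genes, gsm, panel.studies[:50])
        out = ge.empirical_fdr(out, panel.studies[50:80], gsm,
                               panel.studies[:50], n_top=10)
        by_id = {r.set_id: r for r in out}
        assert by_id["SET00000"].fdr == 0.0

    def test_fdr_monotone_and_capped(self):
        cohort, annotations = _panel_fixture(n_genes=20)
        panel = ge.build_permutation_panel(cohort, annotations, 70,
                                           seed=5)
        gsm = _gsm_for(cohort, n_sets=80)
        input_genes = sorted(panel.panel_genes)[:8]
        out = ge.enrichment(input_genes, gsm, panel.studies[:50])
        out = ge.empirical_fdr(out, panel.studies[50:70], gsm,
                               panel.studies[:50], n_top=8)
        ordered = sorted(out, key=lambda r: r.p)
        fdrs = [r.fdr for r in ordered]
        assert all(b >= a for a, b in zip(fdrs, fdrs[1:]))
        assert all(0.0 <= f <= 1.0 for f in fdrs)


class TestMetaGeneSets:
    def test_identical_columns_cocluster(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=(200, 6))
        z[:, 5] = z[:, 0]     # duplicate column
        gsm = ge.GeneSetMatrix(genes=[f"G{i}" for i in range(200)],
                               sets=[f"S{i}" for i in range(6)], z=z)
        results = [ge.EnrichmentResult(f"S{i}", 0, 0, 1, 0, p=0.5)
                   for i in range(6)]
        out = ge.cluster_meta_gene_sets(gsm, results, seed=0)
        cluster_of = {}
        for ms in out:
            for m in ms.members:
                cluster_of[m] = ms.exemplar
        assert cluster_of["S0"] == cluster_of["S5"]
        # valid partition
        assert sorted(cluster_of) == [f"S{i}" for i in range(6)]

    def test_partition_deterministic(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=(100, 8))
        gsm = ge.GeneSetMatrix(genes=[f"G{i}" for i in range(100)],
                               sets=[f"S{i}" for i in range(8)], z=z)
        results = [ge.EnrichmentResult(f"S{i}", 0, 0, 1, 0,
                                       p=0.1 * (i + 1)) for i in range(8)]
        a = ge.cluster_meta_gene_sets(gsm, results, seed=3)
        b = ge.cluster_meta_gene_sets(gsm, results, seed=3)
        assert [(m.exemplar, m.members) for m in a] == \
            [(m.exemplar, m.members) for m in b]

    def test_sister_sets_recovered(self):
        """Construction-correlated sister sets co-cluster in nearly every
        seeded run."""
        genes = [f"G{i}" for i in range(300)]
        hits = 0
        runs = 10
        for seed in range(runs):
            gsm = sd.simulate_geneset_matrix(
                genes, n_sets=12, n_sister_pairs=2, sister_noise_sd=0.1,
                seed=seed)
            results = [ge.EnrichmentResult(s, 0, 0, 1, 0, p=0.5)
                       for s in gsm.sets]
            out = ge.cluster_meta_gene_sets(gsm, results, seed=seed)
            cluster_of = {}
            for ms in out:
                for m in ms.members:
                    cluster_of[m] = ms.exemplar
            pair_ok = all(
                cluster_of[f"SET{k % 12:05d}"]
                == cluster_of[f"SET{k % 12:05d}_SISTER{k}"]
                for k in range(2))
            hits += pair_ok
        assert hits >= runs - 1

    def test_representative_is_best_p_member(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=200)
        z = np.column_stack([base, base + rng.normal(size=200) * 0.01])
        gsm = ge.GeneSetMatrix(genes=[f"G{i}" for i in range(200)],
                               sets=["S0", "S1"], z=z)
        results = [ge.EnrichmentResult("S0", 0, 0, 1, 0, p=0.9),
                   ge.EnrichmentResult("S1", 0, 0, 1, 0, p=0.001)]
        out = ge.cluster_meta_gene_sets(gsm, results, seed=0)
        assert len(out) >= 1
        for ms in out:
            if "S1" in ms.members:
                assert ms.representative == "S1"


class TestRunGsea:
    def _fixture(self, seed=9):
        cohort, annotations = _panel_fixture(n_genes=40, seed=seed)
        panel = ge.build_permutation_panel(cohort, annotations, 130,
                                           seed=seed)
        # sub-threshold hits in the first 8 genes
        results = []
        gene_variant = {g: v for v, g in zip(cohort.variants,
                                             cohort.variant_genes)}
        target = sorted(panel.panel_genes)[:8]
        for g in target:
            v = gene_variant[g]
            results.append(MetaVariantResult(
                key=v, U_meta=1.0, V_meta=1.0, beta=0.1, se=0.05,
                p=1e-8, n=1000, eaf=0.2, n_cohorts=2))
        planted = [sd.PlantedSet("SET00000", tuple(target), z_mean=3.0)]
        gsm = _gsm_for(cohort, n_sets=80, planted=planted, seed=seed)
        return results, annotations, gsm, panel

    def test_planted_set_significant_at_fdr(self):
        results, annotations, gsm, panel = self._fixture()
        out = ge.run_gsea(results, annotations, gsm, panel,
                          n_moment=100, n_fdr=30)
        by_id = {r.set_id: r for r in out.results}
        assert by_id["SET00000"].fdr is not None
        assert by_id["SET00000"].fdr < 0.05
        assert len(out.retained) == 8

    def test_output_deterministic(self):
        results, annotations, gsm, panel = self._fixture()
        a = ge.run_gsea(results, annotations, gsm, panel,
                        n_moment=100, n_fdr=30)
        b = ge.run_gsea(results, annotations, gsm, panel,
                        n_moment=100, n_fdr=30)
        assert [(r.set_id, r.p, r.fdr) for r in a.results] == \
            [(r.set_id, r.p, r.fdr) for r in b.results]
        assert a.heatmap.equals(b.heatmap)

    def test_two_panels_concordant(self):
        """Enrichment z-scores from two independent permutation panels on
        the same inputs correlate strongly."""
        results, annotations, gsm, _ = self._fixture()
        cohort, _ = _panel_fixture(n_genes=40, seed=9)
        panel_a = ge.build_permutation_panel(cohort, annotations, 100,
                                             seed=101)
        panel_b = ge.build_permutation_panel(cohort, annotations, 100,
                                             seed=202)
        out_a = ge.run_gsea(results, annotations, gsm, panel_a,
                            n_moment=80, n_fdr=20)
        out_b = ge.run_gsea(results, annotations, gsm, panel_b,
                            n_moment=80, n_fdr=20)
        za = {r.set_id: r.z_enrich for r in out_a.results}
        zb = {r.set_id: r.z_enrich for r in out_b.results}
        shared = sorted(set(za) & set(zb))
        r = np.corrcoef([za[s] for s in shared],
                        [zb[s] for s in shared])[0, 1]
        assert r > 0.9

    def test_heatmap_flags_panel_excluded_genes(self):
        results, annotations, gsm, panel = self._fixture()
        # one extra input hit whose gene is absent from the panel
        extra_key = VariantKey("9", 5_000_000, "A", "G")
        annotations = annotations + [_annot_from(extra_key, "OFFPANEL")]
        results = results + [MetaVariantResult(
            key=extra_key, U_meta=1.0, V_meta=1.0, beta=0.1, se=0.05,
            p=1e-9, n=1000, eaf=0.2, n_cohorts=2)]
        gsm_aug = ge.GeneSetMatrix(
            genes=gsm.genes + ["OFFPANEL"], sets=list(gsm.sets),
            z=np.vstack([gsm.z, np.zeros((1, len(gsm.sets)))]))
        out = ge.run_gsea(results, annotations, gsm_aug, panel,
                          n_moment=100, n_fdr=30)
        assert "OFFPANEL" in out.removed
        heat = out.heatmap
        assert not heat.empty
        off = heat[heat["gene"] == "OFFPANEL"]
        assert off["excluded_from_analysis"].all()
        kept = heat[heat["gene"] != "OFFPANEL"]
        assert not kept["excluded_from_analysis"].any()

    def test_empty_heatmap_when_nothing_significant(self):
        cohort, annotations = _panel_fixture(n_genes=30, seed=31)
        panel = ge.build_permutation_panel(cohort, annotations, 80,
                                           seed=31)
        gsm = _gsm_for(cohort, n_sets=40, seed=31)
        gene_variant = {g: v for v, g in zip(cohort.variants,
                                             cohort.variant_genes)}
        results = [MetaVariantResult(
            key=gene_variant[g], U_meta=1.0, V_meta=1.0, beta=0.1,
            se=0.05, p=1e-7, n=1000, eaf=0.2, n_cohorts=2)
            for g in sorted(panel.panel_genes)[:5]]
        out = ge.run_gsea(results, annotations, gsm, panel,
                          n_moment=60, n_fdr=20)
        sig = [r for r in out.results
               if r.fdr is not None and r.fdr < 0.05]
        if not sig:
            assert out.heatmap.empty
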