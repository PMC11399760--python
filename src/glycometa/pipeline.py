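"""End-to-end orchestration: simulate -> cohort stats -> meta -> gene tests
-> gene-set enrichment, from one YAML config with full determinism.

Config keys (all optional, shown with defaults):

.. code-block:: yaml

    seed: 0                  # master seed for every stage
    traits: [FG, FI, 2hGlu, HbA1c]
    simulation:              # SimConfig fields, e.g.
      n_individuals: 1000
      n_variants: 200
      n_genes: 20
      causal_genes:          # planted signal
        - {gene: GENE00, effect: 0.08, fraction_causal: 1.0}
    annotation_file: null    # use an existing annotation TSV instead of
                             # simulating one
    geneset_file: null       # likewise for the gene-set z-matrix
    known_loci: []           # [{trait, chrom, pos, source_label}]
    gsea:
      n_sets: 150
      n_moment: 200          # permuted studies for moments
      n_fdr: 50              # held-out studies for empirical FDR
      p_cut: 1.0e-5

Each stage writes plain-TSV outputs that the next stage can equally consume
from disk, and a ``manifest.json`` records config hash, seeds, per-stage
output digests and filter counts.  One structured log line is emitted per
filter with before/after counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import cohort_engine, formats_io, gene_tests, gsea_engine
from . import meta_engine, synthetic_data
from .formats_io import KnownLocus
from .synthetic_data import CausalGene, SimConfig

logger = logging.getLogger(__name__)

TRAITS = ("FG", "FI", "2hGlu", "HbA1c")

STAGES = ("simulate", "cohort_stats", "meta", "gene_tests", "gsea")


def configure_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    """Reproducibility record for one pipeline run."""

    config_hash: str
    seed: int
    stages: list[dict] = field(default_factory=list)
    counts: dict = field(default_factory=dict)
    failed_at: str | None = None

    def add_stage(self, name: str, outputs: list[Path]) -> None:
        self.stages.append({
            "name": name,
            "outputs": {str(p.name): _digest(p) for p in sorted(outputs)},
        })

    def write(self, path: Path) -> None:
        with path.open("w", newline="\n") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def sim_config_from_dict(d: dict, seed: int) -> SimConfig:
    d = dict(d or {})
    causal = [CausalGene(**cg) for cg in d.pop("causal_genes", [])]
    if "n_cohorts_per_ancestry" in d:
        d["n_cohorts_per_ancestry"] = dict(d["n_cohorts_per_ancestry"])
    return SimConfig(causal_genes=causal, seed=seed, **d)


def run_all(config: dict | str | Path, out_dir: str | Path) -> RunManifest:
    """Execute every stage for each configured trait.

    Outputs of completed stages survive a downstream failure; the manifest
    then records the failing stage.  Reruns with the same config produce
    byte-identical summary TSVs.
    """
    if not isinstance(config, dict):
        config = formats_io.read_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    traits = list(config.get("traits", TRAITS))
    manifest = RunManifest(config_hash=_config_hash(config), seed=seed)

    # fail fast on referenced-but-missing inputs, before any compute
    for key in ("annotation_file", "geneset_file", "known_loci_file"):
        ref = config.get(key)
        if ref and not Path(ref).exists():
            raise PipelineError("validate", f"{key} not found: {ref}")

    try:
        state = _stage_simulate(config, seed, out, manifest)
        _stage_cohort_stats(state, traits, out, manifest)
        _stage_meta(state, config, traits, out, manifest)
        _stage_gene_tests(state, out, manifest)
        _stage_gsea(state, config, traits, seed, out, manifest)
    except PipelineError as exc:
        manifest.failed_at = exc.stage
        manifest.write(out / "manifest.json")
        raise
    except Exception as exc:
        stage = STAGES[len(manifest.stages)] if \
            len(manifest.stages) < len(STAGES) else "unknown"
        manifest.failed_at = stage
        manifest.write(out / "manifest.json")
        raise PipelineError(stage, str(exc)) from exc
    manifest.write(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

@dataclass
class _State:
    sim_cfg: SimConfig
    cohorts: list
    annotations: list
    gsm: object
    known: list
    score_sets: dict = field(default_factory=dict)   # (trait, transform)
    meta_sets: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)      # trait -> merged list


def _stage_simulate(config: dict, seed: int, out: Path,
                    manifest: RunManifest) -> _State:
    sim_cfg = sim_config_from_dict(config.get("simulation", {}), seed)
    cohorts = synthetic_data.simulate_all_cohorts(sim_cfg)
    outputs = []
    sim_dir = out / "simulated"
    for cohort in cohorts:
        cdir = sim_dir / cohort.cohort_id
        synthetic_data.write_cohort_dir(cohort, cdir)
        outputs += [cdir / "dosages.tsv", cdir / "phenotypes.tsv"]
    truth_path = sim_dir / "truth.tsv"
    sim_dir.mkdir(parents=True, exist_ok=True)
    synthetic_data.write_truth_table(sim_cfg, truth_path)
    outputs.append(truth_path)

    if config.get("annotation_file"):
        annotations = formats_io.read_annotation_table(
            config["annotation_file"])
    else:
        mafs = synthetic_data.ancestry_mafs(sim_cfg)
        annotations = synthetic_data.simulate_annotations(
            sim_cfg.variant_panel(), sim_cfg.variant_gene_assignment(),
            seed=seed, maf_by_ancestry=mafs)
    annot_path = out / "annotations.tsv"
    formats_io.write_annotation_table(annotations, annot_path)
    outputs.append(annot_path)

    if config.get("geneset_file"):
        gsm = formats_io.read_geneset_matrix(config["geneset_file"])
    else:
        gcfg = config.get("gsea", {})
        planted = [synthetic_data.PlantedSet(
            set_id=p["set_id"], member_genes=tuple(p["member_genes"]),
            z_mean=float(p["z_mean"]))
            for p in gcfg.get("planted", [])]
        gsm = synthetic_data.simulate_geneset_matrix(
            sim_cfg.gene_names(), int(gcfg.get("n_sets", 150)),
            planted=planted, seed=seed)
    gsm_path = out / "genesets.tsv"
    formats_io.write_geneset_matrix(gsm, gsm_path)
    outputs.append(gsm_path)

    known = [KnownLocus(**k) for k in config.get("known_loci", [])]
    known_path = out / "known_loci.tsv"
    formats_io.write_known_loci(known, known_path)
    outputs.append(known_path)

    manifest.add_stage("simulate", outputs)
    return _State(sim_cfg=sim_cfg, cohorts=cohorts,
                  annotations=annotations, gsm=gsm, known=known)


def _stage_cohort_stats(state: _State, traits: list[str], out: Path,
                        manifest: RunManifest) -> None:
    outputs = []
    score_dir = out / "scores"
    score_dir.mkdir(parents=True, exist_ok=True)
    for cohort in state.cohorts:
        for trait in traits:
            for transform in ("raw", "INT"):
                ss = cohort_engine.compute_cohort_scores(
                    cohort, trait, transform)
                state.score_sets.setdefault((trait, transform),
                                            []).append(ss)
                stem = (f"{cohort.cohort_id}.{cohort.ancestry}."
                        f"{trait}.{transform}")
                path = score_dir / f"{stem}.scores.tsv"
                formats_io.write_score_table(ss.to_frame(), path)
                cov_path = score_dir / f"{stem}.genecov.tsv"
                formats_io.write_gene_covariance_table(ss.gene_cov,
                                                       cov_path)
                outputs.append(path)
                outputs.append(cov_path)
                logger.info(
                    "cohort_stats cohort=%s trait=%s transform=%s "
                    "excluded=%d analyzed=%d", cohort.cohort_id, trait,
                    transform, ss.n_excluded,
                    state.sim_cfg.n_individuals - ss.n_excluded)
    manifest.counts["diabetes_excluded_per_cohort"] = {
        s.cohort_id: s.n_excluded
        for s in state.score_sets[(traits[0], "INT")]}
    manifest.add_stage("cohort_stats", outputs)


def _stage_meta(state: _State, config: dict, traits: list[str], out: Path,
                manifest: RunManifest) -> None:
    outputs = []
    meta_dir = out / "meta"
    meta_dir.mkdir(parents=True, exist_ok=True)
    qc_dropped = {}
    for trait in traits:
        for transform in ("raw", "INT"):
            sets = state.score_sets[(trait, transform)]
            # one global fixed-effect pass; summation is associative, so
            # this equals the within-ancestry-then-across flow (property-
            # tested), without combining twice
            ancestries = {ss.ancestry for ss in sets}
            meta = meta_engine.combine_scores(sets)
            state.meta_sets[(trait, transform)] = meta
            n_entries = sum(len(s.variants) for s in sets)
            n_used = int(meta.n_cohorts.sum())
            qc_dropped[f"{trait}.{transform}"] = n_entries - n_used
            logger.info("meta trait=%s transform=%s cohort_variant_entries"
                        "=%d surviving_qc=%d ancestries=%d", trait,
                        transform, n_entries, n_used, len(ancestries))
        results = meta_engine.merge_raw_int(
            state.meta_sets[(trait, "raw")],
            state.meta_sets[(trait, "INT")])
        state.results[trait] = results
        path = meta_dir / f"{trait}.sumstats.tsv"
        formats_io.write_sumstats(
            meta_engine.results_to_sumstats(results), path)
        outputs.append(path)

        flagged = meta_engine.significant_coding(results,
                                                 state.annotations)
        loci = meta_engine.clump(flagged, trait=trait)
        loci = meta_engine.classify_novelty(loci, state.known)
        loci_path = meta_dir / f"{trait}.loci.tsv"
        with loci_path.open("w", newline="\n") as fh:
            fh.write("trait\tlead\tlead_p\tn_members\tnovel\t"
                     "matched_known\tmembers\n")
            for locus in loci:
                fh.write("\t".join([
                    trait, locus.lead.label, format(locus.lead_p, ".6g"),
                    str(len(locus.members)),
                    str(int(bool(locus.novel))),
                    locus.matched_known or "",
                    ",".join(m.label for m in locus.members)]) + "\n")
        outputs.append(loci_path)
    manifest.counts["cohort_variant_entries_failing_qc"] = qc_dropped
    manifest.add_stage("meta", outputs)


def _stage_gene_tests(state: _State, out: Path,
                      manifest: RunManifest) -> None:
    masks = gene_tests.build_masks(state.annotations)
    manifest.counts["mask_sizes"] = {
        m: sum(1 for gm in masks if gm.mask == m)
        for m in gene_tests.MASKS}
    rows = []
    for trait in state.results:
        meta = state.meta_sets[(trait, "INT")]
        for res in gene_tests.run_gene_tests(masks, meta):
            rows.append({
                "gene": res.gene, "mask": res.mask, "trait": res.trait,
                "n_var": res.n_var, "T_burden": res.T_burden,
                "p_burden": res.p_burden, "Q_skat": res.Q_skat,
                "p_skat": res.p_skat,
                "significant": int(res.significant),
                "skat_method": res.skat_method,
            })
    path = out / "gene_results.tsv"
    pd.DataFrame(rows, columns=["gene", "mask", "trait", "n_var",
                                "T_burden", "p_burden", "Q_skat",
                                "p_skat", "significant", "skat_method"]
                 ).to_csv(path, sep="\t", index=False, lineterminator="\n")
    manifest.add_stage("gene_tests", [path])


def _gsea_groupings(traits: list[str]) -> dict[str, list[str]]:
    groups = {trait: [trait] for trait in traits}
    if len(traits) > 1:
        groups["all"] = list(traits)
        if "HbA1c" in traits:
            groups["all_except_HbA1c"] = [t for t in traits
                                          if t != "HbA1c"]
    return groups


def _min_p_union(results_by_trait: dict[str, list],
                 traits: list[str]) -> list:
    """Across-trait variant union keeping each variant's smallest p."""
    best: dict[tuple, meta_engine.MetaVariantResult] = {}
    for trait in traits:
        for r in results_by_trait[trait]:
            ident = meta_engine._ident(r.key)
            if ident not in best or r.p < best[ident].p:
                best[ident] = r
    return list(best.values())


def _stage_gsea(state: _State, config: dict, traits: list[str], seed: int,
                out: Path, manifest: RunManifest) -> None:
    gcfg = config.get("gsea", {})
    n_moment = int(gcfg.get("n_moment", 200))
    n_fdr = int(gcfg.get("n_fdr", 50))
    p_cut = float(gcfg.get("p_cut", gsea_engine.INPUT_P_CUTOFF))
    # a dedicated panel cohort stands in for the permutation genotypes
    panel_cohort = synthetic_data.simulate_cohort(
        state.sim_cfg, "PANEL",
        max(state.sim_cfg.n_cohorts_per_ancestry,
            key=lambda a: state.sim_cfg.n_cohorts_per_ancestry[a]))
    panel = gsea_engine.build_permutation_panel(
        panel_cohort, state.annotations, n_moment + n_fdr, seed=seed)
    outputs = []
    gsea_dir = out / "gsea"
    gsea_dir.mkdir(parents=True, exist_ok=True)
    panel_filter_counts = {}
    for group, members in _gsea_groupings(traits).items():
        results = _min_p_union(state.results, members)
        try:
            gout = gsea_engine.run_gsea(
                results, state.annotations, state.gsm, panel,
                n_moment=n_moment, n_fdr=n_fdr, p_cut=p_cut, ap_seed=seed)
        except gsea_engine.GseaError as exc:
            logger.warning("gsea group=%s skipped: %s", group, exc)
            continue
        panel_filter_counts[group] = {
            "input": len(gout.input_genes),
            "retained": len(gout.retained)}
        logger.info("gsea group=%s input_genes=%d retained=%d "
                    "significant_sets=%d", group, len(gout.input_genes),
                    len(gout.retained),
                    sum(1 for r in gout.results
                        if r.fdr is not None and r.fdr < 0.05))
        enr_path = gsea_dir / f"{group}.enrichment.tsv"
        with enr_path.open("w", newline="\n") as fh:
            fh.write("set_id\tS_obs\tmu_perm\tsd_perm\tz_enrich\tp\tfdr\n")
            for r in sorted(gout.results, key=lambda r: (r.p, r.set_id)):
                fh.write("\t".join([
                    r.set_id, format(r.S_obs, ".6g"),
                    format(r.mu_perm, ".6g"), format(r.sd_perm, ".6g"),
                    format(r.z_enrich, ".6g"), format(r.p, ".6g"),
                    format(r.fdr, ".6g") if r.fdr is not None else "NA",
                ]) + "\n")
        outputs.append(enr_path)
        meta_path = gsea_dir / f"{group}.meta_gene_sets.tsv"
        with meta_path.open("w", newline="\n") as fh:
            fh.write("exemplar\trepresentative\trepresentative_p\t"
                     "n_members\tmembers\n")
            for ms in gout.meta_sets:
                fh.write("\t".join([
                    ms.exemplar, ms.representative,
                    format(ms.representative_p, ".6g"),
                    str(len(ms.members)), ",".join(sorted(ms.members)),
                ]) + "\n")
        outputs.append(meta_path)
        heat_path = gsea_dir / f"{group}.heatmap.tsv"
        gout.heatmap.to_csv(heat_path, sep="\t", index=False,
                            lineterminator="\n")
        outputs.append(heat_path)
    manifest.counts["gsea_panel_filtering"] = panel_filter_counts
    manifest.add_stage("gsea", outputs)
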