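"""Permutation-based gene-set enrichment over reconstituted gene sets.

The method scores each gene set by summing, over the trait-associated
input genes, the genes' membership z-scores in that set.  The null
distribution of the sum is taken from permuted association studies:
random normal phenotypes analysed against real (here: synthetic) exome
genotypes, each permuted study contributing its top-N genes where N
matches the observed input count.  The observed sum is standardized by
the permutation mean and standard deviation and converted to an upper-tail
normal p-value.  False discovery rates are empirical: observed p-values
are compared with the p-value distribution obtained by running the same
analysis on a held-out batch of permuted studies.  Finally, strongly
correlated gene sets are grouped into meta-gene sets by affinity
propagation on the set-by-set correlation matrix, each summarized by its
best-p member.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.cluster import AffinityPropagation
from sklearn.exceptions import ConvergenceWarning

from .formats_io import GeneSetMatrix, PTV_CONSEQUENCES, AnnotationRecord
from .meta_engine import MetaVariantResult, clump, _ident

logger = logging.getLogger(__name__)

NONSYNONYMOUS = PTV_CONSEQUENCES | {"missense"}

INPUT_P_CUTOFF = 1e-5
INPUT_WINDOW_BP = 500_000
FDR_THRESHOLD = 0.05

_P_FLOOR = 1e-300


class GseaError(ValueError):
    pass


# ---------------------------------------------------------------------------
# input-gene selection
# ---------------------------------------------------------------------------

def select_input_genes(results: list[MetaVariantResult],
                       annotations: list[AnnotationRecord],
                       p_cut: float = INPUT_P_CUTOFF,
                       window: int = INPUT_WINDOW_BP) -> list[str]:
    """Genes carrying the best nonsynonymous variant of each sub-threshold
    locus.

    Variants with p strictly below ``p_cut`` are clumped into +/-``window``
    loci; within each locus the smallest-p nonsynonymous (missense or PTV)
    variant is mapped to its gene.  Loci without any nonsynonymous variant
    contribute nothing; duplicate genes are reported once, in locus order.
    """
    hits = [r for r in results if r.p < p_cut]
    if not hits:
        logger.warning("select_input_genes: no variants below p=%g", p_cut)
        return []
    gene_of: dict[tuple, list[str]] = {}
    nonsyn: set[tuple] = set()
    for rec in annotations:
        ident = _ident(rec.key)
        if rec.consequence in NONSYNONYMOUS:
            nonsyn.add(ident)
            gene_of.setdefault(ident, []).append(rec.gene)
    p_of = {_ident(r.key): r.p for r in hits}
    genes: list[str] = []
    for locus in clump(hits, window=window):
        candidates = [m for m in locus.members if _ident(m) in nonsyn]
        if not candidates:
            continue
        best = min(candidates,
                   key=lambda m: (p_of[_ident(m)], m.sort_key()))
        for g in gene_of[_ident(best)]:
            if g not in genes:
                genes.append(g)
    return genes


# ---------------------------------------------------------------------------
# permutation panel
# ---------------------------------------------------------------------------

@dataclass
class PermutationPanel:
    """Ranked gene lists from permuted (null-phenotype) association runs."""

    studies: list[list[str]]
    panel_genes: set[str]
    seeds: list[int]

    def __post_init__(self):
        for ranked in self.studies:
            if not set(ranked) <= self.panel_genes:
                raise ValueError("ranked list contains non-panel genes")


def filter_to_panel(input_genes: list[str], panel: PermutationPanel,
                    ) -> tuple[list[str], list[str]]:
    """Drop input genes absent from the permuted data.

    Genes not represented in the permutation panel cannot be modelled by
    the null and are removed (logged); removing every input gene is fatal.
    """
    retained = [g for g in input_genes if g in panel.panel_genes]
    removed = [g for g in input_genes if g not in panel.panel_genes]
    if removed:
        logger.info("filter_to_panel: removed %d/%d input genes absent "
                    "from the permutation panel", len(removed),
                    len(input_genes))
    if input_genes and not retained:
        raise GseaError("every input gene is absent from the permutation "
                        "panel; enrichment analysis impossible")
    return retained, removed


def build_permutation_panel(cohort, annotations: list[AnnotationRecord],
                            n_studies: int, seed: int) -> PermutationPanel:
    """Permuted association studies over a real-genotype stand-in.

    Each study draws standard-normal phenotypes for the panel cohort, runs
    the single-variant score test (intercept-only null: the phenotypes
    carry no covariate structure), reduces to genes by their best
    nonsynonymous-variant p, and ranks genes ascending.  Reproducible from
    ``seed``; studies are independently seeded so moment and FDR batches
    can be split without overlap.
    """
    if n_studies < 52:
        logger.warning("build_permutation_panel: %d studies is below the "
                       "52 needed for a separate FDR batch", n_studies)
    nonsyn_gene: dict[tuple, list[str]] = {}
    for rec in annotations:
        if rec.consequence in NONSYNONYMOUS:
            nonsyn_gene.setdefault(_ident(rec.key), []).append(rec.gene)
    dosages = np.nan_to_num(np.asarray(cohort.dosages, dtype=float))
    cols = []
    col_genes = []
    for j, key in enumerate(cohort.variants):
        genes = nonsyn_gene.get(_ident(key))
        if not genes:
            continue
        g = dosages[:, j]
        if np.all(g == g[0]):
            continue          # monomorphic: no test
        for gene in genes:
            cols.append(j)
            col_genes.append(gene)
    if not cols:
        raise GseaError("panel genotypes contain no polymorphic "
                        "nonsynonymous variants")
    G = dosages[:, cols]
    Gc = G - G.mean(axis=0)
    col_norm = np.sqrt(np.einsum("ij,ij->j", Gc, Gc))
    n_ind = G.shape[0]

    rng = np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=(0x6753,)))
    seeds = [int(s) for s in
             rng.integers(0, 2 ** 31 - 1, size=n_studies)]
    all_genes = sorted(set(col_genes))
    gene_pos = {g: i for i, g in enumerate(all_genes)}
    col_gene_idx = np.array([gene_pos[g] for g in col_genes])
    studies = []
    # z_js = g~' e / (sigma |g~|); generated study-by-study to bound memory
    for s in seeds:
        y = np.random.default_rng(s).normal(size=n_ind)
        e = y - y.mean()
        sigma = np.sqrt(e @ e / (n_ind - 1))
        z = (Gc.T @ e) / (col_norm * sigma)
        p = 2.0 * stats.norm.sf(np.abs(z))
        best = np.full(len(all_genes), np.inf)
        np.minimum.at(best, col_gene_idx, p)
        order = np.lexsort((np.array(all_genes), best))
        studies.append([all_genes[i] for i in order])
    return PermutationPanel(studies=studies, panel_genes=set(all_genes),
                            seeds=seeds)


# ---------------------------------------------------------------------------
# enrichment statistics
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    set_id: str
    S_obs: float
    mu_perm: float
    sd_perm: float
    z_enrich: float
    p: float
    fdr: float | None = None


def _study_sums(gsm: GeneSetMatrix, studies: list[list[str]],
                n_top: int) -> np.ndarray:
    """Per-study sum of z over its top-``n_top`` panel genes present in
    the gene-set matrix; shape (n_studies, n_sets)."""
    gene_index = gsm.gene_index
    sums = np.empty((len(studies), len(gsm.sets)))
    for s, ranked in enumerate(studies):
        rows = []
        for g in ranked:
            idx = gene_index.get(g)
            if idx is not None:
                rows.append(idx)
            if len(rows) == n_top:
                break
        if len(rows) < n_top:
            raise GseaError(
                f"permuted study {s} has only {len(rows)} genes in the "
                f"gene-set matrix; {n_top} required")
        sums[s] = gsm.z[rows].sum(axis=0)
    return sums


def enrichment(input_genes: list[str], gsm: GeneSetMatrix,
               moment_studies: list[list[str]],
               ) -> list[EnrichmentResult]:
    """Observed sum-of-z per set, standardized by permutation moments.

    ``input_genes`` must already be filtered to the permutation panel and
    present in the gene-set matrix.  Sets whose permutation standard
    deviation is zero are excluded (logged).
    """
    if not input_genes:
        raise GseaError("no input genes")
    gene_index = gsm.gene_index
    missing = [g for g in input_genes if g not in gene_index]
    if missing:
        raise GseaError(f"input genes absent from gene-set matrix: "
                        f"{missing[:5]}")
    n_top = len(input_genes)
    obs = gsm.z[[gene_index[g] for g in input_genes]].sum(axis=0)
    sums = _study_sums(gsm, moment_studies, n_top)
    mu = sums.mean(axis=0)
    sd = sums.std(axis=0, ddof=1)
    results = []
    n_degenerate = 0
    for k, set_id in enumerate(gsm.sets):
        if sd[k] <= 0:
            n_degenerate += 1
            continue
        z = (obs[k] - mu[k]) / sd[k]
        p = max(float(stats.norm.sf(z)), _P_FLOOR)
        results.append(EnrichmentResult(
            set_id=set_id, S_obs=float(obs[k]), mu_perm=float(mu[k]),
            sd_perm=float(sd[k]), z_enrich=float(z), p=p))
    if n_degenerate:
        logger.info("enrichment: excluded %d sets with zero permutation "
                    "variance", n_degenerate)
    return results


def empirical_fdr(observed: list[EnrichmentResult],
                  fdr_studies: list[list[str]], gsm: GeneSetMatrix,
                  moment_studies: list[list[str]],
                  n_top: int) -> list[EnrichmentResult]:
    """Empirical FDR from a held-out batch of permuted studies.

    Each held-out study's top-``n_top`` genes act as pseudo-input and are
    scored against the same permutation moments, yielding a null p-value
    distribution.  FDR(p0) = mean over null studies of #{null p <= p0},
    divided by #{observed p <= p0}, then made non-decreasing in p and
    capped at 1.  Mutates and returns ``observed``.
    """
    if not observed:
        return observed
    sums = _study_sums(gsm, moment_studies, n_top)
    mu = sums.mean(axis=0)
    sd = sums.std(axis=0, ddof=1)
    live_ids = {r.set_id for r in observed}
    live = np.array([s in live_ids for s in gsm.sets])
    null_ps = []
    null_sums = _study_sums(gsm, fdr_studies, n_top)
    for row in null_sums:
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (row[live] - mu[live]) / sd[live]
        null_ps.append(np.maximum(stats.norm.sf(z), _P_FLOOR))
    null_ps = np.asarray(null_ps)        # n_fdr x n_live_sets

    obs_p = np.array([r.p for r in observed])
    order = np.argsort(obs_p, kind="stable")
    sorted_p = obs_p[order]
    # observed exceedance count: rank within sorted p
    n_obs_le = np.searchsorted(sorted_p, sorted_p, side="right")
    mean_null_le = np.array([
        np.mean(np.sum(null_ps <= p0, axis=1)) for p0 in sorted_p])
    raw = mean_null_le / np.maximum(n_obs_le, 1)
    # monotonize: fdr never decreases as p grows
    monotone = np.minimum.accumulate(raw[::-1])[::-1]
    monotone = np.minimum(monotone, 1.0)
    for rank, idx in enumerate(order):
        observed[idx].fdr = float(monotone[rank])
    return observed


# ---------------------------------------------------------------------------
# meta-gene sets
# ---------------------------------------------------------------------------

@dataclass
class MetaGeneSet:
    exemplar: str
    members: list[str]
    representative: str
    representative_p: float

    def __post_init__(self):
        if self.exemplar not in self.members:
            raise ValueError("exemplar must be a member")


def cluster_meta_gene_sets(gsm: GeneSetMatrix,
                           results: list[EnrichmentResult],
                           damping: float = 0.5, max_iter: int = 1000,
                           seed: int = 0) -> list[MetaGeneSet]:
    """Affinity propagation on set-by-set correlation of membership z.

    Preference is the median similarity (the algorithm's usual default)
    and damping 0.5; heavier damping measurably degrades recovery of
    construction-correlated set pairs on desk-scale problems.  On
    non-convergence every set becomes its own cluster, with a warning.
    Each meta-gene set is represented by the member with the smallest
    enrichment p-value.
    """
    if len(results) < 2:
        raise GseaError("need at least two analyzed sets to cluster")
    set_ids = [r.set_id for r in results]
    p_of = {r.set_id: r.p for r in results}
    cols = [gsm.sets.index(s) for s in set_ids]
    sim = np.corrcoef(gsm.z[:, cols], rowvar=False)
    sim = np.nan_to_num(sim, nan=0.0)
    pref = float(np.median(sim[np.triu_indices_from(sim, k=1)]))
    with warnings.catch_warnings():
        warnings.simplefilter("error", ConvergenceWarning)
        try:
            ap = AffinityPropagation(
                affinity="precomputed", damping=damping, max_iter=max_iter,
                preference=pref, random_state=seed).fit(sim)
            labels = ap.labels_
            centers = ap.cluster_centers_indices_
            converged = centers is not None and len(centers) > 0
        except ConvergenceWarning:
            converged = False
    if not converged:
        logger.warning("cluster_meta_gene_sets: affinity propagation did "
                       "not converge; falling back to singleton clusters")
        return [MetaGeneSet(exemplar=s, members=[s], representative=s,
                            representative_p=p_of[s]) for s in set_ids]
    out = []
    for c, center in enumerate(centers):
        members = [set_ids[i] for i in range(len(set_ids))
                   if labels[i] == c]
        rep = min(members, key=lambda s: (p_of[s], s))
        out.append(MetaGeneSet(exemplar=set_ids[center], members=members,
                               representative=rep,
                               representative_p=p_of[rep]))
    return out


# ---------------------------------------------------------------------------
# heatmap export and one-call driver
# ---------------------------------------------------------------------------

def export_heatmap_table(results: list[EnrichmentResult],
                         meta_sets: list[MetaGeneSet],
                         input_genes: list[str], retained: list[str],
                         gsm: GeneSetMatrix,
                         fdr_threshold: float = FDR_THRESHOLD):
    """Long-format table backing gene-by-meta-gene-set heatmaps.

    One row per (input gene, significant meta-gene set) with the gene's
    membership z in the representative set.  Input genes excluded from the
    analysis (panel filtering) still appear, flagged, because strong
    membership of an excluded gene is independent supporting evidence.
    """
    import pandas as pd

    fdr_of = {r.set_id: r.fdr for r in results}
    p_of = {r.set_id: r.p for r in results}
    gene_index = gsm.gene_index
    retained_set = set(retained)
    rows = []
    for ms in meta_sets:
        fdr = fdr_of.get(ms.representative)
        if fdr is None or fdr >= fdr_threshold:
            continue
        rep_col = gsm.sets.index(ms.representative)
        for gene in input_genes:
            gi = gene_index.get(gene)
            rows.append({
                "gene": gene,
                "meta_gene_set": ms.exemplar,
                "representative_set": ms.representative,
                "representative_p": p_of[ms.representative],
                "representative_fdr": fdr,
                "z": gsm.z[gi, rep_col] if gi is not None else np.nan,
                "significant": True,
                "excluded_from_analysis": gene not in retained_set,
            })
    columns = ["gene", "meta_gene_set", "representative_set",
               "representative_p", "representative_fdr", "z",
               "significant", "excluded_from_analysis"]
    return pd.DataFrame(rows, columns=columns)


@dataclass
class GseaOutput:
    input_genes: list[str]
    retained: list[str]
    removed: list[str]
    results: list[EnrichmentResult]
    meta_sets: list[MetaGeneSet]
    heatmap: "object" = field(default=None, repr=False)


def run_gsea(results: list[MetaVariantResult],
             annotations: list[AnnotationRecord], gsm: GeneSetMatrix,
             panel: PermutationPanel, n_moment: int = 200, n_fdr: int = 50,
             p_cut: float = INPUT_P_CUTOFF, ap_seed: int = 0,
             ) -> GseaOutput:
    """Full enrichment pass: input selection, panel filtering, moments,
    empirical FDR, meta-gene-set clustering and heatmap table.

    The first ``n_moment`` panel studies supply the permutation moments
    and the following ``n_fdr`` (disjoint) studies supply the empirical
    FDR null, honoring the separate-batch design.
    """
    if len(panel.studies) < n_moment + n_fdr:
        raise GseaError(f"panel has {len(panel.studies)} studies; "
                        f"{n_moment}+{n_fdr} required")
    moment_studies = panel.studies[:n_moment]
    fdr_studies = panel.studies[n_moment:n_moment + n_fdr]
    input_genes = select_input_genes(results, annotations, p_cut=p_cut)
    retained, removed = filter_to_panel(input_genes, panel)
    # genes must also be scoreable in the z-matrix
    retained = [g for g in retained if g in gsm.gene_index]
    if not retained:
        raise GseaError("no input genes usable for enrichment")
    enr = enrichment(retained, gsm, moment_studies)
    enr = empirical_fdr(enr, fdr_studies, gsm, moment_studies,
                        n_top=len(retained))
    meta_sets = cluster_meta_gene_sets(gsm, enr, seed=ap_seed) \
        if len(enr) >= 2 else []
    heatmap = export_heatmap_table(enr, meta_sets, input_genes, retained,
                                   gsm)
    return GseaOutput(input_genes=input_genes, retained=retained,
                      removed=removed, results=enr, meta_sets=meta_sets,
                      heatmap=heatmap)
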