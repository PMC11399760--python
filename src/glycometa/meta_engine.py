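"""Fixed-effect meta-analysis of cohort score sets; loci and novelty.

Score statistics are summed over cohorts that survive the per-cohort QC
filters (HWE exact p >= 1e-4 and call rate >= 0.99): U_meta = sum U_j,
V_meta = sum V_j.  Because the sums are associative, combining within
ancestries first and then across ancestries gives the same result as one
global combination.  Reported effect estimates and standard errors come
from the raw-trait analysis while p-values come from the inverse-normal
transformed analysis; the two streams are merged on variant identity.

Significant coding variants (p < 2.2e-7, a weighted-Bonferroni constant
taken as given) are partitioned into loci by greedy distance-based
clumping: the smallest-p unassigned variant seeds a locus and absorbs all
unassigned variants within 500 kb on the same chromosome.  A locus is
novel when every member is more than 500 kb from every known
trait-associated position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort_engine import (CALL_RATE_THRESHOLD, CohortScoreSet,
                            GeneCovariance, HWE_P_THRESHOLD)
from .formats_io import (CODING_CONSEQUENCES, AnnotationRecord, KnownLocus,
                         SumstatsRecord, VariantKey)

logger = logging.getLogger(__name__)

#: single-variant significance threshold for coding variants
CODING_P_THRESHOLD = 2.2e-7
#: distance defining distinct loci / novelty
LOCUS_WINDOW_BP = 500_000


class MetaInputError(ValueError):
    """Cohort score sets cannot be combined (mixed traits/transforms)."""


def _ident(key: VariantKey) -> tuple:
    """Orientation-free variant identity used to align cohorts."""
    return (key.chrom, key.pos,
            tuple(sorted((key.effect_allele, key.other_allele))))


@dataclass
class MetaScoreSet:
    """Combined per-variant scores for one trait/transform."""

    trait: str
    transform: str
    variants: list[VariantKey]
    U: np.ndarray
    V: np.ndarray
    n: np.ndarray
    eaf: np.ndarray
    n_cohorts: np.ndarray
    gene_cov: dict[str, GeneCovariance] = field(default_factory=dict)

    def index(self) -> dict[tuple, int]:
        return {_ident(v): i for i, v in enumerate(self.variants)}


def _qc_pass(ss: CohortScoreSet) -> np.ndarray:
    return ((ss.hwe_p >= HWE_P_THRESHOLD)
            & (ss.call_rate >= CALL_RATE_THRESHOLD))


def combine_scores(score_sets: list[CohortScoreSet],
                   apply_qc: bool = True) -> MetaScoreSet:
    """Sum score statistics across cohorts under a fixed-effect model.

    Cohort entries failing QC are dropped per variant before summation.
    Entries whose effect/other alleles are swapped relative to the first
    cohort seen are flipped (U negated, eaf complemented) by allele match;
    strand-ambiguous A/T and C/G variants are never flipped by frequency
    since genotyped array data share one strand convention.
    """
    if not score_sets:
        raise MetaInputError("no score sets to combine")
    traits = {s.trait for s in score_sets}
    transforms = {s.transform for s in score_sets}
    if len(traits) > 1:
        raise MetaInputError(f"mixing traits {sorted(traits)}")
    if len(transforms) > 1:
        raise MetaInputError(f"mixing transforms {sorted(transforms)}")

    order: list[tuple] = []
    ref: dict[tuple, VariantKey] = {}
    acc: dict[tuple, dict] = {}
    for ss in score_sets:
        ok = _qc_pass(ss) if apply_qc else np.ones(len(ss.variants), bool)
        for j, key in enumerate(ss.variants):
            ident = _ident(key)
            if ident not in ref:
                ref[ident] = key
                order.append(ident)
                acc[ident] = {"U": 0.0, "V": 0.0, "n": 0, "eaf_n": 0.0,
                              "n_cohorts": 0}
            rk = ref[ident]
            if (key.effect_allele == rk.effect_allele
                    and key.other_allele == rk.other_allele):
                flip = False
            elif (key.effect_allele == rk.other_allele
                    and key.other_allele == rk.effect_allele):
                flip = True
            else:
                raise MetaInputError(
                    f"allele mismatch at {key.chrom}:{key.pos}")
            if not ok[j]:
                continue
            a = acc[ident]
            sign = -1.0 if flip else 1.0
            eaf = ss.eaf[j]
            a["U"] += sign * float(ss.U[j])
            a["V"] += float(ss.V[j])
            a["n"] += int(ss.n[j])
            if np.isfinite(eaf):
                a["eaf_n"] += ((1.0 - eaf) if flip else eaf) * int(ss.n[j])
            a["n_cohorts"] += 1

    variants = [ref[i] for i in order]
    U = np.array([acc[i]["U"] for i in order])
    V = np.array([acc[i]["V"] for i in order])
    n = np.array([acc[i]["n"] for i in order], dtype=int)
    with np.errstate(invalid="ignore"):
        eaf = np.array([acc[i]["eaf_n"] / acc[i]["n"] if acc[i]["n"] else
                        np.nan for i in order])
    n_cohorts = np.array([acc[i]["n_cohorts"] for i in order], dtype=int)
    gene_cov = _combine_gene_cov(score_sets, apply_qc)
    return MetaScoreSet(trait=score_sets[0].trait,
                        transform=score_sets[0].transform,
                        variants=variants, U=U, V=V, n=n, eaf=eaf,
                        n_cohorts=n_cohorts, gene_cov=gene_cov)


def _combine_gene_cov(score_sets: list[CohortScoreSet],
                      apply_qc: bool) -> dict[str, GeneCovariance]:
    """Sum per-gene score covariances with the same QC drops and flips."""
    genes = sorted({g for ss in score_sets for g in ss.gene_cov})
    out: dict[str, GeneCovariance] = {}
    for gene in genes:
        order: list[tuple] = []
        ref: dict[tuple, VariantKey] = {}
        for ss in score_sets:
            gc = ss.gene_cov.get(gene)
            if gc is None:
                continue
            for key in gc.variants:
                ident = _ident(key)
                if ident not in ref:
                    ref[ident] = key
                    order.append(ident)
        k = len(order)
        pos = {ident: i for i, ident in enumerate(order)}
        total = np.zeros((k, k))
        for ss in score_sets:
            gc = ss.gene_cov.get(gene)
            if gc is None:
                continue
            ok = _qc_pass(ss) if apply_qc else np.ones(len(ss.variants),
                                                       bool)
            qc_by_ident = {_ident(v): ok[j]
                           for j, v in enumerate(ss.variants)}
            keep_idx = []
            signs = []
            cols = []
            for local, key in enumerate(gc.variants):
                ident = _ident(key)
                if not qc_by_ident.get(ident, True):
                    continue
                rk = ref[ident]
                flip = key.effect_allele == rk.other_allele
                keep_idx.append(local)
                signs.append(-1.0 if flip else 1.0)
                cols.append(pos[ident])
            if not keep_idx:
                continue
            sub = gc.cov[np.ix_(keep_idx, keep_idx)]
            s = np.asarray(signs)
            sub = sub * np.outer(s, s)
            total[np.ix_(cols, cols)] += sub
        out[gene] = GeneCovariance(gene=gene,
                                   variants=[ref[i] for i in order],
                                   cov=total)
    return out


# ---------------------------------------------------------------------------
# raw / INT pairing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MetaVariantResult:
    """Combined single-variant result: raw-scale effect, INT-scale p."""

    key: VariantKey
    U_meta: float
    V_meta: float
    beta: float
    se: float
    p: float
    n: int
    eaf: float
    n_cohorts: int


def merge_raw_int(raw: MetaScoreSet, int_: MetaScoreSet,
                  ) -> list[MetaVariantResult]:
    """Pair raw-trait effect estimates with INT-trait p-values.

    Inner join on variant identity; variants present in only one stream
    are dropped with a logged count.
    """
    if raw.transform != "raw" or int_.transform != "INT":
        raise MetaInputError("expected a raw and an INT meta score set")
    if raw.trait != int_.trait:
        raise MetaInputError("raw and INT streams are for different traits")
    int_index = int_.index()
    results = []
    dropped = 0
    matched_int = set()
    for i, key in enumerate(raw.variants):
        j = int_index.get(_ident(key))
        if j is None or raw.V[i] <= 0 or int_.V[j] <= 0:
            dropped += 1
            continue
        matched_int.add(j)
        z = int_.U[j] / np.sqrt(int_.V[j])
        results.append(MetaVariantResult(
            key=key,
            U_meta=float(raw.U[i]), V_meta=float(raw.V[i]),
            beta=float(raw.U[i] / raw.V[i]),
            se=float(1.0 / np.sqrt(raw.V[i])),
            p=float(2.0 * stats.norm.sf(abs(z))),
            n=int(int_.n[j]), eaf=float(raw.eaf[i]),
            n_cohorts=int(int_.n_cohorts[j])))
    dropped += len(int_.variants) - len(matched_int)
    if dropped:
        logger.info("merge_raw_int: dropped %d unmatched/degenerate "
                    "variant entries", dropped)
    return results


def results_to_sumstats(results: list[MetaVariantResult],
                        ) -> list[SumstatsRecord]:
    return [SumstatsRecord(key=r.key, eaf=float(np.clip(r.eaf, 0.0, 1.0)),
                           beta=r.beta, se=r.se, p=max(r.p, 5e-324),
                           n=r.n)
            for r in results]


# ---------------------------------------------------------------------------
# significance and locus definition
# ---------------------------------------------------------------------------

def significant_coding(results: list[MetaVariantResult],
                       annotations: list[AnnotationRecord],
                       threshold: float = CODING_P_THRESHOLD,
                       ) -> list[MetaVariantResult]:
    """Variants with a coding consequence and p strictly below threshold.

    A variant annotated in several genes counts as coding if any row has a
    coding consequence; unannotated variants are treated as non-coding.
    """
    coding: set[tuple] = set()
    annotated: set[tuple] = set()
    for rec in annotations:
        ident = _ident(rec.key)
        annotated.add(ident)
        if rec.consequence in CODING_CONSEQUENCES:
            coding.add(ident)
    n_unannotated = sum(1 for r in results
                        if _ident(r.key) not in annotated)
    if n_unannotated:
        logger.info("significant_coding: %d variants without annotation "
                    "treated as non-coding", n_unannotated)
    return [r for r in results
            if _ident(r.key) in coding and r.p < threshold]


@dataclass
class Locus:
    """A distance-defined association signal."""

    lead: VariantKey
    members: list[VariantKey]
    trait: str
    lead_p: float
    novel: bool | None = None
    matched_known: str | None = None


def clump(results: list[MetaVariantResult], trait: str = "",
          window: int = LOCUS_WINDOW_BP) -> list[Locus]:
    """Greedy lead-anchored distance clumping.

    Variants are taken in order of ascending p (ties broken by genomic
    position); each unassigned variant in turn becomes a lead and absorbs
    every unassigned variant within ``window`` bp on its chromosome.
    Signals more than ``window`` bp apart therefore fall in distinct loci.
    The result is independent of the input order.
    """
    items = sorted(results, key=lambda r: (r.p, r.key.sort_key()))
    assigned: set[int] = set()
    loci: list[Locus] = []
    for i, lead in enumerate(items):
        if i in assigned:
            continue
        members = []
        for j, cand in enumerate(items):
            if j in assigned or cand.key.chrom != lead.key.chrom:
                continue
            if abs(cand.key.pos - lead.key.pos) <= window:
                members.append(j)
        assigned.update(members)
        loci.append(Locus(lead=lead.key,
                          members=[items[j].key for j in members],
                          trait=trait or "", lead_p=lead.p))
    return loci


def classify_novelty(loci: list[Locus], known: list[KnownLocus],
                     window: int = LOCUS_WINDOW_BP) -> list[Locus]:
    """Flag loci as novel when no member sits within ``window`` bp of a
    known trait-associated position; otherwise attach the nearest label."""
    if not known:
        logger.warning("classify_novelty: empty known-locus list; "
                       "all loci flagged novel")
    for locus in loci:
        best: tuple[int, str] | None = None
        for member in locus.members:
            for kn in known:
                if kn.chrom != member.chrom:
                    continue
                d = abs(kn.pos - member.pos)
                if best is None or d < best[0]:
                    best = (d, kn.source_label)
        if best is not None and best[0] <= window:
            locus.novel = False
            locus.matched_known = best[1]
        else:
            locus.novel = True
            locus.matched_known = None
    return loci
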