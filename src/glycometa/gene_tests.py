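"""Gene-level burden and SKAT tests from meta-combined score statistics.

Variant masks
-------------
NSstrict collects predicted protein-truncating variants (splice donor or
acceptor, stop gained or lost, frameshift, initiator codon) together with
missense variants called damaging by all five predictors (SIFT, PolyPhen
HumDiv, PolyPhen HumVar, LRT, MutationTaster).  NSbroad additionally admits
missense variants damaging by at least one predictor *and* rarer than 1%
minor-allele frequency in every ancestry group.  Only genes with at least
two qualifying variants are tested.

Tests
-----
With the gene's score vector U and score covariance C, the burden test
collapses variants into T = w'U with variance w'Cw and a two-sided normal
p-value — powerful when effects share a direction.  SKAT uses
Q = sum w_j^2 U_j^2, whose null law is a mixture of one-degree chi-squares
with weights equal to the eigenvalues of W C W; the tail probability comes
from characteristic-function inversion (Davies-style, evaluated through
Imhof's integral) with a Liu moment-matching fallback.  SKAT keeps power
when effect directions are mixed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .formats_io import (AnnotationRecord, PTV_CONSEQUENCES, VariantKey)
from .meta_engine import MetaScoreSet, _ident

logger = logging.getLogger(__name__)

MASKS = ("NSstrict", "NSbroad")

#: Bonferroni threshold for ~20,000 genes at family-wise 0.05
GENE_P_THRESHOLD = 2.5e-6

RARE_MAF_THRESHOLD = 0.01


def gene_based_threshold(n_genes: int = 20_000,
                         alpha: float = 0.05) -> float:
    """Bonferroni significance threshold for gene-level tests."""
    return alpha / n_genes


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

@dataclass
class GeneMask:
    """Variants of one gene qualifying under one mask."""

    gene: str
    mask: str
    variants: list[VariantKey]

    def __post_init__(self):
        if self.mask not in MASKS:
            raise ValueError(f"unknown mask {self.mask!r}")
        if len({_ident(v) for v in self.variants}) != len(self.variants):
            raise ValueError("duplicate variants in mask")
        if len(self.variants) < 2:
            raise ValueError("mask requires at least two variants")


def _qualifies(rec: AnnotationRecord, mask: str,
               required_ancestries: set[str]) -> bool:
    if rec.consequence in PTV_CONSEQUENCES:
        return True          # PTV clause carries no frequency condition
    if rec.consequence != "missense":
        return False
    n_damaging = sum(rec.damaging_flags)
    if n_damaging == 5:
        return True
    if mask == "NSstrict":
        return False
    if n_damaging < 1:
        return False
    # NSbroad frequency clause: MAF < 1% in *each* ancestry group; a
    # missing frequency fails the conjunct (conservative)
    for anc in required_ancestries:
        maf = rec.maf_by_ancestry.get(anc)
        if maf is None or maf >= RARE_MAF_THRESHOLD:
            return False
    return True


def build_masks(annotations: list[AnnotationRecord],
                required_ancestries: set[str] | None = None,
                ) -> list[GeneMask]:
    """NSstrict and NSbroad masks per gene; genes with <2 variants omitted.

    ``required_ancestries`` defaults to every ancestry label appearing in
    the annotation table's frequency columns.
    """
    if required_ancestries is None:
        required_ancestries = {a for r in annotations
                               for a in r.maf_by_ancestry}
    n_missing_maf = sum(
        1 for r in annotations if r.consequence == "missense"
        and any(a not in r.maf_by_ancestry for a in required_ancestries))
    if n_missing_maf:
        logger.info("build_masks: %d missense variants lack a frequency "
                    "for some ancestry and fail the NSbroad MAF clause",
                    n_missing_maf)
    masks: list[GeneMask] = []
    by_gene: dict[str, list[AnnotationRecord]] = {}
    for rec in annotations:
        by_gene.setdefault(rec.gene, []).append(rec)
    for gene in sorted(by_gene):
        for mask in MASKS:
            seen: set[tuple] = set()
            variants = []
            for rec in by_gene[gene]:
                if _ident(rec.key) in seen:
                    continue
                if _qualifies(rec, mask, required_ancestries):
                    seen.add(_ident(rec.key))
                    variants.append(rec.key)
            if len(variants) >= 2:
                masks.append(GeneMask(gene=gene, mask=mask,
                                      variants=variants))
    return masks


# ---------------------------------------------------------------------------
# quadratic-form tail probability
# ---------------------------------------------------------------------------

_MAX_OSCILLATIONS = 600.0


def _imhof_tail(q: float, lambdas: np.ndarray, epsabs: float,
                ) -> tuple[float, float]:
    """P(sum lambda_k chi2_1 > q) by numerical inversion of the
    characteristic function (Imhof's integral form).

    Integrates on (0, U] where U comes from the analytic envelope
    |integrand| <= 1 / (u^(k/2+1) prod sqrt(lambda)); returns the value
    and a certified absolute error (quadrature estimate plus truncation
    bound).  When the truncated range would contain too many oscillations
    for adaptive quadrature the certified error is reported as infinite
    so the caller can switch to the series expansion.
    """
    k = lambdas.size
    log_prod = 0.5 * float(np.sum(np.log(lambdas)))
    # tail(U) = 1 / (pi * (k/2) * U^(k/2) * prod lambda^(1/2))
    with np.errstate(over="ignore"):
        U = float(np.exp((-np.log(np.pi * (k / 2.0) * epsabs) - log_prod)
                         / (k / 2.0)))
    tail_bound = np.exp(-log_prod) / (np.pi * (k / 2.0) * U ** (k / 2.0))
    period = 4.0 * np.pi / max(q, 1e-3)
    n_osc = U / period
    if not np.isfinite(U) or n_osc > _MAX_OSCILLATIONS:
        return np.nan, np.inf

    def integrand(u: float) -> float:
        theta = 0.5 * np.sum(np.arctan(lambdas * u)) - 0.5 * q * u
        rho = np.exp(0.25 * np.sum(np.log1p((lambdas * u) ** 2)))
        return np.sin(theta) / (u * rho)

    # a few oscillations per panel keeps each quad call cheap and reliable
    n_panels = max(1, int(np.ceil(n_osc / 4.0)))
    edges = np.linspace(0.0, U, n_panels + 1)
    value = 0.0
    quad_err = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        v, e = integrate.quad(integrand, a, b, epsabs=epsabs / n_panels,
                              epsrel=0.0, limit=60)
        value += v
        quad_err += abs(e)
    return 0.5 + value / np.pi, quad_err + tail_bound


def _ruben_tail(q: float, lambdas: np.ndarray, eps: float,
                max_terms: int = 20000) -> tuple[float, float]:
    """Exact mixture-of-central-chi-square series (Ruben's expansion).

    With beta = min(lambda) the mixture is a nonnegative series of scaled
    chi-square tails, so the truncation error is bounded by the untouched
    coefficient mass.  Returns (p, error bound).
    """
    k = lambdas.size
    beta = float(lambdas.min())
    ratio = 1.0 - beta / lambdas          # entries in [0, 1)
    log_c0 = 0.5 * float(np.sum(np.log(beta / lambdas)))
    if log_c0 < -700.0:                   # coefficient underflow
        return np.nan, np.inf
    c = np.empty(max_terms)
    c[0] = np.exp(log_c0)
    mass = c[0]
    powers = ratio.copy()
    d = np.empty(max_terms)
    n_terms = 1
    for m in range(1, max_terms):
        d[m] = 0.5 * float(powers.sum())
        powers *= ratio
        c[m] = float(d[1:m + 1] @ c[m - 1::-1]) / m
        mass += c[m]
        n_terms = m + 1
        if 1.0 - mass < eps:
            break
    dof = k + 2 * np.arange(n_terms)
    p = float(c[:n_terms] @ stats.chi2.sf(q / beta, df=dof))
    return p, max(1.0 - mass, 0.0)


def _liu_tail(q: float, lambdas: np.ndarray) -> float:
    """Liu-Tang-Zhang moment-matching approximation of the mixture tail."""
    c1 = lambdas.sum()
    c2 = (lambdas ** 2).sum()
    c3 = (lambdas ** 3).sum()
    c4 = (lambdas ** 4).sum()
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    if s1 ** 2 > s2:
        a = 1.0 / (s1 - np.sqrt(s1 ** 2 - s2))
        delta = s1 * a ** 3 - a ** 2
        dof = a ** 2 - 2.0 * delta
    else:
        delta = 0.0
        dof = 1.0 / s2
    mu_x = dof + delta
    sigma_x = np.sqrt(2.0) * np.sqrt(dof + 2.0 * delta)
    t_star = (q - c1) / np.sqrt(2.0 * c2)
    return float(stats.ncx2.sf(t_star * sigma_x + mu_x, df=dof, nc=delta))


def quadform_pvalue(q: float, eigenvalues, epsabs: float = 1e-9,
                    ) -> tuple[float, str]:
    """Upper-tail probability of a mixture of chi-square(1) variables.

    The characteristic-function inversion is attempted first at absolute
    accuracy ``epsabs``; when its certified error bound exceeds 1e-6 (or
    the value leaves (0, 1)) the exact Ruben series takes over, and the
    Liu moment-matching approximation is the last resort.  Returns
    ``(p, method)`` with method in {"exact", "davies", "ruben", "liu"}.
    """
    lambdas = np.asarray(eigenvalues, dtype=float)
    if lambdas.size == 0:
        raise ValueError("no eigenvalues supplied")
    if np.any(lambdas < -1e-8 * max(1.0, float(np.abs(lambdas).max()))):
        raise ValueError("negative eigenvalue beyond tolerance")
    lambdas = lambdas[lambdas > 0]
    if lambdas.size == 0:
        raise ValueError("eigenvalues all zero")
    q = float(q)
    if q <= 0:
        return 1.0, "exact"
    if np.allclose(lambdas, lambdas[0], rtol=1e-12):
        # equal weights: plain scaled chi-square tail
        return float(stats.chi2.sf(q / lambdas[0], df=lambdas.size)), \
            "exact"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", integrate.IntegrationWarning)
        try:
            with np.errstate(over="raise"):
                p, err = _imhof_tail(q, lambdas, epsabs)
        except FloatingPointError:
            p, err = np.nan, np.inf
    if 0.0 < p < 1.0 and err <= 1e-6:
        return float(p), "davies"
    p, err = _ruben_tail(q, lambdas, max(epsabs, 1e-12))
    if np.isfinite(p) and err <= 1e-6 and 0.0 <= p <= 1.0:
        return float(max(p, 0.0)), "ruben"
    return _liu_tail(q, lambdas), "liu"


# ---------------------------------------------------------------------------
# burden and SKAT
# ---------------------------------------------------------------------------

class DegenerateGeneError(ValueError):
    """The gene's score covariance cannot support the requested test."""


def burden_test(U, cov, weights=None) -> tuple[float, float]:
    """Collapsed-score burden test: T = w'U, var = w'Cw, two-sided p."""
    U = np.asarray(U, dtype=float)
    cov = np.asarray(cov, dtype=float)
    w = np.ones(U.size) if weights is None else np.asarray(weights, float)
    T = float(w @ U)
    var = float(w @ cov @ w)
    if var <= 0:
        raise DegenerateGeneError("burden variance is not positive")
    z = T / np.sqrt(var)
    return T, float(2.0 * stats.norm.sf(abs(z)))


def skat_test(U, cov, weights=None) -> tuple[float, float, str]:
    """Variance-component (SKAT) test from scores and their covariance.

    Q = sum w_j^2 U_j^2; the null distribution is sum lambda_k chi2_1 with
    lambda_k the eigenvalues of W C W.  Returns (Q, p, method).
    """
    U = np.asarray(U, dtype=float)
    cov = np.asarray(cov, dtype=float)
    w = np.ones(U.size) if weights is None else np.asarray(weights, float)
    Q = float(np.sum((w * U) ** 2))
    wcw = cov * np.outer(w, w)
    lambdas = np.linalg.eigvalsh(wcw)
    lambdas = np.clip(lambdas, 0.0, None)
    if not np.any(lambdas > 0):
        return Q, 1.0, "degenerate"
    if Q == 0.0:
        return Q, 1.0, "exact"
    p, method = quadform_pvalue(Q, lambdas)
    return Q, p, method


def beta_maf_weights(mafs, a: float = 1.0, b: float = 25.0) -> np.ndarray:
    """Beta(MAF; a, b) density weights, the common SKAT up-weighting of
    rare variants; the package default remains w = 1."""
    mafs = np.asarray(mafs, dtype=float)
    return stats.beta.pdf(np.clip(mafs, 1e-6, 1 - 1e-6), a, b)


# ---------------------------------------------------------------------------
# per-gene driver
# ---------------------------------------------------------------------------

@dataclass
class GeneTestResult:
    gene: str
    mask: str
    trait: str
    n_var: int
    T_burden: float
    p_burden: float
    Q_skat: float
    p_skat: float
    significant: bool
    skat_method: str = "davies"
    error: str | None = None


def run_gene_tests(masks: list[GeneMask], meta: MetaScoreSet,
                   threshold: float = GENE_P_THRESHOLD,
                   weight_scheme: str = "uniform",
                   ) -> list[GeneTestResult]:
    """Burden and SKAT for every gene x mask on meta-combined INT scores.

    ``weight_scheme`` is ``"uniform"`` (default) or ``"beta_maf"``
    (Beta(1,25) density of the meta effect-allele frequency).  A gene whose
    covariance is absent from the meta store is skipped with a warning.
    """
    index = meta.index()
    results: list[GeneTestResult] = []
    for gm in masks:
        gc = meta.gene_cov.get(gm.gene)
        if gc is None:
            logger.warning("run_gene_tests: no covariance for gene %s; "
                           "skipped", gm.gene)
            continue
        cov_pos = {_ident(v): i for i, v in enumerate(gc.variants)}
        rows = []
        meta_rows = []
        for v in gm.variants:
            ci = cov_pos.get(_ident(v))
            mi = index.get(_ident(v))
            if ci is None or mi is None:
                continue
            rows.append(ci)
            meta_rows.append(mi)
        if len(rows) < 2:
            continue
        U = meta.U[meta_rows]
        cov = gc.cov[np.ix_(rows, rows)]
        if weight_scheme == "uniform":
            w = np.ones(len(rows))
        elif weight_scheme == "beta_maf":
            eaf = meta.eaf[meta_rows]
            w = beta_maf_weights(np.minimum(eaf, 1.0 - eaf))
        else:
            raise ValueError(f"unknown weight scheme {weight_scheme!r}")
        try:
            T, p_burden = burden_test(U, cov, w)
        except DegenerateGeneError as exc:
            results.append(GeneTestResult(
                gene=gm.gene, mask=gm.mask, trait=meta.trait,
                n_var=len(rows), T_burden=np.nan, p_burden=np.nan,
                Q_skat=np.nan, p_skat=np.nan, significant=False,
                error=str(exc)))
            continue
        Q, p_skat, method = skat_test(U, cov, w)
        results.append(GeneTestResult(
            gene=gm.gene, mask=gm.mask, trait=meta.trait, n_var=len(rows),
            T_burden=T, p_burden=p_burden, Q_skat=Q, p_skat=p_skat,
            significant=min(p_burden, p_skat) < threshold,
            skat_method=method))
    return results
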