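"""Per-cohort processing: exclusions, trait transform, null model, scores.

For each cohort and trait the engine excludes individuals in the diabetes
range, optionally applies a rank-based inverse normal transform, fits an
ordinary least-squares null model of the trait on the covariates, and then
computes per-variant score statistics

    U_j = g~_j' e / sigma2        V_j = g~_j' g~_j / sigma2

where ``e`` are the null-model residuals, ``sigma2`` the residual variance
and ``g~_j`` the dosage of variant j residualized on the covariate design
over that variant's non-missing individuals.  U and V are summable across
cohorts under a fixed-effect model, and U/V, 1/sqrt(V) and U/sqrt(V) are
the per-cohort effect estimate, its standard error and the test z-score.
Per-gene score covariances G~'G~ / sigma2 are the additional summary needed
to run burden and SKAT tests from these statistics alone.

The null model is a plain linear model: the synthetic cohorts are
unrelated, and with zero kinship the mixed-model score algebra reduces to
exactly this form.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .formats_io import VariantKey

TRAITS = ("FG", "FI", "2hGlu", "HbA1c")
TRANSFORMS = ("raw", "INT")

#: diabetes-range thresholds, inclusive (trait units: mmol/L, mmol/L, %)
DIABETES_THRESHOLDS = {"FG": 7.0, "2hGlu": 11.1, "HbA1c": 6.5}

#: QC filters applied before meta-analysis
HWE_P_THRESHOLD = 1e-4
CALL_RATE_THRESHOLD = 0.99

_SIGMA2_FLOOR = 1e-12


class DegenerateFitError(ValueError):
    """The null model fit is unusable (rank deficiency or zero variance)."""


# ---------------------------------------------------------------------------
# sample exclusions
# ---------------------------------------------------------------------------

def exclude_diabetes(phenotypes: pd.DataFrame,
                     treatment_flags: np.ndarray | None = None) -> np.ndarray:
    """Inclusion mask: True = keep for analysis.

    An individual is excluded iff the treated/diagnosed flag is set, or any
    of FG >= 7 mmol/L, 2hGlu >= 11.1 mmol/L, HbA1c >= 6.5% holds (boundaries
    inclusive).  Missing trait values never trigger exclusion on their own.
    """
    n = len(phenotypes)
    excluded = np.zeros(n, dtype=bool)
    if treatment_flags is not None:
        excluded |= np.asarray(treatment_flags, dtype=bool)
    for trait, threshold in DIABETES_THRESHOLDS.items():
        if trait not in phenotypes.columns:
            continue
        values = phenotypes[trait].to_numpy(dtype=float)
        finite = np.isfinite(values)
        if np.any(values[finite] < 0):
            raise ValueError(f"negative {trait} value encountered")
        excluded |= finite & (values >= threshold)
    return ~excluded


# ---------------------------------------------------------------------------
# inverse normal transform
# ---------------------------------------------------------------------------

def inverse_normal(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform, Phi^-1((r - c)/(n - 2c + 1)).

    The default offset c = 3/8 is the Blom convention (c = 1/2 gives the
    van der Waerden-like variant).  Ties receive their average rank, so
    tied inputs map to equal outputs; missing values stay missing.
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    mask = np.isfinite(values)
    x = values[mask]
    if x.size < 2:
        raise ValueError("need at least 2 non-missing values")
    if np.all(x == x[0]):
        raise ValueError("all values identical; transform undefined")
    ranks = stats.rankdata(x, method="average")
    quantiles = (ranks - offset) / (x.size - 2.0 * offset + 1.0)
    out[mask] = stats.norm.ppf(quantiles)
    return out


# ---------------------------------------------------------------------------
# null model
# ---------------------------------------------------------------------------

@dataclass
class NullModel:
    """OLS fit of the (possibly transformed) trait on covariates."""

    design: np.ndarray        # n x p, includes intercept column
    residuals: np.ndarray
    sigma2: float
    coef: np.ndarray
    column_names: list[str]


def fit_null_model(trait_values, covariates: pd.DataFrame | None = None,
                   ) -> NullModel:
    """Fit trait ~ intercept + covariates by ordinary least squares.

    sigma2 is the usual unbiased estimate RSS / (n - p).  A rank-deficient
    design raises an error naming the collinear columns.
    """
    y = np.asarray(trait_values, dtype=float)
    if covariates is None or covariates.shape[1] == 0:
        X = np.ones((y.size, 1))
        names = ["intercept"]
    else:
        X = np.column_stack([np.ones(len(covariates)),
                             covariates.to_numpy(dtype=float)])
        names = ["intercept"] + list(covariates.columns)
    if not np.all(np.isfinite(y)):
        keep = np.isfinite(y)
        raise ValueError(
            f"{(~keep).sum()} missing trait values; subset before fitting")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns via pivoted QR diagnostics
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in range(len(names))
               if diag[i] < 1e-8 * max(diag.max(), 1.0)]
        raise DegenerateFitError(
            f"design matrix rank deficient; collinear column(s): {bad}")
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    residuals = y - X @ coef
    dof = y.size - X.shape[1]
    if dof <= 0:
        raise DegenerateFitError("no residual degrees of freedom")
    sigma2 = float(residuals @ residuals) / dof
    return NullModel(design=X, residuals=residuals, sigma2=sigma2,
                     coef=coef, column_names=names)


# ---------------------------------------------------------------------------
# score statistics
# ---------------------------------------------------------------------------

@dataclass
class ScoreStats:
    """Per-variant score statistics for one cohort/trait/transform."""

    U: np.ndarray
    V: np.ndarray
    n: np.ndarray            # non-missing sample count per variant
    eaf: np.ndarray
    monomorphic: np.ndarray  # bool

    @property
    def beta(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.V > 0, self.U / self.V, np.nan)

    @property
    def se(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.where(self.V > 0, 1.0 / np.sqrt(self.V), np.nan)

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(self.V > 0, self.U / np.sqrt(self.V), np.nan)

    @property
    def p(self) -> np.ndarray:
        z = self.z
        out = np.full(z.shape, np.nan)
        ok = np.isfinite(z)
        out[ok] = 2.0 * stats.norm.sf(np.abs(z[ok]))
        return out


def _residualize(g: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Project out the covariate design from a dosage vector."""
    coef, _, _, _ = np.linalg.lstsq(X, g, rcond=None)
    return g - X @ coef


def score_stats(null: NullModel, dosages: np.ndarray) -> ScoreStats:
    """Score statistic U and variance V for each variant column.

    Missing dosages are handled complete-case per variant (no imputation):
    the residualization, inner products and allele frequency all run over
    that variant's genotyped individuals only.  Monomorphic variants get
    U = V = 0 with a flag.
    """
    if null.sigma2 < _SIGMA2_FLOOR:
        raise DegenerateFitError(
            f"sigma2 = {null.sigma2:.3g} below {_SIGMA2_FLOOR}; "
            "refusing variant statistics for a degenerate fit")
    dosages = np.asarray(dosages, dtype=float)
    n_ind, n_var = dosages.shape
    if n_ind != null.design.shape[0]:
        raise ValueError("dosage rows must match null-model individuals")
    U = np.zeros(n_var)
    V = np.zeros(n_var)
    n_obs = np.zeros(n_var, dtype=int)
    eaf = np.full(n_var, np.nan)
    mono = np.zeros(n_var, dtype=bool)
    any_missing = np.isnan(dosages).any()
    if not any_missing:
        # vectorized fast path: one joint residualization
        gtil = dosages - null.design @ np.linalg.lstsq(
            null.design, dosages, rcond=None)[0]
        U = gtil.T @ null.residuals / null.sigma2
        V = np.einsum("ij,ij->j", gtil, gtil) / null.sigma2
        n_obs[:] = n_ind
        eaf = dosages.mean(axis=0) / 2.0
        mono = np.all(dosages == dosages[0:1, :], axis=0)
        U[mono] = 0.0
        V[mono] = 0.0
        return ScoreStats(U=U, V=V, n=n_obs, eaf=eaf, monomorphic=mono)
    for j in range(n_var):
        g = dosages[:, j]
        keep = ~np.isnan(g)
        n_obs[j] = int(keep.sum())
        if n_obs[j] == 0:
            mono[j] = True
            continue
        gk = g[keep]
        eaf[j] = gk.mean() / 2.0
        if np.all(gk == gk[0]):
            mono[j] = True
            continue
        gtil = _residualize(gk, null.design[keep])
        U[j] = float(gtil @ null.residuals[keep]) / null.sigma2
        V[j] = float(gtil @ gtil) / null.sigma2
    return ScoreStats(U=U, V=V, n=n_obs, eaf=eaf, monomorphic=mono)


# ---------------------------------------------------------------------------
# per-gene score covariance
# ---------------------------------------------------------------------------

@dataclass
class GeneCovariance:
    """Covariance of score statistics for one gene's variants."""

    gene: str
    variants: list[VariantKey]
    cov: np.ndarray

    def __post_init__(self):
        self.cov = np.asarray(self.cov, dtype=float)
        k = len(self.variants)
        if self.cov.shape != (k, k):
            raise ValueError("covariance shape does not match variants")
        if k:
            eigmin = float(np.linalg.eigvalsh(self.cov).min())
            if eigmin < -1e-8 * max(1.0, float(np.abs(self.cov).max())):
                raise ValueError(
                    f"covariance not PSD (min eigenvalue {eigmin:.3g})")


def gene_covariance(null: NullModel, dosages: np.ndarray,
                    variants: list[VariantKey],
                    gene_map: dict[str, list[int]],
                    ) -> dict[str, GeneCovariance]:
    """Per-gene G~'G~ / sigma2 over member variants.

    Pairwise products run over individuals genotyped for both variants
    (missing entries contribute nothing), so the diagonal coincides with
    the per-variant score variance V.
    """
    if null.sigma2 < _SIGMA2_FLOOR:
        raise DegenerateFitError("sigma2 below floor")
    dosages = np.asarray(dosages, dtype=float)
    out = {}
    for gene, cols in gene_map.items():
        if not cols:
            continue
        block = np.empty((dosages.shape[0], len(cols)))
        for k, j in enumerate(cols):
            g = dosages[:, j]
            keep = ~np.isnan(g)
            col = np.zeros(dosages.shape[0])
            if keep.sum() and not np.all(g[keep] == g[keep][0]):
                col[keep] = _residualize(g[keep], null.design[keep])
            block[:, k] = col
        cov = block.T @ block / null.sigma2
        out[gene] = GeneCovariance(gene=gene,
                                   variants=[variants[j] for j in cols],
                                   cov=cov)
    return out


# ---------------------------------------------------------------------------
# variant QC: call rate and exact Hardy-Weinberg test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact conditional Hardy-Weinberg test (no mid-p correction).

    Enumerates every heterozygote count compatible with the observed allele
    counts and sums the probabilities of all configurations no more likely
    than the observed one (two-sided by probability ordering).
    """
    n_hom_ref, n_het, n_hom_alt = int(n_hom_ref), int(n_het), int(n_hom_alt)
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    rare = 2 * min(n_hom_ref, n_hom_alt) + n_het
    # anchor the recurrence at the expected heterozygote count
    mid = int(round(rare * (2 * n - rare) / (2.0 * n)))
    if mid % 2 != rare % 2:
        mid += 1
    mid = min(mid, rare)
    probs = np.zeros(rare + 1)
    probs[mid] = 1.0
    # going down in het count: p(h-2) = p(h) * h(h-1) / (4 (r+1)(c+1))
    het = mid
    homr = (rare - mid) // 2
    homc = n - het - homr
    while het >= 2:
        probs[het - 2] = (probs[het] * het * (het - 1)
                          / (4.0 * (homr + 1) * (homc + 1)))
        het -= 2
        homr += 1
        homc += 1
    het = mid
    homr = (rare - mid) // 2
    homc = n - het - homr
    while het <= rare - 2:
        probs[het + 2] = (probs[het] * 4.0 * homr * homc
                          / ((het + 2.0) * (het + 1.0)))
        het += 2
        homr -= 1
        homc -= 1
    total = probs.sum()
    obs = n_het
    # tolerate float fuzz when comparing configuration probabilities
    p = probs[probs <= probs[obs] * (1.0 + 1e-12)].sum() / total
    return float(min(p, 1.0))


def hwe_chi2_p(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """One-degree-of-freedom chi-square alternative to the exact test."""
    n = n_hom_ref + n_het + n_hom_alt
    if n == 0:
        return 1.0
    p = (2 * n_hom_alt + n_het) / (2.0 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([q * q * n, 2 * p * q * n, p * p * n])
    observed = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def variant_qc(dosages: np.ndarray, method: str = "exact",
               ) -> tuple[np.ndarray, np.ndarray]:
    """Call rate and HWE p-value per variant from hard-called dosages."""
    dosages = np.asarray(dosages, dtype=float)
    n_ind, n_var = dosages.shape
    call_rate = 1.0 - np.isnan(dosages).sum(axis=0) / float(n_ind)
    hwe_p = np.ones(n_var)
    test = hwe_exact_p if method == "exact" else hwe_chi2_p
    for j in range(n_var):
        g = dosages[:, j]
        g = g[~np.isnan(g)]
        if g.size == 0:
            continue
        counts = np.round(g).astype(int)
        hwe_p[j] = test(int((counts == 0).sum()), int((counts == 1).sum()),
                        int((counts == 2).sum()))
    return call_rate, hwe_p


# ---------------------------------------------------------------------------
# assembled per-cohort score set
# ---------------------------------------------------------------------------

@dataclass
class CohortScoreSet:
    """Everything downstream meta-analysis needs from one cohort."""

    cohort_id: str
    ancestry: str
    trait: str
    transform: str
    variants: list[VariantKey]
    U: np.ndarray
    V: np.ndarray
    n: np.ndarray
    eaf: np.ndarray
    call_rate: np.ndarray
    hwe_p: np.ndarray
    monomorphic: np.ndarray
    gene_cov: dict[str, GeneCovariance] = field(default_factory=dict)
    n_excluded: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "variant": [v.label for v in self.variants],
            "chromosome": [v.chrom for v in self.variants],
            "base_pair_location": [v.pos for v in self.variants],
            "effect_allele": [v.effect_allele for v in self.variants],
            "other_allele": [v.other_allele for v in self.variants],
            "U": self.U, "V": self.V, "n": self.n, "eaf": self.eaf,
            "call_rate": self.call_rate, "hwe_p": self.hwe_p,
            "monomorphic": self.monomorphic.astype(int),
        })


def compute_cohort_scores(cohort, trait: str, transform: str = "INT",
                          hwe_method: str = "exact",
                          with_gene_cov: bool = True) -> CohortScoreSet:
    """Run the full per-cohort stage for one trait and transform.

    Applies the diabetes exclusions, transforms the trait, fits the null
    model on age/sex/BMI/PC covariates, and computes score statistics,
    QC metrics and (optionally) per-gene score covariances.
    """
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}")
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    include = exclude_diabetes(cohort.phenotypes, cohort.treatment_flags)
    y = cohort.phenotypes[trait].to_numpy(dtype=float)[include]
    if transform == "INT":
        y = inverse_normal(y)
    covariates = cohort.covariates.loc[include].reset_index(drop=True)
    null = fit_null_model(y, covariates)
    dosages = cohort.dosages[include]
    ss = score_stats(null, dosages)
    call_rate, hwe_p = variant_qc(dosages, method=hwe_method)
    gene_cov = {}
    if with_gene_cov:
        gene_map: dict[str, list[int]] = {}
        for j, gene in enumerate(cohort.variant_genes):
            gene_map.setdefault(gene, []).append(j)
        gene_cov = gene_covariance(null, dosages, cohort.variants, gene_map)
    return CohortScoreSet(
        cohort_id=cohort.cohort_id, ancestry=cohort.ancestry, trait=trait,
        transform=transform, variants=list(cohort.variants),
        U=ss.U, V=ss.V, n=ss.n, eaf=ss.eaf, call_rate=call_rate,
        hwe_p=hwe_p, monomorphic=ss.monomorphic, gene_cov=gene_cov,
        n_excluded=int((~include).sum()))
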