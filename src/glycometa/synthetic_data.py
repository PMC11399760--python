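"""Synthetic multi-cohort exome-array fixtures with planted ground truth.

The generator emulates the structure of a multi-ancestry exome-chip
consortium at desk scale: several cohorts per ancestry sharing one fixed
variant panel, ancestry-specific allele-frequency spectra dominated by rare
variants, additive genetic effects concentrated in designated causal genes,
age/sex/BMI/PC covariate effects, Gaussian trait noise, and a fraction of
individuals pushed into the diabetes range to exercise the phenotype
exclusions.  Everything is a pure function of the configuration seed.

Variants are simulated independently (no LD) and cohorts are unrelated;
both simplifications are documented in the methods note.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats_io import (AnnotationRecord, GeneSetMatrix, VariantKey,
                         PTV_CONSEQUENCES)

TRAITS = ("FG", "FI", "2hGlu", "HbA1c")

#: baseline trait means in their natural units
TRAIT_BASELINES = {"FG": 5.1, "FI": 4.4, "2hGlu": 5.5, "HbA1c": 5.4}

#: values that place an individual in the diabetes range (upper bound of
#: the uniform draw used for planted diabetic individuals)
_DIABETES_RANGES = {"FG": (7.0, 10.0), "2hGlu": (11.1, 16.0),
                    "HbA1c": (6.5, 9.5)}


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class CausalGene:
    """A gene carrying planted additive effects.

    ``effect`` is the per-allele effect in trait units, applied to a
    ``fraction_causal`` subset of the gene's variants.  ``trait`` limits the
    effect to one trait; ``None`` applies it to all four.
    """

    gene: str
    effect: float
    fraction_causal: float = 1.0
    trait: str | None = None

    def __post_init__(self):
        if not 0.0 <= self.fraction_causal <= 1.0:
            raise ConfigError("fraction_causal outside [0, 1]")
        if self.trait is not None and self.trait not in TRAITS:
            raise ConfigError(f"unknown trait {self.trait!r}")


@dataclass
class SimConfig:
    """Study conditions for the synthetic consortium.

    Defaults describe a desk-scale consortium: five ancestry groups with a
    European-dominant cohort mix, 1,000 individuals per cohort, a rare-heavy
    allele-frequency spectrum (half the panel below 1% MAF) and unit-variance
    Gaussian trait noise.
    """

    n_cohorts_per_ancestry: Mapping[str, int] = field(
        default_factory=lambda: {"EUR": 3, "AFR": 1, "SAS": 1, "EAS": 1,
                                 "HISP": 1})
    n_individuals: int = 1000
    n_variants: int = 200
    n_genes: int = 20
    maf_spectrum: tuple[float, float, float] = (0.5, 0.25, 0.25)
    causal_genes: Sequence[CausalGene] = field(default_factory=tuple)
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.01, "sex": 0.15, "bmi": 0.03,
                                 "pc": 0.1})
    n_pcs: int = 2
    # residual sd in trait units; 0.5 keeps the natural fraction of
    # simulated individuals beyond the diabetes cutoffs realistically
    # small while diabetes_fraction plants explicit positives
    noise_sd: float = 0.5
    diabetes_fraction: float = 0.02
    treated_fraction: float = 0.01
    missing_rate: float = 0.0
    inbreeding_f: float = 0.0
    between_cohort_effect_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_individuals < 1 or self.n_variants < 1 or self.n_genes < 1:
            raise ConfigError("all counts must be >= 1")
        if any(n < 1 for n in self.n_cohorts_per_ancestry.values()):
            raise ConfigError("cohort counts must be >= 1")
        if abs(sum(self.maf_spectrum) - 1.0) > 1e-9:
            raise ConfigError("maf_spectrum proportions must sum to 1")
        for frac in (self.diabetes_fraction, self.treated_fraction,
                     self.missing_rate):
            if not 0.0 <= frac <= 1.0:
                raise ConfigError("fractions must lie in [0, 1]")
        if not self.noise_sd > 0:
            raise ConfigError("noise_sd must be > 0")
        self.causal_genes = tuple(self.causal_genes)

    # -- derived, deterministic panel structure --------------------------

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes - 1))
        return [f"GENE{str(i).zfill(width)}" for i in range(self.n_genes)]

    def variant_gene_assignment(self) -> list[str]:
        """Variant i belongs to gene i mod n_genes (fixed panel layout)."""
        genes = self.gene_names()
        return [genes[i % self.n_genes] for i in range(self.n_variants)]

    def variant_panel(self) -> list[VariantKey]:
        """Fixed variant panel shared by every cohort.

        Genes are laid out on chromosomes 1-22 (cycling), 2 Mb apart, with
        member variants 1 kb apart inside the gene, so distance-based
        locus logic has realistic structure to work on.
        """
        genes = self.gene_names()
        gene_chrom = {g: str((i % 22) + 1) for i, g in enumerate(genes)}
        gene_start = {g: 1_000_000 + (i // 22) * 2_000_000
                      for i, g in enumerate(genes)}
        offsets: dict[str, int] = {g: 0 for g in genes}
        panel = []
        for i, g in enumerate(self.variant_gene_assignment()):
            pos = gene_start[g] + offsets[g] * 1000
            offsets[g] += 1
            panel.append(VariantKey(chrom=gene_chrom[g], pos=pos,
                                    effect_allele="A", other_allele="G",
                                    rsid=f"sv{i:06d}"))
        return panel


@dataclass
class CohortData:
    """Simulated genotypes, phenotypes and covariates for one cohort."""

    cohort_id: str
    ancestry: str
    variants: list[VariantKey]
    variant_genes: list[str]
    dosages: np.ndarray              # individuals x variants, NaN = missing
    phenotypes: pd.DataFrame         # columns = TRAITS
    covariates: pd.DataFrame         # age, sex, bmi, pc1..pck
    treatment_flags: np.ndarray      # bool, diagnosed/treated diabetes
    truth: pd.DataFrame              # per-variant planted effects per trait

    def __post_init__(self):
        n, m = self.dosages.shape
        if len(self.phenotypes) != n or len(self.covariates) != n:
            raise ValueError("inconsistent individual dimension")
        if len(self.variants) != m or len(self.variant_genes) != m:
            raise ValueError("inconsistent variant dimension")
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be 0, 1, 2 or missing")


# ---------------------------------------------------------------------------
# seed plumbing: stable, collision-resistant streams
# ---------------------------------------------------------------------------

def _stream(seed: int, *labels: str) -> np.random.Generator:
    """Independent generator derived from (seed, labels) only."""
    keys = [zlib.crc32(lab.encode()) for lab in labels]
    return np.random.default_rng(np.random.SeedSequence(
        entropy=seed, spawn_key=tuple(keys)))


# ---------------------------------------------------------------------------
# allele frequencies
# ---------------------------------------------------------------------------

def _base_mafs(cfg: SimConfig) -> np.ndarray:
    """Panel-wide base MAFs from the configured rare/low/common mixture."""
    rng = _stream(cfg.seed, "panel-maf")
    cls = rng.choice(3, size=cfg.n_variants, p=list(cfg.maf_spectrum))
    maf = np.empty(cfg.n_variants)
    maf[cls == 0] = rng.uniform(0.0005, 0.01, size=(cls == 0).sum())
    maf[cls == 1] = rng.uniform(0.01, 0.05, size=(cls == 1).sum())
    maf[cls == 2] = rng.uniform(0.05, 0.5, size=(cls == 2).sum())
    return maf


def ancestry_mafs(cfg: SimConfig) -> dict[str, np.ndarray]:
    """Per-ancestry allele frequencies, drawn once per ancestry.

    Ancestry spectra are logit-normal perturbations (sd 0.3) of the shared
    base spectrum, so rare variants stay rare but frequencies differ
    between ancestry groups, as on a genotyped fixed array.
    """
    base = _base_mafs(cfg)
    out = {}
    for ancestry in sorted(cfg.n_cohorts_per_ancestry):
        rng = _stream(cfg.seed, "ancestry-maf", ancestry)
        logit = np.log(base / (1 - base)) + rng.normal(0.0, 0.3, size=base.size)
        f = 1.0 / (1.0 + np.exp(-logit))
        out[ancestry] = np.clip(f, 1e-5, 0.5)
    return out


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def _planted_effects(cfg: SimConfig) -> pd.DataFrame:
    """Per-variant planted effect for each trait (trait-units per allele)."""
    genes = cfg.variant_gene_assignment()
    known = set(cfg.gene_names())
    effects = pd.DataFrame(0.0, index=range(cfg.n_variants),
                           columns=list(TRAITS))
    for cg in cfg.causal_genes:
        if cg.gene not in known:
            raise ConfigError(f"causal gene {cg.gene!r} not simulated")
        members = [i for i, g in enumerate(genes) if g == cg.gene]
        rng = _stream(cfg.seed, "causal", cg.gene)
        n_causal = max(1, int(round(cg.fraction_causal * len(members))))
        chosen = rng.choice(members, size=n_causal, replace=False)
        traits = [cg.trait] if cg.trait else list(TRAITS)
        for t in traits:
            effects.loc[chosen, t] += cg.effect
    return effects


def simulate_cohort(cfg: SimConfig, cohort_id: str,
                    ancestry: str | None = None) -> CohortData:
    """Simulate one cohort; reproducible from (cfg.seed, cohort_id).

    Phenotype model per trait: baseline + covariate terms + planted dosage
    effects + Normal(0, noise_sd) noise, then a ``diabetes_fraction`` of
    individuals overwritten with diabetes-range FG/2hGlu/HbA1c values.
    """
    if ancestry is None:
        ancestry = cohort_ancestries(cfg).get(cohort_id)
        if ancestry is None:
            raise ConfigError(f"unknown cohort id {cohort_id!r}")
    if ancestry not in cfg.n_cohorts_per_ancestry:
        raise ConfigError(f"unknown ancestry {ancestry!r}")
    rng = _stream(cfg.seed, "cohort", cohort_id)
    n, m = cfg.n_individuals, cfg.n_variants
    freqs = ancestry_mafs(cfg)[ancestry]

    # genotypes: HWE by default; optional inbreeding F for QC positive cases
    f = cfg.inbreeding_f
    p = freqs[np.newaxis, :]
    if f == 0.0:
        dosages = rng.binomial(2, np.broadcast_to(p, (n, m))).astype(float)
    else:
        p_hom_eff = p * p + f * p * (1 - p)
        p_het = 2 * p * (1 - p) * (1 - f)
        u = rng.random((n, m))
        dosages = np.where(u < p_hom_eff, 2.0,
                           np.where(u < p_hom_eff + p_het, 1.0, 0.0))
    if cfg.missing_rate > 0:
        miss = rng.random((n, m)) < cfg.missing_rate
        dosages[miss] = np.nan

    # covariates
    age = rng.normal(55.0, 8.0, size=n)
    sex = rng.binomial(1, 0.5, size=n).astype(float)
    bmi = rng.normal(27.0, 4.0, size=n)
    pcs = rng.normal(0.0, 1.0, size=(n, cfg.n_pcs))
    cov = {"age": age, "sex": sex, "bmi": bmi}
    for k in range(cfg.n_pcs):
        cov[f"pc{k + 1}"] = pcs[:, k]
    covariates = pd.DataFrame(cov)

    ce = cfg.covariate_effects
    cov_term = (ce.get("age", 0.0) * (age - 55.0)
                + ce.get("sex", 0.0) * sex
                + ce.get("bmi", 0.0) * (bmi - 27.0)
                + ce.get("pc", 0.0) * pcs.sum(axis=1))

    effects = _planted_effects(cfg)
    dose_filled = np.nan_to_num(dosages, nan=0.0)
    phen = {}
    for trait in TRAITS:
        beta = effects[trait].to_numpy()
        if cfg.between_cohort_effect_sd > 0:
            shift = _stream(cfg.seed, "hetero", cohort_id, trait).normal(
                0.0, cfg.between_cohort_effect_sd, size=m)
            beta = beta + np.where(beta != 0.0, shift, 0.0)
        genetic = dose_filled @ beta
        noise = rng.normal(0.0, cfg.noise_sd, size=n)
        phen[trait] = TRAIT_BASELINES[trait] + cov_term + genetic + noise
    phenotypes = pd.DataFrame(phen)

    # diabetes-range plants and treatment flags (exclusion positive cases)
    n_diab = int(round(cfg.diabetes_fraction * n))
    diab_idx = rng.choice(n, size=n_diab, replace=False)
    for trait, (lo, hi) in _DIABETES_RANGES.items():
        phenotypes.loc[diab_idx, trait] = rng.uniform(lo, hi, size=n_diab)
    treatment = np.zeros(n, dtype=bool)
    n_treat = int(round(cfg.treated_fraction * n))
    treatment[rng.choice(n, size=n_treat, replace=False)] = True

    return CohortData(
        cohort_id=cohort_id, ancestry=ancestry,
        variants=cfg.variant_panel(),
        variant_genes=cfg.variant_gene_assignment(),
        dosages=dosages, phenotypes=phenotypes, covariates=covariates,
        treatment_flags=treatment, truth=effects)


def cohort_ancestries(cfg: SimConfig) -> dict[str, str]:
    """Deterministic cohort-id -> ancestry layout, e.g. EUR_1, EUR_2, AFR_1."""
    out = {}
    for ancestry in sorted(cfg.n_cohorts_per_ancestry):
        for i in range(cfg.n_cohorts_per_ancestry[ancestry]):
            out[f"{ancestry}_{i + 1}"] = ancestry
    return out


def simulate_all_cohorts(cfg: SimConfig) -> list[CohortData]:
    return [simulate_cohort(cfg, cid, anc)
            for cid, anc in cohort_ancestries(cfg).items()]


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

DEFAULT_CONSEQUENCE_PROPORTIONS = {
    "ptv": 0.05, "missense": 0.55, "synonymous": 0.28,
    "splice_region": 0.05, "inframe_indel": 0.02, "other": 0.05,
}

_PTV_CYCLE = sorted(PTV_CONSEQUENCES)


def simulate_annotations(
    variants: Sequence[VariantKey],
    genes: Sequence[str],
    seed: int,
    proportions: Mapping[str, float] | None = None,
    damaging_prior: float = 0.5,
    flip_noise: float = 0.1,
    maf_by_ancestry: Mapping[str, np.ndarray] | None = None,
) -> list[AnnotationRecord]:
    """Assign consequence categories and correlated damaging flags.

    The five predictor flags share one latent damaging indicator
    (probability ``damaging_prior`` for missense variants) with independent
    per-predictor flip noise, so predictors agree more often than chance.
    Per-ancestry MAFs are copied from the genotype simulation when given.
    """
    if len(variants) != len(genes):
        raise ValueError("variants and genes must align")
    props = dict(proportions or DEFAULT_CONSEQUENCE_PROPORTIONS)
    cats = sorted(props)
    weights = np.array([props[c] for c in cats], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("consequence proportions must sum to > 0")
    weights = weights / weights.sum()
    rng = _stream(seed, "annotations")
    records = []
    n_ptv_seen = 0
    for i, (key, gene) in enumerate(zip(variants, genes)):
        cat = cats[rng.choice(len(cats), p=weights)]
        if cat == "ptv":
            consequence = _PTV_CYCLE[n_ptv_seen % len(_PTV_CYCLE)]
            n_ptv_seen += 1
        else:
            consequence = cat
        latent = bool(rng.random() < damaging_prior)
        flags = tuple(bool(latent ^ (rng.random() < flip_noise))
                      for _ in range(5))
        mafs = {}
        if maf_by_ancestry is not None:
            for anc, arr in maf_by_ancestry.items():
                f = float(arr[i])
                mafs[anc] = min(f, 1.0 - f)
        records.append(AnnotationRecord(
            key=key, gene=gene, consequence=consequence,
            damaging_flags=flags, maf_by_ancestry=mafs))
    return records


# ---------------------------------------------------------------------------
# gene-set z matrix
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSet:
    """A gene set whose member genes get elevated membership z-scores."""

    set_id: str
    member_genes: tuple[str, ...]
    z_mean: float


def simulate_geneset_matrix(
    genes: Sequence[str],
    n_sets: int,
    planted: Sequence[PlantedSet] = (),
    seed: int = 0,
    n_sister_pairs: int = 0,
    sister_noise_sd: float = 0.1,
) -> GeneSetMatrix:
    """Background z ~ N(0,1); planted member entries ~ N(z_mean, 1).

    ``n_sister_pairs`` appends pairs of near-duplicate columns
    (copy + N(0, sister_noise_sd) noise) to exercise meta-gene-set
    clustering of strongly correlated sets.
    """
    genes = list(genes)
    rng = _stream(seed, "genesets")
    set_ids = [f"SET{i:05d}" for i in range(n_sets)]
    if len(set(ps.set_id for ps in planted)) != len(planted):
        raise ValueError("duplicate planted set IDs")
    z = rng.normal(0.0, 1.0, size=(len(genes), n_sets))
    gene_index = {g: i for i, g in enumerate(genes)}
    for ps in planted:
        if ps.set_id not in set_ids:
            raise ValueError(f"planted set {ps.set_id!r} not among set IDs")
        col = set_ids.index(ps.set_id)
        for g in ps.member_genes:
            if g not in gene_index:
                raise ValueError(f"planted member gene {g!r} not simulated")
            z[gene_index[g], col] = rng.normal(ps.z_mean, 1.0)
    for k in range(n_sister_pairs):
        src = k % n_sets
        sister = z[:, src] + rng.normal(0.0, sister_noise_sd,
                                        size=len(genes))
        z = np.column_stack([z, sister])
        set_ids.append(f"SET{src:05d}_SISTER{k}")
    return GeneSetMatrix(genes=genes, sets=set_ids, z=z)


# ---------------------------------------------------------------------------
# on-disk fixture tree (CLI `simulate`)
# ---------------------------------------------------------------------------

def write_cohort_dir(cohort: CohortData, out_dir) -> None:
    """Write one cohort as dosage + phenotype/covariate TSVs."""
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = [v.label for v in cohort.variants]
    dos = pd.DataFrame(cohort.dosages, columns=labels)
    dos.insert(0, "individual", [f"ind{i:05d}" for i in range(len(dos))])
    dos.to_csv(out / "dosages.tsv", sep="\t", index=False,
               lineterminator="\n", na_rep="NA")
    pheno = pd.concat([cohort.phenotypes, cohort.covariates], axis=1)
    pheno.insert(0, "individual", dos["individual"])
    pheno["treated_diabetes"] = cohort.treatment_flags.astype(int)
    pheno.to_csv(out / "phenotypes.tsv", sep="\t", index=False,
                 lineterminator="\n", na_rep="NA")
    variants = pd.DataFrame({
        "variant": labels,
        "chromosome": [v.chrom for v in cohort.variants],
        "base_pair_location": [v.pos for v in cohort.variants],
        "effect_allele": [v.effect_allele for v in cohort.variants],
        "other_allele": [v.other_allele for v in cohort.variants],
        "gene": cohort.variant_genes,
    })
    variants.to_csv(out / "variants.tsv", sep="\t", index=False,
                    lineterminator="\n")


def write_truth_table(cfg: SimConfig, path) -> None:
    effects = _planted_effects(cfg)
    effects.insert(0, "variant", [v.label for v in cfg.variant_panel()])
    effects.insert(1, "gene", cfg.variant_gene_assignment())
    effects.to_csv(path, sep="\t", index=False, lineterminator="\n")
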