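"""Readers and writers for every on-disk artifact of the pipeline.

All files are plain tab-separated text with a header row, chosen to be
diff-able and streamable.  Positions are 1-based and genome-build agnostic.
Writers are deterministic: the same records always produce byte-identical
output (fixed column order, fixed float rendering, ``\\n`` line endings).

The summary-statistics schema (``variant, chromosome, base_pair_location,
effect_allele, other_allele, effect_allele_frequency, beta, standard_error,
p_value, n``) is a declared dialect modelled on public GWAS-catalog exome
deposits; the exact column layout of those deposits is not standardized, so
this module's schema is the package's canonical on-disk form.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

ALLOWED_CHROMS = frozenset([str(i) for i in range(1, 23)] + ["X"])

#: protein-truncating consequence categories
PTV_CONSEQUENCES = frozenset(
    ["stop_gained", "stop_lost", "frameshift", "splice_donor",
     "splice_acceptor", "initiator_codon"]
)
#: full coding list used for the single-variant significance call
CODING_CONSEQUENCES = PTV_CONSEQUENCES | frozenset(
    ["missense", "inframe_indel", "splice_region"]
)
CONSEQUENCES = CODING_CONSEQUENCES | frozenset(["synonymous", "other"])

#: predictor order for the five damaging flags
DAMAGING_PREDICTORS = ("sift", "polyphen_hdiv", "polyphen_hvar", "lrt",
                       "mutation_taster")

SUMSTATS_COLUMNS = ("variant", "chromosome", "base_pair_location",
                    "effect_allele", "other_allele",
                    "effect_allele_frequency", "beta", "standard_error",
                    "p_value", "n")


class SchemaError(ValueError):
    """A file is missing a required column or has a malformed layout."""


class RecordError(ValueError):
    """A data row violates a field invariant; carries the 1-based line."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VariantKey:
    """Identity of a genotyped variant: chromosome, position and alleles."""

    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    rsid: str | None = field(default=None, compare=False)

    def __post_init__(self):
        if self.chrom not in ALLOWED_CHROMS:
            raise ValueError(f"chromosome {self.chrom!r} not in 1-22, X")
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele must differ")

    @property
    def label(self) -> str:
        """rsid if present, else the stable 'chrom:pos:other:effect' key."""
        if self.rsid:
            return self.rsid
        return f"{self.chrom}:{self.pos}:{self.other_allele}:{self.effect_allele}"

    def sort_key(self) -> tuple:
        chrom_rank = 23 if self.chrom == "X" else int(self.chrom)
        return (chrom_rank, self.pos, self.other_allele, self.effect_allele)


@dataclass(frozen=True)
class SumstatsRecord:
    """One row of single-variant association summary statistics."""

    key: VariantKey
    eaf: float
    beta: float
    se: float
    p: float
    n: int

    def __post_init__(self):
        if not 0.0 <= self.eaf <= 1.0:
            raise ValueError(f"eaf {self.eaf} outside [0, 1]")
        if not self.se > 0:
            raise ValueError(f"standard error must be > 0, got {self.se}")
        if not 0.0 < self.p <= 1.0:
            raise ValueError(f"p-value {self.p} outside (0, 1]")
        if self.n < 1:
            raise ValueError(f"sample count must be >= 1, got {self.n}")


@dataclass(frozen=True)
class AnnotationRecord:
    """Functional annotation of one variant in one gene.

    ``damaging_flags`` are ordered (SIFT, PolyPhen-HumDiv, PolyPhen-HumVar,
    LRT, MutationTaster).  ``maf_by_ancestry`` maps ancestry labels to
    minor-allele frequencies; unknown labels are kept verbatim.
    """

    key: VariantKey
    gene: str
    consequence: str
    damaging_flags: tuple[bool, bool, bool, bool, bool]
    maf_by_ancestry: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if len(self.damaging_flags) != 5:
            raise ValueError("exactly 5 damaging flags required")
        for anc, maf in self.maf_by_ancestry.items():
            if not 0.0 <= maf <= 0.5:
                raise ValueError(f"MAF {maf} for {anc} outside [0, 0.5]")
        object.__setattr__(self, "maf_by_ancestry",
                           dict(self.maf_by_ancestry))
        object.__setattr__(self, "damaging_flags",
                           tuple(bool(f) for f in self.damaging_flags))

    def __hash__(self):
        return hash((self.key, self.gene, self.consequence,
                     self.damaging_flags,
                     tuple(sorted(self.maf_by_ancestry.items()))))

    def __eq__(self, other):
        if not isinstance(other, AnnotationRecord):
            return NotImplemented
        return (self.key == other.key and self.gene == other.gene
                and self.consequence == other.consequence
                and self.damaging_flags == other.damaging_flags
                and dict(self.maf_by_ancestry) == dict(other.maf_by_ancestry))


@dataclass(frozen=True)
class KnownLocus:
    """A previously reported trait-associated position."""

    trait: str
    chrom: str
    pos: int
    source_label: str = ""

    def __post_init__(self):
        if self.chrom not in ALLOWED_CHROMS:
            raise ValueError(f"chromosome {self.chrom!r} not in 1-22, X")
        if self.pos < 1:
            raise ValueError("position must be >= 1")


@dataclass
class GeneSetMatrix:
    """Gene-set membership z-scores: genes x sets.

    Each entry is a z-score for the probability that the gene belongs to
    the (co-expression reconstituted) gene set.
    """

    genes: list[str]
    sets: list[str]
    z: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if len(self.genes) != len(set(self.genes)):
            raise ValueError("duplicate gene symbols")
        if len(self.sets) != len(set(self.sets)):
            raise ValueError("duplicate set IDs")
        if self.z.shape != (len(self.genes), len(self.sets)):
            raise ValueError(
                f"z shape {self.z.shape} does not match "
                f"({len(self.genes)}, {len(self.sets)})")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("non-finite entries in z matrix")

    @property
    def gene_index(self) -> dict[str, int]:
        return {g: i for i, g in enumerate(self.genes)}

    def __eq__(self, other):
        if not isinstance(other, GeneSetMatrix):
            return NotImplemented
        return (self.genes == other.genes and self.sets == other.sets
                and np.array_equal(self.z, other.z))


# ---------------------------------------------------------------------------
# float rendering (shared by all writers for determinism)
# ---------------------------------------------------------------------------

def _fmt6(x: float) -> str:
    """Render with 6 significant digits (p, beta columns)."""
    return format(float(x), ".6g")


def _fmt_full(x: float) -> str:
    """Shortest round-tripping decimal representation."""
    return repr(float(x))


def _parse_variant_fields(chrom: str, pos_s: str, ea: str, oa: str,
                          rsid: str, line: int) -> VariantKey:
    try:
        pos = int(pos_s)
    except ValueError:
        raise RecordError(f"non-integer position {pos_s!r}", line) from None
    try:
        return VariantKey(chrom=chrom, pos=pos, effect_allele=ea,
                          other_allele=oa, rsid=rsid or None)
    except ValueError as exc:
        raise RecordError(str(exc), line) from None


def _float_field(value: str, name: str, line: int) -> float:
    try:
        return float(value)
    except ValueError:
        raise RecordError(f"non-numeric {name} {value!r}", line) from None


# ---------------------------------------------------------------------------
# summary statistics
# ---------------------------------------------------------------------------

def read_sumstats(path: str | Path) -> list[SumstatsRecord]:
    """Read a summary-statistics TSV, preserving row order.

    Raises :class:`SchemaError` when a required column is absent and
    :class:`RecordError` (with the 1-based line number) when a row cannot
    be parsed or violates a field invariant.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, header expected") from None
        missing = [c for c in SUMSTATS_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
        idx = {c: header.index(c) for c in SUMSTATS_COLUMNS}
        records: list[SumstatsRecord] = []
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            get = lambda col: row[idx[col]]
            key = _parse_variant_fields(
                get("chromosome"), get("base_pair_location"),
                get("effect_allele"), get("other_allele"),
                get("variant"), line_no)
            p = _float_field(get("p_value"), "p_value", line_no)
            try:
                rec = SumstatsRecord(
                    key=key,
                    eaf=_float_field(get("effect_allele_frequency"),
                                     "effect_allele_frequency", line_no),
                    beta=_float_field(get("beta"), "beta", line_no),
                    se=_float_field(get("standard_error"), "standard_error",
                                    line_no),
                    p=p,
                    n=int(_float_field(get("n"), "n", line_no)),
                )
            except ValueError as exc:
                raise RecordError(str(exc), line_no) from None
            records.append(rec)
    return records


def write_sumstats(records: Iterable[SumstatsRecord],
                   path: str | Path) -> None:
    """Write summary statistics; byte-stable for identical input."""
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write("\t".join(SUMSTATS_COLUMNS) + "\n")
        for rec in records:
            k = rec.key
            fh.write("\t".join([
                k.label, k.chrom, str(k.pos), k.effect_allele,
                k.other_allele, _fmt_full(rec.eaf), _fmt6(rec.beta),
                _fmt_full(rec.se), _fmt6(rec.p), str(rec.n),
            ]) + "\n")


# ---------------------------------------------------------------------------
# annotation table
# ---------------------------------------------------------------------------

ANNOTATION_FIXED_COLUMNS = ("variant", "chromosome", "base_pair_location",
                            "effect_allele", "other_allele", "gene",
                            "consequence") + DAMAGING_PREDICTORS

def _parse_flag(value: str, line: int) -> bool:
    v = value.strip().lower()
    if v == "d" or v == "1" or v == "true" or v == "yes":
        return True
    if v in ("t", "0", "false", "no", ".", "", "na", "b", "n", "u"):
        # T = tolerated (SIFT convention); B/N = benign/neutral
        return False
    raise RecordError(f"unrecognized damaging flag {value!r}", line)


def read_annotation_table(path: str | Path) -> list[AnnotationRecord]:
    """Read a variant annotation TSV.

    Consequence strings outside the known vocabulary map to ``"other"``.
    Any column named ``maf_<LABEL>`` is taken as a per-ancestry minor-allele
    frequency; labels are kept verbatim.  Duplicate (variant, gene) rows are
    an error, but a variant may map to several genes via distinct rows.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, header expected") from None
        missing = [c for c in ANNOTATION_FIXED_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
        idx = {c: header.index(c) for c in ANNOTATION_FIXED_COLUMNS}
        maf_cols = [(c[len("maf_"):], header.index(c)) for c in header
                    if c.startswith("maf_")]
        records: list[AnnotationRecord] = []
        seen: set[tuple[VariantKey, str]] = set()
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            get = lambda col: row[idx[col]]
            key = _parse_variant_fields(
                get("chromosome"), get("base_pair_location"),
                get("effect_allele"), get("other_allele"),
                get("variant"), line_no)
            gene = get("gene")
            if (key, gene) in seen:
                raise RecordError(
                    f"duplicate annotation row for {key.label} / {gene}",
                    line_no)
            seen.add((key, gene))
            consequence = get("consequence")
            if consequence not in CONSEQUENCES:
                consequence = "other"
            flags = tuple(_parse_flag(row[idx[c]], line_no)
                          for c in DAMAGING_PREDICTORS)
            mafs = {}
            for label, col in maf_cols:
                raw = row[col].strip()
                if raw in ("", "NA", "."):
                    continue
                mafs[label] = _float_field(raw, f"maf_{label}", line_no)
            try:
                records.append(AnnotationRecord(
                    key=key, gene=gene, consequence=consequence,
                    damaging_flags=flags, maf_by_ancestry=mafs))
            except ValueError as exc:
                raise RecordError(str(exc), line_no) from None
    return records


def write_annotation_table(records: Sequence[AnnotationRecord],
                           path: str | Path) -> None:
    path = Path(path)
    ancestries = sorted({a for r in records for a in r.maf_by_ancestry})
    header = list(ANNOTATION_FIXED_COLUMNS) + [f"maf_{a}" for a in ancestries]
    with path.open("w", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for rec in records:
            k = rec.key
            row = [k.label, k.chrom, str(k.pos), k.effect_allele,
                   k.other_allele, rec.gene, rec.consequence]
            row += ["D" if f else "T" for f in rec.damaging_flags]
            for a in ancestries:
                maf = rec.maf_by_ancestry.get(a)
                row.append("NA" if maf is None else _fmt_full(maf))
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# gene-set z-matrix
# ---------------------------------------------------------------------------

def read_geneset_matrix(path: str | Path) -> GeneSetMatrix:
    """Read a genes-by-sets z-score TSV (header row of set IDs)."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, header expected") from None
        if not header or header[0] != "gene":
            raise SchemaError(f"{path}: first column must be 'gene'")
        sets = header[1:]
        genes: list[str] = []
        rows: list[list[float]] = []
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            genes.append(row[0])
            try:
                rows.append([float(v) for v in row[1:]])
            except ValueError:
                raise RecordError("non-numeric z entry", line_no) from None
    z = np.array(rows, dtype=float) if rows else np.empty((0, len(sets)))
    return GeneSetMatrix(genes=genes, sets=sets, z=z)


def write_geneset_matrix(gsm: GeneSetMatrix, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write("\t".join(["gene"] + list(gsm.sets)) + "\n")
        for i, gene in enumerate(gsm.genes):
            fh.write("\t".join([gene] + [_fmt_full(v) for v in gsm.z[i]])
                     + "\n")


# ---------------------------------------------------------------------------
# known-locus list
# ---------------------------------------------------------------------------

KNOWN_LOCUS_COLUMNS = ("trait", "chrom", "pos", "source_label")


def read_known_loci(path: str | Path) -> list[KnownLocus]:
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path}: empty file, header expected") from None
        missing = [c for c in KNOWN_LOCUS_COLUMNS if c not in header]
        if missing:
            raise SchemaError(f"{path}: missing column(s) {missing}")
        idx = {c: header.index(c) for c in KNOWN_LOCUS_COLUMNS}
        loci = []
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            try:
                loci.append(KnownLocus(
                    trait=row[idx["trait"]], chrom=row[idx["chrom"]],
                    pos=int(row[idx["pos"]]),
                    source_label=row[idx["source_label"]]))
            except ValueError as exc:
                raise RecordError(str(exc), line_no) from None
    return loci


def write_known_loci(loci: Sequence[KnownLocus], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write("\t".join(KNOWN_LOCUS_COLUMNS) + "\n")
        for loc in loci:
            fh.write("\t".join([loc.trait, loc.chrom, str(loc.pos),
                                loc.source_label]) + "\n")


# ---------------------------------------------------------------------------
# score sets and per-gene covariance (cohort-stage artifacts)
# ---------------------------------------------------------------------------

SCORE_COLUMNS = ("variant", "chromosome", "base_pair_location",
                 "effect_allele", "other_allele", "U", "V", "n", "eaf",
                 "call_rate", "hwe_p", "monomorphic")


def write_score_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a per-variant score table (columns: SCORE_COLUMNS)."""
    out = df.loc[:, list(SCORE_COLUMNS)].copy()
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_score_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t",
                     dtype={"chromosome": str, "variant": str})
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def write_gene_covariance_table(records: Mapping[str, "object"],
                                path: str | Path) -> None:
    """Write per-gene score covariances in long form.

    ``records`` maps gene symbol to an object with ``variants`` (list of
    VariantKey) and ``cov`` (square matrix).
    """
    path = Path(path)
    with path.open("w", newline="\n") as fh:
        fh.write("gene\tvariant_i\tvariant_j\tcov\n")
        for gene in sorted(records):
            gc = records[gene]
            labels = [v.label for v in gc.variants]
            cov = np.asarray(gc.cov)
            for i in range(len(labels)):
                for j in range(i, len(labels)):
                    fh.write(f"{gene}\t{labels[i]}\t{labels[j]}\t"
                             f"{_fmt_full(cov[i, j])}\n")


def read_gene_covariance_table(path: str | Path,
                               variant_lookup: Mapping[str, VariantKey],
                               ) -> dict[str, "object"]:
    """Rebuild per-gene covariance objects from the long-form TSV.

    ``variant_lookup`` maps variant labels (as used by the score table)
    back to full variant identities.  Returns gene -> object with
    ``gene``, ``variants`` and ``cov`` attributes (late import avoids a
    module cycle with the cohort engine).
    """
    from .cohort_engine import GeneCovariance

    path = Path(path)
    entries: dict[str, dict[tuple[str, str], float]] = {}
    order: dict[str, list[str]] = {}
    with path.open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header != ["gene", "variant_i", "variant_j", "cov"]:
            raise SchemaError(f"{path}: unexpected gene-covariance header")
        for line_no, row in enumerate(reader, start=2):
            if not row:
                continue
            gene, vi, vj, val = row
            entries.setdefault(gene, {})[(vi, vj)] = _float_field(
                val, "cov", line_no)
            lst = order.setdefault(gene, [])
            for lab in (vi, vj):
                if lab not in lst:
                    lst.append(lab)
    out = {}
    for gene, labels in order.items():
        k = len(labels)
        pos = {lab: i for i, lab in enumerate(labels)}
        cov = np.zeros((k, k))
        for (vi, vj), val in entries[gene].items():
            i, j = pos[vi], pos[vj]
            cov[i, j] = cov[j, i] = val
        try:
            variants = [variant_lookup[lab] for lab in labels]
        except KeyError as exc:
            raise SchemaError(
                f"{path}: unknown variant label {exc.args[0]!r}") from None
        out[gene] = GeneCovariance(gene=gene, variants=variants, cov=cov)
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def read_config(path: str | Path) -> dict:
    """Load a YAML run configuration into a plain dict."""
    with Path(path).open() as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        cfg = {}
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: top level must be a mapping")
    return cfg


def write_config(cfg: Mapping, path: str | Path) -> None:
    with Path(path).open("w", newline="\n") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
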