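"""Shared containers, coordinate conventions and file I/O.

Internal coordinates are 0-based half-open throughout the package; VCF and
GFF3 (1-based inclusive) are converted at the boundary, BED is written
natively.  Genotypes are reduced to unphased alt-allele dosage in
{0, 1, 2, MISSING}; phase is never used downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing diploid genotype call.
MISSING: int = -1

_NUCLEOTIDES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# coordinate conventions
# ---------------------------------------------------------------------------

def to_zero_based(start1: int, end1: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    return start1 - 1, end1


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    return start0 + 1, end0


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(
                f"empty/inverted interval {self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos0: int) -> bool:
        return self.start <= pos0 < self.end


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Diploid alt-allele dosages at ordered biallelic SNPs.

    ``dosage`` has shape (n_samples, n_variants) with values in
    {0, 1, 2, MISSING}.  ``pos`` is 1-based and strictly increasing within a
    chromosome.
    """

    sample_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        if self.dosage.shape != (len(self.sample_ids), self.pos.size):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {self.pos.size} variants"
            )
        for c in pd.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if p.size > 1 and not np.all(np.diff(p) > 0):
                bad = int(p[np.argmin(np.diff(p))] if p.size else 0)
                raise ValueError(
                    f"positions not strictly increasing on {c} near {bad}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return int(self.pos.size)

    def sample_indices(self, sample_ids: list[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return np.asarray([lookup[s] for s in sample_ids], dtype=np.intp)

    def variant_mask(self, interval: GenomicInterval) -> np.ndarray:
        """Boolean mask of variants falling inside a 0-based interval."""
        pos0 = self.pos - 1
        return (
            (self.chrom == interval.chrom)
            & (pos0 >= interval.start)
            & (pos0 < interval.end)
        )

    def take_variants(self, mask_or_idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            chrom=self.chrom[mask_or_idx],
            pos=self.pos[mask_or_idx],
            ref=self.ref[mask_or_idx],
            alt=self.alt[mask_or_idx],
            dosage=self.dosage[:, mask_or_idx],
        )

    def chromosomes(self) -> list[str]:
        return list(pd.unique(self.chrom))


def allele_counts(dosage: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-variant (alt allele count, called allele count) for a dosage block.

    ``dosage`` is (samples, variants); MISSING cells are excluded.
    """
    called = dosage != MISSING
    alt = np.where(called, dosage, 0).sum(axis=0).astype(np.int64)
    n = 2 * called.sum(axis=0).astype(np.int64)
    return alt, n


# ---------------------------------------------------------------------------
# population map & role binding
# ---------------------------------------------------------------------------

@dataclass
class PopulationMap:
    """sample_id -> population label assignments."""

    assignments: dict[str, str]

    def samples(self, population: str) -> list[str]:
        return [s for s, p in self.assignments.items() if p == population]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.assignments.values():
            seen.setdefault(p, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.assignments)


def bind_roles(
    popmap: PopulationMap,
    matrix: GenotypeMatrix,
    roles: dict[str, str | list[str]],
) -> dict[str, list[str]]:
    """Resolve analysis roles (P1/P2/P3/outgroup, ...) to sample lists.

    Each role may name a population label or give an explicit sample list.
    Every role must resolve to >=1 sample present in the matrix, and roles
    must be disjoint.
    """
    present = set(matrix.sample_ids)
    bound: dict[str, list[str]] = {}
    for role, spec in roles.items():
        if isinstance(spec, str):
            samples = popmap.samples(spec)
        else:
            samples = list(spec)
        samples = [s for s in samples if s in present]
        if not samples:
            raise ValueError(f"role {role!r} binds no samples present in the matrix")
        bound[role] = samples
    seen: dict[str, str] = {}
    for role, samples in bound.items():
        for s in samples:
            if s in seen:
                raise ValueError(
                    f"sample {s!r} bound to both {seen[s]!r} and {role!r}"
                )
            seen[s] = role
    return bound


# ---------------------------------------------------------------------------
# annotations and similarity hits
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneAnnotation:
    """A gene model; start/end are 1-based inclusive."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")

    def interval(self) -> GenomicInterval:
        s, e = to_zero_based(self.start, self.end)
        return GenomicInterval(self.chrom, s, e)


@dataclass(frozen=True)
class SimilarityHit:
    """One row of a 12-column tabular protein-similarity search."""

    query_id: str
    subject_id: str
    percent_identity: float
    evalue: float
    bitscore: float


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_vcf(path, keep_biallelic_snps_only: bool = True) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix of alt-allele dosages.

    With ``keep_biallelic_snps_only`` (the default), multiallelic records,
    indels and symbolic alleles are dropped.  ``./.`` becomes MISSING; phased
    and unphased genotypes are treated identically.
    """
    import cyvcf2

    vcf = cyvcf2.VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF has no samples")

    chroms: list[str] = []
    pos: list[int] = []
    ref: list[str] = []
    alt: list[str] = []
    rows: list[np.ndarray] = []
    last: dict[str, int] = {}
    for v in vcf:
        if keep_biallelic_snps_only:
            if len(v.ALT) != 1:
                continue
            r, a = v.REF, v.ALT[0]
            if len(r) != 1 or len(a) != 1:
                continue
            if r not in _NUCLEOTIDES or a not in _NUCLEOTIDES:
                continue
        else:
            if not v.ALT:
                continue
            r, a = v.REF, v.ALT[0]
        if v.CHROM in last and v.POS <= last[v.CHROM]:
            raise ValueError(
                f"{path}: unsorted VCF, {v.CHROM}:{v.POS} after {last[v.CHROM]}"
            )
        last[v.CHROM] = v.POS
        gt = v.gt_types.astype(np.int8)  # 0/1/2 = dosage, 3 = unknown
        gt[gt == 3] = MISSING
        chroms.append(v.CHROM)
        pos.append(v.POS)
        ref.append(r)
        alt.append(a)
        rows.append(gt)
    vcf.close()

    dosage = (
        np.stack(rows, axis=1)
        if rows
        else np.zeros((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(
        sample_ids=samples,
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        dosage=dosage,
    )


def read_indel_sites(path) -> pd.DataFrame:
    """Positions of biallelic indel records (for density tracks only)."""
    import cyvcf2

    vcf = cyvcf2.VCF(str(path))
    rec = []
    for v in vcf:
        if len(v.ALT) != 1:
            continue
        r, a = v.REF, v.ALT[0]
        if a.startswith("<"):
            continue
        if len(r) != len(a) or len(r) > 1:
            rec.append((v.CHROM, v.POS))
    vcf.close()
    return pd.DataFrame(rec, columns=["chrom", "pos"])


def read_population_map(path) -> PopulationMap:
    """Two-column tab-separated (sample, population) file."""
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(f"{path}:{lineno}: malformed population-map line")
            sample, pop = parts
            if sample in assignments:
                raise ValueError(f"{path}:{lineno}: duplicate sample {sample!r}")
            assignments[sample] = pop
    if not assignments:
        raise ValueError(f"{path}: empty population map")
    return PopulationMap(assignments)


def read_gff_genes(path) -> list[GeneAnnotation]:
    """Gene features from a GFF3 file, sorted by (chrom, start).

    Only feature type ``gene`` is retained; gene_id comes from the ID
    attribute.  Records without an ID are skipped with a warning.
    """
    genes: list[GeneAnnotation] = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                continue
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = parts[:9]
            if ftype != "gene":
                continue
            gene_id = None
            for kv in attrs.split(";"):
                kv = kv.strip()
                if kv.startswith("ID="):
                    gene_id = kv[3:]
                    break
            if not gene_id:
                skipped += 1
                continue
            genes.append(
                GeneAnnotation(gene_id, chrom, int(start), int(end), strand or ".")
            )
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} gene record(s) without ID")
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def read_similarity_table(path) -> list[SimilarityHit]:
    """Parse 12-column tabular similarity hits (outfmt-6 semantics)."""
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ValueError(
                    f"{path}:{lineno}: expected 12 columns, got {len(parts)}"
                )
            hits.append(
                SimilarityHit(
                    query_id=parts[0],
                    subject_id=parts[1],
                    percent_identity=float(parts[2]),
                    evalue=float(parts[10]),
                    bitscore=float(parts[11]),
                )
            )
    return hits


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_bed(intervals, path, names=None, scores=None) -> None:
    """Write 0-based half-open intervals as BED3 (+ optional name/score)."""
    rows = []
    for i, iv in enumerate(intervals):
        row = [iv.chrom, iv.start, iv.end]
        if names is not None:
            row.append(names[i])
            if scores is not None:
                row.append(scores[i])
        rows.append(row)
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(path, "w") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
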