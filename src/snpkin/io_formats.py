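"""Genotype, metadata and matrix I/O.

Genotypes are held as an n-individuals x m-loci matrix of ALT-allele
dosages (0, 1, 2) with ``MISSING`` (-1) for uncalled cells.  The ALT
allele is the single frequency reference for every downstream formula:
``p`` always denotes the ALT frequency and MAF = min(p, 1 - p).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel dosage for a missing (or half-called) genotype.
MISSING: int = -1


@dataclass(frozen=True)
class Locus:
    """A biallelic SNP locus.

    Parameters
    ----------
    id : str
        Unique locus identifier.
    chrom : str
        Chromosome / contig name.
    pos : int
        1-based position, as in VCF.
    ref_allele, alt_allele : str
        Single-nucleotide REF and ALT alleles; must differ.
    qual : float or None
        VCF QUAL value; ``None`` when absent (".").
    """

    id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    qual: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"locus {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"locus {self.id}: REF equals ALT ({self.ref_allele})")
        if self.qual is not None and self.qual < 0:
            raise ValueError(f"locus {self.id}: negative QUAL {self.qual}")


@dataclass(frozen=True)
class SampleMeta:
    """Per-individual metadata: population label and river-km position."""

    sample_id: str
    population: str
    river_km: float

    def __post_init__(self) -> None:
        if not self.population:
            raise ValueError(f"sample {self.sample_id}: empty population label")
        if self.river_km < 0:
            raise ValueError(f"sample {self.sample_id}: negative river_km")


@dataclass
class GenotypeMatrix:
    """n x m matrix of ALT-allele dosage codes with missingness.

    Attributes
    ----------
    samples : list of str
        Ordered, unique sample ids (rows).
    loci : list of Locus
        Ordered loci with unique ids (columns).
    calls : ndarray of int8, shape (n, m)
        Entries in {0, 1, 2, MISSING}.
    """

    samples: list[str]
    loci: list[Locus]
    calls: np.ndarray
    skipped_records: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n, m = len(self.samples), len(self.loci)
        if n < 1:
            raise ValueError("GenotypeMatrix needs at least one sample")
        if self.calls.shape != (n, m):
            raise ValueError(
                f"calls shape {self.calls.shape} != (n_samples, n_loci) = ({n}, {m})"
            )
        if len(set(self.samples)) != n:
            raise ValueError("duplicate sample ids")
        ids = [loc.id for loc in self.loci]
        if len(set(ids)) != m:
            raise ValueError("duplicate locus ids")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid dosage codes at {int(bad.sum())} cells")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def subset_loci(self, keep: np.ndarray) -> "GenotypeMatrix":
        """New matrix restricted to loci where ``keep`` (bool or index) holds."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        loci = [self.loci[int(k)] for k in keep]
        return GenotypeMatrix(list(self.samples), loci, self.calls[:, keep])


def read_vcf(path: str | Path, keep_monomorphic: bool = True) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF v4.x file.

    Multi-allelic records are skipped (count logged and kept on the
    returned matrix).  Unphased and phased GT are both accepted; ``./.``
    and half-calls such as ``./1`` decode to ``MISSING`` because a
    dosage is undefined for them.

    Parameters
    ----------
    path : path
        VCF file (plain or bgzipped).
    keep_monomorphic : bool
        If False, drop records whose ALT is missing.
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"{path}: VCF contains zero samples")

    loci: list[Locus] = []
    columns: list[np.ndarray] = []
    skipped = 0
    seen_ids: set[str] = set()
    for rec in vcf:
        alts = rec.ALT
        if len(alts) != 1 or len(rec.REF) != 1 or len(alts[0]) != 1:
            skipped += 1
            continue
        if not keep_monomorphic and alts[0] == ".":
            skipped += 1
            continue
        rid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        if rid in seen_ids:
            rid = f"{rid}#{len(loci)}"
        seen_ids.add(rid)
        qual = None if rec.QUAL is None else float(rec.QUAL)
        loci.append(Locus(rid, rec.CHROM, rec.POS, rec.REF, alts[0], qual))
        col = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            a, b = gt[0], gt[1]
            col[i] = MISSING if (a < 0 or b < 0) else a + b
        columns.append(col)
    vcf.close()
    if skipped:
        logger.info("read_vcf: skipped %d non-biallelic-SNP records", skipped)
    calls = (
        np.column_stack(columns)
        if columns
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples, loci, calls, skipped_records=skipped)


def write_vcf(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal VCF v4.2 with GT-only genotypes (fixture writer)."""
    path = Path(path)
    code_to_gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = sorted({loc.chrom for loc in gm.loci})
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.samples)
            + "\n"
        )
        for j, loc in enumerate(gm.loci):
            qual = "." if loc.qual is None else f"{loc.qual:g}"
            gts = "\t".join(code_to_gt[int(x)] for x in gm.calls[:, j])
            fh.write(
                f"{loc.chrom}\t{loc.pos}\t{loc.id}\t{loc.ref_allele}\t"
                f"{loc.alt_allele}\t{qual}\t.\t.\tGT\t{gts}\n"
            )


def read_sample_table(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata from a CSV/TSV with header sample_id,population,river_km."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str, "population": str})
    required = ("sample_id", "population", "river_km")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id '{dup}'")
    return [
        SampleMeta(row.sample_id, row.population, float(row.river_km))
        for row in df.itertuples(index=False)
    ]


def write_sample_table(meta: Sequence[SampleMeta], path: str | Path) -> None:
    """Write sample metadata as TSV (columns sample_id, population, river_km)."""
    pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in meta],
            "population": [m.population for m in meta],
            "river_km": [m.river_km for m in meta],
        }
    ).to_csv(path, sep="\t", index=False)


def write_square_matrix(
    matrix: np.ndarray, ids: Sequence[str], path: str | Path
) -> None:
    """Write a symmetric square matrix as TSV with id header row and column.

    The matrix must be symmetric within 1e-10; round-tripping through
    :func:`read_square_matrix` reproduces values to 1e-12.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError(f"matrix must be square, got shape {matrix.shape}")
    if len(ids) != matrix.shape[0]:
        raise ValueError(
            f"got {len(ids)} ids for a {matrix.shape[0]}x{matrix.shape[0]} matrix"
        )
    if not np.allclose(matrix, matrix.T, atol=1e-10, rtol=0):
        raise ValueError("matrix is not symmetric within 1e-10")
    df = pd.DataFrame(matrix, index=list(ids), columns=list(ids))
    df.to_csv(path, sep="\t", float_format="%.17g", index_label="id")


def read_square_matrix(path: str | Path) -> tuple[np.ndarray, list[str]]:
    """Read a matrix written by :func:`write_square_matrix`."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_pair_table(pairs: pd.DataFrame, path: str | Path) -> None:
    """Write a pair table (one row per unordered pair) as TSV."""
    pairs.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_pair_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"id1": str, "id2": str})
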