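"""Locus filtering: QUAL, MAF, exact Hardy-Weinberg test, missingness.

The four criteria with their defaults (QUAL >= 30, MAF >= 5%, HWE exact
p >= 0.01, at most 4 individuals missing per locus) reproduce the
filtering used for the 43-fish SLAF-seq SNP panel this package models.
All criteria are evaluated on the original matrix in one pass;
frequencies are not recomputed after removals, so filtering is
idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix

CRITERIA_ORDER = ("qual", "maf", "hwe", "missing")


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds for the four locus filters.

    ``max_missing`` is an absolute count of individuals with a missing
    genotype at the locus; pass ``max_missing_frac`` instead to express
    it as a fraction of the sample.
    """

    min_qual: float = 30.0
    min_maf: float = 0.05
    min_hwe_p: float = 0.01
    max_missing: int = 4

    def __post_init__(self) -> None:
        if not 0 <= self.min_maf <= 0.5:
            raise ValueError("min_maf must be in [0, 0.5]")
        if not 0 <= self.min_hwe_p <= 1:
            raise ValueError("min_hwe_p must be in [0, 1]")
        if self.max_missing < 0:
            raise ValueError("max_missing must be >= 0")

    @classmethod
    def with_missing_fraction(cls, frac: float, n_samples: int, **kw) -> "FilterCriteria":
        return cls(max_missing=int(np.floor(frac * n_samples)), **kw)


@dataclass
class FilterReport:
    """Per-locus pass/fail flags and the first criterion that failed."""

    table: pd.DataFrame  # columns: locus_id, passed, failed_criterion
    totals: dict[str, int] = field(default_factory=dict)

    @property
    def n_pass(self) -> int:
        return int(self.table["passed"].sum())

    @property
    def n_fail(self) -> int:
        return int((~self.table["passed"]).sum())


def allele_frequency(calls: np.ndarray) -> tuple[float, int]:
    """ALT allele frequency and number of called individuals at one locus.

    Returns ``(p_alt, n_called)`` where p_alt = (sum of dosages) /
    (2 * n_called) over non-missing calls only.
    """
    calls = np.asarray(calls)
    called = calls != MISSING
    n_called = int(called.sum())
    if n_called == 0:
        raise ValueError("all genotypes missing at locus")
    p = float(calls[called].sum()) / (2 * n_called)
    return p, n_called


def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value for one biallelic locus.

    Conditions on the observed allele counts and sums the probabilities
    of every heterozygote count no more probable than the observed one
    (the standard exact test for small samples; no mid-p correction).
    Probabilities are built by the ratio recurrence from the observed
    heterozygote count, then normalized.
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0:
            raise ValueError("negative genotype count")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("need at least one genotype")
    # orient so 'a' is the rarer allele
    n_a = 2 * n_aa + n_Aa
    n_A = 2 * n_AA + n_Aa
    rare = min(n_a, n_A)
    if rare == 0:
        return 1.0  # monomorphic: single possible configuration

    # heterozygote counts share the parity of the rare-allele count
    het_counts = np.arange(rare % 2, rare + 1, 2)
    probs = np.empty(het_counts.size, dtype=float)
    obs_idx = int(np.searchsorted(het_counts, n_Aa))
    probs[obs_idx] = 1.0
    # P(h+2)/P(h) = h_hom_rare * h_hom_common * 4 / ((h+2)(h+1)),
    # where hom counts refer to configuration with h hets.
    for k in range(obs_idx, het_counts.size - 1):
        h = int(het_counts[k])
        hom_r = (rare - h) // 2
        hom_c = (2 * n - rare - h) // 2
        probs[k + 1] = probs[k] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
    for k in range(obs_idx, 0, -1):
        h = int(het_counts[k])
        hom_r = (rare - h) // 2
        hom_c = (2 * n - rare - h) // 2
        probs[k - 1] = probs[k] * h * (h - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
    probs /= probs.sum()
    p_obs = probs[obs_idx]
    p = float(probs[probs <= p_obs * (1.0 + 1e-12)].sum())
    return min(p, 1.0)


def genotype_counts(calls: np.ndarray) -> tuple[int, int, int]:
    """(n_REF-hom, n_het, n_ALT-hom) at one locus, missing excluded."""
    calls = np.asarray(calls)
    return (
        int((calls == 0).sum()),
        int((calls == 1).sum()),
        int((calls == 2).sum()),
    )


def filter_loci(
    gm: GenotypeMatrix, criteria: FilterCriteria | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the four locus filters; return retained matrix and report.

    Criteria are checked in the order qual, maf, hwe, missing; the
    report records the first failed criterion per removed locus.  A
    locus with no QUAL value passes the QUAL criterion.  Loci with all
    genotypes missing fail the MAF criterion (frequency undefined).
    """
    if criteria is None:
        criteria = FilterCriteria()
    n, m = gm.n_samples, gm.n_loci
    passed = np.ones(m, dtype=bool)
    failed_by = np.full(m, "", dtype=object)
    totals = {c: 0 for c in CRITERIA_ORDER}

    for j, loc in enumerate(gm.loci):
        col = gm.calls[:, j]
        fail = None
        if loc.qual is not None and loc.qual < criteria.min_qual:
            fail = "qual"
        if fail is None:
            called = col != MISSING
            n_called = int(called.sum())
            if n_called == 0:
                fail = "maf"
            else:
                p = float(col[called].sum()) / (2 * n_called)
                if min(p, 1.0 - p) < criteria.min_maf:
                    fail = "maf"
        if fail is None:
            n0, n1, n2 = genotype_counts(col)
            if hwe_exact_p(n0, n1, n2) < criteria.min_hwe_p:
                fail = "hwe"
        if fail is None:
            if int((col == MISSING).sum()) > criteria.max_missing:
                fail = "missing"
        if fail is not None:
            passed[j] = False
            failed_by[j] = fail
            totals[fail] += 1

    report = FilterReport(
        table=pd.DataFrame(
            {
                "locus_id": [loc.id for loc in gm.loci],
                "passed": passed,
                "failed_criterion": failed_by,
            }
        ),
        totals=totals,
    )
    return gm.subset_loci(passed), report
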