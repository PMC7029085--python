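"""Additive and dominance genomic relationship matrices, inbreeding,
coancestry and dominance coefficients.

Both matrices use within-SNP standardization: every SNP is scaled by its
own Hardy-Weinberg variance before averaging over loci, so

    A_g[i,j] = (1/m_ij) * sum_k (x_ik - 2 p_k)(x_jk - 2 p_k) / (2 p_k q_k)
    D_g[i,j] = (1/m_ij) * sum_k  w_ik w_jk / (2 p_k q_k)^2

with dominance codes w = -2p^2 (REF hom), 2pq (het), -2q^2 (ALT hom).
Missing genotypes contribute nothing and shrink the pair-specific locus
count m_ij (pairwise-complete accumulation).  Under these codings the
diagonal of A_g averages 1 + F, half the off-diagonal of A_g estimates
the coancestry coefficient theta, and the off-diagonal of D_g estimates
the dominance coefficient D (expectation 1/4 for full sibs, 1/16 for
double first cousins).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import MISSING, GenotypeMatrix


@dataclass
class RelationshipMatrices:
    """Additive (A_g) and dominance (D_g) genomic relationship matrices."""

    A_g: np.ndarray
    D_g: np.ndarray
    freqs_used: np.ndarray
    n_loci_used: np.ndarray  # pairwise-complete locus counts, n x n
    samples: list[str]


def _check_freqs(p: np.ndarray, loci_ids: list[str]) -> None:
    bad = np.flatnonzero((p <= 0) | (p >= 1))
    if bad.size:
        names = [loci_ids[int(b)] for b in bad[:10]]
        raise ValueError(
            f"{bad.size} loci monomorphic under the supplied frequencies "
            f"(first few: {names}); exclude them upstream"
        )


def additive_codes(dosages: np.ndarray, p: float | np.ndarray) -> np.ndarray:
    """Centered additive codes x - 2p (missing dosage -> 0 contribution).

    The per-SNP divisor 2pq is applied at accumulation time by
    :func:`build_grms`, not here.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("allele frequency must be strictly inside (0, 1)")
    dosages = np.asarray(dosages)
    codes = dosages.astype(float) - 2.0 * p
    codes[dosages == MISSING] = 0.0
    return codes


def dominance_codes(dosages: np.ndarray, p: float | np.ndarray) -> np.ndarray:
    """Dominance codes: 0 -> -2p^2, 1 -> 2pq, 2 -> -2q^2 (missing -> 0).

    These codes have expectation zero under Hardy-Weinberg genotype
    frequencies at any p, and the per-SNP divisor (2pq)^2 at
    accumulation yields E[D] = 1/4 for full-sib pairs.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("allele frequency must be strictly inside (0, 1)")
    q = 1.0 - p
    dosages = np.asarray(dosages)
    codes = np.select(
        [dosages == 0, dosages == 1, dosages == 2],
        [np.broadcast_to(-2 * p**2, dosages.shape),
         np.broadcast_to(2 * p * q, dosages.shape),
         np.broadcast_to(-2 * q**2, dosages.shape)],
        default=0.0,
    )
    return codes


def sample_frequencies(gm: GenotypeMatrix) -> np.ndarray:
    """Observed ALT frequency per locus over non-missing calls."""
    calls = gm.calls
    called = calls != MISSING
    n_called = called.sum(axis=0)
    if np.any(n_called == 0):
        raise ValueError("locus with all genotypes missing")
    sums = np.where(called, calls, 0).sum(axis=0)
    return sums / (2.0 * n_called)


def build_grms(
    gm: GenotypeMatrix, freqs: str | np.ndarray = "sample", loo: bool = False
) -> RelationshipMatrices:
    """Build A_g and D_g with within-SNP standardization.

    Parameters
    ----------
    gm : GenotypeMatrix
    freqs : "sample" or array of per-locus ALT frequencies
        "sample" uses the observed frequencies; an explicit vector (for
        example simulation truth) may be supplied instead.  Every locus
        must be polymorphic under the chosen frequencies.
    loo : bool
        Re-estimate frequencies excluding the focal pair for every
        entry (and excluding the focal individual on the diagonal).
        Addresses the downward bias of sample-frequency estimates that
        include the individuals being compared.  Loci monomorphic after
        exclusion are dropped for that entry.  Only valid with
        ``freqs="sample"``.
    """
    if loo:
        if not (isinstance(freqs, str) and freqs == "sample"):
            raise ValueError("loo=True requires freqs='sample'")
        return _build_grms_loo(gm)
    if isinstance(freqs, str):
        if freqs != "sample":
            raise ValueError(f"unknown freqs mode {freqs!r}")
        p = sample_frequencies(gm)
    else:
        p = np.asarray(freqs, dtype=float)
        if p.shape != (gm.n_loci,):
            raise ValueError("frequency vector length != number of loci")
    _check_freqs(p, [loc.id for loc in gm.loci])

    q = 1.0 - p
    called = (gm.calls != MISSING).astype(float)
    m_pair = called @ called.T

    # additive: product of (x-2p)/sqrt(2pq) sums to (x_i-2p)(x_j-2p)/(2pq)
    U = additive_codes(gm.calls, p) / np.sqrt(2.0 * p * q)
    A = (U @ U.T) / m_pair

    W = dominance_codes(gm.calls, p) / (2.0 * p * q)
    D = (W @ W.T) / m_pair

    A = (A + A.T) / 2.0
    D = (D + D.T) / 2.0
    return RelationshipMatrices(
        A_g=A, D_g=D, freqs_used=p, n_loci_used=m_pair.astype(int),
        samples=list(gm.samples),
    )


def _build_grms_loo(gm: GenotypeMatrix) -> RelationshipMatrices:
    """GRMs with per-entry leave-pair-out allele frequencies."""
    n, m = gm.n_samples, gm.n_loci
    calls = gm.calls
    called = calls != MISSING
    sums_all = np.where(called, calls, 0).sum(axis=0).astype(float)
    n_called_all = called.sum(axis=0).astype(float)

    A = np.zeros((n, n))
    D = np.zeros((n, n))
    m_pair = np.zeros((n, n), dtype=int)
    contrib = np.where(called, calls, 0).astype(float)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                sums = sums_all - contrib[i]
                nc = n_called_all - called[i]
            else:
                sums = sums_all - contrib[i] - contrib[j]
                nc = n_called_all - called[i] - called[j]
            with np.errstate(divide="ignore", invalid="ignore"):
                p = np.where(nc > 0, sums / (2.0 * nc), np.nan)
            ok = called[i] & called[j] & (p > 0) & (p < 1)
            if not ok.any():
                raise ValueError(
                    f"no usable loci for pair ({gm.samples[i]}, {gm.samples[j]})"
                )
            pk = p[ok]
            qk = 1.0 - pk
            xi = calls[i, ok].astype(float)
            xj = calls[j, ok].astype(float)
            A[i, j] = A[j, i] = np.mean(
                (xi - 2 * pk) * (xj - 2 * pk) / (2 * pk * qk)
            )
            wi = np.select([xi == 0, xi == 1], [-2 * pk**2, 2 * pk * qk], -2 * qk**2)
            wj = np.select([xj == 0, xj == 1], [-2 * pk**2, 2 * pk * qk], -2 * qk**2)
            D[i, j] = D[j, i] = np.mean(wi * wj / (2 * pk * qk) ** 2)
            m_pair[i, j] = m_pair[j, i] = int(ok.sum())

    return RelationshipMatrices(
        A_g=A, D_g=D, freqs_used=sample_frequencies(gm),
        n_loci_used=m_pair, samples=list(gm.samples),
    )


def coancestry(A_g: np.ndarray) -> np.ndarray:
    """Pairwise coancestry theta_ij = A_g[i,j] / 2 (diagonal left as is)."""
    return np.asarray(A_g, dtype=float) / 2.0


def grm_inbreeding(A_g: np.ndarray) -> np.ndarray:
    """Per-individual inbreeding F_i = A_g[i,i] - 1."""
    return np.diag(np.asarray(A_g, dtype=float)) - 1.0


def het_inbreeding(gm: GenotypeMatrix, freqs: str | np.ndarray = "sample") -> np.ndarray:
    """Method-of-moments inbreeding from the homozygosity excess.

    F_i = (O_hom(i) - E_hom(i)) / (L_i - E_hom(i)), where O_hom counts
    observed homozygous loci of individual i, L_i its non-missing loci,
    and E_hom = sum_k [1 - 2 p_k q_k * Na_k / (Na_k - 1)] the expected
    homozygosity with the small-sample correction on the allele count
    Na_k = 2 * (called individuals at locus k).  Undefined values
    (L_i == E_hom) are returned as NaN.
    """
    if isinstance(freqs, str):
        p = sample_frequencies(gm)
    else:
        p = np.asarray(freqs, dtype=float)
    q = 1.0 - p
    called = gm.calls != MISSING
    n_called = called.sum(axis=0)
    Na = 2.0 * n_called
    corr = np.where(Na > 1, Na / np.maximum(Na - 1.0, 1.0), 1.0)
    e_hom_k = 1.0 - 2.0 * p * q * corr

    hom = ((gm.calls == 0) | (gm.calls == 2)).astype(float)
    O = hom.sum(axis=1)
    L = called.sum(axis=1).astype(float)
    E = called @ e_hom_k
    denom = L - E
    with np.errstate(divide="ignore", invalid="ignore"):
        F = np.where(denom != 0, (O - E) / denom, np.nan)
    return F


#: Canonical pedigree-expectation inbreeding classes.
INBREEDING_CLASSES = {
    "outbred": 0.0,
    "first_cousin_mating": 1.0 / 16,
    "half_sib_mating": 1.0 / 8,
    "full_sib_mating": 1.0 / 4,
}


def classify_inbreeding(
    F: np.ndarray, classes: dict[str, float] | None = None
) -> list[str]:
    """Assign each F to the nearest pedigree-expectation class.

    Default classes are the matings of unrelated parents (F = 0), first
    cousins (1/16), half sibs (1/8) and full sibs (1/4); boundaries are
    the midpoints between adjacent expectations.
    """
    if classes is None:
        classes = INBREEDING_CLASSES
    names = list(classes)
    values = np.array([classes[k] for k in names])
    F = np.atleast_1d(np.asarray(F, dtype=float))
    idx = np.abs(F[:, None] - values[None, :]).argmin(axis=1)
    return [names[int(i)] for i in idx]


def inbreeding_table(
    gm: GenotypeMatrix,
    freqs: str | np.ndarray = "sample",
    populations: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-individual inbreeding summary: GRM and heterozygosity variants."""
    rm = build_grms(gm, freqs)
    grm_F = grm_inbreeding(rm.A_g)
    het_F = het_inbreeding(gm, rm.freqs_used)
    df = pd.DataFrame(
        {
            "sample": gm.samples,
            "grm_F": grm_F,
            "het_F": het_F,
            "class": classify_inbreeding(grm_F),
        }
    )
    if populations is not None:
        df["population"] = [populations.get(s, "") for s in gm.samples]
    return df
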