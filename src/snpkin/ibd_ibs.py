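"""Pairwise identity-by-state sharing and method-of-moments IBD estimation.

For each pair, loci called in both members are classified into IBS
states (0, 1 or 2 shared alleles); DST = (ibs2 + ibs1/2) / n_shared is
the allele-sharing similarity.  IBD state probabilities Z0/Z1/Z2 (the
pair shares 0, 1 or 2 alleles identical by descent) are recovered by
inverting the expected IBS-class counts under each IBD state, using
allele frequencies with finite-sample bias corrections, then clamping
to the probability simplex.  PI_HAT = Z1/2 + Z2 estimates the
proportion of the genome shared IBD (twice the kinship coefficient).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .grm import build_grms, coancestry, sample_frequencies
from .io_formats import MISSING, GenotypeMatrix, SampleMeta


def ibs_counts(x: np.ndarray, y: np.ndarray) -> tuple[int, int, int, int]:
    """IBS class counts for one pair of dosage vectors.

    Per locus with both calls present: dosage distance 0 -> IBS2,
    distance 1 -> IBS1, distance 2 (opposite homozygotes) -> IBS0.
    Returns ``(ibs0, ibs1, ibs2, n_shared)``.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    both = (x != MISSING) & (y != MISSING)
    d = np.abs(x[both].astype(int) - y[both].astype(int))
    n_shared = int(both.sum())
    ibs0 = int((d == 2).sum())
    ibs1 = int((d == 1).sum())
    ibs2 = int((d == 0).sum())
    return ibs0, ibs1, ibs2, n_shared


def _expected_ibs_given_ibd(p: np.ndarray, n_alleles: np.ndarray):
    """Per-locus expected IBS-class probabilities under IBD states 0 and 1,
    with finite-sample bias corrections on the allele counts.

    Returns (e00, e10, e20, e11, e21): e<ibs><ibd>.  Under IBD 2 the pair
    is IBS 2 with probability 1.
    """
    p = np.asarray(p, dtype=float)
    Na = np.asarray(n_alleles, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("allele frequencies must be strictly inside (0, 1)")
    if np.any(Na < 4):
        raise ValueError("need at least 4 observed alleles per locus")
    q = 1.0 - p
    x = p * Na  # expected ALT allele count
    y = q * Na
    c1 = Na / (Na - 1.0)
    c2 = Na / (Na - 2.0)
    c3 = Na / (Na - 3.0)

    e00 = 2 * p**2 * q**2 * ((x - 1) / x) * ((y - 1) / y) * c1 * c2 * c3
    e10 = (
        4 * p**3 * q * ((x - 1) / x) * ((x - 2) / x)
        + 4 * p * q**3 * ((y - 1) / y) * ((y - 2) / y)
    ) * c1 * c2 * c3
    e20 = (
        p**4 * ((x - 1) / x) * ((x - 2) / x) * ((x - 3) / x)
        + q**4 * ((y - 1) / y) * ((y - 2) / y) * ((y - 3) / y)
        + 4 * p**2 * q**2 * ((x - 1) / x) * ((y - 1) / y)
    ) * c1 * c2 * c3
    e11 = (
        2 * p**2 * q * ((x - 1) / x) + 2 * p * q**2 * ((y - 1) / y)
    ) * c1 * c2
    e21 = (
        p**3 * ((x - 1) / x) * ((x - 2) / x)
        + q**3 * ((y - 1) / y) * ((y - 2) / y)
        + p**2 * q * ((x - 1) / x)
        + p * q**2 * ((y - 1) / y)
    ) * c1 * c2
    return e00, e10, e20, e11, e21


def _simplex_clamp(z0: float, z1: float, z2: float) -> tuple[float, float, float]:
    z = np.array([z0, z1, z2], dtype=float)
    z = np.clip(z, 0.0, None)
    s = z.sum()
    if s <= 0:
        return 0.0, 0.0, 1.0
    z /= s
    return float(z[0]), float(z[1]), float(z[2])


def mom_ibd(
    x: np.ndarray,
    y: np.ndarray,
    freqs: np.ndarray,
    n_alleles: np.ndarray | int,
) -> tuple[float, float, float, float]:
    """Method-of-moments IBD state probabilities for one pair.

    Parameters
    ----------
    x, y : dosage vectors (missing allowed)
    freqs : per-locus ALT frequency, strictly in (0, 1)
    n_alleles : per-locus observed allele count in the frequency sample
        (scalar accepted)

    Returns ``(Z0, Z1, Z2, PI_HAT)`` with the Z's clamped onto the
    simplex.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    p = np.asarray(freqs, dtype=float)
    Na = np.broadcast_to(np.asarray(n_alleles, dtype=float), p.shape)
    both = (x != MISSING) & (y != MISSING)
    if not both.any():
        raise ValueError("pair shares no called loci")
    e00, e10, e20, e11, e21 = _expected_ibs_given_ibd(p[both], Na[both])
    E00, E10, E20 = e00.sum(), e10.sum(), e20.sum()
    E11, E21 = e11.sum(), e21.sum()
    if E00 <= 0 or E11 <= 0:
        raise ValueError("degenerate expected IBS counts for this locus set")

    ibs0, ibs1, ibs2, n = ibs_counts(x, y)
    z0 = ibs0 / E00
    z1 = (ibs1 - z0 * E10) / E11
    z2 = (ibs2 - z0 * E20 - z1 * E21) / n
    Z0, Z1, Z2 = _simplex_clamp(z0, z1, z2)
    return Z0, Z1, Z2, 0.5 * Z1 + Z2


def _loo_pair_freqs(gm: GenotypeMatrix, i: int, j: int) -> tuple[np.ndarray, np.ndarray]:
    """Allele frequencies excluding the focal pair; returns (p, n_alleles)."""
    calls = gm.calls
    called = calls != MISSING
    sums = np.where(called, calls, 0).sum(axis=0).astype(float)
    n_called = called.sum(axis=0).astype(float)
    for r in (i, j):
        sums -= np.where(called[r], calls[r], 0)
        n_called -= called[r]
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_called > 0, sums / (2.0 * n_called), np.nan)
    return p, 2.0 * n_called


def pair_table(
    gm: GenotypeMatrix,
    meta: list[SampleMeta] | None = None,
    freqs: str | np.ndarray = "sample",
    loo: bool = False,
) -> pd.DataFrame:
    """Full per-pair table: IBS counts, DST, Z0/Z1/Z2, PI_HAT, theta, D.

    One row per unordered pair (i < j in sample order).  ``loo``
    re-estimates allele frequencies excluding the focal pair for the IBD
    moments (loci monomorphic after exclusion are dropped for that
    pair).  Loci monomorphic under the chosen frequencies carry no
    pairwise information and are dropped up front.  Population labels
    and river-km distances are attached when metadata is given.
    """
    if isinstance(freqs, str):
        p_all = sample_frequencies(gm)
    else:
        p_all = np.asarray(freqs, dtype=float)
    poly = (p_all > 0) & (p_all < 1)
    if not poly.all():
        gm = gm.subset_loci(poly)
        p_all = p_all[poly]
    n = gm.n_samples
    n_alleles_all = 2.0 * (gm.calls != MISSING).sum(axis=0)

    rm = build_grms(gm, p_all)
    theta = coancestry(rm.A_g)

    meta_by_id = {}
    if meta is not None:
        meta_by_id = {m.sample_id: m for m in meta}

    rows = []
    for i, j in itertools.combinations(range(n), 2):
        x, y = gm.calls[i], gm.calls[j]
        ibs0, ibs1, ibs2, ns = ibs_counts(x, y)
        if loo:
            p, na = _loo_pair_freqs(gm, i, j)
            ok = np.isfinite(p) & (p > 0) & (p < 1) & (na >= 4)
            Z0, Z1, Z2, pihat = mom_ibd(
                np.where(ok, x, MISSING), np.where(ok, y, MISSING), p, na
            )
        else:
            ok = (p_all > 0) & (p_all < 1)
            Z0, Z1, Z2, pihat = mom_ibd(
                np.where(ok, x, MISSING), np.where(ok, y, MISSING),
                p_all, n_alleles_all,
            )
        row = {
            "id1": gm.samples[i],
            "id2": gm.samples[j],
            "n_shared": ns,
            "ibs0": ibs0,
            "ibs1": ibs1,
            "ibs2": ibs2,
            "DST": (ibs2 + 0.5 * ibs1) / ns if ns else np.nan,
            "Z0": Z0,
            "Z1": Z1,
            "Z2": Z2,
            "PI_HAT": pihat,
            "theta": theta[i, j],
            "dom": rm.D_g[i, j],
        }
        if meta_by_id:
            m1 = meta_by_id[gm.samples[i]]
            m2 = meta_by_id[gm.samples[j]]
            row["pop1"] = m1.population
            row["pop2"] = m2.population
            row["dist_km"] = abs(m1.river_km - m2.river_km)
        rows.append(row)
    return pd.DataFrame(rows)
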