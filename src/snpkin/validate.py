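"""Pedigree-expectation recovery protocol.

Simulates replicate pedigrees of one relative class, builds the genomic
relationship matrices per replicate with the TRUE founder frequencies,
and collects the focal statistic (inbreeding F of the focal individual,
or the dominance/coancestry/PI_HAT of the focal pair).  Averaged over
replicates these estimates must recover the classical pedigree
expectations — the package's central validation, since the wild
population it targets has no pedigree records to check against.
"""

from __future__ import annotations

import numpy as np

from .grm import build_grms
from .ibd_ibs import mom_ibd
from .io_formats import GenotypeMatrix
from .pedsim import SimConfig, expected_coefficients, gene_drop, make_pedigree

STATISTICS = ("grm_F", "dominance", "theta", "pihat")


def simulate_focal_estimates(
    template: str,
    statistic: str,
    n_replicates: int = 200,
    n_loci: int = 20_000,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Per-replicate focal estimates and their exact pedigree expectation.

    Returns ``(estimates, expected)`` where estimates has one entry per
    replicate.  Frequencies used are the simulation truth, so the
    recovery is unbiased by frequency estimation.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    ped = make_pedigree(template, n_replicates)
    gm, p = gene_drop(ped, SimConfig(n_loci=n_loci, seed=seed))
    idx = {s: i for i, s in enumerate(gm.samples)}

    if statistic == "grm_F":
        if not ped.focal_individuals:
            raise ValueError(f"template {template!r} has no focal individual")
        focal = ped.focal_individuals
        exp = expected_coefficients(ped, focal[0], focal[0]).inbreeding_i
    else:
        if not ped.focal_pairs:
            raise ValueError(f"template {template!r} has no focal pair")
        a0, b0 = ped.focal_pairs[0]
        e = expected_coefficients(ped, a0, b0)
        exp = {"dominance": e.dominance, "theta": e.kinship,
               "pihat": 2.0 * e.kinship}[statistic]

    n_alleles = 2 * gm.n_samples
    out = np.empty(n_replicates)
    for k in range(n_replicates):
        pref = f"r{k}_"
        rows = [i for s, i in idx.items() if s.startswith(pref)]
        sub = GenotypeMatrix(
            [gm.samples[r] for r in rows], gm.loci, gm.calls[rows]
        )
        if statistic == "pihat":
            a, b = next(pr for pr in ped.focal_pairs if pr[0].startswith(pref))
            i, j = sub.samples.index(a), sub.samples.index(b)
            out[k] = mom_ibd(sub.calls[i], sub.calls[j], p, n_alleles)[3]
            continue
        rm = build_grms(sub, p)
        if statistic == "grm_F":
            z = next(f for f in ped.focal_individuals if f.startswith(pref))
            zi = sub.samples.index(z)
            out[k] = rm.A_g[zi, zi] - 1.0
        else:
            a, b = next(pr for pr in ped.focal_pairs if pr[0].startswith(pref))
            i, j = sub.samples.index(a), sub.samples.index(b)
            M = rm.D_g if statistic == "dominance" else rm.A_g / 2.0
            out[k] = M[i, j]
    return out, float(exp)
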