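"""Per-population summaries, group comparisons and the distance regression.

Population differences are tested with the one-way fixed-effect model
y = mu + population + e; pairwise contrasts at alpha = 0.05 feed a
compact-letter display (groups sharing no letter differ).  The
coancestry-versus-geography relationship is estimated by OLS over
individual pairs, with a Mantel permutation test as the companion that
respects the non-independence of pairs sharing an individual.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def summarize_groups(values, labels) -> pd.DataFrame:
    """Mean, sample SD, min, max and n per group plus an overall row.

    Groups of one observation get SD = NaN (flagged undefined).
    """
    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "group": list(labels)})
    rows = []
    for g, sub in df.groupby("group", sort=True):
        v = sub["value"].to_numpy()
        rows.append(
            {
                "group": g,
                "n": v.size,
                "mean": v.mean(),
                "sd": v.std(ddof=1) if v.size > 1 else np.nan,
                "min": v.min(),
                "max": v.max(),
            }
        )
    v = df["value"].to_numpy()
    rows.append(
        {
            "group": "overall",
            "n": v.size,
            "mean": v.mean(),
            "sd": v.std(ddof=1) if v.size > 1 else np.nan,
            "min": v.min(),
            "max": v.max(),
        }
    )
    return pd.DataFrame(rows)


def pair_group_label(pop1: str, pop2: str) -> str:
    """Canonical label for a pair of population labels (within: 'A-A')."""
    a, b = sorted([pop1, pop2])
    return f"{a}-{b}"


def _letter_display(groups: list[str], differ: set[frozenset]) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Two groups share a letter iff they were NOT declared different.
    """
    letters: list[set[str]] = []
    for g in groups:
        placed = False
        for cluster in letters:
            if all(frozenset((g, h)) not in differ for h in cluster):
                cluster.add(g)
                placed = True
        if not placed:
            letters.append({g})
    # absorb clusters fully contained in another
    letters = [
        c for i, c in enumerate(letters)
        if not any(c < other for j, other in enumerate(letters) if i != j)
    ]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {g: "" for g in groups}
    for c, cluster in zip(alphabet, letters):
        for g in cluster:
            out[g] += c
    return {g: "".join(sorted(s)) for g, s in out.items()}


@dataclass
class GroupComparison:
    """Pairwise contrasts from the one-way model plus letter display."""

    anova_F: float
    anova_p: float
    pairwise: pd.DataFrame  # group1, group2, diff, t, p
    letters: dict[str, str]
    excluded: list[str]


def compare_groups(values, labels, alpha: float = 0.05,
                   adjust: str = "none") -> GroupComparison:
    """One-way fixed-effect model with all pairwise contrasts.

    ``adjust``: "none" for unadjusted t contrasts on the pooled residual
    variance, or "tukey" for Tukey HSD (statsmodels).  Groups with fewer
    than 2 observations are excluded with a warning field.
    """
    import warnings

    df = pd.DataFrame({"value": np.asarray(values, dtype=float),
                       "group": list(labels)}).dropna()
    sizes = df.groupby("group")["value"].size()
    excluded = sorted(sizes[sizes < 2].index)
    if excluded:
        warnings.warn(f"groups excluded from comparison (n < 2): {excluded}")
        df = df[~df["group"].isin(excluded)]
    groups = sorted(df["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups with n >= 2")

    arrays = [df.loc[df["group"] == g, "value"].to_numpy() for g in groups]
    F, p_anova = stats.f_oneway(*arrays)

    N = df.shape[0]
    k = len(groups)
    means = {g: a.mean() for g, a in zip(groups, arrays)}
    ns = {g: a.size for g, a in zip(groups, arrays)}
    sse = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    mse = sse / (N - k)
    dof = N - k

    rows = []
    if adjust == "tukey":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        res = pairwise_tukeyhsd(df["value"], df["group"], alpha=alpha)
        combos = list(itertools.combinations(res.groupsunique, 2))
        for (g1, g2), diff, pv in zip(combos, res.meandiffs, res.pvalues):
            rows.append(
                {"group1": g1, "group2": g2, "diff": float(diff),
                 "t": np.nan, "p": float(pv)}
            )
    elif adjust == "none":
        for g1, g2 in itertools.combinations(groups, 2):
            diff = means[g2] - means[g1]
            se = np.sqrt(mse * (1.0 / ns[g1] + 1.0 / ns[g2]))
            t = diff / se
            pv = 2.0 * stats.t.sf(abs(t), dof)
            rows.append({"group1": g1, "group2": g2, "diff": diff, "t": t, "p": pv})
    else:
        raise ValueError(f"unknown adjust mode {adjust!r}")

    pw = pd.DataFrame(rows)
    differ = {
        frozenset((r.group1, r.group2)) for r in pw.itertuples(index=False)
        if r.p < alpha
    }
    return GroupComparison(
        anova_F=float(F),
        anova_p=float(p_anova),
        pairwise=pw,
        letters=_letter_display(groups, differ),
        excluded=excluded,
    )


@dataclass
class DistanceRegression:
    """OLS of a pair statistic on pairwise distance plus a Mantel test."""

    slope: float
    intercept: float
    r: float
    p_ols: float
    p_mantel: float
    n_pairs: int
    n_permutations: int


def _pairs_to_square(pairs: pd.DataFrame, col: str) -> tuple[np.ndarray, list[str]]:
    ids = sorted(set(pairs["id1"]) | set(pairs["id2"]))
    idx = {s: i for i, s in enumerate(ids)}
    M = np.zeros((len(ids), len(ids)))
    for row in pairs.itertuples(index=False):
        i, j = idx[row.id1], idx[row.id2]
        M[i, j] = M[j, i] = getattr(row, col)
    return M, ids


def mantel_test(
    X: np.ndarray,
    Y: np.ndarray,
    n_permutations: int = 9999,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Mantel permutation test of the correlation between two square
    symmetric pair matrices.

    Rows/columns of Y are permuted jointly; the observed statistic is
    included in the permutation distribution, so p >= 1/(nperm + 1).
    Returns ``(r_observed, p_value)``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[0]
    if X.shape != (n, n) or Y.shape != (n, n):
        raise ValueError("matrices must be square and of equal size")
    iu = np.triu_indices(n, k=1)
    x = X[iu]

    def corr(y):
        return float(np.corrcoef(x, y)[0, 1])

    r_obs = corr(Y[iu])
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    count = 1  # observed statistic included
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        r_perm = corr(Y[np.ix_(perm, perm)][iu])
        if abs(r_perm) >= abs(r_obs) - 1e-12:
            count += 1
    return r_obs, count / (n_permutations + 1)


def regress_on_distance(
    pairs: pd.DataFrame,
    stat: str = "theta",
    dist_col: str = "dist_km",
    n_permutations: int = 9999,
    seed: int = 0,
) -> DistanceRegression:
    """Regress a pairwise statistic on geographic distance.

    OLS over individual pairs (slope, r, p) plus a Mantel permutation
    p-value, since pairs sharing an individual are not independent.
    Requires at least 3 distinct distances.
    """
    d = pairs[dist_col].to_numpy(dtype=float)
    v = pairs[stat].to_numpy(dtype=float)
    if np.unique(d).size < 3:
        raise ValueError("need at least 3 distinct distances")
    res = stats.linregress(d, v)

    V, ids = _pairs_to_square(pairs, stat)
    D, ids2 = _pairs_to_square(pairs, dist_col)
    assert ids == ids2
    _, p_mantel = mantel_test(V, D, n_permutations=n_permutations, seed=seed)
    return DistanceRegression(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        p_ols=float(res.pvalue),
        p_mantel=float(p_mantel),
        n_pairs=int(d.size),
        n_permutations=n_permutations,
    )
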