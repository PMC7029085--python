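"""Classical (metric) multidimensional scaling of IBS distances.

Individuals are embedded by eigendecomposition of the double-centered
squared-distance matrix B = -1/2 J D^2 J; coordinates are the top-k
eigenvectors scaled by the square roots of their (non-negative)
eigenvalues.  The distance fed to it is the standard IBS distance
d = 1 - DST.  Axis signs are not identifiable; compare distances or
absolute geometry, never signed coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

import scipy.linalg


@dataclass
class MDSResult:
    """Embedding coordinates with their eigenvalues (descending)."""

    coordinates: np.ndarray   # n x k
    eigenvalues: np.ndarray   # k, descending
    distance_matrix_used: np.ndarray
    negative_eigenvalues: np.ndarray  # any negative tail of the spectrum


def classical_mds(dist: np.ndarray, k: int) -> MDSResult:
    """Embed a symmetric non-negative distance matrix in k dimensions.

    Axes whose eigenvalue is negative (non-Euclidean input) are zeroed
    and the offending eigenvalues reported on the result.
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(D < 0):
        raise ValueError("distances must be non-negative")
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must be in [1, n-1], got {k}")

    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    B = (B + B.T) / 2.0
    evals, evecs = scipy.linalg.eigh(B)
    order = np.argsort(-evals, kind="stable")  # descending, ties by index
    evals = evals[order]
    evecs = evecs[:, order]

    top = evals[:k]
    lam = np.clip(top, 0.0, None)
    coords = evecs[:, :k] * np.sqrt(lam)[None, :]
    return MDSResult(
        coordinates=coords,
        eigenvalues=top,
        distance_matrix_used=D,
        negative_eigenvalues=evals[evals < 0],
    )


def ibs_distance(pairs: pd.DataFrame, samples: list[str]) -> np.ndarray:
    """Square IBS distance matrix d = 1 - DST from a pair table."""
    idx = {s: i for i, s in enumerate(samples)}
    n = len(samples)
    D = np.zeros((n, n))
    seen = np.zeros((n, n), dtype=bool)
    for row in pairs.itertuples(index=False):
        i, j = idx[row.id1], idx[row.id2]
        D[i, j] = D[j, i] = 1.0 - row.DST
        seen[i, j] = seen[j, i] = True
    np.fill_diagonal(seen, True)
    if not seen.all():
        raise ValueError("pair table does not cover all sample pairs")
    return D


def mds_table(result: MDSResult, samples: list[str]) -> pd.DataFrame:
    """Coordinates as a DataFrame with columns sample, C1..Ck."""
    k = result.coordinates.shape[1]
    df = pd.DataFrame(
        result.coordinates, columns=[f"C{i + 1}" for i in range(k)]
    )
    df.insert(0, "sample", samples)
    return df
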