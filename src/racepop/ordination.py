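"""Principal coordinate analysis (classical metric scaling) of a distance matrix."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import eigh

from .distance_tree import DistanceMatrix

logger = logging.getLogger(__name__)

__all__ = ["PcoaResult", "pcoa", "write_pcoa_tsv"]

_EIG_TOL = 1e-10


@dataclass
class PcoaResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # (n_samples, n_axes)
    eigenvalues: np.ndarray  # retained axes, nonincreasing
    pct_variance: np.ndarray  # percent of the positive-eigenvalue sum


def pcoa(dm: DistanceMatrix, n_axes: int = 3) -> PcoaResult:
    """Gower-centered eigendecomposition of the squared-distance matrix.

    Retains up to ``n_axes`` positive eigenvalues (fewer, with a warning, if
    the matrix has lower positive rank). Negative eigenvalues are logged and
    excluded from the percent-variance denominator; no Cailliez/Lingoes
    correction is applied.
    """
    if n_axes < 1:
        raise ValueError("n_axes must be >= 1")
    n = len(dm.sample_ids)
    d2 = dm.d**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    vals, vecs = eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    vecs = vecs[:, order]

    neg = vals[vals < -_EIG_TOL]
    if neg.size:
        logger.warning(
            "distance matrix is non-Euclidean: %d negative eigenvalues "
            "(most negative %.3g) excluded",
            neg.size,
            neg.min(),
        )
    pos_mask = vals > _EIG_TOL
    n_pos = int(pos_mask.sum())
    k = min(n_axes, n_pos)
    if k < n_axes:
        logger.warning("only %d positive eigenvalues available; returning %d axes", n_pos, k)
    lam = vals[:k]
    coords = vecs[:, :k] * np.sqrt(lam)
    total_pos = vals[pos_mask].sum()
    pct = 100.0 * lam / total_pos if total_pos > 0 else np.zeros(k)
    return PcoaResult(
        sample_ids=list(dm.sample_ids),
        coordinates=coords,
        eigenvalues=lam,
        pct_variance=pct,
    )


def write_pcoa_tsv(result: PcoaResult, path: str | Path) -> None:
    k = result.coordinates.shape[1]
    with open(path, "w") as fh:
        fh.write(
            "# pct_variance\t"
            + "\t".join(f"{x:.6g}" for x in result.pct_variance)
            + "\n"
        )
        fh.write("sample_id\t" + "\t".join(f"axis{i + 1}" for i in range(k)) + "\n")
        for i, s in enumerate(result.sample_ids):
            fh.write(
                s + "\t" + "\t".join(f"{x:.10g}" for x in result.coordinates[i]) + "\n"
            )
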