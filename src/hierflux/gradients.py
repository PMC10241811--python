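"""Functional-connectome construction and diffusion-map embedding.

The principal connectome gradient — the first nontrivial diffusion-map
component of the functional connectivity graph — orders regions along
the unimodal-to-transmodal cortical axis and serves as the hierarchy
reference for the hierarchical index.

Pipeline: pairwise Pearson FC -> per-row top-k sparsification ->
cosine-similarity affinity (negatives clipped to 0) -> anisotropic
diffusion kernel with ``alpha = 0.5`` -> eigendecomposition of the
random-walk transition matrix.
"""

from __future__ import annotations

import numpy as np
from scipy import linalg
from scipy.sparse.csgraph import connected_components
from scipy.stats import spearmanr

from .core import GradientMap, RegionTimeSeries

__all__ = [
    "fc_matrix",
    "sparsify_rows",
    "cosine_affinity",
    "diffusion_embedding",
    "align_sign",
]


def fc_matrix(ts: RegionTimeSeries) -> np.ndarray:
    """Pairwise Pearson correlation between region time series.

    Zero-variance regions get NaN rows/columns (their correlation is
    undefined); the diagonal is forced to exactly 1 for valid regions.
    """
    if ts.n_frames < 3:
        raise ValueError("need at least 3 frames for a correlation matrix")
    sd = ts.data.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(ts.data, rowvar=False)
    c = np.asarray(c, dtype=float)
    dead = sd == 0
    c[dead, :] = np.nan
    c[:, dead] = np.nan
    idx = np.where(~dead)[0]
    c[idx, idx] = 1.0
    return c


def sparsify_rows(c: np.ndarray, sparsity: float = 0.9) -> np.ndarray:
    """Keep the top ``(1 - sparsity)`` fraction of each row, then symmetrize.

    The diagonal is excluded from the selection and zeroed in the output;
    the result is symmetrized as ``(S + S.T) / 2`` so the subsequent
    affinity graph has a real spectrum.
    """
    c = np.asarray(c, dtype=float)
    n = c.shape[0]
    if c.shape != (n, n):
        raise ValueError("expected a square matrix")
    if not (0.0 <= sparsity < 1.0):
        raise ValueError("sparsity must be in [0, 1)")
    k = int(np.ceil((1.0 - sparsity) * (n - 1)))
    k = max(k, 1)
    s = c.copy()
    np.fill_diagonal(s, -np.inf)
    # per-row threshold: the k-th largest off-diagonal entry
    kth = np.partition(s, n - k, axis=1)[:, n - k]
    keep = s >= kth[:, None]
    out = np.where(keep, c, 0.0)
    np.fill_diagonal(out, 0.0)
    return (out + out.T) / 2.0


def cosine_affinity(s: np.ndarray) -> np.ndarray:
    """Cosine similarity between connectivity rows, clipped to [0, 1].

    Negative similarities are set to zero so the matrix can serve as a
    nonnegative random-walk kernel; the diagonal is 1.
    """
    s = np.asarray(s, dtype=float)
    norms = np.linalg.norm(s, axis=1)
    if np.any(norms == 0):
        raise ValueError("all-zero row: cosine similarity undefined")
    a = (s @ s.T) / np.outer(norms, norms)
    a = np.clip(a, 0.0, 1.0)
    np.fill_diagonal(a, 1.0)
    return a


def _check_connected(a: np.ndarray) -> None:
    n_comp, labels = connected_components((a > 0).astype(int), directed=False)
    if n_comp > 1:
        sizes = np.bincount(labels)
        raise ValueError(
            f"affinity graph is disconnected: {n_comp} components with sizes "
            f"{sizes.tolist()}"
        )


def diffusion_embedding(
    a: np.ndarray, alpha: float = 0.5, n_components: int = 9
) -> GradientMap:
    """Diffusion-map embedding of a symmetric nonnegative affinity matrix.

    The affinity is density-normalized as ``W = D^-alpha A D^-alpha``
    (``alpha = 0.5`` balances local and global structure), converted to
    the random-walk transition matrix ``M = D_W^-1 W``, and
    eigendecomposed.  The trivial constant eigenvector (eigenvalue 1) is
    dropped; the reported components are the next ``n_components``
    eigenvectors, unit-norm with deterministic sign, each scaled by its
    eigenvalue (diffusion time t = 0 convention).

    The spectrum is obtained through the symmetric conjugate
    ``D_W^-1/2 W D_W^-1/2``, which shares eigenvalues with ``M`` and
    guarantees real output.
    """
    a = np.asarray(a, dtype=float)
    n = a.shape[0]
    if a.shape != (n, n):
        raise ValueError("affinity must be square")
    if not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("affinity must be symmetric")
    if np.any(a < 0):
        raise ValueError("affinity must be nonnegative")
    _check_connected(a)

    d = a.sum(axis=1)
    w = a / np.outer(d**alpha, d**alpha)
    dw = w.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(dw)
    sym = w * np.outer(inv_sqrt, inv_sqrt)
    sym = (sym + sym.T) / 2.0
    evals, evecs = linalg.eigh(sym)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # back-transform to right eigenvectors of M
    psi = evecs * inv_sqrt[:, None]

    k = min(n_components, n - 1)
    comps = np.empty((n, k))
    lams = np.empty(k)
    for j in range(k):
        v = psi[:, j + 1]
        v = v / np.linalg.norm(v)
        pivot = np.argmax(np.abs(v))
        if v[pivot] < 0:
            v = -v
        comps[:, j] = evals[j + 1] * v
        lams[j] = evals[j + 1]
    return GradientMap(comps, eigenvalues=lams, alpha=alpha)


def align_sign(grad: GradientMap, reference: np.ndarray) -> GradientMap:
    """Flip component signs so each correlates nonnegatively with a reference.

    Eigenvector sign is arbitrary; aligning against a reference map (or a
    template gradient) makes maps comparable across runs.  Components
    with exactly zero rank correlation are left unchanged.
    """
    reference = np.asarray(reference, dtype=float).ravel()
    if reference.size != grad.n_regions:
        raise ValueError("reference length does not match gradient regions")
    comps = grad.components.copy()
    for j in range(comps.shape[1]):
        rho = spearmanr(comps[:, j], reference).statistic
        if np.isfinite(rho) and rho < 0:
            comps[:, j] = -comps[:, j]
    return GradientMap(
        comps,
        eigenvalues=grad.eigenvalues,
        alpha=grad.alpha,
        sparsity=grad.sparsity,
        region_ids=grad.region_ids,
    )
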