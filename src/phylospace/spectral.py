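"""Modified graph Laplacian (MGL) spectra and spectral density profiles.

The MGL of a phylogeny is ``M = D - A`` where ``A`` is the all-pairs
node-to-node path-length matrix (over tips, internal nodes and the root)
and ``D`` is the diagonal "degree" matrix with ``D_ii = sum_j A_ij``.  Rows
of ``M`` sum to zero, so the smallest eigenvalue is a structural zero; the
remaining eigenvalues summarize how path length is distributed over the
tree.

The spectral density profile is a Gaussian kernel density of the
ln-transformed non-zero eigenvalues.  Three scalar statistics are read off
it:

* ``lambda_star`` — ln of the principal eigenvalue, a measure of
  phylogenetic expansion (rescaling every branch by ``c`` shifts it by
  exactly ``ln c``);
* ``psi`` — skewness of the ln-eigenvalues: low values indicate stemmy
  trees (branching concentrated near the root), high values tippy trees;
* ``eta`` — peak height of the unit-integral density: high values indicate
  regular (homogeneous) branch lengths.

A fourth, ``modality``, is the eigengap heuristic: the position of the
largest gap between descending-ranked eigenvalues, read as the number of
modes of division in the tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.linalg import eigvalsh
from scipy.stats import skew

from .tree_io import TreeRecord, node_distance_matrix, tree_metrics

__all__ = [
    "SpectralProfile",
    "build_mgl",
    "spectral_profile",
    "eigengap_modality",
]

#: eigenvalues with |lam| <= ZERO_TOL * lam_max are treated as structural zeros
ZERO_TOL = 1e-8
DEFAULT_GRID_SIZE = 512


def build_mgl(t: TreeRecord) -> np.ndarray:
    """Modified graph Laplacian ``D - A`` over all nodes of a tree."""
    if t.n_tips < 2:
        raise ValueError("MGL requires a tree with at least 2 tips")
    A = node_distance_matrix(t)
    return np.diag(A.sum(axis=1)) - A


def eigengap_modality(eigenvalues: np.ndarray, max_modes: Optional[int] = None) -> int:
    """Number of division modes via the eigengap heuristic.

    For eigenvalues ranked descending, returns the 1-based position ``i`` of
    the largest gap ``lam_i - lam_{i+1}`` over ``i = 1..min(max_modes,
    len-1)``; ties break toward smaller ``i``.
    """
    ev = np.sort(np.asarray(eigenvalues, dtype=float))[::-1]
    if ev.size < 2:
        raise ValueError("eigengap requires at least 2 eigenvalues")
    gaps = ev[:-1] - ev[1:]
    limit = gaps.size if max_modes is None else min(max_modes, gaps.size)
    return int(np.argmax(gaps[:limit])) + 1


def _silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule-of-thumb bandwidth, with a floor for degenerate data."""
    n = x.size
    sd = x.std(ddof=1) if n > 1 else 0.0
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    h = 0.9 * spread * n ** (-0.2)
    if h <= 0:
        h = 1e-6 * max(1.0, float(np.abs(x).max(initial=0.0)))
    return float(h)


@dataclass
class SpectralProfile:
    """Eigen-spectrum of a tree's MGL plus its density profile and statistics."""

    eigenvalues: np.ndarray  # descending, >= -tol
    ln_eigenvalues: np.ndarray  # structural zeros excluded
    grid: np.ndarray  # density abscissae (uniform)
    density: np.ndarray  # unit-integral density on grid
    bandwidth: float
    lambda_star: float
    psi: float
    eta: float
    modality: int
    label: Optional[str] = None
    n_tips: Optional[int] = None
    crown_age: Optional[float] = None
    family: Optional[str] = None
    taxon_class: Optional[str] = None

    def density_at(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the Gaussian KDE of the ln-eigenvalues at ``x``."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        z = (x[:, None] - self.ln_eigenvalues[None, :]) / self.bandwidth
        d = np.exp(-0.5 * z * z).sum(axis=1)
        d /= self.ln_eigenvalues.size * self.bandwidth * np.sqrt(2 * np.pi)
        return d


def spectral_profile(
    t: TreeRecord,
    grid_size: int = DEFAULT_GRID_SIZE,
    zero_tol: float = ZERO_TOL,
    label: Optional[str] = None,
) -> SpectralProfile:
    """Spectral density profile and summary statistics of a tree's MGL.

    Eigenvalues come from a dense symmetric solver; structural zeros
    (``|lam| <= zero_tol * lam_max``) are excluded from the ln-transform.
    The density is a Gaussian KDE (Silverman bandwidth) of the
    ln-eigenvalues on a uniform ``grid_size``-point grid spanning
    ``[min - 3h, max + 3h]``, renormalized to unit integral on the grid.
    """
    if t.n_nodes < 3:
        raise ValueError("spectral profile requires at least 3 nodes")
    ev = eigvalsh(build_mgl(t))[::-1]  # descending
    if not np.all(np.isfinite(ev)):
        raise ValueError("non-finite eigenvalues")
    lam_max = ev[0]
    if lam_max <= 0:
        raise ValueError("degenerate spectrum: all eigenvalues ~ 0")
    keep = np.abs(ev) > zero_tol * lam_max
    ln_ev = np.log(ev[keep])
    h = _silverman_bandwidth(ln_ev)
    grid = np.linspace(ln_ev.min() - 3 * h, ln_ev.max() + 3 * h, grid_size)
    prof = SpectralProfile(
        eigenvalues=ev,
        ln_eigenvalues=ln_ev,
        grid=grid,
        density=np.empty(grid_size),
        bandwidth=h,
        lambda_star=float(np.log(lam_max)),
        psi=float(skew(ln_ev)) if ln_ev.size > 1 else 0.0,
        eta=0.0,
        modality=eigengap_modality(ev),
        label=label if label is not None else t.label,
        family=t.family,
        taxon_class=t.taxon_class,
    )
    dens = prof.density_at(grid)
    area = np.trapezoid(dens, grid)
    dens = dens / area
    prof.density = dens
    prof.eta = float(dens.max())
    m = tree_metrics(t)
    prof.n_tips = m["n_tips"]
    prof.crown_age = m["crown_age"]
    return prof
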