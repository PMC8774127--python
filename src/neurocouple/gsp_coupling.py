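"""Graph-signal-processing decomposition of BOLD on the structural connectome.

The structural network is converted to its symmetric normalized Laplacian
``L = I - D^{-1/2} A D^{-1/2}`` and eigendecomposed into graph harmonics.
Each BOLD volume (TR) is a graph signal; its graph Fourier transform
``Uᵀ x`` splits across eigenmodes, low eigenvalues corresponding to
spatially smooth patterns aligned with white-matter structure. A median
split of the energy spectral density defines ideal low-/high-pass graph
filters; the temporal L2 norm of the low-pass (structure-aligned) and
high-pass (structure-liberal) filtered signal at each node gives the
structural coupling S_C and decoupling S_D of that area.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np
import scipy.linalg

from .io_formats import Connectome, ParcellatedBold, ValidationError

logger = logging.getLogger(__name__)

EIGVAL_TOL = 1e-9
SIGN_TOL = 1e-10


class IsolatedNodeError(ValidationError):
    """A node with zero degree cannot be degree-normalized."""


@dataclass(frozen=True)
class GraphSpectrum:
    """Eigendecomposition of a symmetric normalized graph Laplacian.

    ``eigenvalues`` ascending in [0, 2]; ``eigenvectors`` orthonormal columns,
    column k paired with eigenvalue k; sign fixed so the first component of
    each eigenvector exceeding ``SIGN_TOL`` in magnitude is positive.
    """

    eigenvalues: np.ndarray
    eigenvectors: np.ndarray
    laplacian: np.ndarray

    def __post_init__(self):
        lam, u, lap = self.eigenvalues, self.eigenvectors, self.laplacian
        n = lam.shape[0]
        if u.shape != (n, n) or lap.shape != (n, n):
            raise ValidationError("inconsistent spectrum shapes")
        if lam.min() < -EIGVAL_TOL or lam.max() > 2 + EIGVAL_TOL:
            raise ValidationError("eigenvalues outside [0, 2]")
        if np.any(np.diff(lam) < -EIGVAL_TOL):
            raise ValidationError("eigenvalues not ascending")
        if np.abs(u.T @ u - np.eye(n)).max() > 1e-9:
            raise ValidationError("eigenvectors not orthonormal")
        if np.abs(lap @ u - u * lam).max() > 1e-8:
            raise ValidationError("eigenpairs do not satisfy L U = U diag(lambda)")

    @property
    def n_nodes(self) -> int:
        return self.eigenvalues.shape[0]


@dataclass(frozen=True)
class SpectralBold:
    """Graph Fourier coefficients of a BOLD run plus per-mode energy.

    ``esd[k]`` is the mean over TRs of the squared coefficient of eigenmode k.
    ``split_index`` C marks the low band (modes with index < C); it is the
    smallest index whose cumulative ESD reaches half the total.
    """

    coefficients: np.ndarray
    esd: np.ndarray
    split_index: int | None = None

    def __post_init__(self):
        if (self.esd < 0).any():
            raise ValidationError("negative energy spectral density")
        if self.split_index is not None:
            n = self.esd.shape[0]
            c = self.split_index
            if not (1 <= c <= n - 1):
                raise ValidationError(f"split index {c} outside [1, {n - 1}]")


@dataclass(frozen=True)
class CouplingProfile:
    """Per-node structural coupling (S_C) and decoupling (S_D)."""

    node_ids: tuple
    s_c: np.ndarray
    s_d: np.ndarray

    def __post_init__(self):
        if not (np.isfinite(self.s_c).all() and np.isfinite(self.s_d).all()):
            raise ValidationError("non-finite coupling values")
        if (self.s_c < 0).any() or (self.s_d < 0).any():
            raise ValidationError("negative coupling values")


def normalized_laplacian(connectome: Connectome) -> np.ndarray:
    """``L = I - D^{-1/2} A D^{-1/2}`` with D the diagonal of row sums.

    Isolated (zero-degree) nodes are a hard error: dropping them would shift
    node alignment across subjects.
    """
    a = connectome.weights
    deg = a.sum(axis=1)
    dead = np.where(deg <= 0)[0]
    if dead.size:
        names = [connectome.node_ids[i] for i in dead[:5]]
        raise IsolatedNodeError(f"isolated node(s) with zero degree: {names}")
    dinv = 1.0 / np.sqrt(deg)
    lap = -a * dinv[:, None] * dinv[None, :]
    np.fill_diagonal(lap, 1.0)
    return 0.5 * (lap + lap.T)


def _fix_signs(u: np.ndarray) -> np.ndarray:
    """First component of each column exceeding SIGN_TOL in magnitude is positive."""
    u = u.copy()
    for k in range(u.shape[1]):
        col = u[:, k]
        idx = np.flatnonzero(np.abs(col) > SIGN_TOL)
        if idx.size and col[idx[0]] < 0:
            u[:, k] = -col
    return u


def decompose(laplacian: np.ndarray) -> GraphSpectrum:
    """Full symmetric eigendecomposition with ascending eigenvalues."""
    lap = np.asarray(laplacian, dtype=float)
    if lap.ndim != 2 or lap.shape[0] != lap.shape[1]:
        raise ValidationError("Laplacian must be square")
    if np.abs(lap - lap.T).max() > 1e-8:
        raise ValidationError("Laplacian not symmetric")
    lam, u = scipy.linalg.eigh(lap)
    lam = np.clip(lam, 0.0, 2.0)  # round-off guard at the spectral bounds
    return GraphSpectrum(lam, _fix_signs(u), lap)


def graph_fourier_transform(spectrum: GraphSpectrum, bold: ParcellatedBold) -> SpectralBold:
    """Project each TR onto the graph harmonics: coefficients = Uᵀ X."""
    if bold.data.shape[0] != spectrum.n_nodes:
        raise ValidationError(
            f"{bold.data.shape[0]} signal nodes vs {spectrum.n_nodes} graph nodes"
        )
    coeff = spectrum.eigenvectors.T @ bold.data
    esd = (coeff**2).mean(axis=1)
    return SpectralBold(coeff, esd)


def median_energy_split(spectral: SpectralBold) -> int:
    """Smallest C with cumulative ESD over modes < C reaching half the total.

    Clipped into [1, N-1] (with a warning at the top end) so that neither
    filter band is ever empty.
    """
    esd = spectral.esd
    total = esd.sum()
    if total <= 0:
        raise ValidationError("zero total spectral energy")
    c = int(np.searchsorted(np.cumsum(esd), total / 2.0) + 1)
    n = esd.shape[0]
    if c > n - 1:
        warnings.warn(
            "all spectral energy below the split; clipping C to N-1 so the "
            "high band is non-empty",
            RuntimeWarning,
            stacklevel=2,
        )
        c = n - 1
    return max(c, 1)


def filter_signals(spectrum: GraphSpectrum, spectral: SpectralBold,
                   bold: ParcellatedBold) -> tuple:
    """Ideal low-/high-pass graph filtering via band projectors.

    Returns ``(coupled, decoupled)`` node x TR matrices with
    ``coupled + decoupled == X`` (the projectors are orthogonal complements).
    """
    c = spectral.split_index
    if c is None:
        raise ValidationError("split_index unset; run median_energy_split first")
    u = spectrum.eigenvectors
    coeff = spectral.coefficients
    if coeff.shape[0] != u.shape[0] or bold.data.shape != coeff.shape[:1] + coeff.shape[1:]:
        raise ValidationError("inconsistent shapes for filtering")
    coupled = u[:, :c] @ coeff[:c]
    decoupled = u[:, c:] @ coeff[c:]
    return coupled, decoupled


def coupling_profile(coupled: np.ndarray, decoupled: np.ndarray,
                     normalize: str = "per_tr",
                     node_ids: tuple | None = None) -> CouplingProfile:
    """Temporal L2 norm of each node's filtered signal.

    With ``normalize='per_tr'`` (default) norms are divided by sqrt(TRs),
    making values comparable across scan lengths.
    """
    if coupled.shape != decoupled.shape:
        raise ValidationError("coupled/decoupled shape mismatch")
    if normalize not in ("none", "per_tr"):
        raise ValidationError(f"unknown normalization {normalize!r}")
    s_c = np.linalg.norm(coupled, axis=1)
    s_d = np.linalg.norm(decoupled, axis=1)
    if normalize == "per_tr":
        root_t = np.sqrt(coupled.shape[1])
        s_c, s_d = s_c / root_t, s_d / root_t
    if node_ids is None:
        node_ids = tuple(range(coupled.shape[0]))
    return CouplingProfile(tuple(node_ids), s_c, s_d)


def subject_coupling(connectome: Connectome, bold: ParcellatedBold,
                     normalize: str = "per_tr",
                     split_index: int | None = None) -> CouplingProfile:
    """Full per-subject chain: Laplacian -> spectrum -> GFT -> split -> filter -> norms.

    ``split_index`` overrides the per-subject median split (used for the
    cohort-mean-ESD split mode).
    """
    if connectome.node_ids != bold.node_ids:
        raise ValidationError("connectome/timeseries node ids differ")
    spectrum = decompose(normalized_laplacian(connectome))
    spectral = graph_fourier_transform(spectrum, bold)
    c = split_index if split_index is not None else median_energy_split(spectral)
    spectral = replace(spectral, split_index=c)
    coupled, decoupled = filter_signals(spectrum, spectral, bold)
    logger.info(
        "coupling: N=%d C=%d total_energy=%.6g",
        spectrum.n_nodes, c, float(spectral.esd.sum()),
    )
    return coupling_profile(coupled, decoupled, normalize, connectome.node_ids)


def group_mean_split(spectral_runs) -> int:
    """Split index from the cohort-average energy spectral density."""
    esds = np.stack([s.esd for s in spectral_runs])
    return median_energy_split(SpectralBold(np.zeros((esds.shape[1], 1)), esds.mean(axis=0)))
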