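"""Eigenvalue computation and empirical spectral distribution diagnostics."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .criteria import SpectralPrediction
from .errors import NumericalError, ParameterError
from .rmt import JacobianMatrix

__all__ = ["EigenSummary", "eigen_summary", "disk_coverage", "eigenvalues_to_csv"]


@dataclass
class EigenSummary:
    """Full spectrum of a community matrix plus the stability verdict.

    Local asymptotic stability holds iff the largest real part among the
    eigenvalues is negative.
    """

    eigenvalues: np.ndarray
    leading_real: float
    stable: bool


def eigen_summary(J: JacobianMatrix | np.ndarray) -> EigenSummary:
    """Compute the full spectrum and the leading real part.

    Uses a dense non-symmetric eigensolver: the whole empirical spectral
    distribution is itself an output, so there is nothing to gain from an
    iterative leading-eigenvalue shortcut at the matrix sizes involved
    (nS up to a few thousand).
    """
    matrix = J.matrix if isinstance(J, JacobianMatrix) else np.asarray(J, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ParameterError(f"expected a square matrix, got shape {matrix.shape}")
    if not np.all(np.isfinite(matrix)):
        raise NumericalError("matrix contains non-finite entries")
    eigs = np.linalg.eigvals(matrix)
    leading = float(np.max(eigs.real))
    return EigenSummary(eigenvalues=eigs, leading_real=leading, stable=leading < 0)


def disk_coverage(
    eigs: np.ndarray | EigenSummary,
    prediction: SpectralPrediction,
    inflation: float = 0.0,
) -> float:
    """Fraction of eigenvalues lying inside at least one predicted disk.

    ``inflation`` expands every radius multiplicatively (0.05 = 5%), to
    absorb the finite-size spill of the asymptotic circle law.
    """
    if inflation < 0:
        raise ParameterError(f"inflation must be >= 0, got {inflation}")
    values = eigs.eigenvalues if isinstance(eigs, EigenSummary) else np.asarray(eigs)
    if values.size == 0:
        raise ParameterError("empty spectrum")
    inside = np.zeros(values.shape, dtype=bool)
    for disk in prediction.disks:
        inside |= np.abs(values - disk.centre) <= disk.radius * (1.0 + inflation)
    return float(np.mean(inside))


def eigenvalues_to_csv(eigs: np.ndarray | EigenSummary, path: str | Path) -> None:
    """Dump a spectrum as two-column CSV (real, imaginary) for plotting."""
    values = eigs.eigenvalues if isinstance(eigs, EigenSummary) else np.asarray(eigs)
    with open(path, "w") as fh:
        fh.write("real,imag\n")
        for v in np.atleast_1d(values):
            fh.write(f"{v.real:.12g},{v.imag:.12g}\n")
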