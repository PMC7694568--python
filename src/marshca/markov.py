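"""Class-transition matrices: estimation, annualization, area projection.

The Markov half of the CA-Markov model.  A :class:`TransitionMatrix` holds
row-stochastic probabilities ``P[i -> j]`` for a stated step in years; it can
be estimated from a pair of dated maps by cross-tabulation, converted to a
shorter step by the k-th matrix root (eigendecomposition, clip, renormalize),
and used to project class areas forward.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .raster_io import LandscapeGrid, check_compatible

log = logging.getLogger(__name__)

ROW_SUM_TOL = 1e-9

__all__ = ["TransitionMatrix", "estimate_transitions", "annualize", "project_areas"]


@dataclass
class TransitionMatrix:
    """Row-stochastic class-transition probabilities over ``step_years``.

    ``probs[i, j]`` is the probability that a cell of ``class_codes[i]``
    is ``class_codes[j]`` one step later.  Rows that sum to slightly less
    than one on input (printed round-off, e.g. a row summing to 0.9999)
    are renormalized with a warning; rows off by more than 1 % raise.
    """

    probs: np.ndarray
    class_codes: list[int]
    step_years: float = 1.0
    residual: float | None = None  # k-th-root reconstruction residual, if annualized

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        k = len(self.class_codes)
        if self.probs.shape != (k, k):
            raise ValueError(f"probs must be {k}x{k}, got {self.probs.shape}")
        if self.step_years <= 0:
            raise ValueError("step_years must be positive")
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise ValueError("transition probabilities must lie in [0, 1]")
        self.probs = np.clip(self.probs, 0.0, 1.0)
        sums = self.probs.sum(axis=1)
        off = np.abs(sums - 1.0)
        if np.any(off > 0.01):
            bad = [self.class_codes[i] for i in np.nonzero(off > 0.01)[0]]
            raise ValueError(f"rows for classes {bad} do not sum to 1 (sums={sums})")
        if np.any(off > ROW_SUM_TOL):
            log.warning("renormalizing rows with printed round-off (sums=%s)", sums)
            self.probs = self.probs / sums[:, None]

    @property
    def k(self) -> int:
        return len(self.class_codes)

    def row(self, code: int) -> np.ndarray:
        return self.probs[self.class_codes.index(code)]

    def to_frame(self, names: dict[int, str] | None = None) -> pd.DataFrame:
        labels = [names.get(c, str(c)) if names else str(c) for c in self.class_codes]
        return pd.DataFrame(self.probs, index=labels, columns=labels)

    def to_csv(self, path: str | Path, names: dict[int, str] | None = None) -> None:
        self.to_frame(names).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path, class_codes: list[int] | None = None,
                 step_years: float = 1.0) -> "TransitionMatrix":
        df = pd.read_csv(path, index_col=0)
        if class_codes is None:
            try:
                class_codes = [int(c) for c in df.index]
            except ValueError as exc:
                raise ValueError(
                    "matrix CSV uses class names; pass class_codes explicitly"
                ) from exc
        return cls(probs=df.to_numpy(float), class_codes=list(class_codes),
                   step_years=step_years)


def estimate_transitions(
    grid_a: LandscapeGrid,
    grid_b: LandscapeGrid,
    dynamic_codes: list[int] | None = None,
) -> TransitionMatrix:
    """Cross-tabulate two dated maps into a transition-probability matrix.

    ``P[i -> j]`` is the fraction of cells of class *i* at the first date
    that are class *j* at the second, counted over cells that are dynamic
    at BOTH dates.  Classes with no source cells get an identity row so the
    matrix stays well-defined on sparse maps.  ``step_years`` is the date
    difference.
    """
    check_compatible(grid_a, grid_b)
    if grid_b.date <= grid_a.date:
        raise ValueError(f"grid_b.date ({grid_b.date}) must exceed grid_a.date ({grid_a.date})")
    codes = list(dynamic_codes) if dynamic_codes is not None else grid_a.scheme.dynamic_codes
    k = len(codes)
    lut = {c: i for i, c in enumerate(codes)}

    a, b = grid_a.values, grid_b.values
    mask = np.isin(a, codes) & np.isin(b, codes)
    if not mask.any():
        raise ValueError("no cells are dynamic at both dates")
    ai = np.vectorize(lut.get, otypes=[np.int64])(a[mask])
    bi = np.vectorize(lut.get, otypes=[np.int64])(b[mask])
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (ai, bi), 1)

    probs = np.eye(k)
    row_tot = counts.sum(axis=1)
    nz = row_tot > 0
    probs[nz] = counts[nz] / row_tot[nz, None]
    return TransitionMatrix(probs=probs, class_codes=codes,
                            step_years=float(grid_b.date - grid_a.date))


def annualize(matrix: TransitionMatrix, target_step: float = 1.0) -> TransitionMatrix:
    """Convert a k-year-step matrix to ``target_step`` via the k-th matrix root.

    Takes the principal eigenvalue root, discards small imaginary parts,
    clips negative entries to zero and renormalizes rows — the standard
    regularization for transition matrices that are not exactly embeddable.
    The Frobenius reconstruction residual ``||A^k - P||_F`` is stored on the
    result (0 means the root is exact) and logged rather than hidden.
    """
    ratio = matrix.step_years / target_step
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-9:
        raise ValueError(
            f"step_years / target_step must be a positive integer, got {ratio}")
    if k == 1:
        return TransitionMatrix(matrix.probs.copy(), list(matrix.class_codes),
                                step_years=target_step, residual=0.0)

    P = matrix.probs
    w, V = np.linalg.eig(P)
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1e12:
        raise np.linalg.LinAlgError(
            f"transition matrix is not diagonalizable within tolerance (cond={cond:.3g})")
    root = V @ np.diag(w.astype(complex) ** (1.0 / k)) @ np.linalg.inv(V)
    imag_mag = float(np.abs(root.imag).max())
    if imag_mag > 1e-6:
        raise np.linalg.LinAlgError(
            f"matrix root has imaginary magnitude {imag_mag:.3g} above tolerance; "
            "the matrix is not embeddable at this step")
    A = np.clip(root.real, 0.0, None)
    A = A / A.sum(axis=1, keepdims=True)
    residual = float(np.linalg.norm(np.linalg.matrix_power(A, k) - P, "fro"))
    log.info("annualize: k=%d, reconstruction residual %.3g", k, residual)
    return TransitionMatrix(probs=A, class_codes=list(matrix.class_codes),
                            step_years=target_step, residual=residual)


def project_areas(
    areas: dict[int, float],
    matrix: TransitionMatrix,
    n_steps: int = 1,
) -> dict[int, float]:
    """Project class areas ``n_steps`` steps forward: ``a <- a . P`` repeated.

    Total area is conserved exactly because P is row-stochastic.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    if set(areas) != set(matrix.class_codes):
        raise ValueError(
            f"area keys {sorted(areas)} != matrix classes {sorted(matrix.class_codes)}")
    vec = np.array([areas[c] for c in matrix.class_codes], dtype=float)
    if np.any(vec < 0):
        raise ValueError("areas must be non-negative")
    P = matrix.probs / matrix.probs.sum(axis=1, keepdims=True)
    out = vec @ np.linalg.matrix_power(P, n_steps)
    return dict(zip(matrix.class_codes, out.tolist()))
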