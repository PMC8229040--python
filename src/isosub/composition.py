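"""Aitchison-geometry primitives for behaviour compositions.

A day of waking time splits exhaustively into sitting, standing and
stepping, so the three durations carry only relative information once the
waking total is fixed.  This module provides the simplex operations the
substitution models are built on: closure, isometric log-ratio (ILR)
transforms defined by a sequential binary partition (SBP), compositional
means, and the minute-reallocation perturbation.

All coordinate machinery is written for generic ``D``-part compositions;
the :class:`BehaviourComposition` wrapper fixes the 3-part
sit/stand/step case used throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

#: Canonical part order used everywhere in the package.
PARTS: tuple[str, str, str] = ("sit", "stand", "step")

_PART_INDEX = {name: i for i, name in enumerate(PARTS)}

_CLOSURE_TOL = 1e-9


class CompositionError(ValueError):
    """Invalid compositional input (zeros, malformed partitions, ...)."""


@dataclass(frozen=True)
class BehaviourComposition:
    """Daily minutes of sitting, standing and stepping plus the waking total.

    Parameters
    ----------
    sit_min, stand_min, step_min
        Average daily minutes in each posture; must be non-negative and
        strictly positive wherever log-ratio operations are applied.
    total_min
        Waking wear minutes.  Must equal the sum of the three parts
        (the behaviours partition waking time exhaustively).
    """

    sit_min: float
    stand_min: float
    step_min: float
    total_min: float

    def __post_init__(self) -> None:
        parts = (self.sit_min, self.stand_min, self.step_min)
        if any(p < 0 for p in parts):
            raise CompositionError(f"behaviour minutes must be non-negative, got {parts}")
        if abs(sum(parts) - self.total_min) > 1e-6:
            raise CompositionError(
                f"parts sum to {sum(parts):.6f} but total_min={self.total_min:.6f}"
            )

    @classmethod
    def from_parts(cls, parts: Sequence[float]) -> "BehaviourComposition":
        parts = [float(p) for p in parts]
        return cls(parts[0], parts[1], parts[2], sum(parts))

    def as_array(self) -> np.ndarray:
        return np.array([self.sit_min, self.stand_min, self.step_min], dtype=float)

    def __getitem__(self, part: str) -> float:
        return float(self.as_array()[_PART_INDEX[part]])


@dataclass(frozen=True)
class ILRBasis:
    """Orthonormal log-contrast basis derived from a sequential binary partition.

    ``sbp`` is a ``D x (D-1)`` sign matrix: column ``k`` assigns each part to
    the numerator (+1) or denominator (-1) group of balance ``k``, or leaves
    it out (0).  ``contrast_matrix`` holds the resulting ``(D-1) x D``
    orthonormal log-contrast coefficients (Egozcue balances).
    """

    sbp: np.ndarray
    contrast_matrix: np.ndarray
    basis_id: str

    @property
    def n_parts(self) -> int:
        return self.contrast_matrix.shape[1]

    def __eq__(self, other: object) -> bool:  # arrays defeat dataclass eq
        if not isinstance(other, ILRBasis):
            return NotImplemented
        return self.basis_id == other.basis_id and np.array_equal(
            self.contrast_matrix, other.contrast_matrix
        )

    def __hash__(self) -> int:
        return hash(self.basis_id)


@dataclass(frozen=True)
class ILRCoordinates:
    """ILR coordinates of a composition under a particular basis."""

    z: np.ndarray
    basis_id: str


def close_composition(parts: Iterable[float], kappa: float = 1.0) -> np.ndarray:
    """Rescale non-negative parts to sum to ``kappa`` (compositional closure)."""
    parts = np.asarray(list(parts) if not isinstance(parts, np.ndarray) else parts, dtype=float)
    if parts.ndim != 1 or parts.size < 2:
        raise CompositionError("closure needs a 1-d vector of at least 2 parts")
    if np.any(parts < 0):
        raise CompositionError("parts must be non-negative")
    total = parts.sum()
    if total <= 0:
        raise CompositionError("cannot close an all-zero composition")
    if kappa <= 0:
        raise CompositionError("closure constant must be positive")
    return parts * (kappa / total)


def build_ilr_basis(sbp: np.ndarray, basis_id: str | None = None) -> ILRBasis:
    """Construct orthonormal ILR balances from a sequential binary partition.

    For a balance with ``r`` numerator parts and ``s`` denominator parts the
    contrast row carries ``+sqrt(s / (r (r + s)))`` on numerator parts and
    ``-sqrt(r / (s (r + s)))`` on denominator parts.  Orthonormality of the
    resulting rows is verified and certifies that ``sbp`` is a valid
    sequential partition.
    """
    sbp = np.asarray(sbp, dtype=float)
    if sbp.ndim != 2:
        raise CompositionError("sbp must be a 2-d sign matrix")
    D, K = sbp.shape
    if K != D - 1:
        raise CompositionError(f"sbp must be D x (D-1); got {D} x {K}")
    if not np.all(np.isin(sbp, (-1.0, 0.0, 1.0))):
        raise CompositionError("sbp entries must be -1, 0 or +1")

    rows = np.zeros((K, D))
    for k in range(K):
        plus = sbp[:, k] > 0
        minus = sbp[:, k] < 0
        r, s = int(plus.sum()), int(minus.sum())
        if r == 0 or s == 0:
            raise CompositionError(
                f"sbp column {k} must have both a +1 and a -1 group (got r={r}, s={s})"
            )
        rows[k, plus] = np.sqrt(s / (r * (r + s)))
        rows[k, minus] = -np.sqrt(r / (s * (r + s)))

    gram = rows @ rows.T
    if not np.allclose(gram, np.eye(K), atol=1e-10):
        raise CompositionError("sbp is not a valid sequential binary partition (rows not orthonormal)")
    if basis_id is None:
        basis_id = "sbp:" + ";".join(
            "".join({1.0: "+", -1.0: "-", 0.0: "0"}[v] for v in sbp[:, k]) for k in range(K)
        )
    return ILRBasis(sbp=sbp, contrast_matrix=rows, basis_id=basis_id)


def default_basis() -> ILRBasis:
    """Pivot basis for (sit, stand, step): sit vs {stand, step}, then stand vs step."""
    sbp = np.array([[1, 0], [-1, 1], [-1, -1]], dtype=float)
    return build_ilr_basis(sbp, basis_id="pivot-sit-stand-step")


def _parts_array(comp: "BehaviourComposition | np.ndarray | Sequence[float]") -> np.ndarray:
    if isinstance(comp, BehaviourComposition):
        return comp.as_array()
    return np.asarray(comp, dtype=float)


def ilr_transform(comp, basis: ILRBasis | None = None) -> ILRCoordinates:
    """Map a strictly positive composition to its ILR coordinates.

    The result is invariant to the closure constant: any rescaling of the
    parts cancels because each contrast row sums to zero.
    """
    basis = basis or default_basis()
    x = _parts_array(comp)
    if x.ndim == 1:
        x = x[None, :]
        squeeze = True
    else:
        squeeze = False
    if x.shape[-1] != basis.n_parts:
        raise CompositionError(f"expected {basis.n_parts} parts, got {x.shape[-1]}")
    if np.any(x <= 0):
        raise CompositionError(
            "zero or negative part in composition; log-ratios are undefined. "
            "Apply a zero-replacement policy (e.g. multiplicative replacement "
            "with a small detection-limit delta) before transforming."
        )
    z = np.log(x) @ basis.contrast_matrix.T
    if squeeze:
        z = z[0]
    return ILRCoordinates(z=z, basis_id=basis.basis_id)


def inverse_ilr(z, basis: ILRBasis | None = None, kappa: float = 1.0) -> np.ndarray:
    """Map ILR coordinates back to a composition closed to ``kappa``."""
    basis = basis or default_basis()
    if isinstance(z, ILRCoordinates):
        z = z.z
    z = np.asarray(z, dtype=float)
    logx = z @ basis.contrast_matrix
    x = np.exp(logx - logx.max(axis=-1, keepdims=True))  # overflow guard
    if x.ndim == 1:
        return close_composition(x, kappa)
    return x * (kappa / x.sum(axis=-1, keepdims=True))


def reallocate(
    comp: BehaviourComposition, from_part: str, to_part: str, minutes: float
) -> BehaviourComposition:
    """Move ``minutes`` from one behaviour to another, holding the total fixed.

    The donor part must retain strictly positive time so downstream
    log-ratio operations stay defined.
    """
    if from_part not in _PART_INDEX or to_part not in _PART_INDEX:
        raise CompositionError(f"unknown behaviour part; expected one of {PARTS}")
    if from_part == to_part:
        raise CompositionError("from_part and to_part must differ")
    if minutes < 0:
        raise CompositionError("reallocated minutes must be non-negative")
    available = comp[from_part]
    if minutes >= available:
        raise CompositionError(
            f"cannot move {minutes:g} min out of '{from_part}': only "
            f"{available:g} min available and the part must stay positive"
        )
    parts = comp.as_array()
    parts[_PART_INDEX[from_part]] -= minutes
    parts[_PART_INDEX[to_part]] += minutes
    return BehaviourComposition(parts[0], parts[1], parts[2], comp.total_min)


def mean_composition(
    rows: Sequence[BehaviourComposition], method: str = "geometric"
) -> BehaviourComposition:
    """Average a set of behaviour compositions.

    ``geometric`` (the compositional convention) takes per-part geometric
    means and closes them to the mean waking total; ``arithmetic`` takes
    plain per-part means, which is how cohort descriptive tables are
    usually reported.
    """
    if len(rows) == 0:
        raise CompositionError("mean_composition needs at least one composition")
    mat = np.array([r.as_array() for r in rows], dtype=float)
    mean_total = float(np.mean([r.total_min for r in rows]))
    if method == "arithmetic":
        parts = mat.mean(axis=0)
    elif method == "geometric":
        if np.any(mat <= 0):
            raise CompositionError("geometric mean requires strictly positive parts")
        parts = close_composition(np.exp(np.log(mat).mean(axis=0)), kappa=mean_total)
    else:
        raise ValueError(f"unknown mean method {method!r}; use 'geometric' or 'arithmetic'")
    return BehaviourComposition(parts[0], parts[1], parts[2], float(parts.sum()))


def multiplicative_zero_replacement(parts: np.ndarray, delta: float = 1.0) -> np.ndarray:
    """Replace zero parts with ``delta`` minutes, shrinking positive parts to keep the total.

    Standard multiplicative replacement: zeros become ``delta`` and the
    non-zero parts are scaled down proportionally so each row's sum is
    preserved.
    """
    parts = np.asarray(parts, dtype=float)
    out = parts.copy()
    single = out.ndim == 1
    if single:
        out = out[None, :]
    for row in out:
        zeros = row == 0
        if zeros.any():
            total = row.sum()
            replaced = delta * zeros.sum()
            if replaced >= total:
                raise CompositionError("zero-replacement delta exceeds the row total")
            row[~zeros] *= (total - replaced) / total
            row[zeros] = delta
    return out[0] if single else out
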