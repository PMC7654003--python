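"""Growth-stage weight vectors: IAHP, entropy weighting and their combination.

Three routes to a 5-element stage weight vector:

* **IAHP** (improved analytic hierarchy process) — subjective.  A three-scale
  (0/1/2) pairwise comparison matrix of stage importance is condensed into
  per-stage importance totals, expanded into a consistent judgment matrix,
  and the principal eigenvector of the resulting quasi-optimal matrix gives
  the weights.  No consistency test is needed: the quasi-optimal matrix is
  multiplicatively consistent by construction.
* **EW** (entropy weighting) — objective.  Column weights proportional to
  one minus the Shannon entropy of each stage column's share distribution in
  a plot x stage data matrix.
* **OCW** (optimal combination weighting) — a convex combination of the two.
  The distance objective it formally optimizes is constant along the segment
  between the two input vectors, so the combination coefficient alpha is an
  explicit convention (default 0.7 on the subjective side);
  :func:`calibrate_alpha` recovers alpha from a published combined vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .growth import STAGES

__all__ = [
    "DEFAULT_COMPARISON",
    "WeightVector",
    "WeightAudit",
    "validate_comparison_matrix",
    "iahp_weights",
    "entropy_weights",
    "ocw_weights",
    "calibrate_alpha",
    "read_comparison_csv",
]

#: Default three-scale stage comparison matrix (stage order SS, TFS, TES,
#: SAS, HS), encoding the agronomic importance ranking
#: TES > SAS > TFS > HS > SS: 2 = row stage more important than column
#: stage, 1 = equally important, 0 = less important.
DEFAULT_COMPARISON = np.array(
    [
        [1, 0, 0, 0, 0],
        [2, 1, 0, 0, 2],
        [2, 2, 1, 2, 2],
        [2, 2, 0, 1, 2],
        [2, 0, 0, 0, 1],
    ],
    dtype=float,
)


@dataclass(frozen=True)
class WeightVector:
    """A nonnegative stage weight vector summing to 1, tagged by method."""

    w: np.ndarray
    method: str = ""

    def __post_init__(self):
        w = np.asarray(self.w, dtype=float).reshape(-1)
        if np.any(w < -1e-12):
            raise ValidationError(f"negative weights: {w}")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError(f"weights must sum to 1, got {w.sum()!r}")
        object.__setattr__(self, "w", np.clip(w, 0.0, None))

    def __len__(self):
        return self.w.size

    def as_series(self, labels=STAGES) -> pd.Series:
        return pd.Series(self.w, index=list(labels[: len(self.w)]), name=self.method)


@dataclass
class WeightAudit:
    """Intermediate quantities of a weight computation, for reporting.

    IAHP fills ``r`` (importance totals), ``kappa`` (scale ratio
    r_max/r_min), ``B`` (judgment matrix), ``C`` (log-transfer matrix) and
    ``Cstar`` (quasi-optimal matrix).  EW fills ``e`` (entropies) and ``d``
    (difference coefficients).  OCW fills ``alpha`` and ``R_objective``.
    """

    r: np.ndarray | None = None
    kappa: float | None = None
    B: np.ndarray | None = None
    C: np.ndarray | None = None
    Cstar: np.ndarray | None = None
    e: np.ndarray | None = None
    d: np.ndarray | None = None
    alpha: float | None = None
    R_objective: float | None = None
    notes: list = field(default_factory=list)


def validate_comparison_matrix(A) -> np.ndarray:
    """Validate a three-scale comparison matrix: square, entries in {0,1,2},
    unit diagonal, complementary off-diagonal (a_ij + a_ji = 2)."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError("comparison matrix must be square")
    if not np.isin(A, (0.0, 1.0, 2.0)).all():
        raise ValidationError("comparison matrix entries must be in {0, 1, 2}")
    if not np.all(np.diag(A) == 1.0):
        raise ValidationError("comparison matrix diagonal must be all 1")
    if not np.allclose(A + A.T, 2.0):
        raise ValidationError("comparison matrix must satisfy a_ij + a_ji = 2")
    return A


def iahp_weights(A=DEFAULT_COMPARISON, tol: float = 1e-12) -> tuple[WeightVector, WeightAudit]:
    """Improved-AHP stage weights from a three-scale comparison matrix.

    Importance totals are the ROW sums of A.  The judgment matrix B stretches
    total differences onto the ratio scale [1/kappa, kappa] with
    kappa = r_max/r_min; the quasi-optimal matrix ``Cstar = 10**C`` with
    ``C_ij = mean_t log10(b_it / b_jt)`` is multiplicatively consistent, and
    its normalized principal eigenvector (power iteration to ``tol``) is the
    weight vector.
    """
    A = validate_comparison_matrix(A)
    n = A.shape[0]
    r = A.sum(axis=1)
    audit = WeightAudit(r=r)
    if r.max() == r.min():
        warnings.warn("all stages equally important; kappa undefined, returning uniform weights")
        audit.notes.append("uniform fallback: r_max == r_min")
        return WeightVector(np.full(n, 1.0 / n), method="IAHP"), audit
    kappa = r.max() / r.min()
    diff = (r[:, None] - r[None, :]) / (r.max() - r.min()) * (kappa - 1.0)
    B = np.where(r[:, None] >= r[None, :], diff + 1.0, 1.0 / (np.abs(diff) + 1.0))
    C = np.log10(B[:, None, :] / B[None, :, :]).mean(axis=2)
    Cstar = 10.0 ** C
    w = np.full(n, 1.0 / n)
    for _ in range(1000):
        w_next = Cstar @ w
        w_next /= w_next.sum()
        if np.abs(w_next - w).max() < tol:
            w = w_next
            break
        w = w_next
    audit.kappa = float(kappa)
    audit.B, audit.C, audit.Cstar = B, C, Cstar
    return WeightVector(w, method="IAHP"), audit


def entropy_weights(G, normalization: str = "minmax_shift",
                    eps: float = 1e-6) -> tuple[WeightVector, WeightAudit]:
    """Entropy-method column weights for a plots x stages data matrix.

    Each column is turned into a share distribution ``p_ij = g_ij / sum_i
    g_ij``; its entropy ``e_j = -(1/ln n) sum_i p_ij ln p_ij`` (with
    0 ln 0 := 0) gives difference coefficients ``d_j = (1 - e_j) /
    (m - sum e)`` which normalize to the weights.  Relativized variables can
    be negative, so the default normalization min-max rescales each column
    to [eps, 1] first; ``normalization="none"`` requires nonnegative data.
    """
    if isinstance(G, pd.DataFrame):
        G = G.to_numpy(dtype=float)
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] < 2:
        raise ValidationError("data matrix must be 2-D with at least 2 plots")
    if not np.isfinite(G).all():
        raise ValidationError("data matrix has missing or non-finite cells")
    n, m = G.shape
    audit = WeightAudit()
    if normalization == "minmax_shift":
        lo, hi = G.min(axis=0), G.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        G = eps + (1.0 - eps) * (G - lo) / span
        G = np.where(hi[None, :] > lo[None, :], G, 1.0)  # constant columns -> uniform shares
    elif normalization == "none":
        if np.any(G < 0):
            raise ValidationError(
                "negative entries with normalization='none'; use normalization='minmax_shift'"
            )
    else:
        raise ValidationError(f"unknown normalization {normalization!r}")
    colsum = G.sum(axis=0)
    if np.any(colsum <= 0):
        raise ValidationError("each column must have positive sum after normalization")
    P = G / colsum
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    e = -plogp.sum(axis=0) / np.log(n)
    audit.e = e
    if abs(m - e.sum()) < 1e-12:
        warnings.warn("all columns perfectly uniform; returning uniform weights")
        audit.notes.append("uniform fallback: sum of entropies equals column count")
        audit.d = np.zeros(m)
        return WeightVector(np.full(m, 1.0 / m), method="EW"), audit
    d = (1.0 - e) / (m - e.sum())
    audit.d = d
    return WeightVector(d / d.sum(), method="EW"), audit


def _distance_objective(w, vectors):
    """Sum over input vectors of (1 - RMS distance to w)."""
    total = 0.0
    for wm in vectors:
        total += 1.0 - np.sqrt(np.mean((w - wm) ** 2))
    return float(total)


def ocw_weights(W1: WeightVector, W2: WeightVector,
                alpha: float = 0.7) -> tuple[WeightVector, WeightAudit]:
    """Combination weights ``W = alpha*W1 + (1-alpha)*W2``.

    The distance objective ``R = sum_m (1 - sqrt(mean_j (w_j - w_j^m)^2))``
    is constant on the whole segment between W1 and W2, so alpha (subjective
    share, default 0.7) is an explicit convention rather than a solver
    output; the audit records alpha and the attained objective value.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValidationError(f"alpha must be in [0, 1], got {alpha!r}")
    w1, w2 = W1.w, W2.w
    if w1.size != w2.size:
        raise ValidationError("weight vectors must have equal length")
    w = alpha * w1 + (1.0 - alpha) * w2
    audit = WeightAudit(alpha=float(alpha),
                        R_objective=_distance_objective(w, (w1, w2)))
    return WeightVector(w, method="OCW"), audit


def calibrate_alpha(W1: WeightVector, W2: WeightVector, W_combined: WeightVector) -> float:
    """Recover the combination coefficient from a published combined vector.

    Least-squares projection of ``W_combined - W2`` onto ``W1 - W2``,
    clipped to [0, 1].  Raises if W1 == W2 (alpha unidentifiable).
    """
    d = W1.w - W2.w
    denom = float(d @ d)
    if denom == 0.0:
        raise ValidationError("W1 equals W2; combination coefficient is unidentifiable")
    alpha = float((W_combined.w - W2.w) @ d / denom)
    return min(max(alpha, 0.0), 1.0)


def read_comparison_csv(path) -> np.ndarray:
    """Read a 5x5 three-scale comparison matrix from a headerless CSV."""
    A = pd.read_csv(path, header=None).to_numpy(dtype=float)
    return validate_comparison_matrix(A)
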