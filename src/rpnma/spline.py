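"""Restricted cubic spline (RCS) bases of log time.

The baseline log cumulative hazard of each trial is modelled as an RCS in
ln(t): piecewise cubic, continuous with continuous first and second
derivatives, and constrained to be linear beyond the boundary knots.  With
interior knots k_1 < ... < k_p and boundary knots k_min < k_max the raw basis
is

    column 0:  x  (= ln t)
    column j:  v_j(x) = (x-k_j)_+^3 - lam_j (x-k_min)_+^3
                         - (1-lam_j)(x-k_max)_+^3,
               lam_j = (k_max - k_j) / (k_max - k_min)

For numerical conditioning the basis (with a prepended intercept) is
orthogonalised by Gram-Schmidt, realised as a QR factorisation with the
intercept first; the invertible transform is recorded so that fits are
invariant to the change of basis and so that new time points (and analytic
derivatives) can be mapped into the same orthogonal coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KnotSet", "SplineBasis", "place_knots", "rcs_raw", "rcs_raw_deriv", "orthogonalise"]


class SingularBasisError(np.linalg.LinAlgError):
    """Raised when the spline design matrix is rank deficient over the sample."""


@dataclass(frozen=True)
class KnotSet:
    """Interior and boundary knots on the ln(time) scale."""

    interior: tuple[float, ...]
    boundary_min: float
    boundary_max: float

    def __post_init__(self):
        ks = (self.boundary_min, *self.interior, self.boundary_max)
        if not all(a < b for a, b in zip(ks, ks[1:])):
            raise ValueError(
                f"knots must be strictly increasing within the boundaries, got {ks}"
            )

    @property
    def p(self) -> int:
        return len(self.interior)

    @classmethod
    def from_times(cls, interior, boundary_min, boundary_max) -> "KnotSet":
        """Build from knots given on the original time scale."""
        return cls(
            tuple(np.log(np.asarray(interior, dtype=float))),
            float(np.log(boundary_min)),
            float(np.log(boundary_max)),
        )


_CENTILES = {0: (), 1: (50.0,), 2: (33.0, 67.0), 3: (25.0, 50.0, 75.0)}


def place_knots(trial_data, n_interior: int = 2, custom=None) -> KnotSet:
    """Place knots for one trial's RCS.

    Boundary knots sit at the minimum and maximum uncensored ln survival
    times.  Interior knots default to centiles of the uncensored ln times
    (1 knot: 50; 2 knots: 33/67; 3 knots: 25/50/75), computed as empirical
    quantiles with linear interpolation.  ``custom`` (ln scale) overrides the
    defaults and is validated to lie strictly inside the boundaries.

    ``trial_data`` is an :class:`~rpnma.ipd.IPDDataset` restricted to one
    trial, or anything with ``time`` and ``event`` columns in a ``df``
    attribute / DataFrame.
    """
    df = getattr(trial_data, "df", trial_data)
    times = np.asarray(df["time"], dtype=float)
    events = np.asarray(df["event"], dtype=int)
    lnt = np.log(times[events == 1])
    distinct = np.unique(lnt)
    if n_interior not in _CENTILES:
        raise ValueError(f"n_interior must be 0..3, got {n_interior}")
    if distinct.size < n_interior + 2:
        raise ValueError(
            f"need >= {n_interior + 2} distinct uncensored ln times for "
            f"{n_interior} interior knots, have {distinct.size}"
        )
    bmin, bmax = float(distinct[0]), float(distinct[-1])
    if custom is not None:
        interior = tuple(float(k) for k in custom)
        if len(set(interior)) != len(interior):
            raise ValueError(f"duplicate custom knots: {interior}")
        for k in interior:
            if not bmin < k < bmax:
                raise ValueError(
                    f"custom knot {k} outside the open boundary interval ({bmin}, {bmax})"
                )
        interior = tuple(sorted(interior))
    else:
        interior = tuple(
            float(np.percentile(lnt, c, method="linear")) for c in _CENTILES[n_interior]
        )
        if len(set(interior)) != len(interior):
            raise ValueError(
                f"default centile knots coincide ({interior}); supply custom knots"
            )
    return KnotSet(interior, bmin, bmax)


def rcs_raw(ln_times, knots: KnotSet) -> np.ndarray:
    """Raw RCS basis: columns [x, v_1(x), ..., v_p(x)] without intercept."""
    x = np.asarray(ln_times, dtype=float)
    cols = [x]
    kmin, kmax = knots.boundary_min, knots.boundary_max
    span = kmax - kmin
    for kj in knots.interior:
        lam = (kmax - kj) / span
        cols.append(
            np.clip(x - kj, 0.0, None) ** 3
            - lam * np.clip(x - kmin, 0.0, None) ** 3
            - (1.0 - lam) * np.clip(x - kmax, 0.0, None) ** 3
        )
    return np.column_stack(cols)


def rcs_raw_deriv(ln_times, knots: KnotSet) -> np.ndarray:
    """d/dx of the raw basis columns: [1, dv_1(x), ..., dv_p(x)]."""
    x = np.asarray(ln_times, dtype=float)
    cols = [np.ones_like(x)]
    kmin, kmax = knots.boundary_min, knots.boundary_max
    span = kmax - kmin
    for kj in knots.interior:
        lam = (kmax - kj) / span
        cols.append(
            3.0 * np.clip(x - kj, 0.0, None) ** 2
            - 3.0 * lam * np.clip(x - kmin, 0.0, None) ** 2
            - 3.0 * (1.0 - lam) * np.clip(x - kmax, 0.0, None) ** 2
        )
    return np.column_stack(cols)


@dataclass(frozen=True)
class SplineBasis:
    """An orthogonalised RCS basis over a construction sample.

    Attributes
    ----------
    knots : KnotSet
    raw : (n, p+1) raw basis over the construction sample
    ortho : (n, p+1) orthogonalised columns u_0..u_p
    ortho_deriv : (n, p+1) analytic derivatives du_0..du_p w.r.t. ln t
    transform : (p+2, p+2) invertible map with [1, raw] @ transform = [1, ortho]
    """

    knots: KnotSet
    raw: np.ndarray
    ortho: np.ndarray
    ortho_deriv: np.ndarray
    transform: np.ndarray

    @property
    def n_coef(self) -> int:
        """Number of spline coefficients gamma_1..gamma_{p+2} (incl. intercept)."""
        return self.transform.shape[0]

    def design(self) -> np.ndarray:
        """[1, ortho] over the construction sample — the gamma design matrix."""
        return np.column_stack([np.ones(len(self.ortho)), self.ortho])

    def design_deriv(self) -> np.ndarray:
        """Derivative of the gamma design: zero intercept column + ortho_deriv."""
        return np.column_stack([np.zeros(len(self.ortho_deriv)), self.ortho_deriv])

    def evaluate(self, ln_times) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate [1, ortho] and its ln-t derivative at new points."""
        x = np.atleast_1d(np.asarray(ln_times, dtype=float))
        raw1 = np.column_stack([np.ones_like(x), rcs_raw(x, self.knots)])
        basis = raw1 @ self.transform
        deriv = np.column_stack(
            [np.zeros_like(x), rcs_raw_deriv(x, self.knots) @ self.transform[1:, 1:]]
        )
        return basis, deriv

    def to_raw_coef(self, gamma_ortho: np.ndarray) -> np.ndarray:
        """Map coefficients on [1, ortho] to coefficients on [1, raw]."""
        return self.transform @ np.asarray(gamma_ortho, dtype=float)

    def from_raw_coef(self, gamma_raw: np.ndarray) -> np.ndarray:
        return np.linalg.solve(self.transform, np.asarray(gamma_raw, dtype=float))


def orthogonalise(ln_times, knots: KnotSet) -> SplineBasis:
    """Construct the orthogonalised basis over a construction sample.

    Gram-Schmidt with the intercept first, realised by QR; the intercept
    column of the result is rescaled back to exactly 1 and every other column
    is signed so its inner product with its raw source column is positive
    (removes the sign ambiguity of QR for reproducibility).
    """
    x = np.asarray(ln_times, dtype=float)
    raw = rcs_raw(x, knots)
    n, p1 = raw.shape
    A = np.column_stack([np.ones(n), raw])
    Q, R = np.linalg.qr(A)
    diag = np.abs(np.diag(R))
    if np.any(diag < 1e-10 * max(1.0, diag.max())):
        raise SingularBasisError(
            "spline basis is rank deficient over the sample (times too few or tied)"
        )
    transform = np.linalg.inv(R)  # A @ transform = Q, columns orthonormal
    # rescale intercept column back to exactly 1
    transform[:, 0] = 0.0
    transform[0, 0] = 1.0
    ortho_full = A @ transform
    # sign convention: positive inner product with the raw source column
    for j in range(1, p1 + 1):
        s = ortho_full[:, j] @ raw[:, j - 1]
        if s < 0:
            transform[:, j] *= -1.0
            ortho_full[:, j] *= -1.0
    ortho = ortho_full[:, 1:]
    ortho_deriv = rcs_raw_deriv(x, knots) @ transform[1:, 1:]
    return SplineBasis(knots=knots, raw=raw, ortho=ortho, ortho_deriv=ortho_deriv,
                       transform=transform)
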