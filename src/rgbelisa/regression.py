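"""Calibration-curve regression models.

Three model families relate the RGBscore y to the analyte concentration x:

* linear        y = a*x + b                       (ordinary least squares)
* logarithmic   y = a*ln(x + b) + c, b > 0        (b profiled: for fixed b the
                                                   problem is linear; a grid
                                                   scan over b is refined by
                                                   golden-section search)
* logistic4     y = a / (1 + b*exp(-c*x)) + d     (four-parameter logistic,
                                                   Levenberg-Marquardt with a
                                                   fixed iteration budget and
                                                   analytic initialization)

Every fitter is written over a batch of response vectors sharing one x grid:
``fit_model`` is the single-series front end (batch of one) and the
brute-force coefficient search calls the same batched routines, so a naive
per-triple enumeration and the vectorized search produce identical floats.

Degenerate responses (zero variance) are assigned R^2 = 0 by convention
rather than an undefined value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MODEL_KINDS = ("linear", "logarithmic", "logistic4")

#: iteration budget for the logistic4 Levenberg-Marquardt refinement
LOGISTIC_MAX_ITER = 100

#: b-profile settings for the logarithmic model
_LOG_GRID_POINTS = 49
_LOG_GOLDEN_ITER = 48


@dataclass
class RegressionFit:
    """A fitted calibration model; unused parameters are fixed at 0."""

    kind: str
    a: float
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0
    r_squared: float = 0.0
    converged: bool = True

    @property
    def params(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)

    def predict(self, x) -> np.ndarray:
        """Forward-evaluate the model at concentrations ``x``."""
        x = np.asarray(x, dtype=np.float64)
        if self.kind == "linear":
            return self.a * x + self.b
        if self.kind == "logarithmic":
            return self.a * np.log(x + self.b) + self.c
        if self.kind == "logistic4":
            z = np.clip(-self.c * x, -500.0, 500.0)
            return self.a / (1.0 + self.b * np.exp(z)) + self.d
        raise ValueError(f"unknown model kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "d": self.d,
            "r_squared": self.r_squared,
            "converged": self.converged,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionFit":
        return cls(
            kind=d["kind"], a=d["a"], b=d["b"], c=d["c"], d=d["d"],
            r_squared=d["r_squared"], converged=d.get("converged", True),
        )


def r_squared(y_obs, y_fit) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot.

    Returns 0 when the observations have zero variance (degenerate series).
    """
    y_obs = np.asarray(y_obs, dtype=np.float64)
    y_fit = np.asarray(y_fit, dtype=np.float64)
    if y_obs.shape != y_fit.shape:
        raise ValueError("y_obs and y_fit must have the same length")
    if y_obs.ndim != 1 or y_obs.size < 2:
        raise ValueError("need at least two paired observations")
    sse, sst = _sse_sst(y_obs[None, :], y_fit[None, :])
    return float(_r2(sse, sst, y_obs[None, :])[0])


# ---------------------------------------------------------------------------
# batched internals (Y has shape (N, L); x has shape (L,))

def _sse_sst(Y: np.ndarray, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sse = ((Y - F) ** 2).sum(axis=-1)
    ybar = Y.mean(axis=-1, keepdims=True)
    sst = ((Y - ybar) ** 2).sum(axis=-1)
    return sse, sst


def _degenerate(sst: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Zero-variance detection with a scale-aware floor (summing identical
    floats need not produce an exactly-zero centered sum)."""
    scale = np.maximum(1.0, np.abs(Y).max(axis=-1))
    return sst <= Y.shape[-1] * (1e-10 * scale) ** 2


def _r2(sse: np.ndarray, sst: np.ndarray, Y: np.ndarray) -> np.ndarray:
    degen = _degenerate(sst, Y)
    safe = np.where(degen, 1.0, sst)
    out = 1.0 - sse / safe
    return np.where(degen, 0.0, out)


def _fit_linear_batch(x: np.ndarray, Y: np.ndarray):
    """OLS line fit per batch row; returns (a, b, r2)."""
    xbar = x.mean()
    xc = x - xbar
    sxx = float(xc @ xc)
    ybar = Y.mean(axis=-1)
    a = (Y @ xc) / sxx
    b = ybar - a * xbar
    F = a[:, None] * x[None, :] + b[:, None]
    sse, sst = _sse_sst(Y, F)
    degen = _degenerate(sst, Y)
    a = np.where(degen, 0.0, a)
    b = np.where(degen, ybar, b)
    r2 = _r2(np.where(degen, 0.0, sse), sst, Y)
    return a, b, r2


def _log_profile_sse(x: np.ndarray, Yc: np.ndarray, sstY: np.ndarray, b: np.ndarray):
    """Residual SS of regressing each (centered) row of Y on ln(x + b).

    ``b`` may be scalar (shared) or per-row.  For fixed b the slope has the
    closed form a = <Yc, tc>/<tc, tc> and SSE = SST - a^2 <tc, tc>.
    """
    b = np.asarray(b, dtype=np.float64)
    if b.ndim == 0:
        t = np.log(x + b)
        tc = t - t.mean()
        stt = float(tc @ tc)
        a = (Yc @ tc) / max(stt, 1e-300)
    else:
        t = np.log(x[None, :] + b[:, None])
        tc = t - t.mean(axis=-1, keepdims=True)
        stt = (tc * tc).sum(axis=-1)
        a = (Yc * tc).sum(axis=-1) / np.maximum(stt, 1e-300)
    sse = sstY - a * a * stt
    return np.maximum(sse, 0.0), a


def _fit_log_batch(x: np.ndarray, Y: np.ndarray):
    """Profiled logarithmic fit per batch row; returns (a, b, c, r2).

    The offset b is scanned on a fixed geometric grid spanning tiny offsets
    (sharp curvature near x = 0) to offsets far beyond max(x) (where
    ln(x + b) is nearly affine), then refined per row by golden-section
    search on ln(b) inside the bracketing grid interval.
    """
    n = Y.shape[0]
    xmax = float(x.max())
    b_lo = 1e-6 * max(1.0, xmax)
    b_hi = 1e4 * (xmax + 1.0)
    grid = np.geomspace(b_lo, b_hi, _LOG_GRID_POINTS)

    ybar = Y.mean(axis=-1)
    Yc = Y - ybar[:, None]
    sstY = (Yc * Yc).sum(axis=-1)

    best_sse = np.full(n, np.inf)
    best_idx = np.zeros(n, dtype=int)
    for i, b in enumerate(grid):
        sse, _ = _log_profile_sse(x, Yc, sstY, np.float64(b))
        better = sse < best_sse
        best_sse = np.where(better, sse, best_sse)
        best_idx = np.where(better, i, best_idx)

    log_grid = np.log(grid)
    lo = log_grid[np.maximum(best_idx - 1, 0)]
    hi = log_grid[np.minimum(best_idx + 1, len(grid) - 1)]
    phi = (np.sqrt(5.0) - 1.0) / 2.0
    for _ in range(_LOG_GOLDEN_ITER):
        u1 = hi - phi * (hi - lo)
        u2 = lo + phi * (hi - lo)
        f1, _ = _log_profile_sse(x, Yc, sstY, np.exp(u1))
        f2, _ = _log_profile_sse(x, Yc, sstY, np.exp(u2))
        keep_low = f1 < f2
        hi = np.where(keep_low, u2, hi)
        lo = np.where(keep_low, lo, u1)

    b = np.exp((lo + hi) / 2.0)
    sse, a = _log_profile_sse(x, Yc, sstY, b)
    t = np.log(x[None, :] + b[:, None])
    c = ybar - a * t.mean(axis=-1)
    degen = _degenerate(sstY, Y)
    a = np.where(degen, 0.0, a)
    b = np.where(degen, 1.0, b)
    c = np.where(degen, ybar, c)
    r2 = _r2(np.where(degen, 0.0, sse), sstY, Y)
    return a, b, c, r2


def _logistic_forward(x: np.ndarray, a, b, c, d) -> np.ndarray:
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        z = np.clip(-np.asarray(c)[:, None] * x[None, :], -500.0, 500.0)
        return np.asarray(a)[:, None] / (1.0 + np.asarray(b)[:, None] * np.exp(z)) + np.asarray(d)[:, None]


def _fit_logistic_batch(x: np.ndarray, Y: np.ndarray, max_iter: int = LOGISTIC_MAX_ITER):
    """Batched Levenberg-Marquardt 4PL fit; returns (a, b, c, d, r2, converged).

    Initialization: d ~ min y (max y for decreasing series), a ~ signed
    range, c ~ 4/x-span (a transition spanning the data), inflection placed
    at the half-range crossing.  A fixed iteration budget with per-row
    damping keeps the routine deterministic; rows that end with non-finite
    parameters are flagged converged = False with an R^2 of -inf.
    """
    n, L = Y.shape
    ymin = Y.min(axis=-1)
    ymax = Y.max(axis=-1)
    yrange = ymax - ymin
    xbar = x.mean()
    increasing = (Y @ (x - xbar)) >= 0.0

    d0 = np.where(increasing, ymin, ymax)
    a0 = np.where(increasing, yrange, -yrange)
    xspan = float(x.max() - x.min())
    c0 = np.full(n, 4.0 / max(xspan, 1e-12))
    mid = (ymin + ymax) / 2.0
    half_idx = np.abs(Y - mid[:, None]).argmin(axis=-1)
    x_half = x[half_idx]
    b0 = np.exp(np.clip(c0 * x_half, -500.0, 500.0))

    ybar = Y.mean(axis=-1)
    sst = ((Y - ybar[:, None]) ** 2).sum(axis=-1)
    degen = _degenerate(sst, Y)

    P = np.column_stack([a0, b0, c0, d0])
    lam = np.full(n, 1e-3)

    def sse_of(P):
        F = _logistic_forward(x, P[:, 0], P[:, 1], P[:, 2], P[:, 3])
        s = ((Y - F) ** 2).sum(axis=-1)
        return np.where(np.isfinite(s), s, np.inf)

    sse = sse_of(P)
    eye = np.eye(4)
    for _ in range(max_iter):
        a, b, c, d = P[:, 0], P[:, 1], P[:, 2], P[:, 3]
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            z = np.clip(-c[:, None] * x[None, :], -500.0, 500.0)
            E = np.exp(z)
            D = 1.0 + b[:, None] * E
            D = np.where(np.abs(D) < 1e-300, 1e-300, D)
            F = a[:, None] / D + d[:, None]
            r = Y - F
            J = np.empty((n, L, 4))
            J[:, :, 0] = 1.0 / D
            J[:, :, 1] = -a[:, None] * E / (D * D)
            J[:, :, 2] = a[:, None] * b[:, None] * x[None, :] * E / (D * D)
            J[:, :, 3] = 1.0
        J = np.where(np.isfinite(J), J, 0.0)
        r = np.where(np.isfinite(r), r, 0.0)
        g = np.einsum("nli,nl->ni", J, r)
        H = np.einsum("nli,nlj->nij", J, J)
        diag = np.maximum(np.einsum("nii->ni", H), 1e-12)
        Haug = H + (lam[:, None] * diag)[:, :, None] * eye[None, :, :]
        try:
            step = np.linalg.solve(Haug, g[:, :, None])[:, :, 0]
        except np.linalg.LinAlgError:
            Haug = Haug + 1e-8 * eye[None, :, :]
            step = np.linalg.solve(Haug, g[:, :, None])[:, :, 0]
        Pnew = P + step
        sse_new = sse_of(Pnew)
        accept = sse_new < sse
        P = np.where(accept[:, None], Pnew, P)
        sse = np.where(accept, sse_new, sse)
        lam = np.clip(np.where(accept, lam / 3.0, lam * 5.0), 1e-12, 1e12)

    a, b, c, d = P[:, 0], P[:, 1], P[:, 2], P[:, 3]
    # canonicalize to c >= 0: a/(1+b e^{-cx}) == -a/(1+(1/b) e^{cx}) + a
    flip = (c < 0.0) & (b > 0.0)
    a, b, c, d = (
        np.where(flip, -a, a),
        np.where(flip, 1.0 / b, b),
        np.where(flip, -c, c),
        np.where(flip, a + d, d),
    )
    ok = (
        np.isfinite(P).all(axis=-1)
        & np.isfinite(sse)
        & np.isfinite(a) & np.isfinite(b) & np.isfinite(c) & np.isfinite(d)
    )
    r2 = _r2(sse, sst, Y)
    r2 = np.where(ok, r2, -np.inf)
    a = np.where(degen, 0.0, a)
    b = np.where(degen, 1.0, b)
    c = np.where(degen, 1.0, c)
    d = np.where(degen, ybar, d)
    r2 = np.where(degen, 0.0, r2)
    ok = ok | degen
    return a, b, c, d, r2, ok


def _validate_xy(x, y, min_points: int, min_distinct: int):
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("x and y must be finite")
    if x.size < min_points:
        raise ValueError(f"need at least {min_points} points, got {x.size}")
    if np.unique(x).size < min_distinct:
        raise ValueError(f"need at least {min_distinct} distinct x values")
    return x, y


def fit_model(kind: str, x, y) -> RegressionFit:
    """Fit one regression model to (concentration, score) pairs."""
    if kind == "linear":
        x, y = _validate_xy(x, y, 2, 2)
        a, b, r2 = _fit_linear_batch(x, y[None, :])
        return RegressionFit("linear", float(a[0]), float(b[0]), r_squared=float(r2[0]))
    if kind == "logarithmic":
        x, y = _validate_xy(x, y, 3, 3)
        if (x < 0).any():
            raise ValueError("logarithmic model requires x >= 0")
        a, b, c, r2 = _fit_log_batch(x, y[None, :])
        return RegressionFit(
            "logarithmic", float(a[0]), float(b[0]), float(c[0]), r_squared=float(r2[0])
        )
    if kind == "logistic4":
        x, y = _validate_xy(x, y, 4, 4)
        a, b, c, d, r2, ok = _fit_logistic_batch(x, y[None, :])
        return RegressionFit(
            "logistic4", float(a[0]), float(b[0]), float(c[0]), float(d[0]),
            r_squared=float(r2[0]), converged=bool(ok[0]),
        )
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


def fit_batch(kind: str, x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """R^2 of ``kind`` fitted independently to every row of Y (shared x)."""
    if kind == "linear":
        return _fit_linear_batch(x, Y)[2]
    if kind == "logarithmic":
        return _fit_log_batch(x, Y)[3]
    if kind == "logistic4":
        return _fit_logistic_batch(x, Y)[4]
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
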