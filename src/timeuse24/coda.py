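"""Compositional geometry for 24-h time-use data.

A day of time use is a composition: four mutually exclusive, exhaustive
behaviours — sleep, sedentary time, light physical activity (LPA) and
moderate-to-vigorous physical activity (MVPA) — that together fill the
1440 minutes of the day.  Only relative information is meaningful, so all
analysis happens on the simplex after *closure* (rescaling to the fixed
total) and is mapped to unconstrained real space with isometric log-ratio
(ilr) coordinates built from a sequential binary partition.

The ilr used here is the pivot ("one versus the geometric mean of the
rest") partition.  For an ordered 4-part composition (x1, x2, x3, x4):

    z1 = sqrt(3/4) * ln( x1 / (x2*x3*x4)^(1/3) )
    z2 = sqrt(2/3) * ln( x2 / (x3*x4)^(1/2) )
    z3 = sqrt(1/2) * ln( x3 / x4 )

Four cyclic rotations of the part order put each behaviour in the leading
pivot position, so that each model's first ilr coordinate carries the
"this behaviour relative to all remaining behaviours" contrast.

All functions accept either a single composition (shape ``(4,)``) or a
stack of compositions (shape ``(n, 4)``) and preserve the input shape.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm

#: canonical part order of a 24-h time-use composition
PARTS: tuple[str, ...] = ("sleep", "sedentary", "lpa", "mvpa")

#: minutes in a 24-h day, the closure total
DAY_MINUTES: float = 1440.0

#: number of pivot rotations (one per part)
N_ROTATIONS: int = len(PARTS)


def rotation_order(rotation: int) -> tuple[int, ...]:
    """Part indices in pivot order for a cyclic rotation.

    Rotation ``r`` puts part ``r`` first: rotation 0 is
    (sleep, sedentary, lpa, mvpa), rotation 1 is
    (sedentary, lpa, mvpa, sleep), and so on.
    """
    d = len(PARTS)
    return tuple((rotation + i) % d for i in range(d))


def rotation_label(rotation: int) -> str:
    """Name of the behaviour in the leading pivot position."""
    return PARTS[rotation % N_ROTATIONS]


def _as_parts(parts) -> np.ndarray:
    x = np.asarray(parts, dtype=float)
    if x.shape[-1] != len(PARTS):
        raise ValueError(
            f"expected {len(PARTS)}-part compositions, got shape {x.shape}"
        )
    return x


def close_composition(parts, total: float = DAY_MINUTES) -> np.ndarray:
    """Rescale positive parts so each composition sums to ``total``.

    Raises ``ValueError`` on non-positive parts: zeros must be replaced
    first (see :func:`replace_zeros`).
    """
    x = _as_parts(parts)
    if np.any(x <= 0):
        raise ValueError("closure requires strictly positive parts; "
                         "replace zeros first")
    s = x.sum(axis=-1, keepdims=True)
    return x * (total / s)


def proportional_impute_nonwear(parts, nonwear_min,
                                total: float = DAY_MINUTES) -> np.ndarray:
    """Redistribute non-wear time proportionally over the behaviour parts.

    A day with ``nonwear_min`` minutes of monitor non-wear has only
    ``total - nonwear_min`` minutes of observed behaviour; the observed
    parts are scaled by ``total / (total - nonwear_min)`` so the
    behaviours again fill the whole day.  Zeros are permitted (a zero
    stays zero).
    """
    x = _as_parts(parts)
    nw = np.asarray(nonwear_min, dtype=float)
    if np.any(nw < 0) or np.any(nw >= total):
        raise ValueError("non-wear must be in [0, total) minutes")
    scale = total / (total - nw)
    return x * np.expand_dims(scale, -1) if x.ndim > nw.ndim else x * scale


def compositional_mean(compositions, total: float = DAY_MINUTES) -> np.ndarray:
    """Centre of a compositional sample.

    The per-part geometric mean across observations, closed back to
    ``total``.  This is the compositional analogue of the arithmetic
    mean and is the reference point for reallocation modelling.
    """
    x = _as_parts(compositions)
    if x.ndim != 2:
        raise ValueError("expected a stack of compositions, shape (n, 4)")
    if np.any(x <= 0):
        raise ValueError("compositional mean requires positive parts")
    g = np.exp(np.mean(np.log(x), axis=0))
    return close_composition(g, total)


def pivot_basis(d: int) -> np.ndarray:
    """Orthonormal sequential-binary-partition contrast matrix (d x d-1).

    Column ``j`` contrasts part ``j`` against the geometric mean of parts
    ``j+1 .. d-1``.  Columns are orthonormal and each sums to zero, so
    ``z = V.T @ log(x)`` is scale-invariant and an isometry.
    """
    V = np.zeros((d, d - 1))
    for j in range(d - 1):
        r = d - j - 1
        c = np.sqrt(r / (r + 1.0))
        V[j, j] = c
        V[j + 1:, j] = -c / r
    return V


_V4 = pivot_basis(len(PARTS))


def ilr_transform(parts, rotation: int = 0) -> np.ndarray:
    """Map compositions to three pivot ilr coordinates.

    ``rotation`` selects which behaviour leads the partition (see
    :func:`rotation_order`); the leading coordinate is then that
    behaviour's log-ratio against the geometric mean of the rest.
    """
    x = _as_parts(parts)
    if np.any(x <= 0):
        raise ValueError("ilr requires strictly positive parts")
    order = list(rotation_order(rotation))
    return np.log(x[..., order]) @ _V4


def ilr_inverse(z, rotation: int = 0, total: float = DAY_MINUTES) -> np.ndarray:
    """Unique positive composition (closed to ``total``) with ilr ``z``."""
    z = np.asarray(z, dtype=float)
    if z.shape[-1] != len(PARTS) - 1:
        raise ValueError("expected 3 ilr coordinates per composition")
    clr = z @ _V4.T
    x = np.exp(clr - clr.max(axis=-1, keepdims=True))  # overflow guard
    order = list(rotation_order(rotation))
    inv = np.empty_like(x)
    inv[..., order] = x
    return close_composition(inv, total)


def aitchison_distance(a, b) -> np.ndarray:
    """Aitchison distance between compositions (norm of clr difference)."""
    xa, xb = _as_parts(a), _as_parts(b)
    la, lb = np.log(xa), np.log(xb)
    da = la - la.mean(axis=-1, keepdims=True)
    db = lb - lb.mean(axis=-1, keepdims=True)
    return np.linalg.norm(da - db, axis=-1)


# ---------------------------------------------------------------------------
# zero replacement

def _censored_lognormal_em(logs_obs: np.ndarray, log_dl: float,
                           n_censored: int, max_iter: int = 200,
                           tol: float = 1e-10) -> float:
    """EM for a lognormal left-censored at the detection limit.

    Fits (mu, sigma) on the log scale treating the censored observations
    as below ``log_dl``, and returns the conditional expectation
    E[log X | log X < log_dl] under the fitted parameters.  Because the
    conditional mean of a truncated normal lies below its truncation
    point, the imputed value is guaranteed below the detection limit.
    """
    mu = logs_obs.mean()
    sd = max(logs_obs.std(ddof=0), 1e-3)
    n_obs = logs_obs.size
    n = n_obs + n_censored
    for _ in range(max_iter):
        a = (log_dl - mu) / sd
        lam = norm.pdf(a) / max(norm.cdf(a), 1e-300)  # inverse Mills ratio
        e1 = mu - sd * lam                     # E[Z | Z < log_dl]
        var_c = sd**2 * (1.0 - lam * (lam - a))
        e2 = var_c + e1**2                     # E[Z^2 | Z < log_dl]
        mu_new = (logs_obs.sum() + n_censored * e1) / n
        s2_new = ((np.sum(logs_obs**2) + n_censored * e2) / n) - mu_new**2
        sd_new = np.sqrt(max(s2_new, 1e-12))
        if abs(mu_new - mu) < tol and abs(sd_new - sd) < tol:
            mu, sd = mu_new, sd_new
            break
        mu, sd = mu_new, sd_new
    a = (log_dl - mu) / sd
    lam = norm.pdf(a) / max(norm.cdf(a), 1e-300)
    return mu - sd * lam


def replace_zeros(compositions, part: str | int = "mvpa",
                  method: str = "em", detection_limit: float | None = None,
                  delta_fraction: float = 0.65,
                  total: float = DAY_MINUTES) -> np.ndarray:
    """Replace zeros in one part with small positive values.

    Zeros (typically in MVPA: some participants record no
    moderate-to-vigorous activity at all) cannot be log-transformed.
    They are imputed below a detection limit — by default the smallest
    observed positive value of the part — and the non-zero parts of each
    affected composition are scaled down multiplicatively so it still
    sums to ``total``.

    Parameters
    ----------
    method : {"em", "multiplicative"}
        ``"em"`` fits a left-censored lognormal to the part by
        expectation-maximisation and imputes the conditional expectation
        below the detection limit.  ``"multiplicative"`` imputes the
        fixed fraction ``delta_fraction`` of the detection limit
        (simple multiplicative replacement).
    """
    x = _as_parts(compositions).copy()
    if x.ndim != 2:
        raise ValueError("expected a stack of compositions, shape (n, 4)")
    j = PARTS.index(part) if isinstance(part, str) else int(part)
    col = x[:, j]
    zeros = col == 0
    if not zeros.any():
        return x
    pos = col[col > 0]
    if pos.size == 0:
        raise ValueError(f"part {PARTS[j]!r} is zero in every composition; "
                         "cannot impute")
    dl = float(detection_limit) if detection_limit is not None else float(pos.min())
    if method == "em":
        imputed = float(np.exp(_censored_lognormal_em(
            np.log(pos), np.log(dl), int(zeros.sum()))))
    elif method == "multiplicative":
        imputed = delta_fraction * dl
    else:
        raise ValueError(f"unknown zero-replacement method {method!r}")
    imputed = min(imputed, np.nextafter(dl, 0.0))
    # shrink the remaining parts so each amended row still sums to `total`
    rows = np.where(zeros)[0]
    for i in rows:
        others = x[i].sum()  # the zero contributed nothing
        x[i] *= (total - imputed) / others
        x[i, j] = imputed
    return x
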