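"""Worm-like chain (flexible cylinder) SAXS modelling and fitting, plus a
Debye-sum theoretical profile from bead coordinates.

The chain form factor follows the Pedersen-Schurtenberger treatment of
semi-flexible, self-avoiding chains ("method 3" with excluded-volume
corrections): an excluded-volume chain scattering function at low q that
crosses over to local-rod scattering (pi/(qL) leading term) at high q.
The two power-law coefficients of the rod regime are fixed by requiring
continuity of the scattering function and of its first derivative at the
crossover, so the model is smooth in both q and the parameters.  The
cross-section is a homogeneous circular cylinder, [2 J1(x)/x]^2 with
x = q * r_cs, optionally averaged over a Gaussian radius distribution.

Model parameters: contour length L_c, Kuhn length L_k (twice the
persistence length), cross-section radius r_cs, optional Gaussian
dispersity of r_cs, scale and flat background.  q in 1/nm, lengths in nm.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.special import j1, sici

# excluded-volume chain constants (Pedersen-Schurtenberger fits to
# off-lattice simulations of self-avoiding semi-flexible chains)
_NU = 0.585
_C1, _C2, _C3 = 1.22, 0.4288, -1.651
_W_CENTER, _W_WIDTH = 1.523, 0.1477
# rod-regime power-law exponents; long vs short chain branches
_P_LONG = (4.12, 4.42)
_P_SHORT = (5.36, 5.476)
_NB_LONG = 4.0


@dataclass
class WLCParams:
    contour_length: float          # L_c, nm
    kuhn_length: float             # L_k, nm
    radius: float                  # r_cs, nm
    dispersity: float = 0.0        # Gaussian sd of r_cs, nm
    scale: float = 1.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.contour_length <= 0 or self.kuhn_length <= 0 or self.radius <= 0:
            raise ValueError("all lengths must be positive")
        if self.dispersity < 0:
            raise ValueError("dispersity must be non-negative")


@dataclass
class SAXSProfile:
    q: np.ndarray          # 1/nm, strictly ascending
    intensity: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be positive and strictly increasing")
        if np.any(self.sigma < 0):
            raise ValueError("sigma must be non-negative")


# ---------------------------------------------------------------------------
# chain scattering function
# ---------------------------------------------------------------------------

def _rg2(contour: float, kuhn: float) -> float:
    """Radius of gyration^2 of a Kratky-Porod chain with excluded-volume
    expansion.  Exact KP result times the PS expansion factor alpha^2."""
    n = contour / kuhn
    alpha2 = (1.0 + (n / 3.12) ** 2 + (n / 8.67) ** 3) ** (0.176 / 3.0)
    if n > 1e-4:
        f = 1.0 - 3.0 / (2 * n) + 3.0 / (2 * n**2) - (3.0 / (4 * n**3)) * (
            1.0 - np.exp(-2 * n)
        )
    else:  # rod limit, series in n
        f = n / 2.0 - n**2 / 5.0
    return alpha2 * (contour * kuhn / 6.0) * f


def _s_debye(u2: np.ndarray) -> np.ndarray:
    """Debye coil function of u^2 = (q Rg)^2, series-safe at zero."""
    u2 = np.asarray(u2, dtype=float)
    small = u2 < 1e-6
    with np.errstate(over="ignore"):
        out = np.where(
            small,
            1.0 - u2 / 3.0,
            2.0 * (np.exp(-np.clip(u2, None, 700)) + u2 - 1.0) / np.maximum(u2, 1e-300) ** 2,
        )
    return out


def _s_exv(q: np.ndarray, rg: float) -> np.ndarray:
    """Excluded-volume chain scattering: Debye at low qRg, the
    three-term power expansion in (qRg)^(-1/nu) beyond, blended by a
    tanh crossover."""
    x = q * rg
    w = 0.5 * (1.0 + np.tanh((x - _W_CENTER) / _W_WIDTH))
    # below x ~ 1 the weight underflows slower than the power tail grows;
    # the blend is pure Debye there anyway
    w = np.where(x < 1.0, 0.0, w)
    with np.errstate(divide="ignore"):
        xs = np.maximum(x, 1e-12)
        tail = (
            _C1 * xs ** (-1.0 / _NU)
            + _C2 * xs ** (-2.0 / _NU)
            + _C3 * xs ** (-3.0 / _NU)
        )
    return (1.0 - w) * _s_debye(x**2) + w * np.where(x < 1.0, 0.0, tail)


def _rod_correction(u: np.ndarray) -> np.ndarray:
    """Local-stiffness correction term; ~u^2/2 at small u, 4/15 + 7/(15u^2)
    asymptotically."""
    u = np.asarray(u, dtype=float)
    u2 = u**2
    small = u2 < 1e-4
    with np.errstate(divide="ignore", over="ignore"):
        full = (
            4.0 / 15.0
            + 7.0 / (15.0 * np.maximum(u2, 1e-300))
            - (11.0 / 15.0 + 7.0 / (15.0 * np.maximum(u2, 1e-300)))
            * np.exp(-np.clip(u2, None, 700))
        )
    return np.where(small, u2 / 2.0 - 13.0 * u2**2 / 45.0, full)


def _s_lowq(q: np.ndarray, contour: float, kuhn: float, rg: float) -> np.ndarray:
    n_b = contour / kuhn
    c = 3.06 * n_b ** (-0.44) if n_b > 10.0 else 1.0
    return _s_exv(q, rg) + (c / n_b) * _rod_correction(q * rg)


def wlc_chain_factor(q, contour_length: float, kuhn_length: float) -> np.ndarray:
    """Dimensionless chain scattering function S(q); S(0) = 1.

    Below the crossover q_c = max(3.1/L_k, 1.9/Rg) the excluded-volume
    chain expression applies; above it the local-rod form
    a1 (q L_k)^-p1 + a2 (q L_k)^-p2 + pi/(q L_c), with a1, a2 fixed by
    value/derivative continuity at q_c.
    """
    if contour_length <= 0 or kuhn_length <= 0:
        raise ValueError("lengths must be positive")
    q = np.atleast_1d(np.asarray(q, dtype=float))
    rg = np.sqrt(_rg2(contour_length, kuhn_length))
    n_b = contour_length / kuhn_length
    p1, p2 = _P_LONG if n_b >= _NB_LONG else _P_SHORT
    qc = max(3.1 / kuhn_length, 1.9 / rg)

    out = np.empty_like(q)
    low = q <= qc
    out[low] = _s_lowq(q[low], contour_length, kuhn_length, rg)

    if np.any(~low):
        # continuity: match value and slope of (S_lowq - pi/(qL)) at qc
        h = 1e-5 * qc
        qs = np.array([qc - h, qc, qc + h])
        g = _s_lowq(qs, contour_length, kuhn_length, rg) - np.pi / (
            qs * contour_length
        )
        g0 = g[1]
        g1 = (g[2] - g[0]) / (2 * h)
        # A + B = g0 ; -(p1 A + p2 B)/qc = g1, with A = a1 (qc Lk)^-p1 etc.
        bmat = np.array([[1.0, 1.0], [-p1 / qc, -p2 / qc]])
        a_coef, b_coef = np.linalg.solve(bmat, np.array([g0, g1]))
        qq = q[~low]
        out[~low] = (
            a_coef * (qq / qc) ** (-p1)
            + b_coef * (qq / qc) ** (-p2)
            + np.pi / (qq * contour_length)
        )
    return out


# ---------------------------------------------------------------------------
# cross-section
# ---------------------------------------------------------------------------

def cross_section_factor(q, r_cs: float, dispersity: float = 0.0) -> np.ndarray:
    """Circular-cylinder cross-section form factor [2 J1(q r)/(q r)]^2,
    1 at q -> 0, optionally averaged over r ~ N(r_cs, dispersity) by
    15-point Gauss-Hermite quadrature (truncated at r > 0)."""
    if r_cs <= 0:
        raise ValueError("r_cs must be positive")
    q = np.atleast_1d(np.asarray(q, dtype=float))

    def single(radius: float) -> np.ndarray:
        x = q * radius
        out = np.ones_like(x)
        nz = x > 1e-8
        out[nz] = (2.0 * j1(x[nz]) / x[nz]) ** 2
        return out

    if dispersity <= 0:
        return single(r_cs)
    nodes, weights = np.polynomial.hermite_e.hermegauss(15)
    radii = r_cs + dispersity * nodes
    keep = radii > 0
    w = weights[keep] / weights[keep].sum()
    acc = np.zeros_like(q)
    for wi, ri in zip(w, radii[keep]):
        acc += wi * single(ri)
    return acc


def model_intensity(q, params: WLCParams) -> np.ndarray:
    """I(q) = scale * S_chain(q) * S_cs(q) + background."""
    chain = wlc_chain_factor(q, params.contour_length, params.kuhn_length)
    cs = cross_section_factor(q, params.radius, params.dispersity)
    return params.scale * chain * cs + params.background


def rigid_rod_factor(q, length: float) -> np.ndarray:
    """Orientation-averaged thin rigid rod form factor (exact),
    2 Si(qL)/(qL) - 4 sin^2(qL/2)/(qL)^2.  Used as an oracle for the
    rigid limit of the chain model."""
    q = np.atleast_1d(np.asarray(q, dtype=float))
    x = q * length
    si, _ = sici(x)
    out = np.ones_like(x)
    nz = x > 1e-8
    out[nz] = 2.0 * si[nz] / x[nz] - 4.0 * np.sin(x[nz] / 2.0) ** 2 / x[nz] ** 2
    return out


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_PARAM_ORDER = (
    "contour_length",
    "kuhn_length",
    "radius",
    "dispersity",
    "scale",
    "background",
)

_DEFAULT_BOUNDS = {
    "contour_length": (1.0, 1e4),
    "kuhn_length": (0.5, 1e3),
    "radius": (0.1, 50.0),
    "dispersity": (0.0, 5.0),
    "scale": (1e-12, 1e12),
    "background": (-1e6, 1e6),
}


@dataclass
class FitResult:
    params: WLCParams
    stderr: dict[str, float]
    chi2_per_n: float
    success: bool
    at_bounds: list[str]
    message: str


def fit_wlc(
    profile: SAXSProfile,
    initial: WLCParams,
    bounds: dict[str, tuple[float, float]] | None = None,
    fix: tuple[str, ...] = ("dispersity",),
    multi_start: bool = True,
) -> FitResult:
    """Weighted least squares fit of the flexible-cylinder model.

    Minimises sum(((I - model)/sigma)^2); points with sigma = 0 get unit
    weight.  Parameters named in ``fix`` are held at their initial value.
    The cross-section Bessel zeros make the objective multi-modal in
    r_cs, so by default a small deterministic grid of starting radii and
    Kuhn lengths around the initial guess is tried and the best optimum
    kept.  Reports chi^2/N with N the number of points,
    asymptotic-covariance standard errors, and flags parameters that
    ended on a bound (a fit that runs into a bound, e.g. an unresolvable
    contour length, is diagnosed rather than raised).  Non-convergence
    returns a flagged result, not an exception.
    """
    if len(profile.q) < 10:
        raise ValueError("need at least 10 points to fit")
    merged = dict(_DEFAULT_BOUNDS)
    if bounds:
        merged.update(bounds)
    free = [p for p in _PARAM_ORDER if p not in fix]
    x0 = np.array([getattr(initial, p) for p in free])
    lo = np.array([merged[p][0] for p in free])
    hi = np.array([merged[p][1] for p in free])
    x0 = np.clip(x0, lo, hi)
    weights = np.where(profile.sigma > 0, profile.sigma, 1.0)

    def build(x: np.ndarray) -> WLCParams:
        return replace(initial, **dict(zip(free, x)))

    def residuals(x: np.ndarray) -> np.ndarray:
        return (model_intensity(profile.q, build(x)) - profile.intensity) / weights

    starts = [x0]
    if multi_start:
        for r_fac in (0.7, 1.3):
            for k_fac in (0.5, 1.0, 2.0):
                alt = x0.copy()
                for i, p in enumerate(free):
                    if p == "radius":
                        alt[i] = np.clip(x0[i] * r_fac, lo[i], hi[i])
                    elif p == "kuhn_length":
                        alt[i] = np.clip(x0[i] * k_fac, lo[i], hi[i])
                starts.append(alt)

    res = None
    for start in starts:
        try:
            cand = least_squares(
                residuals, start, bounds=(lo, hi), x_scale="jac", method="trf"
            )
        except Exception:
            continue
        if res is None or cand.cost < res.cost:
            res = cand
    if res is None:
        return FitResult(
            params=initial,
            stderr={p: np.nan for p in free},
            chi2_per_n=np.nan,
            success=False,
            at_bounds=[],
            message="fit failed from every start",
        )

    fitted = build(res.x)
    n = len(profile.q)
    chi2_per_n = float(2 * res.cost / n)
    jac = res.jac
    try:
        cov = np.linalg.inv(jac.T @ jac)
        dof = max(n - len(free), 1)
        sigma2 = 2 * res.cost / dof
        stderr = {p: float(np.sqrt(sigma2 * cov[i, i])) for i, p in enumerate(free)}
    except np.linalg.LinAlgError:
        stderr = {p: np.inf for p in free}
    at_bounds = [
        p
        for i, p in enumerate(free)
        if np.isclose(res.x[i], lo[i], rtol=0, atol=1e-8 * max(1, abs(lo[i])))
        or np.isclose(res.x[i], hi[i], rtol=1e-8)
    ]
    return FitResult(
        params=fitted,
        stderr=stderr,
        chi2_per_n=chi2_per_n,
        success=bool(res.success),
        at_bounds=at_bounds,
        message=res.message,
    )


# ---------------------------------------------------------------------------
# Debye sum
# ---------------------------------------------------------------------------

def debye_profile(
    coords_angstrom: np.ndarray,
    form_factors: np.ndarray | float = 1.0,
    q_grid: np.ndarray | None = None,
) -> SAXSProfile:
    """Orientation-averaged scattering of a rigid bead assembly:

        I(q) = sum_ij f_i f_j sinc(q r_ij)

    with the i = j terms equal to f_i^2.  Bead coordinates in Angstrom,
    q in 1/nm (converted internally).  A uniform per-bead form factor is
    the default; no hydration shell or excluded-solvent term is applied,
    so this is a theoretical-profile approximation, not a full
    solution-scattering calculation.
    """
    coords = np.atleast_2d(np.asarray(coords_angstrom, dtype=float))
    if coords.shape[0] < 1:
        raise ValueError("need at least one bead")
    if q_grid is None:
        from .synthetic_data import default_q_grid

        q_grid = default_q_grid()
    q_grid = np.asarray(q_grid, dtype=float)
    f = np.broadcast_to(
        np.asarray(form_factors, dtype=float), (coords.shape[0],)
    ).astype(float)
    r_nm = (
        np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1) / 10.0
    )
    iu, ju = np.triu_indices(coords.shape[0], k=1)
    rij = r_nm[iu, ju]
    fij = f[iu] * f[ju]
    intensity = np.empty_like(q_grid)
    self_term = float((f**2).sum())
    for k, qv in enumerate(q_grid):
        x = qv * rij
        intensity[k] = self_term + 2.0 * float(
            (fij * np.sinc(x / np.pi)).sum()
        )
    return SAXSProfile(q=q_grid, intensity=intensity, sigma=np.zeros_like(q_grid))
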