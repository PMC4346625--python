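"""FRET-ratio computation and biexponential exchange-kinetics fitting.

A mixing assay follows two fibre populations carrying a donor/acceptor
dye pair: as monomers exchange between fibres the dyes co-localise, the
FRET ratio rises, and the approach to the plateau carries the exchange
timescales.  The ratio is modelled as a plateau minus two decaying
deficits,

    F(t) = F_plateau - A_fast exp(-t/tau_fast) - A_slow exp(-t/tau_slow),

with canonical ordering tau_fast <= tau_slow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares


@dataclass
class FRETTrace:
    time: np.ndarray          # s (or h; any single consistent unit)
    i_donor: np.ndarray       # donor-channel intensity (570 nm)
    i_acceptor: np.ndarray    # acceptor-channel intensity (670 nm)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.i_donor = np.asarray(self.i_donor, dtype=float)
        self.i_acceptor = np.asarray(self.i_acceptor, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class BiexpFit:
    f_plateau: float
    a_fast: float
    tau_fast: float
    a_slow: float
    tau_slow: float
    residual_sd: float = 0.0
    stderr: dict | None = None
    success: bool = True
    message: str = ""

    def __post_init__(self) -> None:
        if self.tau_fast <= 0 or self.tau_slow <= 0:
            raise ValueError("timescales must be positive")
        if self.a_fast < 0 or self.a_slow < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.tau_fast > self.tau_slow:
            # canonical ordering: fast component first
            self.a_fast, self.a_slow = self.a_slow, self.a_fast
            self.tau_fast, self.tau_slow = self.tau_slow, self.tau_fast


def biexponential(t: np.ndarray, fit: BiexpFit) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    return (
        fit.f_plateau
        - fit.a_fast * np.exp(-t / fit.tau_fast)
        - fit.a_slow * np.exp(-t / fit.tau_slow)
    )


def fret_ratio(trace: FRETTrace, mode: str = "total") -> np.ma.MaskedArray:
    """FRET ratio per time point.

    ``total`` (default): acceptor / (donor + acceptor), in [0, 1].
    ``acceptor_over_donor``: acceptor / donor.
    Points with zero total (or zero donor) intensity are masked.

    The ratio is invariant under a common rescaling of both channels, so
    instrument gain drops out.
    """
    total = trace.i_donor + trace.i_acceptor
    if mode == "total":
        denom = total
        num = trace.i_acceptor
    elif mode == "acceptor_over_donor":
        denom = trace.i_donor
        num = trace.i_acceptor
    else:
        raise ValueError(f"unknown mode {mode!r}")
    masked = np.ma.masked_where(denom == 0, denom)
    return num / masked


def fit_biexponential(
    time: np.ndarray,
    ratio: np.ndarray,
    n_starts: int = 6,
) -> BiexpFit:
    """Least-squares biexponential fit of a rising-to-plateau ratio series.

    Multi-start initialisation over log-spaced timescale pairs guards the
    non-convex landscape; the best start wins.  Degenerate inputs are
    handled gracefully: a constant series returns zero amplitudes with
    the plateau at the mean, and a monoexponential series returns one
    near-zero amplitude.  Total non-convergence is flagged on the result
    rather than raised.
    """
    time = np.asarray(time, dtype=float)
    ratio = np.ma.filled(np.asarray(ratio), np.nan)
    keep = ~np.isnan(ratio)
    time, ratio = time[keep], ratio[keep]
    if time.size < 5:
        raise ValueError("need at least 5 valid points")

    f_end = float(np.mean(ratio[-max(3, time.size // 10):]))
    rise = f_end - float(ratio[0])
    if np.std(ratio) < 1e-12:
        return BiexpFit(
            f_plateau=float(np.mean(ratio)),
            a_fast=0.0,
            tau_fast=1.0,
            a_slow=0.0,
            tau_slow=1.0,
            residual_sd=0.0,
        )

    t_pos = time[time > 0]
    t_lo, t_hi = float(t_pos.min()), float(time.max())
    tau_grid = np.geomspace(max(t_lo, t_hi * 1e-4), t_hi * 2, n_starts)

    def residuals(x):
        p, af, lf, as_, ls = x
        return (
            p - af * np.exp(-time / np.exp(lf)) - as_ * np.exp(-time / np.exp(ls))
        ) - ratio

    best = None
    amp0 = max(abs(rise), 1e-6)
    for i in range(len(tau_grid) - 1):
        x0 = np.array(
            [
                f_end,
                amp0 / 2,
                np.log(tau_grid[i]),
                amp0 / 2,
                np.log(tau_grid[i + 1]),
            ]
        )
        lo = [-np.inf, 0.0, np.log(t_hi) - 25.0, 0.0, np.log(t_hi) - 25.0]
        hi = [np.inf, np.inf, np.log(t_hi) + 10.0, np.inf, np.log(t_hi) + 10.0]
        try:
            res = least_squares(residuals, x0, bounds=(lo, hi), x_scale="jac")
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return BiexpFit(
            f_plateau=f_end,
            a_fast=0.0,
            tau_fast=1.0,
            a_slow=0.0,
            tau_slow=1.0,
            residual_sd=float(np.std(ratio)),
            success=False,
            message="no start converged",
        )

    p, af, lf, as_, ls = best.x
    resid = best.fun
    n = time.size
    stderr = None
    try:
        cov = np.linalg.inv(best.jac.T @ best.jac) * (
            2 * best.cost / max(n - 5, 1)
        )
        diag = np.sqrt(np.clip(np.diag(cov), 0, None))
        stderr = {
            "f_plateau": float(diag[0]),
            "a_fast": float(diag[1]),
            "tau_fast": float(np.exp(lf) * diag[2]),  # delta method on log-tau
            "a_slow": float(diag[3]),
            "tau_slow": float(np.exp(ls) * diag[4]),
        }
    except np.linalg.LinAlgError:
        pass
    fit = BiexpFit(
        f_plateau=float(p),
        a_fast=float(af),
        tau_fast=float(np.exp(lf)),
        a_slow=float(as_),
        tau_slow=float(np.exp(ls)),
        residual_sd=float(np.std(resid, ddof=1)) if n > 1 else 0.0,
        stderr=stderr,
        success=bool(best.success),
        message=best.message,
    )
    if stderr is not None and fit.stderr is not None and fit.tau_fast != np.exp(lf):
        # canonical reordering swapped the components; swap errors too
        fit.stderr = {
            **fit.stderr,
            "a_fast": stderr["a_slow"],
            "tau_fast": stderr["tau_slow"],
            "a_slow": stderr["a_fast"],
            "tau_slow": stderr["tau_fast"],
        }
    return fit


def fit_fret_trace(trace: FRETTrace, mode: str = "total") -> BiexpFit:
    """Convenience: ratio computation followed by the biexponential fit."""
    return fit_biexponential(trace.time, fret_ratio(trace, mode))


def plateau_time(fit: BiexpFit, fraction: float = 0.95) -> float:
    """Smallest t with F(t) >= F(0) + fraction * (F_plateau - F(0)).

    Returns inf at fraction >= 1 (the plateau is an asymptote) and 0 when
    the total amplitude is zero.  Solved by bracketed root finding on the
    closed form.
    """
    if not 0 < fraction:
        raise ValueError("fraction must be positive")
    amp = fit.a_fast + fit.a_slow
    if amp == 0:
        return 0.0
    if fraction >= 1.0:
        return np.inf

    # F(t) - target = (1 - fraction) * amp - af e^-t/tf - as e^-t/ts
    def gap(t: float) -> float:
        return (
            (1.0 - fraction) * amp
            - fit.a_fast * np.exp(-t / fit.tau_fast)
            - fit.a_slow * np.exp(-t / fit.tau_slow)
        )

    hi = fit.tau_slow
    while gap(hi) < 0:
        hi *= 2
        if hi > 1e12 * fit.tau_slow:  # pragma: no cover
            return np.inf
    if gap(0.0) >= 0:
        return 0.0
    return float(brentq(gap, 0.0, hi, xtol=1e-12 * hi))


def compare_kinetics(
    fit_a: BiexpFit, fit_b: BiexpFit
) -> dict[str, tuple[float, float]]:
    """Fold changes tau_b / tau_a per component, with propagated
    1-sigma uncertainty (first-order, independent errors)."""
    out = {}
    for name in ("tau_fast", "tau_slow"):
        ta, tb = getattr(fit_a, name), getattr(fit_b, name)
        ratio = tb / ta
        sa = (fit_a.stderr or {}).get(name, 0.0)
        sb = (fit_b.stderr or {}).get(name, 0.0)
        err = abs(ratio) * np.sqrt((sa / ta) ** 2 + (sb / tb) ** 2)
        out[name] = (float(ratio), float(err))
    return out
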