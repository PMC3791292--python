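"""Mono- and bi-exponential decay fitting of shell-averaged diffusion signal.

The central model is the two-compartment description of multi-shell decay,

    S(b) = S0 * [ Mu * exp(-b * Du) + (1 - Mu) * exp(-b * Dr) ],

where ``Mu`` is the signal fraction of the unrestricted (fast) compartment and
``Du >= Dr`` are the apparent diffusion coefficients of the unrestricted and
restricted compartments (mm²/s). The model is symmetric under the exchange
``(Mu, Du) <-> (1 - Mu, Dr)``; the ``Du >= Dr`` labeling convention is enforced
on every returned fit. Fitting is constrained nonlinear least squares in signal
space (unweighted residuals).

The module follows the statsmodels pattern: ``BiExponentialDecayModel(decay)``
builds a model from data and ``.fit()`` returns a :class:`BiExpFit` results
object carrying the estimates, their standard errors, fit diagnostics, a
``summary()`` table and a ``plot()`` method. ``fit_mono`` / ``fit_biexp`` are
one-call conveniences over the same classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import ContractError, DegenerateInputError, ValidationError
from .io import ShellTable

__all__ = [
    "ShellMeanDecay",
    "MonoExpFit",
    "BiExpFit",
    "MonoExponentialDecayModel",
    "BiExponentialDecayModel",
    "shell_average",
    "fit_mono",
    "fit_biexp",
    "r_squared",
    "grid_oracle",
    "biexp_signal",
]

#: upper bound on both apparent diffusion coefficients, mm²/s (an order of
#: magnitude above free water; prevents runaway components on degenerate data)
D_MAX = 0.05

#: b-value thresholds (s/mm²) splitting the shells for initialization:
#: the low-b segment estimates the fast component, the high-b tail the slow one
_B_FAST_MAX = 1000.0
_B_SLOW_MIN = 2500.0


def biexp_signal(b, s0: float, mu: float, du: float, dr: float):
    """Two-compartment decay S(b) = S0*(Mu*exp(-b*Du) + (1-Mu)*exp(-b*Dr))."""
    b = np.asarray(b, dtype=float)
    return s0 * (mu * np.exp(-b * du) + (1.0 - mu) * np.exp(-b * dr))


@dataclass(frozen=True)
class ShellMeanDecay:
    """Shell-averaged decay curve: one mean signal per b-shell.

    Fields
    ------
    b : (k,) array of shell b-values, s/mm²
    mean_signal : (k,) array of direction-averaged signal, arbitrary units
    n_volumes : (k,) int array, number of volumes averaged per shell
    """

    b: np.ndarray
    mean_signal: np.ndarray
    n_volumes: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.b, dtype=float)
        s = np.asarray(self.mean_signal, dtype=float)
        n = np.asarray(self.n_volumes, dtype=int)
        if not (b.shape == s.shape == n.shape) or b.ndim != 1:
            raise ValidationError("b, mean_signal and n_volumes must be equal-length 1-D arrays")
        if np.any(s < 0):
            raise ValidationError("shell-mean signals must be non-negative")
        if len(np.unique(b)) != len(b):
            raise ValidationError("one entry per shell required (duplicate b-values)")
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "mean_signal", s)
        object.__setattr__(self, "n_volumes", n)

    def __len__(self) -> int:
        return len(self.b)


def shell_average(signals: Sequence[float], shells: ShellTable) -> ShellMeanDecay:
    """Average per-volume signals within each b-shell.

    ``signals`` is indexed by volume number (position = volume index). Every
    volume index referenced by ``shells`` must be present and finite.
    """
    sig = np.asarray(signals, dtype=float)
    bs, means, ns = [], [], []
    for shell in shells:
        if shell.volumes.max() >= sig.shape[0]:
            raise ValidationError(f"missing volume index {int(shell.volumes.max())} in signals")
        vals = sig[shell.volumes]
        if np.any(~np.isfinite(vals)):
            missing = int(shell.volumes[np.flatnonzero(~np.isfinite(vals))[0]])
            raise ValidationError(f"missing volume index {missing} in signals")
        bs.append(shell.b)
        means.append(float(vals.mean()))
        ns.append(shell.n_volumes)
    return ShellMeanDecay(b=np.array(bs), mean_signal=np.array(means), n_volumes=np.array(ns))


def r_squared(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination 1 − SS_res/SS_tot about the observed mean."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ContractError("observed and predicted must have equal length")
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateInputError("zero total sum of squares (constant signal)")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def _check_decay_for_fit(decay: ShellMeanDecay, min_shells: int) -> None:
    if np.all(decay.mean_signal == 0):
        raise DegenerateInputError("all-zero signal cannot be fitted")
    positive = decay.mean_signal > 0
    if len(np.unique(decay.b[positive])) < min_shells:
        raise DegenerateInputError(
            f"need at least {min_shells} distinct b-values with positive signal, "
            f"got {len(np.unique(decay.b[positive]))}"
        )


@dataclass(frozen=True)
class _FitResultBase:
    decay: ShellMeanDecay = field(repr=False)
    converged: bool
    rsquared: float

    @property
    def resid(self) -> np.ndarray:
        return self.decay.mean_signal - self.predict(self.decay.b)

    @property
    def ssr(self) -> float:
        return float(np.sum(self.resid**2))

    def plot(self, ax=None):
        """Plot shell means and the fitted curve on a log signal axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.semilogy(self.decay.b, self.decay.mean_signal, "o", label="shell means")
        bb = np.linspace(self.decay.b.min(), self.decay.b.max(), 200)
        ax.semilogy(bb, self.predict(bb), "-", label=type(self).__name__)
        ax.set_xlabel("b (s/mm²)")
        ax.set_ylabel("S(b)")
        ax.legend()
        return ax


@dataclass(frozen=True)
class MonoExpFit(_FitResultBase):
    """Mono-exponential fit S(b) = S0·exp(−b·ADC)."""

    s0: float = 0.0
    adc: float = 0.0
    bse: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.adc < 0:
            raise ValidationError("ADC must be non-negative")
        if self.rsquared > 1 + 1e-12:
            raise ValidationError("r² cannot exceed 1")

    def predict(self, b) -> np.ndarray:
        return self.s0 * np.exp(-np.asarray(b, dtype=float) * self.adc)

    def summary(self) -> str:
        lines = [
            "Mono-exponential decay fit",
            "--------------------------",
            f"  S0   {self.s0:12.6g}   (se {self.bse.get('s0', float('nan')):.3g})",
            f"  ADC  {self.adc:12.6g} mm²/s   (se {self.bse.get('adc', float('nan')):.3g})",
            f"  r²   {self.rsquared:12.6f}",
            f"  converged: {self.converged}   shells: {len(self.decay)}",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class BiExpFit(_FitResultBase):
    """Two-compartment fit with the Du ≥ Dr labeling convention enforced."""

    s0: float = 0.0
    mu: float = 0.0
    du: float = 0.0
    dr: float = 0.0
    at_bound: bool = False
    bse: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu <= 1.0 + 1e-12):
            raise ValidationError(f"Mu = {self.mu} outside [0, 1]")
        if not (self.du >= self.dr >= 0.0):
            raise ValidationError(f"labeling convention violated: Du={self.du}, Dr={self.dr}")
        if self.rsquared > 1 + 1e-12:
            raise ValidationError("r² cannot exceed 1")

    @property
    def params(self) -> dict:
        return {"s0": self.s0, "mu": self.mu, "du": self.du, "dr": self.dr}

    def predict(self, b) -> np.ndarray:
        return biexp_signal(b, self.s0, self.mu, self.du, self.dr)

    def summary(self) -> str:
        rows = [
            ("S0", self.s0, ""),
            ("Mu", self.mu, "(unrestricted fraction)"),
            ("Du", self.du, "mm²/s (unrestricted)"),
            ("Dr", self.dr, "mm²/s (restricted)"),
        ]
        lines = ["Two-compartment decay fit", "-------------------------"]
        for name, val, note in rows:
            se = self.bse.get(name.lower(), float("nan"))
            lines.append(f"  {name:<3} {val:12.6g}   (se {se:.3g})  {note}")
        lines.append(f"  r²  {self.rsquared:12.6f}")
        lines.append(
            f"  converged: {self.converged}   at_bound: {self.at_bound}   shells: {len(self.decay)}"
        )
        return "\n".join(lines)


def _bse_from_jacobian(jac: np.ndarray, resid: np.ndarray, names: Sequence[str]) -> dict:
    n, p = jac.shape
    if n <= p:
        return {}
    try:
        cov = np.linalg.inv(jac.T @ jac) * float(np.sum(resid**2)) / (n - p)
    except np.linalg.LinAlgError:
        return {}
    d = np.diag(cov)
    if np.any(d < 0):
        return {}
    return dict(zip(names, np.sqrt(d)))


class MonoExponentialDecayModel:
    """Single-pool decay model S(b) = S0·exp(−b·ADC) for shell-mean data.

    Adequate at modest diffusion weighting (b up to ~1000 s/mm²) and for free
    water (CSF); on tissue at high b it underfits the restricted tail.
    """

    n_params = 2

    def __init__(self, decay: ShellMeanDecay):
        _check_decay_for_fit(decay, min_shells=2)
        self.decay = decay

    def _start(self) -> np.ndarray:
        pos = self.decay.mean_signal > 0
        b, y = self.decay.b[pos], self.decay.mean_signal[pos]
        slope, intercept = np.polyfit(b, np.log(y), 1)
        return np.array([float(np.exp(intercept)), float(np.clip(-slope, 0.0, D_MAX))])

    def fit(self, ftol: float = 1e-12, xtol: float = 1e-12, max_nfev: int = 500) -> MonoExpFit:
        b, y = self.decay.b, self.decay.mean_signal

        def resid(theta):
            return theta[0] * np.exp(-b * theta[1]) - y

        def jac(theta):
            e = np.exp(-b * theta[1])
            return np.column_stack([e, -theta[0] * b * e])

        x0 = self._start()
        res = least_squares(
            resid, x0, jac=jac,
            bounds=([0.0, 0.0], [np.inf, D_MAX]),
            ftol=ftol, xtol=xtol, gtol=1e-12, max_nfev=max_nfev,
            x_scale=[max(x0[0], 1e-12), 1e-3],
        )
        s0, adc = res.x
        try:
            r2 = r_squared(y, s0 * np.exp(-b * adc))
        except DegenerateInputError:
            r2 = float("nan")
        return MonoExpFit(
            decay=self.decay, converged=bool(res.success), rsquared=r2,
            s0=float(s0), adc=float(adc),
            bse=_bse_from_jacobian(jac(res.x), res.fun, ["s0", "adc"]),
        )


class BiExponentialDecayModel:
    """Two-compartment decay model for shell-mean multi-shell data.

    Parameters are bounded to 0 ≤ Mu ≤ 1, 0 ≤ Dr, Du ≤ 0.05 mm²/s, S0 > 0.
    Starting values come from exponential peeling: a log-linear fit of the
    high-b tail (b ≥ 2500 s/mm²) estimates the slow component, the low-b
    segment (0 < b ≤ 1000) after tail subtraction estimates the fast one.
    """

    n_params = 4
    _BOUND_RTOL = 1e-6

    def __init__(self, decay: ShellMeanDecay):
        _check_decay_for_fit(decay, min_shells=4)
        self.decay = decay

    # -- initialization -----------------------------------------------------

    def _segments(self) -> tuple[np.ndarray, np.ndarray]:
        b = self.decay.b
        nz = b[b > 0]
        lo, hi = _B_FAST_MAX, _B_SLOW_MIN
        if (np.sum((b > 0) & (b <= lo)) < 2) or (np.sum(b >= hi) < 2):
            med = float(np.median(nz))
            lo = hi = med
        fast = (b > 0) & (b <= lo)
        slow = b >= hi
        return fast, slow

    def _start(self) -> np.ndarray:
        b, y = self.decay.b, self.decay.mean_signal
        s0_default = float(y[np.argmin(b)])
        fast, slow = self._segments()
        try:
            ys = y[slow]
            ok = ys > 0
            slope_s, icpt_s = np.polyfit(b[slow][ok], np.log(ys[ok]), 1)
            dr0 = float(np.clip(-slope_s, 1e-7, D_MAX))
            a_r = float(np.exp(icpt_s))
            resid_fast = y[fast] - a_r * np.exp(-b[fast] * dr0)
            pos = resid_fast > 0
            if pos.sum() >= 2:
                slope_f, icpt_f = np.polyfit(b[fast][pos], np.log(resid_fast[pos]), 1)
                du0 = float(np.clip(-slope_f, dr0, D_MAX))
                a_u = float(np.exp(icpt_f))
            else:
                du0, a_u = min(20 * dr0, D_MAX), max(s0_default - a_r, 0.1 * s0_default)
            mu0 = float(np.clip(a_u / max(a_u + a_r, 1e-300), 0.01, 0.99))
            s00 = max(a_u + a_r, 1e-12)
        except (np.linalg.LinAlgError, ValueError):
            s00, mu0, du0, dr0 = max(s0_default, 1e-12), 0.5, 1.5e-3, 1e-4
        return np.array([s00, mu0, du0, dr0])

    # -- fitting ------------------------------------------------------------

    def fit(
        self,
        start: Sequence[float] | None = None,
        ftol: float = 1e-12,
        xtol: float = 1e-12,
        max_nfev: int = 2000,
    ) -> BiExpFit:
        """Bounded least squares of the two-compartment model.

        Never raises on non-convergence; the result carries ``converged=False``
        instead. ``start`` optionally overrides the peeling initializer with
        ``(S0, Mu, Du, Dr)``.
        """
        b, y = self.decay.b, self.decay.mean_signal

        def resid(theta):
            s0, mu, du, dr = theta
            return biexp_signal(b, s0, mu, du, dr) - y

        def jac(theta):
            s0, mu, du, dr = theta
            eu, er = np.exp(-b * du), np.exp(-b * dr)
            return np.column_stack(
                [mu * eu + (1 - mu) * er, s0 * (eu - er), -s0 * mu * b * eu,
                 -s0 * (1 - mu) * b * er]
            )

        x0 = np.array(self._start() if start is None else start, dtype=float)
        lower = np.array([1e-300, 0.0, 0.0, 0.0])
        upper = np.array([np.inf, 1.0, D_MAX, D_MAX])
        x0 = np.clip(x0, lower, upper)
        res = least_squares(
            resid, x0, jac=jac, bounds=(lower, upper),
            ftol=ftol, xtol=xtol, gtol=1e-14, max_nfev=max_nfev,
            x_scale=[max(x0[0], 1e-12), 1.0, 1e-3, 1e-4],
        )
        s0, mu, du, dr = (float(v) for v in res.x)
        bse = _bse_from_jacobian(jac(res.x), res.fun, ["s0", "mu", "du", "dr"])
        if du < dr:  # component-exchange symmetry: relabel to Du >= Dr
            mu, du, dr = 1.0 - mu, dr, du
            bse = {"s0": bse.get("s0"), "mu": bse.get("mu"), "du": bse.get("dr"),
                   "dr": bse.get("du")} if bse else {}
        at_bound = bool(
            mu <= self._BOUND_RTOL or mu >= 1.0 - self._BOUND_RTOL
            or du >= D_MAX * (1 - self._BOUND_RTOL) or dr <= D_MAX * self._BOUND_RTOL * 1e-3
            or du - dr <= self._BOUND_RTOL * max(du, 1e-12)
        )
        try:
            r2 = r_squared(y, biexp_signal(b, s0, mu, du, dr))
        except DegenerateInputError:
            r2 = float("nan")
        return BiExpFit(
            decay=self.decay, converged=bool(res.success), rsquared=min(r2, 1.0),
            s0=s0, mu=mu, du=du, dr=dr, at_bound=at_bound, bse=bse,
        )


def fit_mono(decay: ShellMeanDecay) -> MonoExpFit:
    """Fit S0·exp(−b·ADC) to a shell-mean decay curve."""
    return MonoExponentialDecayModel(decay).fit()


def fit_biexp(decay: ShellMeanDecay, start: Sequence[float] | None = None) -> BiExpFit:
    """Fit the two-compartment decay model to a shell-mean decay curve."""
    return BiExponentialDecayModel(decay).fit(start=start)


def grid_oracle(
    decay: ShellMeanDecay,
    s0_grid: Sequence[float],
    mu_grid: Sequence[float],
    du_grid: Sequence[float],
    dr_grid: Sequence[float],
) -> tuple[tuple[float, float, float, float], float]:
    """Exhaustive minimum of the two-compartment sum of squared residuals on a grid.

    Testing oracle: returns the best grid point ``(S0, Mu, Du, Dr)`` and its
    residual sum of squares. Intended for small grids (≤ 50 per axis).
    """
    s0g = np.asarray(s0_grid, float)
    mug = np.asarray(mu_grid, float)
    dug = np.asarray(du_grid, float)
    drg = np.asarray(dr_grid, float)
    if s0g.size * mug.size * dug.size * drg.size > 50**4:
        raise ContractError("grid too large for the exhaustive oracle (limit 50⁴ points)")
    b, y = decay.b, decay.mean_signal
    eu = np.exp(-np.outer(dug, b))  # (du, b)
    er = np.exp(-np.outer(drg, b))  # (dr, b)
    best_sse, best = np.inf, None
    for i_s0, s0 in enumerate(s0g):
        for i_mu, mu in enumerate(mug):
            # model: (du, dr, b)
            model = s0 * (mu * eu[:, None, :] + (1 - mu) * er[None, :, :])
            sse = np.sum((model - y) ** 2, axis=2)
            k = np.unravel_index(np.argmin(sse), sse.shape)
            if sse[k] < best_sse:
                best_sse = float(sse[k])
                best = (float(s0), float(mu), float(dug[k[0]]), float(drg[k[1]]))
    return best, best_sse
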