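"""Permeability-diffusivity quantities derived from fitted decay parameters.

The permeability-diffusivity index is the ratio of the restricted to the
unrestricted apparent diffusion coefficient, PDI = Dr/Du. In the permeable-
membrane account of bi-exponential decay, PDI rises steeply with membrane
permeability across the physiological range while the unrestricted fraction
Mu moves only modestly, which makes PDI the sensitive summary of the fit.
The dimensionless effective permeability mu_eff = mu*d/D0 combines the
membrane water flux mu (mm/s), the membrane-bound compartment distance d (mm)
and the free-water diffusivity D0 (mm²/s).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from .decay import BiExpFit
from .errors import ContractError

__all__ = ["PDMetrics", "EffectivePermeability", "pdi", "mu_eff", "metrics_from_fit"]


class FitQualityWarning(UserWarning):
    """Raised when metrics are derived from a boundary or degenerate fit."""


@dataclass(frozen=True)
class PDMetrics:
    """Derived permeability-diffusivity metrics for one fitted decay curve."""

    pdi: float
    mu: float
    du: float
    dr: float
    quality_warning: str | None = None


@dataclass(frozen=True)
class EffectivePermeability:
    """Dimensionless effective permeability and its physical ingredients."""

    mu: float      # membrane water flux, mm/s
    d: float       # membrane-bound compartment distance, mm
    d0: float      # free-water diffusivity, mm²/s
    mu_eff: float  # = mu * d / d0

    def __post_init__(self) -> None:
        if self.d <= 0 or self.d0 <= 0:
            raise ContractError("d and D0 must be positive")
        if self.mu < 0:
            raise ContractError("membrane flux mu must be non-negative")
        if abs(self.mu_eff - self.mu * self.d / self.d0) > 1e-12 * max(1.0, abs(self.mu_eff)):
            raise ContractError("mu_eff must equal mu*d/D0")


def pdi(dr: float, du: float) -> float:
    """Permeability-diffusivity index Dr/Du.

    Under the Du >= Dr labeling convention the result lies in [0, 1]; a raw
    ratio above 1 (unlabeled fit) is returned unclamped with a warning.
    """
    if du <= 0:
        raise ContractError(f"Du must be positive, got {du}")
    if dr < 0:
        raise ContractError(f"Dr must be non-negative, got {dr}")
    ratio = dr / du
    if ratio > 1.0:
        warnings.warn(
            f"PDI = {ratio:.4g} > 1: input violates the Du >= Dr labeling convention",
            FitQualityWarning,
            stacklevel=2,
        )
    return ratio


def mu_eff(mu: float, d: float, d0: float) -> float:
    """Dimensionless effective permeability mu*d/D0."""
    if d <= 0 or d0 <= 0:
        raise ContractError("d and D0 must be positive")
    if mu < 0:
        raise ContractError("membrane flux mu must be non-negative")
    return mu * d / d0


def effective_permeability(mu: float, d: float, d0: float) -> EffectivePermeability:
    """Build an :class:`EffectivePermeability` record from its physical inputs."""
    return EffectivePermeability(mu=mu, d=d, d0=d0, mu_eff=mu_eff(mu, d, d0))


def metrics_from_fit(fit: BiExpFit) -> PDMetrics:
    """Derive PD metrics from a converged two-compartment fit.

    Boundary-flagged fits and degenerate Dr = Du fits propagate a quality
    warning in the returned record (and emit :class:`FitQualityWarning`).
    """
    if not fit.converged:
        raise ContractError("cannot derive metrics from a non-converged fit")
    note = None
    if fit.du == fit.dr:
        note = "degenerate compartments (Dr = Du)"
    elif fit.at_bound:
        note = "parameter at a bound"
    if note is not None:
        warnings.warn(note, FitQualityWarning, stacklevel=2)
    return PDMetrics(
        pdi=pdi(fit.dr, fit.du), mu=fit.mu, du=fit.du, dr=fit.dr, quality_warning=note
    )
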