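"""Synthetic multi-shell cohorts from the two-compartment decay model.

Generates cohorts of subjects with group effects, age trends in the
permeability-diffusivity index (PDI), FA scalars coupled to PDI through a
Gaussian copula, and per-ROI multi-shell magnitude signals with Rician noise,
so the whole fit-and-statistics pipeline is testable without any acquisition.

The default protocol emulates a 3 T multi-b-value acquisition: fifteen
b-shells at 250-3800 s/mm² with 30 isotropically distributed directions per
shell plus sixteen b = 0 volumes (466 volumes in total), with the noise scale
anchored so that the corpus-callosum signal at the highest shell sits at a
configurable SNR (default 6.1).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, ContractError, ValidationError
from .io import BTable, ROISignalTable, ShellTable, group_shells

__all__ = [
    "MBI_SHELL_BVALUES",
    "mbi_btable",
    "synthesize_signal",
    "add_rician_noise",
    "GroupROIParams",
    "ROIGenParams",
    "CohortConfig",
    "ROITrueParams",
    "SubjectRecord",
    "SyntheticCohort",
    "generate_cohort",
    "study_config",
    "subjects_to_covariates",
    "true_params_frame",
]

#: the fifteen non-zero shell b-values of the emulated protocol, s/mm²
MBI_SHELL_BVALUES = (
    250, 500, 600, 700, 800, 900, 1000, 1250, 1500, 1750, 2000, 2500, 3000, 3500, 3800
)
MBI_N_B0 = 16
MBI_DIRECTIONS_PER_SHELL = 30

#: free-water diffusivity used for the mono-exponential CSF reference ROI, mm²/s
CSF_DIFFUSIVITY = 3.0e-3


def _fibonacci_directions(n: int) -> np.ndarray:
    """n approximately isotropic unit vectors (golden-spiral sphere covering)."""
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(1 - z**2)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def mbi_btable(
    shell_bvalues: Sequence[float] = MBI_SHELL_BVALUES,
    n_b0: int = MBI_N_B0,
    directions_per_shell: int = MBI_DIRECTIONS_PER_SHELL,
) -> BTable:
    """Gradient table of the emulated multi-b-value protocol.

    Volume order: the b = 0 volumes first, then the shells in ascending b, each
    with the same isotropic direction set.
    """
    dirs = _fibonacci_directions(directions_per_shell)
    b = [0.0] * n_b0
    d = [np.zeros(3)] * n_b0
    for bv in shell_bvalues:
        b.extend([float(bv)] * directions_per_shell)
        d.extend(dirs)
    return BTable(b_values=np.array(b), directions=np.array(d))


def synthesize_signal(
    params: Sequence[float],
    shells: ShellTable,
    mode: str = "shell-mean",
) -> np.ndarray:
    """Noiseless two-compartment signal at each shell of a protocol.

    ``params`` is ``(S0, Mu, Du, Dr)``. The model is direction-free, so
    ``per-direction`` mode replicates each shell's value across its member
    volumes (returning a per-volume array); ``shell-mean`` returns one value
    per shell.
    """
    s0, mu, du, dr = (float(v) for v in params)
    if not (0.0 <= mu <= 1.0):
        raise ContractError(f"Mu = {mu} outside [0, 1]")
    if not (du >= dr >= 0.0):
        raise ContractError(f"require Du >= Dr >= 0, got Du={du}, Dr={dr}")
    if s0 < 0:
        raise ContractError("S0 must be non-negative")
    b = shells.b_values
    if np.any(b < 0):
        raise ContractError("negative b-value in shell table")
    shell_vals = s0 * (mu * np.exp(-b * du) + (1 - mu) * np.exp(-b * dr))
    if mode == "shell-mean":
        return shell_vals
    if mode == "per-direction":
        n = max(int(s.volumes.max()) for s in shells) + 1
        out = np.empty(n)
        out.fill(np.nan)
        for val, shell in zip(shell_vals, shells):
            out[shell.volumes] = val
        return out
    raise ContractError(f"unknown mode {mode!r}")


def add_rician_noise(signal, sigma: float, seed) -> np.ndarray:
    """Rician-corrupt magnitude signals.

    Each output is the magnitude of the complex perturbation
    ``|(s + g1) + i*g2|`` with g1, g2 independent N(0, sigma²). ``sigma = 0``
    returns the input unchanged. ``seed`` is an int or a Generator; a fixed
    seed gives bit-identical output.
    """
    if sigma < 0:
        raise ContractError("sigma must be non-negative")
    s = np.asarray(signal, dtype=float)
    if sigma == 0:
        return s.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    g1 = rng.normal(0.0, sigma, size=s.shape)
    g2 = rng.normal(0.0, sigma, size=s.shape)
    return np.sqrt((s + g1) ** 2 + g2**2)


# --------------------------------------------------------------------------
# cohort configuration


@dataclass(frozen=True)
class GroupROIParams:
    """Generating distribution of decay parameters for one group in one ROI.

    ``mu``/``du``/``dr`` are (mean, sd) of the unrestricted fraction and the
    two apparent diffusivities (mm²/s); draws are truncated Gaussians (Mu to
    [0, 1], diffusivities to (0, inf)). ``pdi_age_slope`` shifts each
    subject's PDI linearly with age (per year, centered at the cohort age
    midpoint); Dr is back-computed as PDI·Du. ``fa``/``fa_pdi_corr`` add an FA
    scalar with the target Pearson correlation to PDI via a Gaussian copula.
    """

    mu: tuple[float, float]
    du: tuple[float, float]
    dr: tuple[float, float]
    pdi_age_slope: float = 0.0
    fa: tuple[float, float] | None = None
    fa_pdi_corr: float | None = None
    d_axial: tuple[float, float] | None = None
    d_radial: tuple[float, float] | None = None

    def validate(self, mono: bool) -> None:
        if not (0.0 <= self.mu[0] <= 1.0):
            raise ConfigurationError(f"mean Mu {self.mu[0]} outside [0, 1]")
        if not mono and not (self.du[0] > self.dr[0] > 0):
            raise ConfigurationError(
                f"require mean Du > mean Dr > 0, got {self.du[0]}, {self.dr[0]}"
            )
        for name, (m, s) in (("mu", self.mu), ("du", self.du), ("dr", self.dr)):
            if s < 0:
                raise ConfigurationError(f"negative SD for {name}")
        if self.fa_pdi_corr is not None and abs(self.fa_pdi_corr) > 1:
            raise ConfigurationError(
                f"target FA-PDI correlation {self.fa_pdi_corr} outside [-1, 1]"
            )


@dataclass(frozen=True)
class ROIGenParams:
    """Per-ROI generator settings: one GroupROIParams per group, shared S0."""

    groups: Mapping[str, GroupROIParams]
    s0: float = 1.0
    mono: bool = False
    mono_d: float = CSF_DIFFUSIVITY

    def validate(self) -> None:
        for gp in self.groups.values():
            gp.validate(self.mono)


@dataclass(frozen=True)
class CohortConfig:
    """Full specification of a synthetic cohort.

    ``pdi_coupling`` optionally names two ROIs and a per-group target Pearson
    correlation of their restricted-diffusivity draws (gray-white PDI
    coupling). ``snr`` anchors the Rician noise scale: the per-volume sigma is
    (noiseless reference-ROI signal at the highest shell)/snr; ``None`` means
    noiseless signals.
    """

    group_sizes: Mapping[str, int]
    rois: Mapping[str, ROIGenParams]
    age_range: tuple[float, float] = (20.0, 61.0)
    snr: float | None = 6.1
    snr_reference_roi: str | None = "cc"
    pdi_coupling: tuple[str, str, Mapping[str, float]] | None = None
    male_fraction: Mapping[str, float] | None = None
    bmi: tuple[float, float] | None = (28.0, 5.0)
    dose: Mapping[str, tuple[float, float] | None] | None = None
    seed: int | None = None

    def validate(self) -> None:
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ConfigurationError(f"group {g!r} size {n} < 2")
        if self.snr is not None and not self.snr > 0:
            raise ConfigurationError("snr must be positive (or None for noiseless)")
        if self.age_range[1] <= self.age_range[0]:
            raise ConfigurationError("empty age range")
        for roi in self.rois.values():
            roi.validate()
        if self.pdi_coupling is not None:
            ra, rb, rs = self.pdi_coupling
            for roi in (ra, rb):
                if roi not in self.rois:
                    raise ConfigurationError(f"coupled ROI {roi!r} not in config")
            for g, r in rs.items():
                if abs(r) > 1:
                    raise ConfigurationError(f"coupling correlation {r} outside [-1, 1]")


# --------------------------------------------------------------------------
# subjects


@dataclass(frozen=True)
class ROITrueParams:
    """Generating decay parameters of one subject in one ROI."""

    s0: float
    mu: float
    du: float
    dr: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.mu <= 1.0):
            raise ValidationError(f"Mu = {self.mu} outside [0, 1]")
        if not (self.du >= self.dr >= 0.0):
            raise ValidationError(f"require Du >= Dr >= 0, got {self.du}, {self.dr}")

    @property
    def pdi(self) -> float:
        return self.dr / self.du if self.du > 0 else float("nan")


@dataclass(frozen=True)
class SubjectRecord:
    """One synthetic participant: covariates plus per-ROI true parameters."""

    id: str
    group: str
    age: float
    sex: str
    roi_params: Mapping[str, ROITrueParams]
    fa: Mapping[str, float] = field(default_factory=dict)
    d_axial: Mapping[str, float] = field(default_factory=dict)
    d_radial: Mapping[str, float] = field(default_factory=dict)
    bmi: float | None = None
    dose: float | None = None

    def __post_init__(self) -> None:
        for roi, v in self.fa.items():
            if not (0.0 <= v <= 1.0):
                raise ValidationError(f"FA = {v} outside [0, 1] for ROI {roi!r}")


@dataclass(frozen=True)
class SyntheticCohort:
    """Output of :func:`generate_cohort`."""

    subjects: tuple[SubjectRecord, ...]
    signals: ROISignalTable | None
    btable: BTable
    shells: ShellTable
    config: CohortConfig = field(repr=False)


# --------------------------------------------------------------------------
# generation


def _trunc_gauss_from_z(z: np.ndarray, mean: float, sd: float, lo: float, hi: float) -> np.ndarray:
    """Map standard-normal latents to a truncated Gaussian (exact marginal)."""
    if sd == 0:
        return np.full_like(z, mean, dtype=float)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.ppf(sps.norm.cdf(z), a, b, loc=mean, scale=sd)


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    if s == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / s


def generate_cohort(
    config: CohortConfig,
    seed: int | None = None,
    with_signals: bool = True,
    signal_mode: str = "per-direction",
) -> SyntheticCohort:
    """Draw a full synthetic cohort from a :class:`CohortConfig`.

    Deterministic under a fixed seed (``seed`` overrides ``config.seed``).
    When ``with_signals`` is true, every subject/ROI gets per-volume signals
    from :func:`synthesize_signal` plus :func:`add_rician_noise` on the
    emulated protocol.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    btable = mbi_btable()
    shells = group_shells(btable)
    age_mid = 0.5 * (config.age_range[0] + config.age_range[1])

    coupling = config.pdi_coupling
    # sorted iteration makes the draw order (hence the seed stream) independent
    # of the mapping order a config happens to arrive in
    roi_names = sorted(config.rois)
    subjects: list[SubjectRecord] = []

    for group in sorted(config.group_sizes):
        n = int(config.group_sizes[group])
        ages = rng.uniform(*config.age_range, size=n)
        p_male = (config.male_fraction or {}).get(group, 0.5)
        sexes = np.where(rng.random(n) < p_male, "M", "F")
        bmis = rng.normal(*config.bmi, size=n) if config.bmi else np.full(n, np.nan)
        dose_cfg = (config.dose or {}).get(group)
        doses = (
            np.clip(rng.normal(*dose_cfg, size=n), 0.0, None)
            if dose_cfg is not None
            else np.full(n, np.nan)
        )

        # correlated restricted-diffusivity latents for the coupled ROI pair
        z_dr: dict[str, np.ndarray] = {}
        if coupling is not None:
            roi_a, roi_b, rmap = coupling
            r = float(rmap.get(group, 0.0))
            cov = np.array([[1.0, r], [r, 1.0]])
            try:
                chol = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
            except np.linalg.LinAlgError:
                raise ConfigurationError(f"coupling correlation {r} is not positive definite")
            zz = rng.standard_normal((n, 2)) @ chol.T
            z_dr[roi_a], z_dr[roi_b] = zz[:, 0], zz[:, 1]

        draws: dict[str, dict[str, np.ndarray]] = {}
        for roi in roi_names:
            rp = config.rois[roi]
            if rp.mono:
                draws[roi] = {
                    "mu": np.ones(n), "du": np.full(n, rp.mono_d), "dr": np.zeros(n),
                    "fa": None, "dax": None, "drad": None,
                }
                continue
            gp = rp.groups[group]
            zmu = rng.standard_normal(n)
            zdu = rng.standard_normal(n)
            zdr = z_dr.get(roi, rng.standard_normal(n))
            mu = _trunc_gauss_from_z(zmu, *gp.mu, 0.0, 1.0)
            du = _trunc_gauss_from_z(zdu, *gp.du, 0.0, np.inf)
            dr = _trunc_gauss_from_z(zdr, *gp.dr, 0.0, np.inf)
            swap = du < dr
            du[swap], dr[swap] = dr[swap], du[swap]
            pdi = dr / du + gp.pdi_age_slope * (ages - age_mid)
            pdi = np.clip(pdi, 1e-6, 1.0)
            dr = pdi * du
            fa = dax = drad = None
            if gp.fa is not None:
                r = gp.fa_pdi_corr if gp.fa_pdi_corr is not None else 0.0
                eps = rng.standard_normal(n)
                z_pdi = _standardize(pdi)
                fa = gp.fa[0] + gp.fa[1] * (r * z_pdi + np.sqrt(max(0.0, 1 - r**2)) * eps)
                fa = np.clip(fa, 0.0, 1.0)
            if gp.d_axial is not None:
                dax = np.clip(rng.normal(*gp.d_axial, size=n), 1e-12, None)
            if gp.d_radial is not None:
                drad = np.clip(rng.normal(*gp.d_radial, size=n), 1e-12, None)
            draws[roi] = {"mu": mu, "du": du, "dr": dr, "fa": fa, "dax": dax, "drad": drad}

        for i in range(n):
            roi_params = {
                roi: ROITrueParams(
                    s0=config.rois[roi].s0,
                    mu=float(draws[roi]["mu"][i]),
                    du=float(draws[roi]["du"][i]),
                    dr=float(draws[roi]["dr"][i]),
                )
                for roi in roi_names
            }
            fa = {
                roi: float(draws[roi]["fa"][i])
                for roi in roi_names
                if draws[roi]["fa"] is not None
            }
            dax = {
                roi: float(draws[roi]["dax"][i])
                for roi in roi_names
                if draws[roi]["dax"] is not None
            }
            drad = {
                roi: float(draws[roi]["drad"][i])
                for roi in roi_names
                if draws[roi]["drad"] is not None
            }
            subjects.append(
                SubjectRecord(
                    id=f"{group}-{i + 1:03d}", group=group, age=float(ages[i]),
                    sex=str(sexes[i]), roi_params=roi_params, fa=fa,
                    d_axial=dax, d_radial=drad,
                    bmi=float(bmis[i]) if np.isfinite(bmis[i]) else None,
                    dose=float(doses[i]) if np.isfinite(doses[i]) else None,
                )
            )

    signals = _make_signals(subjects, config, shells, btable, rng, signal_mode) if with_signals else None
    return SyntheticCohort(
        subjects=tuple(subjects), signals=signals, btable=btable, shells=shells, config=config
    )


def _noise_sigma(subject: SubjectRecord, config: CohortConfig, shells: ShellTable) -> float:
    if config.snr is None:
        return 0.0
    ref = config.snr_reference_roi
    if ref is None or ref not in subject.roi_params:
        ref = next(r for r in subject.roi_params if not config.rois[r].mono)
    p = subject.roi_params[ref]
    b_max = shells.b_values.max()
    s_ref = p.s0 * (p.mu * np.exp(-b_max * p.du) + (1 - p.mu) * np.exp(-b_max * p.dr))
    return float(s_ref) / config.snr


def _make_signals(
    subjects: Sequence[SubjectRecord],
    config: CohortConfig,
    shells: ShellTable,
    btable: BTable,
    rng: np.random.Generator,
    mode: str,
) -> ROISignalTable:
    frames = []
    volumes = np.arange(btable.n_volumes)
    for subj in subjects:
        sigma = _noise_sigma(subj, config, shells)
        for roi, p in subj.roi_params.items():
            clean = synthesize_signal((p.s0, p.mu, p.du, p.dr), shells, mode=mode)
            noisy = add_rician_noise(clean, sigma, rng)
            if mode == "per-direction":
                frames.append(
                    pd.DataFrame(
                        {"subject": subj.id, "roi": roi, "volume": volumes,
                         "bval": btable.b_values, "signal": noisy}
                    )
                )
            else:
                frames.append(
                    pd.DataFrame(
                        {"subject": subj.id, "roi": roi,
                         "volume": np.arange(len(shells)),
                         "bval": shells.b_values, "signal": noisy}
                    )
                )
    return ROISignalTable(frame=pd.concat(frames, ignore_index=True))


def subjects_to_covariates(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Covariate table: one row per subject (group, age, sex, BMI, dose)."""
    return pd.DataFrame(
        {
            "subject": [s.id for s in subjects],
            "group": [s.group for s in subjects],
            "age": [s.age for s in subjects],
            "sex": [s.sex for s in subjects],
            "bmi": [s.bmi if s.bmi is not None else np.nan for s in subjects],
            "dose": [s.dose if s.dose is not None else np.nan for s in subjects],
        }
    )


def true_params_frame(subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Long table of generating parameters: one row per (subject, ROI).

    Has the same layout as a fitted-parameter table (mu, du, dr, pdi plus FA
    and DTI scalars where present), so the statistics layer can run directly
    on the generating truth.
    """
    rows = []
    for s in subjects:
        for roi, p in s.roi_params.items():
            rows.append(
                {
                    "subject": s.id, "roi": roi, "s0": p.s0, "mu": p.mu,
                    "du": p.du, "dr": p.dr, "pdi": p.pdi,
                    "fa": s.fa.get(roi, np.nan),
                    "d_axial": s.d_axial.get(roi, np.nan),
                    "d_radial": s.d_radial.get(roi, np.nan),
                }
            )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# plain-dict (YAML-able) config round-trip


def config_to_dict(config: CohortConfig) -> dict:
    """Plain-dict form of a CohortConfig (for YAML serialization)."""
    d = asdict(config)
    d["group_sizes"] = dict(config.group_sizes)
    d["rois"] = {
        name: {
            "s0": rp.s0, "mono": rp.mono, "mono_d": rp.mono_d,
            "groups": {g: {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in asdict(gp).items() if v is not None}
                       for g, gp in rp.groups.items()},
        }
        for name, rp in config.rois.items()
    }
    if config.pdi_coupling is not None:
        ra, rb, rs = config.pdi_coupling
        d["pdi_coupling"] = {"rois": [ra, rb], "r": dict(rs)}
    d["age_range"] = list(config.age_range)
    d["bmi"] = list(config.bmi) if config.bmi else None
    d["male_fraction"] = dict(config.male_fraction) if config.male_fraction else None
    d["dose"] = (
        {g: (list(v) if v is not None else None) for g, v in config.dose.items()}
        if config.dose else None
    )
    return d


def config_from_dict(d: Mapping) -> CohortConfig:
    """Inverse of :func:`config_to_dict`."""
    def pair(v):
        return tuple(v) if v is not None else None

    rois = {}
    for name, rp in d["rois"].items():
        groups = {
            g: GroupROIParams(
                mu=tuple(gp["mu"]), du=tuple(gp["du"]), dr=tuple(gp["dr"]),
                pdi_age_slope=gp.get("pdi_age_slope", 0.0),
                fa=pair(gp.get("fa")), fa_pdi_corr=gp.get("fa_pdi_corr"),
                d_axial=pair(gp.get("d_axial")), d_radial=pair(gp.get("d_radial")),
            )
            for g, gp in rp.get("groups", {}).items()
        }
        rois[name] = ROIGenParams(
            groups=groups, s0=rp.get("s0", 1.0), mono=rp.get("mono", False),
            mono_d=rp.get("mono_d", CSF_DIFFUSIVITY),
        )
    coupling = None
    if d.get("pdi_coupling"):
        c = d["pdi_coupling"]
        coupling = (c["rois"][0], c["rois"][1], dict(c["r"]))
    return CohortConfig(
        group_sizes=dict(d["group_sizes"]), rois=rois,
        age_range=tuple(d.get("age_range", (20.0, 61.0))),
        snr=d.get("snr", 6.1), snr_reference_roi=d.get("snr_reference_roi", "cc"),
        pdi_coupling=coupling,
        male_fraction=dict(d["male_fraction"]) if d.get("male_fraction") else None,
        bmi=pair(d.get("bmi")),
        dose={g: pair(v) for g, v in d["dose"].items()} if d.get("dose") else None,
        seed=d.get("seed"),
    )


# --------------------------------------------------------------------------
# the emulated study conditions


def study_config(
    n_per_group: int = 26,
    snr: float | None = 6.1,
    include_signals_rois: bool = True,
) -> CohortConfig:
    """Cohort configuration emulating the printed study conditions.

    Patient/control decay parameters per ROI follow the published
    mean ± SD summaries for the corpus callosum (whole, genu, body, splenium)
    and cingulate gray matter; PDI age slopes, FA levels, FA-PDI correlations
    and the gray-white PDI coupling follow the printed regression and
    correlation summaries. A mono-exponential CSF reference ROI is included.
    Gray-matter diffusivities are not published; Du = 1.2e-3 mm²/s is used
    with Dr back-computed from the printed PDI means.
    """

    def gpair(mu, du, dr, slope=0.0, fa=None, r=None, dax=None, drad=None):
        return GroupROIParams(
            mu=mu, du=du, dr=dr, pdi_age_slope=slope, fa=fa, fa_pdi_corr=r,
            d_axial=dax, d_radial=drad,
        )

    rois = {
        "cc": ROIGenParams(groups={
            "patient": gpair((0.55, 0.03), (1.8e-3, 0.2e-3), (7.1e-5, 1.5e-5),
                             slope=-3.3e-4, fa=(0.69, 0.03), r=0.67,
                             dax=(1.3e-3, 0.1e-3), drad=(5.0e-4, 0.5e-4)),
            "control": gpair((0.55, 0.02), (1.8e-3, 0.1e-3), (8.4e-5, 1.5e-5),
                             slope=-2.0e-4, fa=(0.72, 0.03), r=-0.02,
                             dax=(1.4e-3, 0.1e-3), drad=(4.8e-4, 0.5e-4)),
        }),
        "genu": ROIGenParams(groups={
            "patient": gpair((0.58, 0.03), (1.6e-3, 0.1e-3), (6.7e-5, 1.6e-5),
                             slope=-4.3e-4, fa=(0.71, 0.05), r=0.72),
            "control": gpair((0.58, 0.02), (1.7e-3, 0.1e-3), (8.3e-5, 1.7e-5),
                             slope=-2.5e-4, fa=(0.73, 0.03), r=0.03),
        }),
        "body": ROIGenParams(groups={
            "patient": gpair((0.55, 0.03), (1.8e-3, 0.3e-3), (8.0e-5, 2.5e-5),
                             fa=(0.63, 0.06)),
            "control": gpair((0.56, 0.02), (1.7e-3, 0.2e-3), (9.2e-5, 1.7e-5),
                             fa=(0.66, 0.04)),
        }),
        "splenium": ROIGenParams(groups={
            "patient": gpair((0.51, 0.02), (2.0e-3, 0.2e-3), (6.5e-5, 0.1e-5),
                             fa=(0.74, 0.03)),
            "control": gpair((0.51, 0.02), (2.1e-3, 0.2e-3), (7.8e-5, 0.2e-5),
                             fa=(0.76, 0.02)),
        }),
        # gray matter: printed PDI .067/.081 and Mu .66/.67; Du not printed
        "cingulate": ROIGenParams(groups={
            "patient": gpair((0.66, 0.02), (1.2e-3, 0.1e-3), (0.067 * 1.2e-3, 0.014 * 1.2e-3)),
            "control": gpair((0.67, 0.02), (1.2e-3, 0.1e-3), (0.081 * 1.2e-3, 0.011 * 1.2e-3)),
        }),
        "csf": ROIGenParams(groups={}, mono=True),
    }
    return CohortConfig(
        group_sizes={"patient": n_per_group, "control": n_per_group},
        rois=rois,
        age_range=(20.0, 61.0),
        snr=snr,
        snr_reference_roi="cc",
        pdi_coupling=("cingulate", "cc", {"patient": 0.73, "control": 0.70}),
        male_fraction={"patient": 19 / 26, "control": 15 / 27},
        dose={"patient": (400.0, 200.0), "control": None},
    )
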