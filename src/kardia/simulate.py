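"""Synthetic RR cohorts with controlled autonomic structure.

Heartbeats are generated with an integral pulse frequency modulation (IPFM)
model: an instantaneous rate ``(1 + m(t)) / T`` (T = mean RR in seconds) is
integrated and a beat is emitted each time the integral crosses the next
integer.  The modulation ``m(t)`` combines an LF oscillator (sympathetic /
baroreflex band, default 0.1 Hz), an HF oscillator (respiratory band,
default 0.25 Hz) and broadband noise, which gives direct control over the
spectral band structure and attractor complexity of the resulting series.

Two default group profiles emulate the contrast between healthy controls
and fibromyalgia-like dysautonomia: the HC profile has rich two-oscillator
modulation plus noise (higher SDNN/RMSSD/band powers, higher correlation
dimension), while the FM profile is dominated by a single weak oscillator
with little noise (reduced variability, near-periodic dynamics, lower D2).
Clinical covariates (FIQ, NRS, SF-36 PHI, ...) are attached afterwards via
a Gaussian copula calibrated against the *realised* HRV indices, so the
rank-correlation structure the statistics module measures is the structure
that was designed in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .io import RRSeries, SubjectMeta

__all__ = [
    "SubjectSimParams",
    "GroupProfile",
    "CohortSimConfig",
    "simulate_rr",
    "simulate_cohort",
    "attach_clinical",
    "DEFAULT_COPULA_TARGETS",
]

#: integration step for the IPFM integral, seconds
IPFM_STEP_S = 0.005
#: grid rate for the broadband noise component, Hz (covers the HF band)
NOISE_FS = 2.0


@dataclass(frozen=True)
class SubjectSimParams:
    """IPFM parameters for one subject.

    Amplitudes are dimensionless fractions of the mean rate; the invariant
    ``a_lf + a_hf + 3·noise_sd < 1`` keeps the instantaneous rate positive.
    """

    mean_rr: float = 850.0
    a_lf: float = 0.05
    a_hf: float = 0.05
    f_lf: float = 0.1
    f_hf: float = 0.25
    phase_lf: float = 0.0
    phase_hf: float = 0.0
    noise_sd: float = 0.02
    noise_kind: str = "white"
    duration_s: float = 330.0

    def __post_init__(self) -> None:
        if self.a_lf < 0 or self.a_hf < 0 or self.noise_sd < 0:
            raise ValueError("modulation amplitudes must be ≥ 0")
        if self.a_lf + self.a_hf + 3.0 * self.noise_sd >= 1.0:
            raise ValueError(
                "a_lf + a_hf + 3·noise_sd must stay below 1 to keep the "
                "instantaneous rate positive"
            )
        if self.noise_kind not in {"white", "one_over_f"}:
            raise ValueError(f"noise_kind must be 'white' or 'one_over_f', "
                             f"got {self.noise_kind!r}")
        if self.mean_rr <= 0 or self.duration_s <= 0:
            raise ValueError("mean_rr and duration_s must be positive")


@dataclass(frozen=True)
class GroupProfile:
    """Sampling ranges for per-subject IPFM parameters in one group.

    A single latent "autonomic richness" u ~ U(0, 1) per subject
    interpolates the oscillator amplitudes and the broadband noise level
    between their (min, max) ranges, so that variability, band powers and
    attractor complexity rise and fall together within a group — the
    coupling observed between D2 and the linear indices in patients.
    ``jitter`` adds independent relative spread on top of the latent.
    """

    mean_rr: tuple[float, float]
    a_lf: tuple[float, float]
    a_hf: tuple[float, float]
    noise_sd: tuple[float, float]
    noise_kind: str = "white"
    age: tuple[float, float] = (47.7, 12.3)  # mean, sd (years)
    duration_s: float = 330.0
    jitter: float = 0.15

    def draw(self, rng: np.random.Generator) -> tuple[SubjectSimParams, float]:
        u = rng.uniform()

        def interp(lo_hi: tuple[float, float]) -> float:
            lo, hi = lo_hi
            value = lo + u * (hi - lo)
            return float(value * rng.uniform(1 - self.jitter, 1 + self.jitter))

        params = SubjectSimParams(
            mean_rr=rng.uniform(*self.mean_rr),
            a_lf=interp(self.a_lf),
            a_hf=interp(self.a_hf),
            phase_lf=rng.uniform(0, 2 * np.pi),
            phase_hf=rng.uniform(0, 2 * np.pi),
            noise_sd=interp(self.noise_sd),
            noise_kind=self.noise_kind,
            duration_s=self.duration_s,
        )
        age = float(np.clip(rng.normal(*self.age), 20.0, 80.0))
        return params, age


#: default copula targets: (variable a, variable b, target Spearman rho).
#: FIQ is anchored on the realised d2 and grade; pain, physical health and
#: the remaining scales hang off FIQ.
DEFAULT_COPULA_TARGETS: tuple[tuple[str, str, float], ...] = (
    ("d2", "fiq", -0.4567),
    ("grade", "fiq", 0.5058),
    ("fiq", "nrs", 0.6976),
    ("fiq", "sf36_phi", -0.5720),
    ("fiq", "maf", 0.45),
    ("fiq", "sas", 0.35),
    ("fiq", "sds", 0.35),
    ("fiq", "mos", -0.30),
    ("fiq", "wpi", 0.50),
    ("fiq", "ss", 0.45),
    ("fiq", "disease_duration", 0.15),
)

#: default group profiles; chosen once to emulate a healthy two-oscillator
#: autonomic spectrum vs. a fibromyalgia-like impoverished one with a
#: standardized D2 contrast of about 0.65 between groups
DEFAULT_PROFILES: Mapping[str, GroupProfile] = {
    "HC": GroupProfile(
        mean_rr=(750.0, 950.0),
        a_lf=(0.040, 0.085),
        a_hf=(0.040, 0.090),
        noise_sd=(0.0085, 0.050),
        noise_kind="white",
        age=(47.7, 12.3),
    ),
    "FM": GroupProfile(
        mean_rr=(720.0, 920.0),
        a_lf=(0.010, 0.050),
        a_hf=(0.002, 0.030),
        noise_sd=(0.00025, 0.018),
        noise_kind="white",
        age=(50.8, 11.8),
    ),
}


@dataclass(frozen=True)
class CohortSimConfig:
    """Full parameterisation of a synthetic two-group cohort."""

    n_hc: int = 39
    n_fm: int = 85
    profiles: Mapping[str, GroupProfile] = field(
        default_factory=lambda: dict(DEFAULT_PROFILES))
    copula_targets: Sequence[tuple[str, str, float]] = DEFAULT_COPULA_TARGETS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc < 2 or self.n_fm < 2:
            raise ValueError("group sizes must be ≥ 2")
        for a, b, rho in self.copula_targets:
            if not abs(rho) < 1:
                raise ValueError(f"target rho for ({a}, {b}) must satisfy |rho| < 1")


def _noise_track(rng: np.random.Generator, n_grid: int, kind: str,
                 sd: float) -> np.ndarray:
    """Broadband modulation noise on a coarse grid, normalised to ``sd``."""
    z = rng.standard_normal(n_grid)
    if kind == "one_over_f":
        spec = np.fft.rfft(z)
        f = np.fft.rfftfreq(n_grid, d=1.0 / NOISE_FS)
        scale = np.ones_like(f)
        nonzero = f > 0
        scale[nonzero] = 1.0 / np.sqrt(f[nonzero])
        scale[0] = 0.0
        z = np.fft.irfft(spec * scale, n=n_grid)
    z = z - z.mean()
    s = z.std()
    return sd * z / s if s > 0 else np.zeros(n_grid)


def simulate_rr(params: SubjectSimParams, seed: int,
                subject_id: str = "sim") -> RRSeries:
    """Generate one subject's RR series with the IPFM model.

    The modulated rate ``(1 + m(t))/T`` is integrated with a trapezoidal
    rule on a 5-ms grid; beat k occurs where the integral first crosses k,
    located by linear interpolation.  RR_k is the difference of successive
    beat times in ms.  Deterministic for a fixed (params, seed) pair.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, params.duration_s + IPFM_STEP_S, IPFM_STEP_S)
    mod = (
        params.a_lf * np.sin(2 * np.pi * params.f_lf * t + params.phase_lf)
        + params.a_hf * np.sin(2 * np.pi * params.f_hf * t + params.phase_hf)
    )
    if params.noise_sd > 0:
        n_grid = int(np.ceil(params.duration_s * NOISE_FS)) + 2
        track = _noise_track(rng, n_grid, params.noise_kind, params.noise_sd)
        grid_t = np.arange(n_grid) / NOISE_FS
        mod = mod + np.interp(t, grid_t, track)
    else:
        rng.standard_normal(4)  # keep the stream position seed-dependent anyway
    rate = (1.0 + mod) / (params.mean_rr / 1000.0)
    # cumulative trapezoid of the rate = expected beat count by time t
    integral = np.concatenate(
        [[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * IPFM_STEP_S)]
    )
    n_beats = int(np.floor(integral[-1]))
    targets = np.arange(1, n_beats + 1, dtype=float)
    beat_times = np.interp(targets, integral, t)
    intervals_ms = np.diff(np.concatenate([[0.0], beat_times])) * 1000.0
    return RRSeries(intervals=intervals_ms, subject_id=subject_id,
                    meta={"sim_params": params, "seed": seed})


def _subject_seed(master_seed: int, index: int) -> int:
    """Deterministic per-subject seed, independent of generation order."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def simulate_cohort(
    config: CohortSimConfig,
) -> tuple[list[RRSeries], list[SubjectMeta]]:
    """Draw per-subject IPFM parameters and simulate every subject.

    Per-subject seeds are derived from the master seed and the subject
    index, so regenerating with the same config is bit-identical and
    independent of iteration order.  Clinical covariates are *not* attached
    here — they are copula-generated against realised HRV indices by
    :func:`attach_clinical` after the analysis stages have run.
    """
    rng = np.random.default_rng(config.seed)
    series_list: list[RRSeries] = []
    meta_list: list[SubjectMeta] = []
    index = 0
    for group, n in (("HC", config.n_hc), ("FM", config.n_fm)):
        profile = config.profiles[group]
        for i in range(n):
            params, age = profile.draw(rng)
            sid = f"{group}{i + 1:03d}"
            seed = _subject_seed(config.seed, index)
            series_list.append(simulate_rr(params, seed, subject_id=sid))
            sex = "M" if rng.uniform() < 0.18 else "F"  # ~FM sex ratio
            meta_list.append(SubjectMeta(subject_id=sid, group=group,
                                         age=age, sex=sex))
            index += 1
    return series_list, meta_list


def _normal_scores(values: np.ndarray) -> np.ndarray:
    """Map a sample to standard-normal scores via midranks."""
    ranks = sps.rankdata(values, method="average")
    u = (ranks - 0.5) / values.size
    return sps.norm.ppf(u)


def _latent_to_pearson(rho_s: float) -> float:
    """Spearman target → latent Gaussian Pearson correlation."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


_SCALE_MAPPERS = {
    "fiq": lambda u: 100.0 * u,
    "nrs": lambda u: np.round(10.0 * u),
    "sf36_phi": lambda u: 100.0 * u,
    "maf": lambda u: 50.0 * u,
    "sas": lambda u: 20.0 + 60.0 * u,
    "sds": lambda u: 20.0 + 60.0 * u,
    "mos": lambda u: 100.0 * u,
    "wpi": lambda u: np.round(19.0 * u),
    "ss": lambda u: np.round(12.0 * u),
    "disease_duration": lambda u: np.round(30.0 * u**2, 1),
}


def attach_clinical(
    table: pd.DataFrame,
    copula_targets: Sequence[tuple[str, str, float]] = DEFAULT_COPULA_TARGETS,
    seed: int = 0,
) -> pd.DataFrame:
    """Attach clinical covariates with a target Spearman structure.

    The targets form a tree: anchor variables (existing columns of
    ``table``, e.g. ``d2`` and ``grade``) drive generated variables, which
    may in turn drive further generated ones (FIQ drives NRS, SF-36, ...).
    Each generated variable's latent Gaussian is a linear combination of
    its parents' normal scores plus independent noise, with coefficients
    solving the target (latent-Pearson-converted) correlations; latents are
    mapped to their clinical scales by monotone transforms, which preserves
    rank correlations.

    Raises ``ValueError`` naming the offending variable when the requested
    correlations are jointly infeasible (negative residual variance).
    """
    rng = np.random.default_rng(seed)
    out = table.copy()
    n = len(out)
    latents: dict[str, np.ndarray] = {}

    # group targets by generated (child) variable
    children: dict[str, list[tuple[str, float]]] = {}
    order: list[str] = []
    for a, b, rho in copula_targets:
        if a in out.columns or a in children:
            parent, child = a, b
        elif b in out.columns or b in children:
            parent, child = b, a
        else:
            raise ValueError(
                f"anchor variable {a!r} not present in table and not "
                f"generated by an earlier target"
            )
        children.setdefault(child, []).append((parent, rho))
        if child not in order:
            order.append(child)

    def latent_of(name: str) -> np.ndarray:
        if name in latents:
            return latents[name]
        if name not in out.columns:
            raise ValueError(f"anchor variable {name!r} not present in table")
        z = _normal_scores(out[name].to_numpy(dtype=float))
        latents[name] = z
        return z

    for child in order:
        parents = children[child]
        names = [p for p, _ in parents]
        rho_lat = np.array([_latent_to_pearson(r) for _, r in parents])
        z_par = np.column_stack([latent_of(p) for p in names])
        # realised correlation among parents' scores
        sigma_pp = np.corrcoef(z_par, rowvar=False) if len(names) > 1 \
            else np.array([[1.0]])
        try:
            beta = np.linalg.solve(sigma_pp, rho_lat)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                f"copula targets for {child!r} are degenerate: {exc}") from exc
        resid_var = 1.0 - float(rho_lat @ beta)
        if resid_var < 0:
            worst = names[int(np.argmax(np.abs(rho_lat)))]
            raise ValueError(
                f"copula targets infeasible for {child!r}: pair "
                f"({worst!r}, {child!r}) leaves negative residual variance"
            )
        z_child = z_par @ beta + np.sqrt(resid_var) * rng.standard_normal(n)
        # standardise so the monotone scale mapping sees a unit latent
        z_child = (z_child - z_child.mean()) / (z_child.std() or 1.0)
        latents[child] = z_child
        u = sps.norm.cdf(z_child)
        mapper = _SCALE_MAPPERS.get(child, lambda u: u)
        out[child] = mapper(u)
    return out
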