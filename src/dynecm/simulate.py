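"""Synthetic cohort generator: 4D series, network templates, phenotypes.

Generates a complete study — grey-matter probability map, canonical-network
style templates, per-subject phenotypes with CSF biomarkers, and per-subject
4D time series — with the statistical structure the centrality analysis
assumes, so every pipeline stage is testable without restricted data.

Signal model per subject (voxel v, volume t):

    x_v(t) = sum_k  m_k(v) * a_k(t) * s_k(t)  +  w_v * g(t)  +  sigma * eps

where ``m_k`` are smooth spatial templates, ``s_k`` slow network latents,
``a_k(t) = 1 + d_k sin(2 pi t / P + phi)`` a time-varying amplitude whose
modulation depth ``d_k`` controls sliding-window (dynamic) EC variability,
and ``g`` a global latent whose voxel coupling ``w_v`` creates functional
hubs: strongly coupled voxels correlate with everything and receive high
static EC.

Planted group effects, all switchable to zero for null calibration:

* posterior hub coupling reduced in A+  -> lower static EC (posterior);
* frontal hub coupling raised in A+     -> higher static EC (frontal);
* DMN-like (first) template's modulation depth reduced in A+ by
  ``dyn_sd_reduction`` (in units of the cohort depth SD) -> lower dynamic
  EC variability in that network;
* within A+, depth additionally varies with the subject's latent cognitive
  ability with slope ``cognition_interaction_slope`` (negative: A+ with
  good cognition have the lowest variability), creating the amyloid x
  cognition interaction.

Because the depth effects are expressed in depth-SD units, their population
standardized effect on any outcome that is (approximately) linear in depth
equals the nominal parameter.  The truth record additionally stores the
*realized* standardized effects — OLS of the z-scored drawn depths on the
analysis covariates over the exact analysis subset — which is the right
reference when checking recovery at finite n.

Everything is reproducible from ``config.seed``; per-subject series use an
independent child seed per subject index.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd


from .dualreg import TemplateSet
from .io_volumes import AnalysisMask, MaskedSeries, VolumeGeometry, build_mask
from .phenotypes import RBANS_DOMAINS, classify_amyloid_tau, fd_qc

__all__ = [
    "SimulationConfig",
    "SyntheticStudy",
    "make_templates",
    "simulate_cohort",
    "simulate_subject",
    "simulate_study",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate a preclinical-amyloid cohort study: 200 volumes at TR = 2 s on a
    down-scaled 20x20x20 grid (4 mm voxels, ~2900 in-mask voxels), 33.1% A+,
    age ~ N(64.6, 7.01), education ~ N(14.69, 3.79), and group effects in
    the directions reported for preclinical amyloid pathology.  Effect
    magnitudes (0.3 fractional coupling change; 0.35 SD depth reduction;
    -0.45 per-SD cognition slope) sit at the upper end of the 0.2-0.45
    standardized-effect range typical of such cohorts, chosen once so a
    desk-scale n = 200 cohort has adequate power for recovery tests.
    """

    shape: tuple[int, int, int] = (20, 20, 20)
    voxel_size_mm: float = 4.0
    T: int = 200
    tr_seconds: float = 2.0
    n_subjects: int = 200
    n_networks: int = 4
    seed: int = 0

    # planted effects (all zero -> exchangeable null)
    static_ec_decrease: float = 0.3
    static_ec_increase: float = 0.3
    dyn_sd_reduction: float = 0.35
    cognition_interaction_slope: float = -0.45

    # signal architecture
    noise_sd: float = 2.4
    template_amplitude: float = 1.8
    base_coupling: float = 0.3
    hub_coupling: float = 0.8
    depth_base: float = 0.7
    depth_sd_rel: float = 0.35
    other_depth: float = 0.15
    other_period_seconds: tuple[float, ...] = (150.0, 180.0, 210.0)
    mod_period_seconds: float = 500.0
    latent_n_sinusoids: int = 6
    latent_period_range_s: tuple[float, float] = (15.0, 60.0)
    template_sigma_vox: float = 3.0

    # cohort marginals
    a_plus_fraction: float = 0.331
    t_plus_given_aplus: float = 0.45
    t_plus_given_aminus: float = 0.10
    age_mean: float = 64.6
    age_sd: float = 7.01
    female_fraction: float = 0.583
    education_mean: float = 14.69
    education_sd: float = 3.79
    mmse_mean: float = 28.7
    mmse_sd: float = 1.53
    fd_median_mm: float = 0.15
    fd_log_sd: float = 0.35

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape) or self.T < 2 or self.n_subjects < 1:
            raise ValueError("sizes must be positive")
        if not (0 < self.a_plus_fraction < 1):
            raise ValueError("a_plus_fraction must be in (0, 1)")
        for name in (
            "static_ec_decrease",
            "static_ec_increase",
            "dyn_sd_reduction",
            "cognition_interaction_slope",
        ):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"effect {name} must be finite")


# ---------------------------------------------------------------------------
# Geometry, mask, templates, regions


def make_geometry(config: SimulationConfig) -> VolumeGeometry:
    aff = np.diag([config.voxel_size_mm] * 3 + [1.0])
    return VolumeGeometry(shape=config.shape, affine=aff)


def make_gm_map(config: SimulationConfig) -> np.ndarray:
    """Radially tapered grey-matter probability map (spherical cortex stand-in)."""
    shape = np.asarray(config.shape)
    center = (shape - 1) / 2.0
    radius = shape.min() / 2.0 - 0.5
    grids = np.indices(config.shape)
    r = np.sqrt(sum((g - c) ** 2 for g, c in zip(grids, center)))
    return np.clip((radius - r) / 3.0, 0.0, 1.0)


def _sphere_region(mask: AnalysisMask, center: np.ndarray, radius: float) -> np.ndarray:
    d = np.linalg.norm(mask.voxel_indices - center, axis=1)
    return d <= radius


def _hub_centers(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Posterior (low y) and frontal (high y) hub-region centers."""
    shape = np.asarray(config.shape)
    center = (shape - 1) / 2.0
    offset = shape.min() / 2.0 - 4.0
    return (
        center + np.array([0.0, -offset, 0.0]),
        center + np.array([0.0, offset, 0.0]),
    )


def make_templates(config: SimulationConfig, mask: AnalysisMask) -> TemplateSet:
    """K smooth, weakly overlapping Gaussian blobs at deterministic centers.

    Pairwise template correlations stay below 0.3: the blob width shrinks
    automatically when the realized center separation would otherwise make
    neighbouring templates overlap too much.
    """
    K = config.n_networks
    shape = np.asarray(config.shape)
    center = (shape - 1) / 2.0
    idx = mask.voxel_indices
    # Deterministic center placement: candidate points on a sphere well
    # inside the mask (Fibonacci lattice), kept clear of the hub regions so
    # planted static (coupling) effects cannot leak into network outcomes,
    # then greedy farthest-point selection.  No randomness: template
    # geometry is a study-level constant, identical across seeds.
    ring_radius = shape.min() / 2.0 - 4.5
    golden = np.pi * (3.0 - np.sqrt(5.0))
    ii = np.arange(100)
    zz = 1.0 - 2.0 * (ii + 0.5) / 100
    rr = np.sqrt(1.0 - zz**2)
    pts = center + ring_radius * np.column_stack(
        [rr * np.cos(golden * ii), zz, rr * np.sin(golden * ii)]
    )
    post_c, front_c = _hub_centers(config)
    clear = (np.linalg.norm(pts - post_c, axis=1) >= 6.0) & (
        np.linalg.norm(pts - front_c, axis=1) >= 6.0
    )
    cand = pts[clear]
    if len(cand) < K:
        raise ValueError(f"grid too small for {K} templates")
    centers = [cand[0]]
    while len(centers) < K:
        d = np.min(
            np.stack([np.linalg.norm(cand - c, axis=1) for c in centers]), axis=0
        )
        centers.append(cand[int(np.argmax(d))])
    sigma = config.template_sigma_vox
    if K > 1:
        d_min = min(
            np.linalg.norm(a - b) for i, a in enumerate(centers) for b in centers[:i]
        )
        # keep pairwise overlap low: Gaussian blobs at distance d correlate
        # ~exp(-d^2/4 sigma^2); cap sigma so that stays well under 0.3
        sigma = min(sigma, d_min / 2.3)
    maps = np.empty((mask.n_voxels, K))
    for k, c in enumerate(centers):
        d2 = ((idx - c) ** 2).sum(axis=1)
        blob = np.exp(-d2 / (2 * sigma**2))
        blob[blob < 0.05] = 0.0
        maps[:, k] = blob
    names = tuple(
        ["DMN-like"] + [f"network_{k}" for k in range(2, K + 1)]
    )
    return TemplateSet(mask=mask, maps=maps, names=names)


# ---------------------------------------------------------------------------
# Phenotypes


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, dict]:
    """Draw per-subject phenotypes and the hidden generative internals.

    Returns the raw cohort table (the pipeline classifies it itself) and a
    truth record holding every planted quantity: nominal effects, the latent
    cognitive ability, per-subject DMN modulation depths, and the realized
    standardized depth effects on the analysis subset.
    """
    if config.n_subjects < 10:
        raise ValueError("need at least 10 subjects")
    if not (0 <= config.t_plus_given_aplus <= 1 and 0 <= config.t_plus_given_aminus <= 1):
        raise ValueError("infeasible T+ fractions")
    n = config.n_subjects
    rng = np.random.default_rng([config.seed, 11])

    a_pos = rng.random(n) < config.a_plus_fraction
    p_t = np.where(a_pos, config.t_plus_given_aplus, config.t_plus_given_aminus)
    t_pos = rng.random(n) < p_t
    abeta = np.where(a_pos, rng.uniform(550, 990, n), rng.uniform(1010, 1900, n))
    ptau = np.where(t_pos, rng.uniform(28, 60, n), rng.uniform(10, 26, n))

    age = np.clip(rng.normal(config.age_mean, config.age_sd, n), 50, 90)
    sex = (rng.random(n) >= config.female_fraction).astype(int)  # 0=F, 1=M
    education = np.clip(
        rng.normal(config.education_mean, config.education_sd, n), 6, 25
    )
    z_cog = rng.standard_normal(n)
    mmse = np.minimum(
        30.0,
        config.mmse_mean
        + config.mmse_sd * (0.4 * z_cog + np.sqrt(1 - 0.16) * rng.standard_normal(n)),
    )
    loadings = {
        "rbans_attention": 0.7,
        "rbans_language": 0.6,
        "rbans_delayed_memory": 0.8,
        "rbans_immediate_memory": 0.7,
        "rbans_visuoconstructional": 0.6,
    }
    rbans = {
        dom: 100 + 15 * (lam * z_cog + np.sqrt(1 - lam**2) * rng.standard_normal(n))
        for dom, lam in loadings.items()
    }
    mean_fd = config.fd_median_mm * np.exp(rng.normal(0, config.fd_log_sd, n))

    # hidden DMN modulation depth, in depth-SD units around depth_base
    eps = rng.standard_normal(n)
    shift = (
        -config.dyn_sd_reduction + config.cognition_interaction_slope * z_cog
    ) * a_pos
    depth = config.depth_base * (1 + config.depth_sd_rel * (eps + shift))
    depth = np.clip(depth, 0.05, 0.95)

    cohort = pd.DataFrame(
        {
            "subject_id": [f"sub-{i:04d}" for i in range(n)],
            "csf_abeta42": abeta,
            "csf_ptau": ptau,
            "age": age,
            "sex": sex,
            "education": education,
            "mmse": mmse,
            **{dom: rbans[dom] for dom in RBANS_DOMAINS},
            "mean_fd": mean_fd,
        }
    )

    truth = {
        "config": asdict(config),
        "nominal": {
            "static_ec_decrease": config.static_ec_decrease,
            "static_ec_increase": config.static_ec_increase,
            "dyn_sd_reduction": config.dyn_sd_reduction,
            "cognition_interaction_slope": config.cognition_interaction_slope,
        },
        "z_cog": z_cog.tolist(),
        "depth_dmn": depth.tolist(),
        "amyloid_pos_true": a_pos.astype(int).tolist(),
    }
    truth["realized"] = _realized_effects(cohort, depth, config)
    return cohort, truth


def _realized_effects(
    cohort: pd.DataFrame, depth: np.ndarray, config: SimulationConfig
) -> dict:
    """Realized standardized depth effects on the analysis subset.

    OLS of z-scored depths on the same covariate structures the pipeline
    models use, restricted to QC-passing, classifiable, non-A-T+ subjects.
    Computed from generator internals only.
    """
    df = fd_qc(classify_amyloid_tau(cohort)).assign(_depth=depth)
    sub = df[df["qc_pass"] & ~df["unclassifiable"] & ~df["at_excluded"]].copy()
    dz = sub["_depth"].to_numpy()
    sd = dz.std(ddof=1)
    if sd == 0:
        return {"dyn_sd_effect": 0.0, "slope_aplus": 0.0, "slope_aminus": 0.0}
    dz = (dz - dz.mean()) / sd
    a = sub["amyloid_pos"].to_numpy(dtype=float)

    X = np.column_stack(
        [np.ones(len(sub)), a, sub["age"].to_numpy(), sub["sex"].to_numpy(dtype=float)]
    )
    group_beta = float(np.linalg.lstsq(X, dz, rcond=None)[0][1])

    s = sub["rbans_delayed_memory"].to_numpy()
    s = (s - s.mean()) / s.std(ddof=1)
    Xc = np.column_stack(
        [
            np.ones(len(sub)),
            s,
            a,
            s * a,
            sub["age"].to_numpy(),
            sub["sex"].to_numpy(dtype=float),
            sub["education"].to_numpy(),
        ]
    )
    coefs = np.linalg.lstsq(Xc, dz, rcond=None)[0]
    return {
        "dyn_sd_effect": group_beta,
        "slope_aminus": float(coefs[1]),
        "slope_aplus": float(coefs[1] + coefs[3]),
        "interaction": float(coefs[3]),
        "n_analysis": int(len(sub)),
    }


# ---------------------------------------------------------------------------
# Study assembly and per-subject series


@dataclass
class SyntheticStudy:
    """All fixed study objects: geometry, mask, templates, regions, cohort."""

    config: SimulationConfig
    geometry: VolumeGeometry
    gm_map: np.ndarray
    mask: AnalysisMask
    templates: TemplateSet
    posterior_region: np.ndarray  # bool over mask voxels
    frontal_region: np.ndarray
    cohort: pd.DataFrame  # classified + QC'd
    truth: dict = field(repr=False)

    def subject_series(self, subject_index: int) -> MaskedSeries:
        return simulate_subject(self, subject_index)

    def save_truth(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.truth, fh, indent=1)


def simulate_study(config: SimulationConfig) -> SyntheticStudy:
    """Build the complete synthetic study (phenotypes classified and QC'd)."""
    geometry = make_geometry(config)
    gm = make_gm_map(config)
    mask = build_mask(gm, geometry, threshold=0.2)
    templates = make_templates(config, mask)

    post_c, front_c = _hub_centers(config)
    posterior = _sphere_region(mask, post_c, 3.0)
    frontal = _sphere_region(mask, front_c, 3.0)

    raw_cohort, truth = simulate_cohort(config)
    cohort = fd_qc(classify_amyloid_tau(raw_cohort))
    return SyntheticStudy(
        config=config,
        geometry=geometry,
        gm_map=gm,
        mask=mask,
        templates=templates,
        posterior_region=posterior,
        frontal_region=frontal,
        cohort=cohort,
        truth=truth,
    )


def _stable_latent(
    stream: int, t_sec: np.ndarray, config: SimulationConfig
) -> np.ndarray:
    """Band-limited latent with near-constant variance over any 100 s window.

    A sum of sinusoids at fixed phases has deterministic local variance
    (unlike filtered noise, whose window variance fluctuates as chi^2),
    which lets the planted amplitude modulation — not latent luck — control
    window-to-window connectivity changes.  Phases follow a golden-ratio
    sequence per ``stream`` so every latent is a deterministic study-level
    fixture, identical across seeds: the depth -> variability transfer gain
    is then a fixed property of the design rather than a per-study draw.
    """
    lo, hi = config.latent_period_range_s
    m = config.latent_n_sinusoids
    periods = np.exp(np.linspace(np.log(lo), np.log(hi), m))
    j = np.arange(m)
    phases = 2 * np.pi * (((stream * m + j) * 0.6180339887498949) % 1.0)
    x = np.sin(2 * np.pi * t_sec[None, :] / periods[:, None] + phases[:, None]).sum(0)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def simulate_subject(study: SyntheticStudy, subject_index: int) -> MaskedSeries:
    """Generate one subject's 4D series (as a MaskedSeries), seed-reproducible.

    The subject must be classifiable (both CSF biomarkers present): group
    membership shapes the signal.
    """
    config = study.config
    row = study.cohort.iloc[subject_index]
    if bool(row["unclassifiable"]):
        raise ValueError(f"subject {row['subject_id']} is unclassifiable")
    a_plus = bool(row["amyloid_pos"] == 1.0)
    rng = np.random.default_rng([config.seed, 1000 + subject_index])

    n_vox = study.mask.n_voxels
    T, tr = config.T, config.tr_seconds
    K = study.templates.n_networks
    t_sec = np.arange(T) * tr

    depth_dmn = study.truth["depth_dmn"][subject_index]
    # Network latents and the global hub signal are study-level fixtures:
    # every subject receives the same underlying waveforms (as in a shared
    # paradigm), while depths, couplings, and noise are subject-specific.
    # This keeps the gain from modulation depth to window-EC variability
    # consistent across subjects, so the planted depth — not waveform luck —
    # drives between-subject variability differences.
    net_signals = np.empty((K, T))
    for k in range(K):
        s = _stable_latent(k, t_sec, config)
        if k == 0:
            # DMN-like: depth carries the planted effects; waveform time-locked
            depth = float(np.clip(depth_dmn, 0.02, 0.95))
            period, phase = config.mod_period_seconds, 0.0
        else:
            depth = config.other_depth * (
                1 + config.depth_sd_rel * rng.standard_normal()
            )
            depth = float(np.clip(depth, 0.02, 0.95))
            periods = config.other_period_seconds
            period = periods[(k - 1) % len(periods)]
            phase = rng.uniform(0, 2 * np.pi)
        a = 1.0 + depth * np.sin(2 * np.pi * t_sec / period + phase)
        net_signals[k] = a * s

    g = _stable_latent(K, t_sec, config)
    w = np.full(n_vox, config.base_coupling)
    w[study.posterior_region] = config.hub_coupling * (
        1 - config.static_ec_decrease * a_plus
    )
    w[study.frontal_region] = config.hub_coupling * (
        1 + config.static_ec_increase * a_plus
    )

    data = (
        config.template_amplitude * (study.templates.maps @ net_signals)
        + w[:, None] * g[None, :]
        + config.noise_sd * rng.standard_normal((n_vox, T))
    )
    return MaskedSeries(mask=study.mask, data=data, tr_seconds=tr)
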