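"""Seeded synthetic cohorts of two-signature subjects.

The generator emulates the statistical structure a SampEn analysis of
online signatures relies on, so the whole pipeline can be exercised without
clinical data:

* 31 AD / 39 HC subjects by default, two signatures each, five channels at
  125 Hz, with pen-up intervals (pressure exactly 0);
* a per-subject irregularity parameter theta drives the amplitude and
  bandwidth of the stochastic component of every channel; the AD group
  receives lower theta (and fewer strokes), so AD signals carry less
  information content and lower SampEn at small tolerance;
* MMSE is positively and age negatively coupled to theta through a Gaussian
  copula, reproducing the sign structure of the clinical metadata
  correlations while keeping the group/sex marginals on their targets;
* azimuth is nearly constant within and between subjects (an almost
  entirely right-handed population holds the pen at a similar angle), and
  its noise does not depend on theta.

Signatures are built from strokes: each pen-down stroke has a
lognormal-in-time speed profile with a rotating direction; x and y are the
integrated velocity plus theta-scaled broadband noise; pressure is a
per-stroke flat-top envelope with raised-cosine attack and release,
modulated by (1 + theta * smooth noise) while the pen is down;
altitude couples to the normalized vertical velocity.  "Smooth noise" is
white Gaussian noise low-pass filtered with a group-dependent cutoff — the
bandwidth knob of the group difference.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import stats
from scipy.ndimage import gaussian_filter1d
from scipy.signal import windows

from .records import Cohort, RawChannel, SignatureRecord, SubjectRecord


@dataclass
class GroupDemographics:
    """Per-sex marginal targets for one clinical group."""

    n_male: int
    n_female: int
    age_male: tuple[float, float]
    age_female: tuple[float, float]
    mmse_male: tuple[float, float]
    mmse_female: tuple[float, float]
    mmse_bounds: tuple[float, float]  # continuous bounds before integer rounding


#: Demographic targets of the emulated cohort: 31 early-stage AD patients
#: (MMSE > 20) and 39 healthy controls, with the sex split and the per-cell
#: age/MMSE means and standard deviations of the clinical sample.
AD_DEMOGRAPHICS = GroupDemographics(
    n_male=14,
    n_female=17,
    age_male=(81.5, 7.4),
    age_female=(78.2, 6.6),
    mmse_male=(23.1, 3.8),
    mmse_female=(22.5, 4.3),
    mmse_bounds=(20.5, 30.49),
)
HC_DEMOGRAPHICS = GroupDemographics(
    n_male=7,
    n_female=32,
    age_male=(75.5, 6.4),
    age_female=(72.2, 6.4),
    mmse_male=(28.8, 0.7),
    mmse_female=(28.8, 1.1),
    mmse_bounds=(25.5, 30.49),
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    ``theta_*`` set the per-group geometric mean of the irregularity
    parameter (dimensionless noise-to-signal amplitude); ``noise_cutoff_*``
    the low-pass cutoff (Hz) of the smooth noise; ``metadata_link`` the
    copula coefficient beta tying theta to MMSE (+) and age (-);
    ``coupling_altitude_y`` the gain kappa (degrees per unit normalized
    vertical velocity) of the altitude/vertical-movement coupling.
    """

    n_ad: int = 31
    n_hc: int = 39
    seed: int = 0
    sampling_rate: float = 125.0
    duration_range: tuple[float, float] = (1.5, 4.0)
    theta_ad: float = 0.06
    theta_hc: float = 0.12
    theta_sigma: float = 0.22
    noise_cutoff_ad: float = 5.8
    noise_cutoff_hc: float = 7.7
    stroke_count_ad: float = 5.0
    stroke_count_hc: float = 7.0
    coupling_altitude_y: float = 10.0
    azimuth_spread: float = 8.0
    metadata_link: float = 0.6
    within_subject_jitter: float = 0.12
    penup_fraction_range: tuple[float, float] = (0.07, 0.17)
    rhythm_hz: float = 4.0
    rhythm_amplitude: float = 0.3
    xy_noise_scale: float = 0.5
    xy_noise_floor: float = 0.20
    alt_noise_scale: float = 6.0
    alt_noise_floor: float = 0.12
    p_noise_scale: float = 1.0
    tremor_cutoff: float = 8.0
    pressure_level: float = 512.0
    pressure_spread: float = 40.0
    altitude_level: float = 600.0
    azimuth_level: float = 900.0
    vertical_emphasis: float = 1.4
    style_probs_ad: tuple[float, float] = (21 / 31, 10 / 31)
    style_probs_hc: tuple[float, float] = (21 / 39, 18 / 39)
    early_stage: bool = True

    def validate(self) -> None:
        if self.n_ad < 1 or self.n_hc < 1:
            raise ValueError("group counts must be >= 1")
        if self.theta_ad <= 0 or self.theta_hc <= 0 or self.theta_sigma <= 0:
            raise ValueError("theta parameters must be > 0")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be > 0")
        if not 0 <= self.metadata_link <= 1:
            raise ValueError("metadata_link must be in [0, 1]")
        for probs in (self.style_probs_ad, self.style_probs_hc):
            if abs(sum(probs) - 1.0) > 1e-9 or any(p < 0 for p in probs):
                raise ValueError("style probabilities must be nonnegative, sum 1")
        lo, hi = self.duration_range
        if not 0 < lo <= hi:
            raise ValueError("invalid duration_range")

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass
class StrokeParams:
    n_samples: int
    amplitude: float
    log_sigma: float
    direction: float
    angular_velocity: float
    pressure_amp: float


@dataclass
class SignatureLatent:
    """Everything needed to synthesize one signature deterministically."""

    subject_id: str
    instance: int
    theta: float
    noise_cutoff: float
    altitude_base: float
    azimuth_base: float
    azimuth_drift: float
    strokes: list[StrokeParams]
    gap_samples: list[int]
    noise_seed_key: tuple[int, ...]


@dataclass
class SubjectLatentState:
    subject_id: str
    group: str
    index: int
    theta_subject: float
    z_theta: float
    sex: str
    age: float
    mmse: int
    handedness: str
    style: str
    signatures: list[SignatureLatent]


# ---------------------------------------------------------------------------
# Helpers
# ---------------------------------------------------------------------------

def _subject_rng(seed: int, index: int) -> np.random.Generator:
    # counter-based substreams: subject `index` always sees the same stream
    # for a given master seed, regardless of the cohort's total size
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def _smooth_noise(rng: np.random.Generator, n: int, cutoff_hz: float, rate: float) -> np.ndarray:
    """Unit-std Gaussian noise low-pass filtered at ``cutoff_hz``."""
    white = rng.standard_normal(n)
    sigma = rate / (2.0 * np.pi * cutoff_hz)
    smooth = gaussian_filter1d(white, sigma, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _truncnorm_loc(target_mean: float, sd: float, lo: float, hi: float) -> float:
    """Location parameter such that the (lo, hi)-truncated normal with scale
    ``sd`` has mean ``target_mean`` (keeps the emulated marginals on target
    despite the inclusion-criterion truncation)."""
    from scipy.optimize import brentq

    def mean_err(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return stats.truncnorm.mean(a, b, loc=loc, scale=sd) - target_mean

    return float(brentq(mean_err, lo - 10 * sd, hi + 10 * sd, xtol=1e-10))


def link_metadata(
    z_theta: float,
    group: str,
    sex: str,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[float, int]:
    """Draw (age, mmse) coupled to the standardized irregularity z_theta.

    A Gaussian copula with coefficient beta = ``config.metadata_link`` makes
    MMSE stochastically increasing and age stochastically decreasing in
    theta, while the marginals stay on the group/sex targets (MMSE through
    a mean-matched truncated normal, rounded to an integer).
    """
    demo = AD_DEMOGRAPHICS if group == "AD" else HC_DEMOGRAPHICS
    age_mu, age_sd = demo.age_male if sex == "M" else demo.age_female
    mmse_mu, mmse_sd = demo.mmse_male if sex == "M" else demo.mmse_female
    lo, hi = demo.mmse_bounds
    beta = config.metadata_link
    resid = np.sqrt(max(0.0, 1.0 - beta**2))

    w_age = -beta * z_theta + resid * rng.standard_normal()
    age = age_mu + age_sd * w_age

    w_mmse = beta * z_theta + resid * rng.standard_normal()
    loc = _truncnorm_loc(mmse_mu, mmse_sd, lo, hi)
    a, b = (lo - loc) / mmse_sd, (hi - loc) / mmse_sd
    q = stats.norm.cdf(w_mmse)
    q = min(max(q, 1e-12), 1 - 1e-12)
    mmse_cont = float(stats.truncnorm.ppf(q, a, b, loc=loc, scale=mmse_sd))
    return age, int(round(mmse_cont))


def _draw_signature_latent(
    subject_id: str,
    instance: int,
    theta_subject: float,
    group: str,
    index: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    alt_base: float,
    az_base: float,
    n_strokes_override: int | None = None,
) -> SignatureLatent:
    theta = theta_subject * float(
        np.exp(config.within_subject_jitter * rng.standard_normal())
    )
    cutoff = config.noise_cutoff_ad if group == "AD" else config.noise_cutoff_hc
    stroke_mean = config.stroke_count_ad if group == "AD" else config.stroke_count_hc
    duration = rng.uniform(*config.duration_range)
    n = int(round(duration * config.sampling_rate))
    if n_strokes_override is not None:
        k = n_strokes_override
    else:
        k = max(2, int(rng.poisson(stroke_mean)))
    if k > 1:
        penup = rng.uniform(*config.penup_fraction_range)
        n_up = int(round(penup * n))
        n_down = n - n_up
        gap_w = rng.dirichlet(np.full(k - 1, 8.0))
        gap_samples = np.maximum(1, np.round(gap_w * n_up).astype(int)).tolist()
    else:
        n_down = n
        gap_samples = []
    stroke_w = rng.dirichlet(np.full(k, 12.0))
    stroke_samples = np.maximum(10, np.round(stroke_w * n_down).astype(int))
    strokes = [
        StrokeParams(
            n_samples=int(ns),
            amplitude=float(rng.lognormal(0.0, 0.3)),
            log_sigma=float(rng.uniform(0.3, 0.5)),
            direction=float(rng.uniform(0.0, 2.0 * np.pi)),
            angular_velocity=float(rng.normal(0.0, 2.5)),
            pressure_amp=float(
                max(100.0, rng.normal(config.pressure_level, config.pressure_spread))
            ),
        )
        for ns in stroke_samples
    ]
    return SignatureLatent(
        subject_id=subject_id,
        instance=instance,
        theta=theta,
        noise_cutoff=cutoff,
        altitude_base=alt_base,
        azimuth_base=az_base,
        azimuth_drift=float(rng.normal(0.0, 2.0)),
        strokes=strokes,
        gap_samples=gap_samples,
        noise_seed_key=(index, instance, 104729),
    )


def generate_subject_latent(
    config: SimulationConfig, group: str, index: int, within_group_index: int
) -> SubjectLatentState:
    """Latent state of subject ``index`` (deterministic in (config, seed,
    index))."""
    rng = _subject_rng(config.seed, index)
    theta_group = config.theta_ad if group == "AD" else config.theta_hc
    z_theta = float(rng.standard_normal())
    theta_subject = theta_group * float(np.exp(config.theta_sigma * z_theta))

    demo = AD_DEMOGRAPHICS if group == "AD" else HC_DEMOGRAPHICS
    n_group = config.n_ad if group == "AD" else config.n_hc
    # deterministic sex split proportional to the demographic targets
    n_male = int(round(n_group * demo.n_male / (demo.n_male + demo.n_female)))
    sex = "M" if within_group_index < n_male else "F"
    age, mmse = link_metadata(z_theta, group, sex, config, rng)
    handedness = "L" if rng.random() < 1.0 / 70.0 else "R"
    probs = config.style_probs_ad if group == "AD" else config.style_probs_hc
    style = "stylized" if rng.random() < probs[0] else "mixed"

    subject_id = f"{group}{within_group_index + 1:03d}"
    alt_base = float(rng.normal(config.altitude_level, 25.0))
    az_base = float(rng.normal(config.azimuth_level, config.azimuth_spread))
    signatures = [
        _draw_signature_latent(
            subject_id, inst, theta_subject, group, index, config, rng, alt_base, az_base
        )
        for inst in (1, 2)
    ]
    return SubjectLatentState(
        subject_id=subject_id,
        group=group,
        index=index,
        theta_subject=theta_subject,
        z_theta=z_theta,
        sex=sex,
        age=age,
        mmse=mmse,
        handedness=handedness,
        style=style,
        signatures=signatures,
    )


def synthesize_signature(
    latent: SignatureLatent, config: SimulationConfig
) -> SignatureRecord:
    """Render the five raw channels from one signature's latent state."""
    rate = config.sampling_rate
    dt = 1.0 / rate
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=latent.noise_seed_key)
    )
    theta = latent.theta

    vx_parts: list[np.ndarray] = []
    vy_parts: list[np.ndarray] = []
    pressure_parts: list[np.ndarray] = []
    n_strokes = len(latent.strokes)
    for k, sp in enumerate(latent.strokes):
        ns = sp.n_samples
        tau = (np.arange(ns) + 0.5) / ns
        # lognormal-in-time speed bump (peak around 35% of stroke duration)
        log_mu = np.log(0.35)
        speed = (
            sp.amplitude
            / (tau * sp.log_sigma * np.sqrt(2.0 * np.pi))
            * np.exp(-((np.log(tau) - log_mu) ** 2) / (2.0 * sp.log_sigma**2))
        )
        phi = sp.direction + sp.angular_velocity * tau * (ns * dt)
        vx_parts.append(speed * np.cos(phi))
        vy_parts.append(config.vertical_emphasis * speed * np.sin(phi))
        # flat-top pressure envelope with raised-cosine attack/release
        # (Tukey window): grip pressure plateaus mid-stroke, so the
        # theta-scaled modulation acts where template matches concentrate
        pressure_parts.append(sp.pressure_amp * windows.tukey(ns, 0.5))
        if k < n_strokes - 1:
            ng = latent.gap_samples[k]
            # in-air hover: low-amplitude smooth drift of the pen
            hover_amp = 0.1 * sp.amplitude
            vx_parts.append(hover_amp * _smooth_noise(rng, ng, 3.0, rate) * 0.2)
            vy_parts.append(hover_amp * _smooth_noise(rng, ng, 3.0, rate) * 0.2)
            pressure_parts.append(np.zeros(ng))

    vx = np.concatenate(vx_parts)
    vy = np.concatenate(vy_parts)
    pressure_env = np.concatenate(pressure_parts)
    n = vx.size
    pen_down = pressure_env > 0

    x = np.cumsum(vx) * dt
    y = np.cumsum(vy) * dt
    # oscillatory writing rhythm: signatures wave back and forth around the
    # stroke path instead of sweeping monotonically
    t_axis = np.arange(n) * dt
    for arr in (x, y):
        freq = config.rhythm_hz * (1.0 + 0.2 * rng.standard_normal())
        phase = rng.uniform(0.0, 2.0 * np.pi)
        arr += (
            config.rhythm_amplitude
            * np.std(arr)
            * np.sin(2.0 * np.pi * freq * t_axis + phase)
        )
    # every writer carries a theta-independent physiological tremor floor on
    # position; the theta-scaled component is what separates the groups
    if config.xy_noise_floor > 0 or theta > 0:
        for arr in (x, y):
            tremor = config.xy_noise_floor * _smooth_noise(
                rng, n, config.tremor_cutoff, rate
            )
            irregular = theta * _smooth_noise(rng, n, latent.noise_cutoff, rate)
            arr += config.xy_noise_scale * np.std(arr) * (tremor + irregular)

    p = pressure_env.copy()
    if theta > 0:
        p = pressure_env * (
            1.0
            + config.p_noise_scale
            * theta
            * _smooth_noise(rng, n, latent.noise_cutoff, rate)
        )
    p = np.where(pen_down, np.maximum(p, 1.0), 0.0)  # pen-down stays > 0

    vy_sd = np.std(vy)
    vy_norm = vy / vy_sd if vy_sd > 0 else vy
    alt = latent.altitude_base + config.coupling_altitude_y * vy_norm
    if config.alt_noise_floor > 0 or theta > 0:
        alt = alt + config.alt_noise_scale * (
            config.alt_noise_floor * _smooth_noise(rng, n, config.tremor_cutoff, rate)
            + theta * _smooth_noise(rng, n, latent.noise_cutoff, rate)
        )

    az = (
        latent.azimuth_base
        + latent.azimuth_drift * np.linspace(0.0, 1.0, n)
        + 0.8 * _smooth_noise(rng, n, 5.0, rate)
    )

    channels = {
        "x": RawChannel("x", x),
        "y": RawChannel("y", y),
        "p": RawChannel("p", p),
        "Az": RawChannel("Az", az),
        "Alt": RawChannel("Alt", alt),
    }
    return SignatureRecord(
        subject_id=latent.subject_id,
        instance=latent.instance,
        channels=channels,
        sampling_rate=rate,
    )


def generate_cohort(config: SimulationConfig) -> Cohort:
    """Generate the full synthetic cohort (deterministic given config.seed)."""
    config.validate()
    subjects: list[SubjectRecord] = []
    index = 0
    for group, n_group in (("AD", config.n_ad), ("HC", config.n_hc)):
        for g_idx in range(n_group):
            latent = generate_subject_latent(config, group, index, g_idx)
            sigs = [synthesize_signature(sl, config) for sl in latent.signatures]
            subjects.append(
                SubjectRecord(
                    subject_id=latent.subject_id,
                    group=group,
                    age=latent.age,
                    sex=latent.sex,
                    mmse=latent.mmse,
                    handedness=latent.handedness,
                    style=latent.style,
                    signatures=sigs,
                )
            )
            index += 1
    return Cohort(
        subjects,
        provenance=f"sigentropy.simulate config={config.to_json()}",
        early_stage=config.early_stage,
    )
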