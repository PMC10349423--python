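"""Synthetic cohort generator with the generative structure the model assumes.

Everything the pipeline consumes can be produced here: a block panel with
per-block background beta parameters, matched tumor / adjacent-normal
tissue pairs with planted hypermethylated blocks, healthy plasma for
prior fitting, plasma mixtures at chosen (alpha, gamma), in-silico
dilution series, and longitudinal post-surgery cohorts in which the ctDNA
fraction of relapsing patients decays after resection and regrows
exponentially ahead of the relapse date.

Counts are generated exactly as the likelihood assumes: per block draw
the background level b0 ~ Beta(p_j, q_j), mix it with the tissue levels,
draw an overdispersed sequencing depth N, then M ~ Binomial(N, beta).
All randomness flows through a caller-supplied seed, so any cohort is
reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .background_prior import BackgroundPrior, PriorEntry
from .errors import ConstraintError, ValidationError
from .panel_io import BlockCounts, BlockDef, SampleSummary, TissueMethylome


@dataclass(frozen=True)
class SimulationSpec:
    """Panel-level generative parameters.

    Defaults describe a desk-scale stand-in for a targeted hypermethylation
    panel: 1,000 blocks with a hypomethylated background (prior mean mostly
    1-6%), 50 truly tumor-hypermethylated blocks at tissue levels 0.6-0.9,
    and overdispersed depths around 200x per block.
    """

    n_blocks: int = 1000
    n_dmb_true: int = 50
    p_range: tuple[float, float] = (0.5, 2.0)
    q_range: tuple[float, float] = (30.0, 100.0)
    tumor_level_range: tuple[float, float] = (0.6, 0.9)
    normal_noise_sd: float = 0.01
    depth_mean: float = 200.0
    depth_dispersion: float = 10.0  # negative-binomial size; larger = tighter
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_dmb_true > self.n_blocks:
            raise ValidationError("n_dmb_true cannot exceed n_blocks")
        if self.depth_mean < 0:
            raise ValidationError("depth_mean must be >= 0")
        lo, hi = self.tumor_level_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValidationError("tumor_level_range must lie within [0, 1]")


@dataclass(frozen=True)
class LongitudinalSpec:
    """Cohort-level follow-up design and relapse dynamics.

    Plasma draws follow the perioperative A/B/C schedule (pre-surgery,
    day 3, ~1 month) plus quarterly follow-up (F) samples. Relapsing
    patients re-grow ctDNA exponentially with time constant
    ``regrowth_tau_days`` toward ``alpha_relapse`` at the relapse day, so
    signal emerges a few time constants ahead of clinical confirmation.
    The mutation readout (maxAF) is a noisy, attenuated transform of the
    true ctDNA fraction with a reporting floor, emulating the lower
    sensitivity of mutation assays at low burden.
    """

    n_patients: int = 200
    relapse_fraction: float = 0.3
    day_a: int = -3
    day_b: int = 3
    day_c: int = 36
    followup_days: tuple[int, ...] = (90, 180, 270, 360, 450, 540, 630, 720)
    baseline_alpha_range: tuple[float, float] = (0.002, 0.05)  # log-uniform
    alpha_relapse_range: tuple[float, float] = (0.03, 0.15)  # log-uniform
    relapse_day_range: tuple[int, int] = (270, 630)
    surgical_decay_tau_days: float = 7.0
    regrowth_tau_days: float = 90.0
    maxaf_attenuation: float = 0.15  # median maxAF as a fraction of alpha
    maxaf_log_sd: float = 1.2
    maxaf_floor: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.relapse_fraction <= 1.0:
            raise ValidationError("relapse_fraction must be in [0, 1]")
        days = (self.day_a, self.day_b, self.day_c, *self.followup_days)
        if list(days) != sorted(days):
            raise ValidationError("sampling days must be ordered")


@dataclass
class SimulatedPatient:
    """Ground truth and generated data for one simulated patient."""

    patient_id: str
    relapsed: bool
    relapse_day: int | None
    baseline_alpha: float
    samples: list[SampleSummary] = field(default_factory=list)
    counts: list[BlockCounts] = field(default_factory=list)
    true_alpha: dict[str, float] = field(default_factory=dict)
    tumor: TissueMethylome | None = None
    normal: TissueMethylome | None = None


def _rng(spec_seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec_seed, stream]))


def make_block_defs(spec: SimulationSpec) -> list[BlockDef]:
    """Deterministic synthetic block coordinates (plumbing for I/O tests)."""
    return [
        BlockDef(f"b{j:05d}", "chr1", 1000 * j, 1000 * j + 300, 10)
        for j in range(spec.n_blocks)
    ]


def true_background_prior(spec: SimulationSpec) -> BackgroundPrior:
    """The generating per-block Beta(p_j, q_j) background distribution."""
    rng = _rng(spec.seed, 1)
    p = rng.uniform(*spec.p_range, size=spec.n_blocks)
    q = rng.uniform(*spec.q_range, size=spec.n_blocks)
    entries = {
        f"b{j:05d}": PriorEntry(float(p[j]), float(q[j]), 0, "moments")
        for j in range(spec.n_blocks)
    }
    return BackgroundPrior(entries)


def _draw_depths(rng: np.random.Generator, spec: SimulationSpec, size: int) -> np.ndarray:
    """Overdispersed (negative-binomial) per-block depths."""
    if spec.depth_mean == 0:
        return np.zeros(size, dtype=int)
    size_param = spec.depth_dispersion
    p = size_param / (size_param + spec.depth_mean)
    return rng.negative_binomial(size_param, p, size=size)


def simulate_tissue_pair(
    spec: SimulationSpec,
    prior: BackgroundPrior | None = None,
    patient_id: str = "SIM-T",
    stream: int = 2,
) -> tuple[TissueMethylome, TissueMethylome, set[str]]:
    """Matched tumor / adjacent-normal tissue profiles with planted DMBs.

    Normal levels sit near the background prior mean; ``n_dmb_true``
    planted blocks get tumor levels in ``tumor_level_range`` while the
    rest track the normal level up to small noise. Returns the pair plus
    the planted block-id set (ground truth for recovery tests).
    """
    prior = prior or true_background_prior(spec)
    rng = _rng(spec.seed, stream)
    block_ids = [f"b{j:05d}" for j in range(spec.n_blocks)]
    planted = set(
        rng.choice(spec.n_blocks, size=spec.n_dmb_true, replace=False).tolist()
    )
    tumor = TissueMethylome(f"{patient_id}-tumor", "tumor")
    normal = TissueMethylome(f"{patient_id}-normal", "adjacent_normal")
    planted_ids: set[str] = set()
    for j, bid in enumerate(block_ids):
        mean0 = prior[bid].mean
        ln = float(np.clip(mean0 + rng.normal(0.0, spec.normal_noise_sd), 0.0, 1.0))
        if j in planted:
            lt = float(rng.uniform(*spec.tumor_level_range))
            planted_ids.add(bid)
        else:
            lt = float(np.clip(ln + rng.normal(0.0, spec.normal_noise_sd), 0.0, 1.0))
        normal.add(bid, ln, 1000)
        tumor.add(bid, lt, 1000)
    return tumor, normal, planted_ids


def simulate_plasma_mixture(
    alpha: float,
    gamma: float,
    tumor: TissueMethylome,
    normal: TissueMethylome,
    true_prior: BackgroundPrior,
    spec: SimulationSpec,
    rng: np.random.Generator | None = None,
    sample_id: str = "SIM-P",
) -> BlockCounts:
    """One plasma sample from the generative mixture at fixed (alpha, gamma)."""
    if alpha < 0 or gamma < 0 or alpha + gamma >= 1.0:
        raise ConstraintError(f"infeasible (alpha, gamma) = ({alpha}, {gamma})")
    rng = rng if rng is not None else _rng(spec.seed, 3)
    block_ids = list(true_prior.entries)
    p = np.array([true_prior[b].p for b in block_ids])
    q = np.array([true_prior[b].q for b in block_ids])
    bt = np.array([tumor.level(b) if tumor.level(b) is not None else 0.0 for b in block_ids])
    bn = np.array([normal.level(b) if normal.level(b) is not None else 0.0 for b in block_ids])
    b0 = rng.beta(p, q)
    beta = alpha * bt + gamma * bn + (1.0 - alpha - gamma) * b0
    n = _draw_depths(rng, spec, len(block_ids))
    m = rng.binomial(n, beta)
    out = BlockCounts(sample_id)
    for bid, nn, mm in zip(block_ids, n, m):
        out.add(bid, int(nn), int(mm))
    return out


def simulate_healthy_plasma(
    spec: SimulationSpec,
    n_samples: int,
    prior: BackgroundPrior | None = None,
    stream: int = 4,
) -> tuple[list[BlockCounts], BackgroundPrior]:
    """Healthy-donor plasma count tables plus the generating prior."""
    prior = prior or true_background_prior(spec)
    rng = _rng(spec.seed, stream)
    empty_tumor = TissueMethylome("none", "tumor")
    empty_normal = TissueMethylome("none", "adjacent_normal")
    for bid in prior.entries:
        empty_tumor.add(bid, 0.0, 1)
        empty_normal.add(bid, 0.0, 1)
    samples = [
        simulate_plasma_mixture(
            0.0, 0.0, empty_tumor, empty_normal, prior, spec, rng,
            sample_id=f"healthy{i:03d}",
        )
        for i in range(n_samples)
    ]
    return samples, prior


@dataclass
class DilutionSeries:
    """Labelled in-silico dilution samples plus their generative context."""

    tumor: TissueMethylome
    normal: TissueMethylome
    prior: BackgroundPrior
    planted: set[str]
    samples: list[tuple[float, BlockCounts]]  # (true tumor fraction, counts)


def simulate_dilution_series(
    fractions: list[float],
    reps: int,
    spec: SimulationSpec,
) -> DilutionSeries:
    """Replicated plasma mixtures at each tumor fraction (gamma = 0)."""
    prior = true_background_prior(spec)
    tumor, normal, planted = simulate_tissue_pair(spec, prior)
    rng = _rng(spec.seed, 5)
    samples = []
    for frac in fractions:
        for r in range(reps):
            counts = simulate_plasma_mixture(
                frac, 0.0, tumor, normal, prior, spec, rng,
                sample_id=f"dil-{frac:g}-{r:03d}",
            )
            samples.append((frac, counts))
    return DilutionSeries(tumor, normal, prior, planted, samples)


def _alpha_trajectory(
    day: int,
    baseline_alpha: float,
    relapsed: bool,
    relapse_day: int | None,
    alpha_relapse: float,
    lspec: LongitudinalSpec,
) -> float:
    """True ctDNA fraction over the clinical timeline of one patient."""
    if day < 0:
        return baseline_alpha
    if not relapsed:
        return 0.0  # curative resection clears ctDNA
    resid = baseline_alpha * math.exp(-day / lspec.surgical_decay_tau_days)
    assert relapse_day is not None
    regrow = alpha_relapse * math.exp((day - relapse_day) / lspec.regrowth_tau_days)
    alpha = max(resid, regrow if regrow > 1e-6 else 0.0)
    return min(alpha, 0.9)


def simulate_longitudinal_cohort(
    lspec: LongitudinalSpec,
    spec: SimulationSpec,
) -> tuple[list[SimulatedPatient], BackgroundPrior]:
    """Full post-surgical surveillance cohort with ground-truth relapse.

    Each patient gets their own tumor / adjacent-normal pair on a shared
    block panel, a baseline ctDNA fraction, and plasma counts at every
    scheduled day from the alpha trajectory (surgical clearance, then for
    relapsing patients exponential regrowth toward the relapse day).
    Follow-up sampling stops once relapse is clinically confirmed.
    """
    prior = true_background_prior(spec)
    rng = _rng(lspec.seed, 10)
    patients: list[SimulatedPatient] = []
    lo_b, hi_b = lspec.baseline_alpha_range
    lo_r, hi_r = lspec.alpha_relapse_range
    for i in range(lspec.n_patients):
        pid = f"SIM-{i:04d}"
        relapsed = bool(rng.random() < lspec.relapse_fraction)
        relapse_day = (
            int(rng.integers(lspec.relapse_day_range[0], lspec.relapse_day_range[1] + 1))
            if relapsed
            else None
        )
        baseline_alpha = float(np.exp(rng.uniform(np.log(lo_b), np.log(hi_b))))
        alpha_relapse = float(np.exp(rng.uniform(np.log(lo_r), np.log(hi_r))))
        tumor, normal, _ = simulate_tissue_pair(
            spec, prior, patient_id=pid, stream=20 + i
        )
        patient = SimulatedPatient(pid, relapsed, relapse_day, baseline_alpha,
                                   tumor=tumor, normal=normal)
        schedule = [
            ("A", lspec.day_a), ("B", lspec.day_b), ("C", lspec.day_c),
        ] + [("F", d) for d in lspec.followup_days]
        for label, day in schedule:
            if relapsed and relapse_day is not None and day > relapse_day:
                continue
            alpha = _alpha_trajectory(
                day, baseline_alpha, relapsed, relapse_day, alpha_relapse, lspec
            )
            sid = f"{pid}-{label}{day:+04d}"
            counts = simulate_plasma_mixture(
                alpha, 0.0, tumor, normal, prior, spec, rng, sample_id=sid
            )
            latent_af = alpha * lspec.maxaf_attenuation * float(
                np.exp(rng.normal(0.0, lspec.maxaf_log_sd))
            )
            max_af = latent_af if latent_af >= lspec.maxaf_floor else 0.0
            summary = SampleSummary(
                sample_id=sid,
                timepoint_label=label,
                day_from_surgery=day,
                max_af=min(max_af, 1.0),
            )
            patient.samples.append(summary)
            patient.counts.append(counts)
            patient.true_alpha[sid] = alpha
        patients.append(patient)
    return patients, prior
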