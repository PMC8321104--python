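"""Synthetic study-data generators.

Emulates the three inputs of the annotation experiment so the whole
pipeline runs without any restricted data: (1) a cohort with the ten
annotation variables and the liver-fat class structure (none <= 5%,
mild 5-14%, moderate-to-severe >= 14%), with risk-factor distributions
shifted by class so similarity-based annotation has a recoverable signal;
(2) annotator behaviour over triplets — choices whose correctness decays
logistically with triplet difficulty (proxied by the machine annotator's
uncertainty), ordinal stated uncertainty coupled to difficulty, and
durations that fall with triplet ordinal and rise with stated
uncertainty; (3) per-annotator EDA recordings with tonic individual
levels, Gaussian noise, and no ordinal trend by default.

All distribution parameters are config-driven invented defaults with
plausible clinical magnitudes; none are estimates from the real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .datatypes import AnnotationEvent, CohortRecord, EDATimeSeries, Triplet


@dataclass(frozen=True)
class CohortModel:
    """Per-class distributions of the ten annotation variables."""

    size: int = 852
    # class proportions: none, mild, moderate_severe
    proportions: tuple[float, float, float] = (501 / 852, 238 / 852, 113 / 852)
    age_mean: tuple[float, float] = (50.0, 58.0)       # (healthy, steatosis), years
    age_sd: float = 12.0
    alat_log_mean: tuple[float, float] = (-0.9, -0.4)  # ukatal/l, log scale
    alat_log_sd: float = 0.45
    alcohol_scale: tuple[float, float] = (8.0, 16.0)   # exponential mean, g/day
    crp_log_mean: tuple[float, float] = (0.1, 0.7)     # mg/l, log scale
    crp_log_sd: float = 0.8
    ldlch_mean: tuple[float, float] = (3.3, 3.6)       # mmol/l
    ldlch_sd: float = 0.9
    p_beta_blocker: tuple[float, float] = (0.12, 0.28)
    p_diabetes: tuple[float, float] = (0.07, 0.30)
    p_hypertonia: tuple[float, float] = (0.35, 0.65)
    p_male: tuple[float, float] = (0.45, 0.65)
    p_smoke: tuple[tuple[float, float, float], tuple[float, float, float]] = (
        (0.45, 0.35, 0.20),  # never, former, current — healthy
        (0.35, 0.45, 0.20),  # steatosis
    )


@dataclass(frozen=True)
class AnnotatorModel:
    """Behavioural model of the non-expert annotators."""

    n_annotators: int = 29
    # P(correct) = sigmoid(correct_intercept - difficulty_slope * asba_u);
    # calibrated so pooled correctness sits near 0.5 at the default cohort's
    # difficulty distribution, as in the lab study
    correct_intercept: float = 3.1
    difficulty_slope: float = 4.0
    # stated_u = clip(round(uncertainty_intercept + uncertainty_slope*asba_u
    #                       + propensity + noise), 0, 3)
    uncertainty_intercept: float = -1.0
    uncertainty_slope: float = 3.0
    uncertainty_noise_sd: float = 0.7
    propensity_sd: float = 0.5
    # duration(x, t) = baseline + annotator offset - decay*ordinal
    #                  + increment*stated_u + noise
    duration_baseline_s: float = 45.0
    duration_annotator_sd: float = 8.0   # between-annotator speed trait
    duration_decay_s: float = 0.7        # per triplet ordinal
    duration_per_u_s: float = 7.0        # per stated-uncertainty level
    duration_noise_sd: float = 8.0
    duration_floor_s: float = 1.0


@dataclass(frozen=True)
class EDAModel:
    """Tonic-level EDA model; no ordinal trend by default."""

    tonic_mean: float = 2.0      # uS
    tonic_sd: float = 0.5        # between-annotator
    noise_sd: float = 0.15       # within-series
    ordinal_trend: float = 0.0   # uS per triplet ordinal
    sampling_rate_hz: float = 4.0


@dataclass(frozen=True)
class SimulationConfig:
    cohort: CohortModel = field(default_factory=CohortModel)
    annotators: AnnotatorModel = field(default_factory=AnnotatorModel)
    eda: EDAModel = field(default_factory=EDAModel)
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.cohort.proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.eda.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _draw_livfat(rng: np.random.Generator, cls: int) -> float:
    if cls == 0:
        return float(rng.uniform(0.2, 5.0))
    if cls == 1:
        return float(rng.uniform(5.01, 13.99))
    return float(min(14.0 + rng.exponential(8.0), 60.0))


def generate_cohort(cfg: SimulationConfig) -> list[CohortRecord]:
    """Draw a synthetic cohort with class-shifted risk-factor distributions."""
    rng = np.random.default_rng(cfg.seed)
    cm = cfg.cohort
    classes = rng.choice(3, size=cm.size, p=cm.proportions)
    records = []
    for i, cls in enumerate(classes):
        stea = int(cls == 2)
        s = stea  # index into (healthy, steatosis) parameter pairs
        age = float(np.clip(rng.normal(cm.age_mean[s], cm.age_sd), 20, 90))
        alat = float(np.exp(rng.normal(cm.alat_log_mean[s], cm.alat_log_sd)))
        alcohol = float(rng.exponential(cm.alcohol_scale[s]))
        crp = float(np.exp(rng.normal(cm.crp_log_mean[s], cm.crp_log_sd)))
        ldl = float(np.clip(rng.normal(cm.ldlch_mean[s], cm.ldlch_sd), 0.5, 8.0))
        records.append(
            CohortRecord(
                id=f"S{i:04d}",
                age=round(age, 1),
                alat_s=round(alat, 3),
                alcohol_g_day=round(alcohol, 2),
                beta_blocker=int(rng.random() < cm.p_beta_blocker[s]),
                crp_hs=round(crp, 3),
                diabetes=int(rng.random() < cm.p_diabetes[s]),
                hypertonia=int(rng.random() < cm.p_hypertonia[s]),
                ldlch=round(ldl, 2),
                sex="male" if rng.random() < cm.p_male[s] else "female",
                smoke_status=("never", "former", "current")[
                    int(rng.choice(3, p=cm.p_smoke[s]))
                ],
                livfat_per=round(_draw_livfat(rng, int(cls)), 2),
                stea=stea,
            )
        )
    return records


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_annotators(
    triplets: Sequence[Triplet],
    asba_u: Sequence[float],
    cfg: SimulationConfig,
) -> list[AnnotationEvent]:
    """Simulate annotator choices, stated uncertainty and durations.

    ``asba_u`` supplies one difficulty proxy per triplet (by construction
    the machine annotator's own uncertainty score, in [0, 1]).
    """
    if len(asba_u) != len(triplets):
        raise ValueError(
            f"need one difficulty value per triplet: {len(asba_u)} vs {len(triplets)}"
        )
    am = cfg.annotators
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    propensity = rng.normal(0.0, am.propensity_sd, size=am.n_annotators)
    speed_offset = rng.normal(0.0, am.duration_annotator_sd, size=am.n_annotators)
    events = []
    for x in range(am.n_annotators):
        annotator_id = f"A{x + 1:02d}"
        for t, u in zip(triplets, asba_u):
            p_correct = _sigmoid(am.correct_intercept - am.difficulty_slope * float(u))
            correct = rng.random() < p_correct
            wrong = "C" if t.true_label == "A" else "A"
            choice = t.true_label if correct else wrong
            latent = (
                am.uncertainty_intercept
                + am.uncertainty_slope * float(u)
                + propensity[x]
                + rng.normal(0, am.uncertainty_noise_sd)
            )
            stated = int(np.clip(np.floor(latent + 0.5), 0, 3))
            duration = (
                am.duration_baseline_s
                + speed_offset[x]
                - am.duration_decay_s * t.triplet_id
                + am.duration_per_u_s * stated
                + rng.normal(0, am.duration_noise_sd)
            )
            events.append(
                AnnotationEvent(
                    annotator_id=annotator_id,
                    triplet_id=t.triplet_id,
                    choice=choice,
                    stated_u=stated,
                    duration_s=float(max(duration, am.duration_floor_s)),
                )
            )
    return events


def simulate_eda(
    events: Sequence[AnnotationEvent], cfg: SimulationConfig
) -> list[EDATimeSeries]:
    """Simulate one continuous EDA recording per annotator.

    The series spans the summed task durations at the configured sampling
    rate: tonic level + Gaussian noise + optional linear ordinal trend.
    """
    em = cfg.eda
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    by_annotator: dict[str, list[AnnotationEvent]] = {}
    for e in events:
        by_annotator.setdefault(e.annotator_id, []).append(e)
    series = []
    for annotator_id in sorted(by_annotator):
        evs = sorted(by_annotator[annotator_id], key=lambda e: e.triplet_id)
        tonic = max(rng.normal(em.tonic_mean, em.tonic_sd), 0.2)
        dt = 1.0 / em.sampling_rate_hz
        chunks_t, chunks_v = [], []
        start = 0.0
        for ordinal, e in enumerate(evs, start=1):
            ts = np.arange(start, start + e.duration_s, dt)
            level = tonic + em.ordinal_trend * ordinal
            vs = np.maximum(level + rng.normal(0, em.noise_sd, size=ts.size), 0.0)
            chunks_t.append(ts)
            chunks_v.append(vs)
            start += e.duration_s
        series.append(
            EDATimeSeries(
                annotator_id=annotator_id,
                timestamps=np.concatenate(chunks_t),
                values=np.concatenate(chunks_v),
                experiment_start=0.0,
                experiment_end=start,
            )
        )
    return series


def attach_eda_means(
    events: Sequence[AnnotationEvent],
    series: Sequence[EDATimeSeries],
) -> list[AnnotationEvent]:
    """Segment the simulated recordings and write the per-task EDA mean
    back onto each event."""
    from .eda import segment_means

    by_annotator: dict[str, list[AnnotationEvent]] = {}
    for e in events:
        by_annotator.setdefault(e.annotator_id, []).append(e)
    series_map = {s.annotator_id: s for s in series}
    out = []
    for annotator_id, evs in by_annotator.items():
        evs = sorted(evs, key=lambda e: e.triplet_id)
        means = segment_means(
            series_map[annotator_id],
            [e.duration_s for e in evs],
            [e.triplet_id for e in evs],
        )
        for e in evs:
            out.append(
                AnnotationEvent(
                    annotator_id=e.annotator_id,
                    triplet_id=e.triplet_id,
                    choice=e.choice,
                    stated_u=e.stated_u,
                    duration_s=e.duration_s,
                    eda_mean=means[e.triplet_id],
                )
            )
    return out
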