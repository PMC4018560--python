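"""Synthetic resting-state cohorts with planted overlapping communities.

The generator emulates the statistical structure the downstream analysis
assumes: each community has an independent standard-Gaussian latent signal;
a parcel's time series is its coupling constant times the sum of its
communities' latent signals plus Gaussian noise. Designated hub parcels mix
the latent signals of their two communities with weights that alternate
between temporal states in fixed-length blocks; the contrast between the
two states is the subject's *switching amplitude*. Behavioral factor scores
are coupled linearly (with noise) to that amplitude, so planted effects can
be recovered by the association suite.

No hemodynamic forward model, volumetric output, or head-motion time series
is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .graphs import SubjectTimeSeries

#: behavioral score columns, in output order
CONTENT_FACTORS = ["past", "future", "positive", "negative", "social"]
FORM_FACTORS = ["words", "images", "vague"]
COVARIATES = ["age", "gender", "micromovement"]
BEHAVIOR_COLUMNS = ["subject_id", *CONTENT_FACTORS, *FORM_FACTORS, *COVARIATES]


class ConfigurationError(ValueError):
    """Inconsistent simulation configuration."""


def _default_communities() -> list[list[int]]:
    # two communities sharing only the hub parcel 28
    return [list(range(0, 29)), list(range(28, 60))]


def _default_hubs() -> list[tuple[int, int, int]]:
    return [(28, 0, 1)]


@dataclass
class SimulationConfig:
    """Parameters of a synthetic cohort.

    Defaults describe a 50-subject cohort of 60 parcels in two overlapping
    communities with one switching hub, scanned for 847 volumes at
    TR = 0.645 s (11 windows of 77 volumes), with one temporal state per
    window.

    Parameters
    ----------
    communities : list of parcel-index lists (may overlap)
    hub_parcels : list of (parcel, community_a, community_b)
        Each hub must belong to both named communities.
    state_block_length : int
        Timepoints per switching state (piecewise-constant state sequence).
    base_coupling : float in (0, 1)
        Latent-signal weight relative to unit-variance latent processes.
    noise_sd : float >= 0
        Standard deviation of the additive parcel noise.
    coupling_heterogeneity : float >= 0
        Half-range of the deterministic per-parcel coupling spread; nonzero
        values emulate degree heterogeneity (hubs strongly coupled) so that
        top-fraction thresholding retains a stable, hub-containing edge set.
    trait_coupling : float
        Slope linking a subject's switching amplitude to the planted
        behavioral scores.
    behavior_noise_sd : float >= 0
        Noise on the behavioral factor scores.
    switching_amplitudes : optional per-subject array in [0, 1]
        Explicit amplitudes; drawn Uniform(0, 1) when omitted.
    """

    n_subjects: int = 50
    n_parcels: int = 60
    n_timepoints: int = 847
    tr: float = 0.645
    communities: list[list[int]] = field(default_factory=_default_communities)
    hub_parcels: list[tuple[int, int, int]] = field(default_factory=_default_hubs)
    state_block_length: int = 77
    base_coupling: float = 0.8
    noise_sd: float = 0.8
    coupling_heterogeneity: float = 0.25
    trait_coupling: float = 1.0
    behavior_noise_sd: float = 0.5
    switching_amplitudes: list[float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if min(self.n_subjects, self.n_parcels) < 1:
            raise ConfigurationError("need at least one subject and parcel")
        if not 0 < self.base_coupling < 1:
            raise ConfigurationError(
                f"base_coupling must be in (0, 1), got {self.base_coupling}"
            )
        if self.noise_sd < 0 or self.behavior_noise_sd < 0:
            raise ConfigurationError("noise standard deviations must be >= 0")
        if self.state_block_length <= 1:
            raise ConfigurationError("state_block_length must exceed 1")
        if self.n_timepoints < 2 * self.state_block_length:
            raise ConfigurationError(
                "n_timepoints must cover at least two state blocks"
            )
        for comm in self.communities:
            if any(not 0 <= p < self.n_parcels for p in comm):
                raise ConfigurationError(
                    f"community parcel index out of range: {comm}"
                )
        covered = set().union(*map(set, self.communities)) if self.communities else set()
        if covered != set(range(self.n_parcels)):
            missing = sorted(set(range(self.n_parcels)) - covered)
            raise ConfigurationError(
                f"parcels not covered by any community: {missing}"
            )
        for parcel, ca, cb in self.hub_parcels:
            for c in (ca, cb):
                if not 0 <= c < len(self.communities):
                    raise ConfigurationError(f"hub {parcel}: no community {c}")
                if parcel not in self.communities[c]:
                    raise ConfigurationError(
                        f"hub parcel {parcel} is not a member of community {c}"
                    )
        if self.switching_amplitudes is not None:
            amps = np.asarray(self.switching_amplitudes, dtype=float)
            if amps.shape != (self.n_subjects,):
                raise ConfigurationError(
                    "switching_amplitudes must have one value per subject"
                )
            if np.any(amps < 0):
                raise ConfigurationError("switching amplitudes must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["communities"] = [list(c) for c in d.get("communities", [])]
        d["hub_parcels"] = [tuple(h) for h in d.get("hub_parcels", [])]
        return cls(**d)


@dataclass
class PlantedTruth:
    """Ground truth of a simulated cohort."""

    switching_amplitude: np.ndarray            # per subject
    hub_state_sequence: dict[int, np.ndarray]  # hub parcel -> 'A'/'B' per t
    community_map: dict[int, set[int]]         # parcel -> community ids
    behavioral_means: dict[str, float]
    coupling: np.ndarray                       # per-parcel coupling constant


def parcel_coupling(config: SimulationConfig) -> np.ndarray:
    """Deterministic per-parcel coupling constants.

    Spread evenly over ``1 +/- coupling_heterogeneity`` in an interleaved
    index pattern (so every community contains weakly and strongly coupled
    members); hub parcels get the maximal coupling.
    """
    p = config.n_parcels
    h = config.coupling_heterogeneity
    spread = (np.arange(p) * 37 % p) / max(p - 1, 1) * 2.0 - 1.0
    c = 1.0 + h * spread
    for parcel, _, _ in config.hub_parcels:
        c[parcel] = 1.0 + h
    return c


def _state_sequence(config: SimulationConfig) -> np.ndarray:
    """Piecewise-constant A/B labels, blocks of state_block_length, A first."""
    blocks = np.arange(config.n_timepoints) // config.state_block_length
    return np.where(blocks % 2 == 0, "A", "B")


def simulate_timeseries(
    config: SimulationConfig,
) -> tuple[list[SubjectTimeSeries], PlantedTruth]:
    """Generate per-subject parcel time series with planted structure.

    Non-hub parcels: ``c_p * b * sum(latent signals of their communities)
    + noise``. Hub parcels mix their two communities' latent signals with
    state-dependent weights ``(1 - a, a)`` / ``(a, 1 - a)`` where
    ``a = 0.5 * (1 - amplitude)``, scaled by 2 so an amplitude-0 hub is
    statistically identical to a static member of both communities.
    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    communities = config.communities
    n_comm = len(communities)
    if n_comm == 0:
        raise ConfigurationError("need at least one community")
    if config.switching_amplitudes is not None:
        amplitudes = np.asarray(config.switching_amplitudes, dtype=float)
    else:
        amplitudes = rng.uniform(0.0, 1.0, size=config.n_subjects)

    states = _state_sequence(config)
    hub_set = {h[0]: (h[1], h[2]) for h in config.hub_parcels}
    community_map: dict[int, set[int]] = {
        p: {ci for ci, comm in enumerate(communities) if p in comm}
        for p in range(config.n_parcels)
    }
    coupling = parcel_coupling(config)
    b = config.base_coupling

    # per-parcel community loading matrix for non-hub parcels
    loading = np.zeros((config.n_parcels, n_comm))
    for p_idx in range(config.n_parcels):
        if p_idx in hub_set:
            continue
        for ci in community_map[p_idx]:
            loading[p_idx, ci] = coupling[p_idx] * b

    is_a = (states == "A").astype(float)
    subjects = []
    for s in range(config.n_subjects):
        latent = rng.standard_normal((config.n_timepoints, n_comm))
        data = latent @ loading.T
        a = 0.5 * (1.0 - amplitudes[s])
        for parcel, (ca, cb) in hub_set.items():
            w_a = is_a * (1.0 - a) + (1.0 - is_a) * a  # (T,)
            w_b = 1.0 - w_a
            # normalize so the hub's variance matches a static member of
            # both communities (2 b^2 c^2) at every amplitude
            scale = np.sqrt(2.0) / np.sqrt(w_a**2 + w_b**2)
            mix = scale * (w_a * latent[:, ca] + w_b * latent[:, cb])
            data[:, parcel] = coupling[parcel] * b * mix
        if config.noise_sd > 0:
            data = data + rng.normal(
                0.0, config.noise_sd, size=data.shape
            )
        subjects.append(
            SubjectTimeSeries(subject_id=f"sub-{s:03d}", data=data, tr=config.tr)
        )

    truth = PlantedTruth(
        switching_amplitude=amplitudes,
        hub_state_sequence={h: states.copy() for h in hub_set},
        community_map=community_map,
        behavioral_means={c: 0.0 for c in CONTENT_FACTORS + FORM_FACTORS},
        coupling=coupling,
    )
    return subjects, truth


def simulate_behavior(
    truth: PlantedTruth, config: SimulationConfig
) -> pd.DataFrame:
    """Behavioral/covariate table coupled to the planted amplitudes.

    * ``positive = mean - trait_coupling * amplitude + noise``
    * ``past = mean + trait_coupling * amplitude + noise``
    * ``age`` is drawn with a negative linear coupling to amplitude
    * all other scores are independent noise; gender and micro-movement are
      independent of the amplitude so the association suite can isolate
      covariates.

    Deterministic given ``config.seed`` (a separate stream from the time
    series).
    """
    rng = np.random.default_rng([config.seed, 1])
    amp = np.asarray(truth.switching_amplitude, dtype=float)
    n = len(amp)
    tc = config.trait_coupling
    sd = config.behavior_noise_sd
    means = truth.behavioral_means

    table: dict[str, np.ndarray] = {
        "subject_id": np.array([f"sub-{s:03d}" for s in range(n)]),
    }
    for factor in CONTENT_FACTORS + FORM_FACTORS:
        noise = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
        score = means.get(factor, 0.0) + noise
        if factor == "positive":
            score = score - tc * amp
        elif factor == "past":
            score = score + tc * amp
        table[factor] = score
    table["age"] = np.clip(
        45.0 - 15.0 * amp + rng.normal(0.0, 8.0, size=n), 18.0, 85.0
    )
    table["gender"] = rng.integers(0, 2, size=n).astype(float)
    table["micromovement"] = np.abs(rng.normal(0.06, 0.03, size=n))
    return pd.DataFrame(table, columns=BEHAVIOR_COLUMNS)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[list[SubjectTimeSeries], PlantedTruth, pd.DataFrame]:
    """Time series, planted truth, and behavioral table in one call."""
    subjects, truth = simulate_timeseries(config)
    behavior = simulate_behavior(truth, config)
    return subjects, truth, behavior
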