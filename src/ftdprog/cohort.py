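"""Synthetic GENFI-like cohort generation.

Simulates a genetic-FTD observational cohort (C9orf72 / GRN / MAPT mutation
carriers plus non-carrier family controls) with the statistical structure the
downstream analyses assume:

* each subject carries a latent disease stage in [0, 1];
* biomarkers become abnormal in a fixed ground-truth order, biomarker at
  position ``j`` of ``K`` switching from its normal to its abnormal
  distribution once ``latent_stage > j / (K + 1)``;
* lesion and fluid markers (WMH, ventricles, NfL, GFAP) are log-normal with
  abnormality meaning *higher* values, grey-matter volumes are Gaussian
  ICV-normalised fractions with abnormality meaning *lower* values;
* age and sex act as additive confounds on the analysis scale;
* values go missing completely at random at per-biomarker rates patterned on
  real fluid-biomarker availability;
* clinical scores are noisy monotone transforms of the latent stage;
* longitudinal follow-up visits have per-subject annual slopes optionally
  modulated by the standardised baseline value of a predictor biomarker
  (the directional WMH -> subcortical-atrophy coupling).

The latent stage and the ground-truth ordering are generator-internal truth:
analysis modules must never read ``latent_stage``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError

GENOTYPES = ("C9orf72", "GRN", "MAPT", "noncarrier")
STATUSES = ("control", "presymptomatic", "symptomatic")

#: Cohort cell sizes of the full study population (genotype, status) -> N.
TABLE1_GROUP_SIZES: dict[tuple[str, str], int] = {
    ("noncarrier", "control"): 298,
    ("C9orf72", "presymptomatic"): 129,
    ("C9orf72", "symptomatic"): 77,
    ("GRN", "presymptomatic"): 137,
    ("GRN", "symptomatic"): 45,
    ("MAPT", "presymptomatic"): 50,
    ("MAPT", "symptomatic"): 27,
}

#: The nine biomarkers admitted to event-based modelling, in their
#: ground-truth event order (WMH first, then ventricles/NfL, then cortical
#: grey matter, with GFAP late).
DEBM_ORDERING: tuple[str, ...] = (
    "wmh_frontal",
    "wmh_total",
    "wmh_temporal",
    "ventricles",
    "nfl",
    "gm_temporal",
    "gm_frontal",
    "cerebellum",
    "gfap",
)

#: Subcortical volumes reserved for the longitudinal analysis, appended after
#: the nine event-model biomarkers in the default ground-truth cascade.
SUBCORTICAL: tuple[str, ...] = (
    "amygdala",
    "hippocampus",
    "cingulate",
    "insula",
    "thalamus",
    "basal_ganglia",
)

CLINICAL_SCORES: tuple[str, ...] = (
    "cdr_ftld_sob",
    "mmse",
    "tmtb",
    "boston_naming",
    "digit_symbol",
    "verbal_fluency",
)

#: Paired left/right lobar WMH columns used by the regional comparison.
WMH_LOBES: tuple[str, ...] = (
    "wmh_lfrontal",
    "wmh_rfrontal",
    "wmh_ltemporal",
    "wmh_rtemporal",
    "wmh_lparietal",
    "wmh_rparietal",
    "wmh_loccipital",
    "wmh_roccipital",
)

AGE_CENTER = 50.0


@dataclass(frozen=True)
class BiomarkerSpec:
    """Generative and analysis metadata for one biomarker.

    ``normal``/``abnormal`` are (mean, sd) on the *analysis* scale: log10 for
    log-transformed markers, raw for the rest. Stored cohort values are
    back-transformed (``10 ** value``) for log markers so the table looks like
    raw measurements.
    """

    name: str
    direction: str  # 'increase' or 'decrease'
    transform: str  # 'log' or 'identity'
    normal: tuple[float, float]
    abnormal: tuple[float, float]
    age_effect: float = 0.0
    sex_effect: float = 0.0
    missing_rate: float = 0.0
    #: genotypes whose carriers undergo this biomarker's event; None = all.
    event_genotypes: frozenset[str] | None = None


_GRN_ONLY = frozenset({"GRN"})

#: Default biomarker battery. Normal/abnormal separations are 2.3-2.6 sd,
#: consistent with clearly bimodal but overlapping mixtures; WMH events are
#: restricted to GRN carriers, mirroring the genotype specificity of lesion
#: load, while atrophy/fluid events occur in all carriers.
DEFAULT_BIOMARKERS: tuple[BiomarkerSpec, ...] = (
    BiomarkerSpec("wmh_frontal", "increase", "log", (3.10, 0.30), (3.85, 0.30),
                  age_effect=0.010, sex_effect=0.02, event_genotypes=_GRN_ONLY),
    BiomarkerSpec("wmh_total", "increase", "log", (3.45, 0.30), (4.15, 0.30),
                  age_effect=0.010, sex_effect=0.02, event_genotypes=_GRN_ONLY),
    BiomarkerSpec("wmh_temporal", "increase", "log", (2.45, 0.30), (3.15, 0.30),
                  age_effect=0.009, sex_effect=0.02, event_genotypes=_GRN_ONLY),
    BiomarkerSpec("ventricles", "increase", "log", (-1.85, 0.16), (-1.45, 0.16),
                  age_effect=0.006, sex_effect=0.01),
    BiomarkerSpec("nfl", "increase", "log", (0.95, 0.18), (1.42, 0.18),
                  age_effect=0.006, missing_rate=0.21),
    BiomarkerSpec("gm_temporal", "decrease", "identity", (0.0720, 0.0050), (0.0595, 0.0050),
                  age_effect=-1.2e-4, sex_effect=1.0e-3),
    BiomarkerSpec("gm_frontal", "decrease", "identity", (0.1000, 0.0070), (0.0825, 0.0070),
                  age_effect=-1.5e-4, sex_effect=1.5e-3),
    BiomarkerSpec("cerebellum", "decrease", "identity", (0.0740, 0.0050), (0.0625, 0.0050),
                  age_effect=-0.8e-4, sex_effect=1.0e-3),
    BiomarkerSpec("gfap", "increase", "log", (2.20, 0.15), (2.56, 0.15),
                  age_effect=0.005, missing_rate=0.38),
    BiomarkerSpec("amygdala", "decrease", "identity", (0.00110, 0.00010), (0.00086, 0.00010),
                  age_effect=-1.5e-6),
    BiomarkerSpec("hippocampus", "decrease", "identity", (0.00450, 0.00035), (0.00365, 0.00035),
                  age_effect=-7.0e-6),
    BiomarkerSpec("cingulate", "decrease", "identity", (0.00700, 0.00055), (0.00570, 0.00055),
                  age_effect=-8.0e-6),
    BiomarkerSpec("insula", "decrease", "identity", (0.00450, 0.00035), (0.00360, 0.00035),
                  age_effect=-6.0e-6),
    BiomarkerSpec("thalamus", "decrease", "identity", (0.00750, 0.00055), (0.00615, 0.00055),
                  age_effect=-8.0e-6),
    BiomarkerSpec("basal_ganglia", "decrease", "identity", (0.01100, 0.00080), (0.00900, 0.00080),
                  age_effect=-1.0e-5),
)

DEFAULT_ORDERING: tuple[str, ...] = DEBM_ORDERING + SUBCORTICAL


@dataclass(frozen=True)
class StageDistribution:
    """Uniform latent-stage distribution on [low, high] (degenerate allowed)."""

    low: float
    high: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.low == self.high:
            return np.full(n, self.low)
        return rng.uniform(self.low, self.high, n)


#: Controls sit at stage 0; presymptomatic carriers occupy the first half of
#: the cascade (some close to conversion), symptomatic carriers the upper
#: part with overlap into presymptomatic territory.
DEFAULT_STAGE_DISTRIBUTIONS: dict[str, StageDistribution] = {
    "control": StageDistribution(0.0, 0.0),
    "presymptomatic": StageDistribution(0.0, 0.5),
    "symptomatic": StageDistribution(0.4, 1.0),
}


@dataclass(frozen=True)
class CohortConfig:
    group_sizes: dict[tuple[str, str], int] = field(
        default_factory=lambda: dict(TABLE1_GROUP_SIZES))
    biomarkers: tuple[BiomarkerSpec, ...] = DEFAULT_BIOMARKERS
    ground_truth_ordering: tuple[str, ...] = DEFAULT_ORDERING
    stage_distributions: dict[str, StageDistribution] = field(
        default_factory=lambda: dict(DEFAULT_STAGE_DISTRIBUTIONS))
    sex_male_fraction: float = 0.42
    include_lobar_wmh: bool = True
    include_clinical: bool = True
    clinical_missing_rate: float = 0.10
    seed: int = 0

    def biomarker(self, name: str) -> BiomarkerSpec:
        for spec in self.biomarkers:
            if spec.name == name:
                return spec
        raise KeyError(name)

    def validate(self) -> None:
        names = [b.name for b in self.biomarkers]
        if sorted(self.ground_truth_ordering) != sorted(names):
            raise ConfigError(
                "ground_truth_ordering must be a permutation of the biomarker names")
        for (g, s), n in self.group_sizes.items():
            if g not in GENOTYPES or s not in STATUSES:
                raise ConfigError(f"unknown cohort cell ({g}, {s})")
            if n < 0:
                raise ConfigError(f"negative group size for ({g}, {s})")
            if g == "noncarrier" and s != "control":
                raise ConfigError("non-carriers must have status 'control'")
        for b in self.biomarkers:
            if b.direction not in ("increase", "decrease"):
                raise ConfigError(f"{b.name}: direction must be increase/decrease")
            if b.transform not in ("log", "identity"):
                raise ConfigError(f"{b.name}: transform must be log/identity")
            if b.normal[1] < 0 or b.abnormal[1] < 0:
                raise ConfigError(f"{b.name}: negative sd")
            if not 0.0 <= b.missing_rate <= 1.0:
                raise ConfigError(f"{b.name}: missing_rate outside [0, 1]")
            delta = b.abnormal[0] - b.normal[0]
            if b.direction == "increase" and delta <= 0:
                raise ConfigError(f"{b.name}: abnormal mean must exceed normal mean")
            if b.direction == "decrease" and delta >= 0:
                raise ConfigError(f"{b.name}: abnormal mean must lie below normal mean")


def default_cohort_config(seed: int = 0) -> CohortConfig:
    """Full study population: all genotype cells, 15 biomarkers."""
    return CohortConfig(seed=seed)


def debm_cohort_config(seed: int = 0, separation_sd: float | None = None) -> CohortConfig:
    """GRN carriers plus controls (N = 480) with the nine event-model biomarkers.

    ``separation_sd`` optionally rescales every abnormal mean to sit exactly
    that many pooled sds from the normal mean (used by recovery experiments).
    """
    sizes = {
        ("noncarrier", "control"): 298,
        ("GRN", "presymptomatic"): 137,
        ("GRN", "symptomatic"): 45,
    }
    markers = tuple(b for b in DEFAULT_BIOMARKERS if b.name in DEBM_ORDERING)
    if separation_sd is not None:
        markers = tuple(_with_separation(b, separation_sd) for b in markers)
    return CohortConfig(
        group_sizes=sizes,
        biomarkers=markers,
        ground_truth_ordering=DEBM_ORDERING,
        include_lobar_wmh=False,
        seed=seed,
    )


def _with_separation(spec: BiomarkerSpec, separation_sd: float) -> BiomarkerSpec:
    sign = 1.0 if spec.direction == "increase" else -1.0
    mu, sd = spec.normal
    return replace(spec, abnormal=(mu + sign * separation_sd * sd, spec.abnormal[1]))


@dataclass(frozen=True)
class EventOrdering:
    """A permutation of biomarker names plus the cost it achieved (if any)."""

    sequence: tuple[str, ...]
    cost: float | None = None

    def position(self, name: str) -> int:
        return self.sequence.index(name)


def ground_truth(config: CohortConfig) -> EventOrdering:
    """The generator's ground-truth event ordering, for recovery scoring."""
    return EventOrdering(tuple(config.ground_truth_ordering), cost=None)


def _event_threshold(position: int, n_events: int) -> float:
    """Stage threshold of the event at 1-based ``position`` of ``n_events``."""
    return position / (n_events + 1)


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate the baseline (cross-sectional) cohort table.

    Returns one row per subject with ``visit_time = 0``. Missing biomarker
    values are ``NaN``. Identical configs (including seed) give identical
    tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    positions = {name: j + 1 for j, name in enumerate(config.ground_truth_ordering)}
    n_events = len(config.ground_truth_ordering)

    rows: list[dict] = []
    sid = 0
    for (genotype, status), n in sorted(config.group_sizes.items()):
        stage_dist = config.stage_distributions[status]
        stages = stage_dist.sample(n, rng)
        if status == "control":
            ages = rng.normal(47.3, 13.6, n)
            education = rng.normal(14.4, 3.2, n)
        elif status == "presymptomatic":
            ages = rng.normal(46.0, 12.0, n)
            education = rng.normal(14.4, 3.2, n)
        else:
            ages = rng.normal(63.0, 8.5, n)
            education = rng.normal(12.5, 3.5, n)
        ages = np.clip(ages, 20.0, 90.0)
        education = np.clip(education, 5.0, 22.0)
        male = rng.random(n) < config.sex_male_fraction
        for i in range(n):
            sid += 1
            row = {
                "subject_id": f"S{sid:04d}",
                "genotype": genotype,
                "status": status,
                "sex": "male" if male[i] else "female",
                "age": float(ages[i]),
                "education": float(education[i]),
                "visit_time": 0.0,
                "latent_stage": float(stages[i]),
            }
            for spec in config.biomarkers:
                fires = stages[i] > _event_threshold(positions[spec.name], n_events)
                if spec.event_genotypes is not None and genotype not in spec.event_genotypes:
                    fires = False
                mu, sd = spec.abnormal if fires else spec.normal
                value = rng.normal(mu, sd) if sd > 0 else mu
                value += spec.age_effect * (ages[i] - AGE_CENTER)
                value += spec.sex_effect * (1.0 if male[i] else 0.0)
                if spec.transform == "log":
                    value = 10.0 ** value
                if rng.random() < spec.missing_rate:
                    value = np.nan
                row[spec.name] = value
            rows.append(row)

    df = pd.DataFrame(rows)
    if config.include_lobar_wmh:
        _add_lobar_wmh(df, rng)
    if config.include_clinical:
        _add_clinical_scores(df, rng, config.clinical_missing_rate)
    return df


def _add_lobar_wmh(df: pd.DataFrame, rng: np.random.Generator) -> None:
    """Derive left/right lobar WMH columns.

    Frontal and temporal lobes split the corresponding summed WMH marker with
    a near-symmetric random share (so they inherit its event structure);
    parietal and occipital lobes are independent log-normals without disease
    events. The additive total-equals-sum-of-lobes constraint is not enforced;
    no analysis consumes it.
    """
    n = len(df)
    for summed, (left, right) in (
        ("wmh_frontal", ("wmh_lfrontal", "wmh_rfrontal")),
        ("wmh_temporal", ("wmh_ltemporal", "wmh_rtemporal")),
    ):
        share = rng.beta(40.0, 40.0, n)
        df[left] = share * df[summed]
        df[right] = (1.0 - share) * df[summed]
    age = df["age"].to_numpy()
    for col, mu in (
        ("wmh_lparietal", 2.55), ("wmh_rparietal", 2.55),
        ("wmh_loccipital", 2.30), ("wmh_roccipital", 2.30),
    ):
        df[col] = 10.0 ** (rng.normal(mu, 0.30, n) + 0.008 * (age - AGE_CENTER))
    df["wmh_parietal"] = df["wmh_lparietal"] + df["wmh_rparietal"]


def _add_clinical_scores(df: pd.DataFrame, rng: np.random.Generator,
                         missing_rate: float) -> None:
    """Clinical scores as noisy monotone transforms of the latent stage."""
    n = len(df)
    stage = df["latent_stage"].to_numpy()
    scores = {
        "cdr_ftld_sob": np.clip(16.0 * np.maximum(0.0, stage - 0.35)
                                + rng.normal(0, 0.4, n), 0.0, 24.0),
        "mmse": np.clip(29.2 - 8.0 * stage ** 2 + rng.normal(0, 1.0, n), 0.0, 30.0),
        "tmtb": 60.0 + 150.0 * stage + rng.normal(0, 20.0, n),
        "boston_naming": np.clip(28.0 - 10.0 * stage + rng.normal(0, 2.0, n), 0.0, 30.0),
        "digit_symbol": np.clip(55.0 - 25.0 * stage + rng.normal(0, 5.0, n), 0.0, None),
        "verbal_fluency": np.clip(22.0 - 12.0 * stage + rng.normal(0, 3.0, n), 0.0, None),
    }
    for name, values in scores.items():
        mask = rng.random(n) < missing_rate
        values = values.astype(float)
        values[mask] = np.nan
        df[name] = values


# ---------------------------------------------------------------------------
# Longitudinal extension
# ---------------------------------------------------------------------------

#: WMH predictors tested in the cross-lagged analysis.
WMH_PREDICTORS: tuple[str, ...] = ("wmh_total", "wmh_frontal", "wmh_temporal", "wmh_parietal")

#: Default annual drift (z-units/year) of each trajectory marker in carriers.
DEFAULT_BASE_SLOPES: dict[str, float] = {
    **{m: -0.04 for m in SUBCORTICAL},
    **{m: 0.06 for m in WMH_PREDICTORS},
}


def default_couplings() -> dict[tuple[str, str], float]:
    """Forward WMH -> subcortical couplings; all reverse couplings zero."""
    coupling = {(p, r): 0.0 for p in WMH_PREDICTORS for r in SUBCORTICAL}
    coupling.update({(r, p): 0.0 for p in WMH_PREDICTORS for r in SUBCORTICAL})
    for response in ("amygdala", "hippocampus", "cingulate"):
        coupling[("wmh_total", response)] = -0.3
    return coupling


@dataclass(frozen=True)
class LongitudinalConfig:
    n_presymptomatic: int = 70
    n_symptomatic: int = 13
    visits_per_subject: int = 3
    follow_up_interval: float = 1.1
    coupling: dict[tuple[str, str], float] = field(default_factory=default_couplings)
    base_slopes: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BASE_SLOPES))
    noise_sd: float = 0.10
    measurement_noise_sd: float = 0.05
    genotype: str = "GRN"
    seed: int = 0

    @property
    def n_subjects(self) -> int:
        return self.n_presymptomatic + self.n_symptomatic

    def validate(self) -> None:
        if self.visits_per_subject < 2:
            raise ConfigError("visits_per_subject must be at least 2")
        if self.noise_sd < 0 or self.measurement_noise_sd < 0:
            raise ConfigError("noise sds must be non-negative")


def _transform(values: np.ndarray, transform: str) -> np.ndarray:
    return np.log10(values) if transform == "log" else values


def generate_longitudinal(config: LongitudinalConfig,
                          baseline: pd.DataFrame) -> pd.DataFrame:
    """Extend a baseline cohort with follow-up visits for carrier subjects.

    Trajectory markers are the subcortical volumes and the WMH predictors.
    Per subject and marker, the annual slope in z-units is::

        slope = base_slope + sum_p coupling[(p, marker)] * z_p(baseline) + eps

    with ``eps ~ N(0, noise_sd)``; follow-up values are the baseline plus
    ``slope * t`` (converted back to the marker's raw scale) plus measurement
    noise. Standardisation constants are the empirical mean/sd of each
    marker's transformed baseline value over the selected subjects.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    pres = baseline[(baseline.genotype == config.genotype)
                    & (baseline.status == "presymptomatic")]
    sym = baseline[(baseline.genotype == config.genotype)
                   & (baseline.status == "symptomatic")]
    if len(pres) < config.n_presymptomatic or len(sym) < config.n_symptomatic:
        raise ConfigError(
            f"baseline has {len(pres)} presymptomatic / {len(sym)} symptomatic "
            f"{config.genotype} carriers; need "
            f"{config.n_presymptomatic}/{config.n_symptomatic}")
    subjects = pd.concat([pres.head(config.n_presymptomatic),
                          sym.head(config.n_symptomatic)])

    markers = [m for m in config.base_slopes if m in subjects.columns]
    transforms = {m: ("log" if m.startswith("wmh") else "identity") for m in markers}

    tvals = {m: _transform(subjects[m].to_numpy(float), transforms[m]) for m in markers}
    zconst = {m: (np.nanmean(tvals[m]), np.nanstd(tvals[m], ddof=0)) for m in markers}
    zscores = {m: (tvals[m] - zconst[m][0]) / zconst[m][1] if zconst[m][1] > 0
               else np.zeros(len(subjects)) for m in markers}

    n = len(subjects)
    slopes = {}
    for m in markers:
        slope = np.full(n, config.base_slopes.get(m, 0.0))
        for (pred, resp), c in config.coupling.items():
            if resp == m and c != 0.0 and pred in zscores:
                slope = slope + c * np.nan_to_num(zscores[pred])
        if config.noise_sd > 0:
            slope = slope + rng.normal(0, config.noise_sd, n)
        slopes[m] = slope

    visits = [baseline.copy()]
    base_idx = subjects.index.to_numpy()
    for v in range(1, config.visits_per_subject):
        t = v * config.follow_up_interval
        follow = subjects.copy()
        follow["visit_time"] = t
        follow["age"] = follow["age"] + t
        for m in markers:
            mu, sd = zconst[m]
            if sd == 0:
                continue
            meas = (rng.normal(0, config.measurement_noise_sd, n)
                    if config.measurement_noise_sd > 0 else 0.0)
            new_t = tvals[m] + (slopes[m] * t + meas) * sd
            follow[m] = 10.0 ** new_t if transforms[m] == "log" else new_t
        visits.append(follow)

    out = pd.concat(visits, ignore_index=True)
    out.attrs["longitudinal_subjects"] = [baseline.loc[i, "subject_id"] for i in base_idx]
    return out.sort_values(["subject_id", "visit_time"]).reset_index(drop=True)


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write the cohort table; missing values become empty fields."""
    df.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)
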