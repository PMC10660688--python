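"""Synthetic actigraphy, cohort, and liver-biomarker generator with known truth.

Every stage of the pipeline (rhythm estimation, quality filtering, scoring,
survey-weighted association) can be validated by recovering the parameters
this module plants: the minute-level activity mean follows the extended
cosine curve exactly, per-epoch state labels carve out sleep and non-wear
blocks, and abnormal-biomarker status is drawn from a logit model with
configurable quintile log-odds so estimated odds ratios can be compared to
the planted ones.

Reproducibility: one master seed; the per-participant stream is
``np.random.default_rng(np.random.SeedSequence([master_seed, index]))`` so
records are identical however participants are ordered or parallelised.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cosinor import _curve
from .scoring import BIOMARKERS, THRESHOLDS, abnormal_from_level

__all__ = [
    "RhythmTruth",
    "CohortConfig",
    "simulate_actigraphy",
    "simulate_cohort",
    "simulate_biomarkers",
]


@dataclass
class RhythmTruth:
    """Ground-truth rest-activity rhythm for one simulated participant.

    The noiseless mean activity at clock time ``t`` (hours) is
    ``minimum + amplitude * antilogistic(cos(2*pi*(t - acrophase)/24), alpha, beta)``.
    ``sleep_window`` is ``(onset_hour, duration_minutes)``; by default callers
    should centre it on the curve nadir (``acrophase + 12``) so that activity
    during sleep epochs sits near the curve minimum.  ``nonwear_blocks`` is a
    list of ``(day_index, start_minute, length_minutes)``.
    """

    minimum: float = 10.0
    amplitude: float = 100.0
    acrophase: float = 14.0
    alpha: float = 0.0
    beta: float = 8.0
    noise_sd: float = 5.0
    n_days: int = 7
    sleep_window: tuple = (22.0, 480)  # onset hour, duration minutes
    nonwear_blocks: list = field(default_factory=list)

    def __post_init__(self):
        if self.minimum < 0 or self.amplitude < 0 or self.noise_sd < 0:
            raise ValueError("minimum, amplitude and noise_sd must be >= 0")
        if not 0.0 <= self.acrophase < 24.0:
            raise ValueError("acrophase must lie in [0, 24)")
        if not -1.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (-1, 1)")
        if self.beta <= 0:
            raise ValueError("beta must be > 0")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        onset, dur = self.sleep_window
        if not 0 <= dur <= 1440:
            raise ValueError("sleep duration per day must be in [0, 1440] minutes")
        self.sleep_window = (float(onset) % 24.0, int(dur))
        self._validate_blocks()

    def _validate_blocks(self):
        """Reject non-wear blocks that overlap each other or the sleep window."""
        onset_min = int(round(self.sleep_window[0] * 60))
        dur = int(self.sleep_window[1])
        covered = set()
        for day, start, length in self.nonwear_blocks:
            if not (1 <= day <= self.n_days and 0 <= start < 1440 and length > 0):
                raise ValueError(f"invalid non-wear block {(day, start, length)}")
            for m in range(start, start + length):
                key = (day, m % 1440) if m < 1440 else (day + 1, m % 1440)
                if key in covered:
                    raise ValueError("overlapping non-wear blocks")
                covered.add(key)
                rel = (key[1] - onset_min) % 1440
                if rel < dur:
                    raise ValueError("non-wear block overlaps the sleep window")

    def mean_curve(self, t_hours):
        """Noiseless mean activity at clock time ``t_hours``."""
        return _curve(t_hours, self.minimum, self.amplitude, self.acrophase,
                      self.alpha, self.beta)

    @classmethod
    def with_nadir_sleep(cls, sleep_minutes: int = 480, **kwargs) -> "RhythmTruth":
        """Truth whose sleep window is centred on the curve nadir."""
        tmp = cls(**kwargs)
        onset = (tmp.acrophase + 12.0 - sleep_minutes / 120.0) % 24.0
        return cls(sleep_window=(onset, sleep_minutes), **kwargs)


def simulate_actigraphy(truth: RhythmTruth, participant_id, seed: int) -> pd.DataFrame:
    """Simulate a minute-epoch record series for one participant.

    Returns a DataFrame with columns ``participant_id, day_index,
    minute_of_day, activity, state`` and exactly ``1440 * n_days`` rows.
    Activity is the truth's mean curve plus additive Gaussian noise
    (sd ``noise_sd``), clipped at zero; non-wear minutes carry a missing
    activity value.  State labels: ``sleep`` inside the sleep window,
    ``nonwear`` inside non-wear blocks, ``wake`` elsewhere.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
    n = 1440 * truth.n_days
    abs_minute = np.arange(n)
    day = abs_minute // 1440 + 1
    minute = abs_minute % 1440
    t_hours = minute / 60.0

    mean = truth.mean_curve(t_hours)
    activity = mean + rng.normal(0.0, truth.noise_sd, size=n) if truth.noise_sd > 0 \
        else mean.copy()
    activity = np.maximum(activity, 0.0)

    onset_min = int(round(truth.sleep_window[0] * 60))
    sleep = ((minute - onset_min) % 1440) < truth.sleep_window[1]

    nonwear = np.zeros(n, dtype=bool)
    for d, start, length in truth.nonwear_blocks:
        lo = (d - 1) * 1440 + start
        nonwear[lo:lo + length] = True

    state = np.where(nonwear, "nonwear", np.where(sleep, "sleep", "wake"))
    activity = np.where(nonwear, np.nan, activity)

    return pd.DataFrame({
        "participant_id": participant_id,
        "day_index": day.astype(np.int64),
        "minute_of_day": minute.astype(np.int64),
        "activity": activity,
        "state": state,
    })


# ---------------------------------------------------------------------------
# cohort layer
# ---------------------------------------------------------------------------

#: default categorical covariate distributions, loosely matching the marginal
#: frequencies of a US adult examination cohort
DEFAULT_COVARIATES = {
    "gender": {"categories": ["male", "female"], "p": [0.49, 0.51]},
    "race": {"categories": ["nh_white", "nh_black", "hispanic", "other"],
             "p": [0.66, 0.11, 0.15, 0.08]},
    "education": {"categories": ["lt_high_school", "high_school", "some_college",
                                 "college_plus"], "p": [0.15, 0.21, 0.33, 0.31]},
    "income": {"categories": ["lt20k", "20_45k", "45_75k", "75k_plus"],
               "p": [0.16, 0.29, 0.22, 0.33]},
    "marital": {"categories": ["married", "not_married"], "p": [0.58, 0.42]},
    "smoking": {"categories": ["never", "former", "current"],
                "p": [0.56, 0.24, 0.20]},
    "alcohol": {"categories": ["never_former", "light", "moderate", "heavy"],
                "p": [0.30, 0.35, 0.20, 0.15]},
    "bmi_cat": {"categories": ["lt25", "25_30", "30_plus"], "p": [0.30, 0.33, 0.37]},
    "diabetes": {"categories": ["no", "yes"], "p": [0.85, 0.15]},
    "hep_b": {"categories": ["negative", "positive"], "p": [0.95, 0.05]},
    "hep_c": {"categories": ["negative", "positive"], "p": [0.98, 0.02]},
    "hep_e": {"categories": ["negative", "positive"], "p": [0.92, 0.08]},
    "session": {"categories": ["morning", "afternoon", "evening"],
                "p": [0.45, 0.40, 0.15]},
}


@dataclass
class CohortConfig:
    """Configuration of the simulated survey cohort.

    ``true_log_odds`` maps biomarker name -> {quintile (1..5): log-odds
    contrast vs the reference quintile}; ``baseline_prevalence`` maps
    biomarker -> abnormality probability in the reference quintile.
    ``covariate_log_odds`` maps biomarker -> {(covariate, level): log-odds}.
    Weights are lognormal (``weight_sigma`` on the log scale), normalized to
    mean 1 — positive and right-skewed like survey examination weights.
    """

    n_participants: int = 1000
    seed: int = 0
    covariate_distributions: dict = field(default_factory=lambda: DEFAULT_COVARIATES)
    true_log_odds: dict = field(default_factory=dict)
    baseline_prevalence: dict = field(
        default_factory=lambda: {b: 0.08 for b in BIOMARKERS})
    covariate_log_odds: dict = field(default_factory=dict)
    weight_sigma: float = 0.5
    # eligibility-structure rates (fractions of the generated table)
    frac_under_20: float = 0.10
    frac_80_plus: float = 0.05
    pregnancy_rate: float = 0.02
    frac_no_actigraphy: float = 0.10
    frac_few_valid_days: float = 0.08
    frac_missing_biomarkers: float = 0.03
    # rhythm-truth population spread
    rhythm_population: dict = field(default_factory=lambda: {
        "minimum": (8.0, 14.0), "amplitude": (40.0, 160.0),
        "acrophase": (12.0, 16.0), "alpha": (-0.3, 0.3), "beta": (4.0, 12.0),
        "noise_sd": (3.0, 8.0)})

    def __post_init__(self):
        if self.n_participants < 0:
            raise ValueError("n_participants must be >= 0")
        for b, p in self.baseline_prevalence.items():
            if not 0.0 < p < 1.0:
                raise ValueError(f"baseline prevalence for {b} must be in (0, 1)")
        for b in self.true_log_odds:
            if b not in BIOMARKERS:
                raise ValueError(f"unknown biomarker in true_log_odds: {b!r}")
        if self.weight_sigma < 0:
            raise ValueError("weight_sigma must be >= 0")


def _participant_rng(master_seed: int, index: int) -> np.random.Generator:
    """Documented seed-splitting rule: SeedSequence([master, 1 + index])."""
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), 1 + index]))


def simulate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Simulate the participant table: demographics, weights, eligibility.

    One row per participant, with covariates drawn from the configured
    distributions, positive survey weights, rhythm-truth parameters for the
    actigraphy layer, a continuous latent rhythmicity exposure, and the flags
    (age, pregnancy, actigraphy availability, valid days, biomarker
    availability) the exclusion cascade consumes.
    """
    if config.n_participants < 0:
        raise ValueError("n_participants must be >= 0")
    n = config.n_participants
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    cols: dict = {"participant_id": np.arange(1, n + 1)}

    # age structure: a slab of minors, a slab top-coded at 80, adults uniform
    u = rng.random(n)
    age = np.empty(n)
    minors = u < config.frac_under_20
    elders = u > 1.0 - config.frac_80_plus
    adults = ~minors & ~elders
    age[minors] = rng.integers(3, 20, size=int(minors.sum()))
    age[elders] = 80
    age[adults] = rng.integers(20, 80, size=int(adults.sum()))
    cols["age"] = age

    for name, spec in config.covariate_distributions.items():
        cats = np.asarray(spec["categories"], dtype=object)
        p = np.asarray(spec["p"], dtype=float)
        cols[name] = cats[rng.choice(len(cats), size=n, p=p / p.sum())]

    female = cols.get("gender", np.array(["female"] * n)) == "female"
    childbearing = female & (age >= 20) & (age < 45)
    pregnant = np.zeros(n, dtype=bool)
    if config.pregnancy_rate > 0 and childbearing.any():
        # rate is relative to the whole table; concentrate it where eligible
        p_preg = min(config.pregnancy_rate * n / max(childbearing.sum(), 1), 1.0)
        pregnant[childbearing] = rng.random(int(childbearing.sum())) < p_preg
    cols["pregnant"] = pregnant

    cols["has_actigraphy"] = rng.random(n) >= config.frac_no_actigraphy
    n_valid = np.where(rng.random(n) < config.frac_few_valid_days,
                       rng.integers(0, 4, size=n), rng.integers(4, 8, size=n))
    n_valid = np.where(cols["has_actigraphy"], n_valid, 0)
    cols["n_valid_days"] = n_valid
    cols["has_biomarkers"] = rng.random(n) >= config.frac_missing_biomarkers

    w = rng.lognormal(0.0, config.weight_sigma, size=n) if config.weight_sigma > 0 \
        else np.ones(n)
    cols["weight"] = w / w.mean() if n else w

    for pname, (lo, hi) in config.rhythm_population.items():
        cols[f"true_{pname}"] = rng.uniform(lo, hi, size=n)

    # latent rhythmicity exposure (F-like): amplitude-to-noise driven
    cols["exposure"] = (cols["true_amplitude"] / cols["true_noise_sd"]
                        * np.exp(rng.normal(0.0, 0.15, size=n)))

    df = pd.DataFrame(cols)
    if n:
        ranks = df["exposure"].rank(method="first")
        df["exposure_quintile"] = pd.qcut(ranks, 5, labels=False).astype(int) + 1
    else:
        df["exposure_quintile"] = pd.Series(dtype=int)
    return df


def simulate_participant_epochs(cohort_row: pd.Series, master_seed: int) -> pd.DataFrame:
    """Minute epochs for one cohort row, using its planted rhythm truth."""
    truth = RhythmTruth.with_nadir_sleep(
        minimum=float(cohort_row["true_minimum"]),
        amplitude=float(cohort_row["true_amplitude"]),
        acrophase=float(cohort_row["true_acrophase"]),
        alpha=float(cohort_row["true_alpha"]),
        beta=float(cohort_row["true_beta"]),
        noise_sd=float(cohort_row["true_noise_sd"]),
    )
    idx = int(cohort_row["participant_id"])
    rng_seed = np.random.SeedSequence([int(master_seed), 1 + idx]).generate_state(1)[0]
    return simulate_actigraphy(truth, idx, int(rng_seed % (2 ** 31)))


_LEVEL_SCALES = {"ALT": 0.45, "AST": 0.35, "ALP": 0.30, "GGT": 0.60,
                 "albumin": 0.08, "bilirubin": 0.35}


def simulate_biomarkers(cohort: pd.DataFrame, config: CohortConfig,
                        seed: int) -> pd.DataFrame:
    """Draw abnormal statuses from the configured logit model, then levels.

    Abnormal status for biomarker ``b`` is Bernoulli with
    ``logit(p) = logit(baseline_prevalence[b]) + true_log_odds[b][quintile]
    + covariate effects``.  Continuous levels are then sampled on the correct
    side of the sex-specific clinical cut-off, so applying the thresholds to
    the levels reproduces the drawn status exactly.
    """
    for b in config.true_log_odds:
        if b not in BIOMARKERS:
            raise ValueError(f"unknown biomarker in true_log_odds: {b!r}")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))
    n = len(cohort)
    out = pd.DataFrame({"participant_id": cohort["participant_id"].to_numpy(),
                        "sex": cohort["gender"].to_numpy()})
    male = out["sex"].to_numpy() == "male"
    quintile = cohort["exposure_quintile"].to_numpy()

    for b in BIOMARKERS:
        base = config.baseline_prevalence.get(b, 0.08)
        eta = np.full(n, np.log(base / (1.0 - base)))
        for q, lo in config.true_log_odds.get(b, {}).items():
            eta = eta + np.where(quintile == int(q), float(lo), 0.0)
        for (cov, level), lo in config.covariate_log_odds.get(b, {}).items():
            eta = eta + np.where(cohort[cov].to_numpy() == level, float(lo), 0.0)
        abnormal = rng.random(n) < 1.0 / (1.0 + np.exp(-eta))

        cut = np.where(male, THRESHOLDS[b]["male"][1], THRESHOLDS[b]["female"][1])
        direction = THRESHOLDS[b]["male"][0]  # 'above' or 'below', sex-invariant
        scale = _LEVEL_SCALES[b]
        mag = rng.exponential(scale, size=n)
        if direction == "above":
            # abnormal: strictly above the cut; normal: at or below it
            level = np.where(abnormal, cut * np.exp(np.maximum(mag, 1e-9)),
                             cut * np.exp(-mag))
        else:
            level = np.where(abnormal, cut * np.exp(-np.maximum(mag, 1e-9)),
                             cut * np.exp(mag))
        out[b] = np.round(level, 4)
        # rounding must not flip status across the strict cut-off
        flipped = np.array([abnormal_from_level(b, v, "male" if m else "female")
                            for v, m in zip(out[b], male)]) != abnormal
        out.loc[flipped, b] = level[flipped]
        out[f"{b}_abnormal_true"] = abnormal
    return out
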