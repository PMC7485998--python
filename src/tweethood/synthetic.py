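"""Synthetic study generator: zones, tweet streams, training corpus, population.

Everything the pipeline consumes can be generated here with known ground
truth: rectangular zone polygons, per-zone tweet streams whose category
mixture follows configurable true rates, a labeled sentiment corpus, zone
covariates, and an individual-level population whose BMI and binary
outcomes follow configurable zone-tertile effects.  Tweet text is assembled
from templates so the true category of every tweet is knowable; decoy
templates exercise the contextual exclusion rules ("running late",
spectator verbs, team sports without "play").

Two BMI regimes are supported, because a normally distributed BMI and an
independently drawn log-link obesity indicator cannot both hold while
obesity must equal BMI >= 30:

* ``bmi_mode="linear"`` (default) — BMI carries the configured tertile
  effects plus Gaussian noise; obesity is whatever BMI >= 30 implies, and
  the obesity channel may not carry effects.
* ``bmi_mode="obesity_coupled"`` — obesity is Bernoulli with a log-link
  probability (so the modified-Poisson estimand equals the configured
  prevalence ratio exactly), and BMI is built from the same latent uniform
  so that BMI >= 30 coincides with the obesity draw individual by
  individual; BMI tertile effects must be zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy.special import ndtri

from .classify import Tweet
from .geo import CHARACTERISTICS, Zone, tertile_cut

__all__ = [
    "ScenarioConfig",
    "BinaryChannel",
    "PhraseBank",
    "ConfigError",
    "gen_zone_grid",
    "gen_zone_rates",
    "true_exposures",
    "gen_zone_covariates",
    "gen_tweets",
    "gen_training_corpus",
    "gen_population",
    "default_phrase_banks",
    "subcohort_scenario",
    "full_cohort_scenario",
]


class ConfigError(ValueError):
    """Raised when a scenario configuration is internally inconsistent."""


class BinaryChannel(BaseModel):
    """Generating model for one binary outcome.

    Probability is log-linear: baseline prevalence (tertile 1, covariate
    reference) times exp of the tertile contrasts and covariate effects.
    """

    characteristic: str = "happy"
    baseline_prevalence: float = Field(gt=0.0, lt=1.0)
    log_pr_tertile2: float = 0.0
    log_pr_tertile3: float = 0.0


class ScenarioConfig(BaseModel):
    """Full specification of one synthetic study scenario."""

    n_zones: int = Field(default=1384, gt=0)
    n_individuals: int = Field(default=17048, gt=0)
    seed: int = 0

    # tweet stream
    tweets_per_zone: float = Field(default=200.0, gt=0.0)
    tweets_dispersion: float = Field(default=5.0, gt=0.0)  # negative-binomial size
    duplicate_rate: float = Field(default=0.02, ge=0.0, lt=1.0)
    jobpost_rate: float = Field(default=0.01, ge=0.0, lt=1.0)
    decoy_rate: float = Field(default=0.005, ge=0.0, lt=1.0)

    # per-zone true category rates: beta-distributed unless given explicitly
    happy_rate_mean: float = 0.19
    happy_rate_sd: float = 0.05
    pa_rate_mean: float = 0.022
    pa_rate_sd: float = 0.015
    healthy_food_rate_mean: float = 0.010
    healthy_food_rate_sd: float = 0.007
    fast_food_rate_mean: float = 0.003
    fast_food_rate_sd: float = 0.002
    other_food_rate_mean: float = 0.037
    other_food_rate_sd: float = 0.015
    true_happy_rates: Optional[list[float]] = None
    true_pa_rates: Optional[list[float]] = None
    true_healthy_food_rates: Optional[list[float]] = None
    true_fast_food_rates: Optional[list[float]] = None
    true_other_food_rates: Optional[list[float]] = None

    # outcome generation
    bmi_mode: Literal["linear", "obesity_coupled"] = "linear"
    bmi_baseline: float = 29.1
    bmi_noise_sd: float = Field(default=6.0, ge=0.0)
    bmi_characteristic: str = "happy"
    effect_bmi_tertile2: float = 0.0
    effect_bmi_tertile3: float = 0.0
    binary_channels: dict[str, BinaryChannel] = Field(default_factory=dict)

    # covariate effects: additive on BMI, log scale for binary outcomes
    covariate_effects_bmi: dict[str, float] = Field(
        default_factory=lambda: {
            "age_per_year": 0.03,
            "female": 0.6,
            "race_black": 1.0,
            "race_hispanic": 0.4,
            "race_other": -1.2,
            "income_per_band": -0.25,
            "zone_pct_white_per_pct": -0.01,
            "zone_log_income": -0.5,
        }
    )
    covariate_log_effects: dict[str, float] = Field(
        default_factory=lambda: {
            "age_per_year": 0.004,
            "female": -0.05,
            "race_black": 0.08,
            "race_hispanic": 0.03,
            "race_other": 0.0,
            "income_per_band": -0.02,
            "zone_pct_white_per_pct": -0.001,
            "zone_log_income": -0.05,
        }
    )

    weight_lognorm_sd: float = Field(default=0.5, ge=0.0)

    @model_validator(mode="after")
    def _validate(self) -> "ScenarioConfig":
        for name in ("true_happy_rates", "true_pa_rates", "true_healthy_food_rates",
                     "true_fast_food_rates", "true_other_food_rates"):
            rates = getattr(self, name)
            if rates is not None:
                if len(rates) != self.n_zones:
                    raise ConfigError(f"{name} must have n_zones={self.n_zones} entries")
                if any(not 0.0 <= r <= 1.0 for r in rates):
                    raise ConfigError(f"{name} entries must lie in [0, 1]")
        for key in self.binary_channels:
            if key not in ("obesity", "hypertension", "diabetes"):
                raise ConfigError(f"unknown binary outcome channel {key!r}")
        for key, ch in self.binary_channels.items():
            if ch.characteristic not in CHARACTERISTICS:
                raise ConfigError(f"unknown characteristic {ch.characteristic!r} for {key}")
            worst = self._worst_case_log_factor(ch)
            p_max = ch.baseline_prevalence * math.exp(worst)
            if p_max > 1.0:
                raise ConfigError(
                    f"{key}: worst-case probability {p_max:.3f} exceeds 1 "
                    f"(baseline {ch.baseline_prevalence}, max log factor {worst:.3f})"
                )
        if self.bmi_mode == "linear":
            ob = self.binary_channels.get("obesity")
            if ob is not None and (ob.log_pr_tertile2 != 0.0 or ob.log_pr_tertile3 != 0.0):
                raise ConfigError(
                    "bmi_mode='linear' derives obesity from BMI; the obesity "
                    "channel cannot carry tertile effects (use 'obesity_coupled')"
                )
        else:
            if self.effect_bmi_tertile2 != 0.0 or self.effect_bmi_tertile3 != 0.0:
                raise ConfigError(
                    "bmi_mode='obesity_coupled' slaves BMI to the obesity draw; "
                    "BMI tertile effects must be zero"
                )
            if "obesity" not in self.binary_channels:
                raise ConfigError("bmi_mode='obesity_coupled' requires an obesity channel")
        return self

    def _worst_case_log_factor(self, ch: BinaryChannel) -> float:
        e = self.covariate_log_effects
        worst = max(0.0, ch.log_pr_tertile2, ch.log_pr_tertile3)
        a = e.get("age_per_year", 0.0)
        worst += max(a * (AGE_MAX - AGE_CENTER), a * (AGE_MIN - AGE_CENTER))
        worst += max(0.0, e.get("female", 0.0))
        worst += max(0.0, e.get("race_black", 0.0), e.get("race_hispanic", 0.0), e.get("race_other", 0.0))
        b = e.get("income_per_band", 0.0)
        worst += max(b * 2, -b * 2)
        zw = e.get("zone_pct_white_per_pct", 0.0)
        worst += max(zw * (PCT_WHITE_MAX - PCT_WHITE_CENTER), zw * (PCT_WHITE_MIN - PCT_WHITE_CENTER))
        zi = e.get("zone_log_income", 0.0)
        worst += abs(zi) * LOG_INCOME_HALFRANGE
        return worst


AGE_MIN, AGE_MAX, AGE_CENTER = 20.0, 80.0, 47.0
PCT_WHITE_MIN, PCT_WHITE_MAX, PCT_WHITE_CENTER = 20.0, 95.0, 60.0
LOG_INCOME_CENTER = math.log(55000.0)
LOG_INCOME_HALFRANGE = 1.1  # incomes kept within e^±1.1 of the center


# -- phrase banks ---------------------------------------------------------


@dataclass(frozen=True)
class PhraseBank:
    """Templates used to assemble tweets of one ground-truth category."""

    category: str
    templates: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.templates:
            raise ConfigError(f"empty phrase bank for category {self.category!r}")


_FILLERS = (
    "near the library", "on fifth street", "by the river", "after the meeting",
    "before noon", "on the west side", "this evening", "over the weekend",
    "in the neighborhood", "around the corner", "by the station", "this afternoon",
    "later tonight", "downtown", "with the crew", "on my way home",
)

_BANKS = {
    "happy": (
        "i love this so much", "feeling so blessed and happy today",
        "what an amazing wonderful day", "best day ever with my favorite people",
        "so excited and grateful for everything", "this is fantastic i am thrilled",
        "pure joy and laughter with friends", "celebrating great news",
        "happiest moment of my year", "smiling so big right now",
        "wonderful evening full of love", "so proud and delighted today",
    ),
    # the not-happy banks deliberately share the happy bank's function-word
    # profile (and/for/so/with/my/this/today) so only sentiment words separate
    # the classes — otherwise stopwords become spurious sentiment evidence
    "unhappy": (
        "i hate this awful day and everything about it",
        "feeling terrible and sad about my whole day",
        "worst experience ever and i am so angry",
        "this is horrible and i am so miserable",
        "so frustrated and upset with everything right now",
        "everything is going wrong for me today",
        "annoyed and exhausted by this mess again",
        "such a disappointing and gloomy evening for us",
    ),
    "neutral": (
        "the bus arrived at the main stop and waited",
        "meeting moved to tuesday for the whole team",
        "picked up my package and the mail from the office",
        "forecast says clouds and rain for tomorrow",
        "finished reading chapter five and started six",
        "traffic on the highway was slow again today",
        "printer in the office needs toner and paper",
        "new episode comes out friday for everyone",
    ),
    "healthy_food": (
        "eating a kale salad for lunch", "cooked broccoli and brown rice",
        "collard greens are so delicious", "snacking on almonds and blueberries",
        "grilled chicken with spinach for dinner", "made a sweet potato and quinoa bowl",
        "turkey and tomatoes on my plate", "green beans with roast beef for supper",
        "fresh smoothie with banana and strawberries", "greek yogurt and oatmeal this morning",
    ),
    "fast_food": (
        "just left pizzahut with my mother", "taco bell with the crew",
        "waiting in the chipotle line", "grabbed a big mac at mcdonalds",
        "starbucks frappuccino break", "burger king whopper for lunch",
        "kfc and fries tonight", "dunkin stop before work",
    ),
    "other_food": (
        "pizza night with the family", "pasta and garlic bread for dinner",
        "ice cream cone by the pier", "coffee and a donut this morning",
        "sushi date tonight", "bacon and pancakes for breakfast",
        "chocolate cake for the birthday", "tacos from the corner stand",
    ),
    "physical_activity": (
        "gotta get up early for a workout", "just finished running six miles",
        "a fun seven mile hike this weekend", "yoga session at sunrise",
        "heavy squats and deadlift at the gym", "morning swim at the pool",
        "bike ride along the river trail", "crossfit class killed me today",
        "playing basketball with my brother", "played soccer at the park",
        "zumba class tonight was fun", "treadmill and stretching before work",
    ),
    "pa_decoy": (
        "running late to work again", "never walk away from family",
        "watched the basketball game last night", "watching football with my dad",
        "home run derby highlights", "attending the hockey match tonight",
        "running out of patience today", "watch the soccer match with me",
    ),
    "jobpost": (
        "we are growing apply today", "new opening at the downtown branch",
        "come join our team this fall",
    ),
}


def default_phrase_banks() -> dict[str, PhraseBank]:
    """Packaged template banks covering every tweet category."""
    return {cat: PhraseBank(category=cat, templates=t) for cat, t in _BANKS.items()}


# -- zones ----------------------------------------------------------------


def gen_zone_grid(
    n_zones: int, extent: tuple[float, float, float, float] = (0.0, 0.0, 1.0, 1.0)
) -> list[Zone]:
    """Tile the extent with n_zones non-overlapping rectangles.

    Rows get near-equal cell counts, so the rectangles exactly tile the
    extent for any positive ``n_zones``.  Zone ids are stable ("Z00000",
    row-major).  Raises ValueError for a degenerate extent.
    """
    if n_zones <= 0:
        raise ValueError("n_zones must be positive")
    x0, y0, x1, y1 = map(float, extent)
    if not (x1 > x0 and y1 > y0):
        raise ValueError(f"degenerate extent {extent}")
    n_rows = max(1, int(round(math.sqrt(n_zones))))
    base, extra = divmod(n_zones, n_rows)
    zones: list[Zone] = []
    idx = 0
    row_h = (y1 - y0) / n_rows
    for r in range(n_rows):
        cols = base + (1 if r < extra else 0)
        col_w = (x1 - x0) / cols
        ya, yb = y0 + r * row_h, y0 + (r + 1) * row_h
        for c in range(cols):
            xa, xb = x0 + c * col_w, x0 + (c + 1) * col_w
            zones.append(
                Zone(
                    zone_id=f"Z{idx:05d}",
                    rings=(((xa, ya), (xb, ya), (xb, yb), (xa, yb)),),
                )
            )
            idx += 1
    return zones


def gen_zone_rates(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw per-zone true category rates (beta-distributed by default)."""

    def draw(mean: float, sd: float, explicit: Optional[list[float]]) -> np.ndarray:
        if explicit is not None:
            return np.asarray(explicit, dtype=float)
        if sd == 0.0:
            return np.full(config.n_zones, mean)
        var = sd * sd
        if var >= mean * (1.0 - mean):
            raise ConfigError(f"rate sd {sd} too large for mean {mean}")
        ab = mean * (1.0 - mean) / var - 1.0
        return rng.beta(mean * ab, (1.0 - mean) * ab, size=config.n_zones)

    df = pd.DataFrame(
        {
            "zone_id": [f"Z{i:05d}" for i in range(config.n_zones)],
            "rate_happy": draw(config.happy_rate_mean, config.happy_rate_sd, config.true_happy_rates),
            "rate_physical_activity": draw(config.pa_rate_mean, config.pa_rate_sd, config.true_pa_rates),
            "rate_healthy_food": draw(
                config.healthy_food_rate_mean, config.healthy_food_rate_sd, config.true_healthy_food_rates
            ),
            "rate_fast_food": draw(
                config.fast_food_rate_mean, config.fast_food_rate_sd, config.true_fast_food_rates
            ),
            "rate_other_food": draw(
                config.other_food_rate_mean, config.other_food_rate_sd, config.true_other_food_rates
            ),
        }
    )
    total = (
        df[["rate_happy", "rate_physical_activity", "rate_healthy_food", "rate_fast_food", "rate_other_food"]].sum(axis=1)
        + config.decoy_rate
        + config.jobpost_rate
    )
    if (total > 1.0).any():
        raise ConfigError("per-zone category rates sum above 1")
    return df


def true_exposures(rates: pd.DataFrame) -> pd.DataFrame:
    """Zone exposure table implied by the true rates, with tertile codes."""
    out = pd.DataFrame({"zone_id": rates["zone_id"]})
    out["pct_happy"] = 100.0 * rates["rate_happy"]
    out["pct_physical_activity"] = 100.0 * rates["rate_physical_activity"]
    out["pct_healthy_food"] = 100.0 * rates["rate_healthy_food"]
    out["pct_fast_food"] = 100.0 * rates["rate_fast_food"]
    out["pct_food"] = out["pct_healthy_food"] + out["pct_fast_food"] + 100.0 * rates["rate_other_food"]
    for char in CHARACTERISTICS:
        out[f"tertile_{char}"] = tertile_cut(out[f"pct_{char}"].to_numpy())
    return out


def gen_zone_covariates(n_zones: int, rng: np.random.Generator) -> pd.DataFrame:
    """ACS-style zone covariates: percent white, income, density, median age."""
    return pd.DataFrame(
        {
            "zone_id": [f"Z{i:05d}" for i in range(n_zones)],
            "pct_nonhispanic_white": rng.uniform(PCT_WHITE_MIN, PCT_WHITE_MAX, n_zones),
            "median_income": np.exp(
                np.clip(rng.normal(LOG_INCOME_CENTER, 0.3, n_zones),
                        LOG_INCOME_CENTER - LOG_INCOME_HALFRANGE,
                        LOG_INCOME_CENTER + LOG_INCOME_HALFRANGE)
            ),
            "population_density": np.exp(rng.normal(math.log(1000.0), 1.0, n_zones)),
            "median_age": np.clip(rng.normal(38.0, 5.0, n_zones), 22.0, 65.0),
        }
    )


# -- tweets ---------------------------------------------------------------


def gen_tweets(
    zones: list[Zone],
    config: ScenarioConfig,
    banks: dict[str, PhraseBank] | None = None,
    rng: np.random.Generator | None = None,
    rates: pd.DataFrame | None = None,
) -> tuple[list[Tweet], pd.DataFrame]:
    """Generate the per-zone tweet stream with known per-tweet categories.

    Returns (tweets, truth) where truth has one row per tweet: id, zone_id,
    category, is_duplicate.  Tweet counts per zone are negative binomial
    around ``tweets_per_zone``; coordinates are uniform within the zone;
    duplicates copy an earlier same-zone tweet's text; job postings carry a
    blocklisted hashtag.  Deterministic given the rng state.
    """
    banks = banks if banks is not None else default_phrase_banks()
    needed = {"happy", "unhappy", "neutral", "healthy_food", "fast_food",
              "other_food", "physical_activity", "pa_decoy", "jobpost"}
    missing = needed - set(banks)
    if missing:
        raise ConfigError(f"phrase banks missing categories: {sorted(missing)}")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if rates is None:
        rates = gen_zone_rates(config, rng)
    if len(zones) != len(rates):
        raise ConfigError("zones and rates tables disagree on zone count")
    cats = ["happy", "healthy_food", "fast_food", "other_food", "physical_activity",
            "pa_decoy", "jobpost", "unhappy", "neutral"]
    tweets: list[Tweet] = []
    truth_rows: list[tuple[str, str, str, bool]] = []
    counter = 0
    k = config.tweets_dispersion
    p_nb = k / (k + config.tweets_per_zone)
    for zi, zone in enumerate(zones):
        row = rates.iloc[zi]
        base = [
            row["rate_happy"], row["rate_healthy_food"], row["rate_fast_food"],
            row["rate_other_food"], row["rate_physical_activity"],
            config.decoy_rate, config.jobpost_rate,
        ]
        rem = 1.0 - sum(base)
        probs = np.array(base + [0.35 * rem, 0.65 * rem])
        n = int(rng.negative_binomial(k, p_nb))
        if n == 0:
            continue
        cat_idx = rng.choice(len(cats), size=n, p=probs)
        x0, y0, x1, y1 = zone.bbox
        lons = rng.uniform(x0, x1, size=n)
        lats = rng.uniform(y0, y1, size=n)
        zone_texts: list[tuple[str, str]] = []  # (text, category) seen so far in zone
        for j in range(n):
            cat = cats[cat_idx[j]]
            dup = False
            if zone_texts and rng.random() < config.duplicate_rate:
                text, cat = zone_texts[int(rng.integers(0, len(zone_texts)))]
                dup = True
            else:
                bank = banks[cat]
                template = bank.templates[int(rng.integers(0, len(bank.templates)))]
                filler = _FILLERS[int(rng.integers(0, len(_FILLERS)))]
                text = f"{template} {filler} {int(rng.integers(0, 1_000_000))}"
            hashtags: tuple[str, ...] = ("nowhiring",) if cat == "jobpost" else ()
            tid = f"t{counter:09d}"
            minutes = counter % 525600
            created = (
                f"2015-04-01T{(minutes // 60) % 24:02d}:{minutes % 60:02d}:00Z"
            )
            tweets.append(
                Tweet(
                    id=tid,
                    user_id=f"u{int(rng.integers(0, 600_000)):06d}",
                    created_at=created,
                    lon=float(lons[j]),
                    lat=float(lats[j]),
                    text=text,
                    hashtags=hashtags,
                )
            )
            truth_rows.append((tid, zone.zone_id, cat, dup))
            zone_texts.append((text, cat))
            counter += 1
    truth = pd.DataFrame(truth_rows, columns=["id", "zone_id", "category", "is_duplicate"])
    return tweets, truth


def gen_training_corpus(
    n: int, p_happy: float = 0.5, seed: int | np.random.Generator = 0
) -> list[tuple[str, str]]:
    """Labeled happy / not-happy texts for sentiment training.

    Not-happy texts are an even mix of unhappy and neutral templates.
    Deterministic given the seed.
    """
    if n < 2:
        raise ValueError("training corpus needs at least 2 documents")
    if not 0.0 <= p_happy <= 1.0:
        raise ValueError("p_happy must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    banks = default_phrase_banks()
    corpus: list[tuple[str, str]] = []
    for _ in range(n):
        if rng.random() < p_happy:
            bank, label = banks["happy"], "happy"
        else:
            bank = banks["unhappy"] if rng.random() < 0.5 else banks["neutral"]
            label = "not_happy"
        template = bank.templates[int(rng.integers(0, len(bank.templates)))]
        filler = _FILLERS[int(rng.integers(0, len(_FILLERS)))]
        corpus.append((f"{template} {filler} {int(rng.integers(0, 1_000_000))}", label))
    return corpus


# -- population -----------------------------------------------------------

_RACE_LEVELS = np.array(["white", "black", "hispanic", "other"])
_RACE_PROBS = np.array([0.654, 0.114, 0.148, 0.084])
_INCOME_PROBS = np.array([0.149, 0.361, 0.123, 0.108, 0.259])


def _covariate_log_term(
    effects: dict[str, float],
    age: np.ndarray,
    female: np.ndarray,
    race: np.ndarray,
    income_band: np.ndarray,
    pct_white: np.ndarray,
    log_income: np.ndarray,
) -> np.ndarray:
    term = effects.get("age_per_year", 0.0) * (age - AGE_CENTER)
    term = term + effects.get("female", 0.0) * female
    term = term + np.where(race == "black", effects.get("race_black", 0.0), 0.0)
    term = term + np.where(race == "hispanic", effects.get("race_hispanic", 0.0), 0.0)
    term = term + np.where(race == "other", effects.get("race_other", 0.0), 0.0)
    term = term + effects.get("income_per_band", 0.0) * (income_band - 3.0)
    term = term + effects.get("zone_pct_white_per_pct", 0.0) * (pct_white - PCT_WHITE_CENTER)
    term = term + effects.get("zone_log_income", 0.0) * (log_income - LOG_INCOME_CENTER)
    return term


def gen_population(
    zone_exposures: pd.DataFrame,
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
    zone_covariates: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Generate the survey population with raw physiologic measures.

    ``zone_exposures`` needs zone_id and tertile_<characteristic> columns
    (either the generator's true-rate tertiles or pipeline output).  Raw
    measures (weight/height, paired BP readings, HbA1c, self-report flags)
    are constructed so the outcome definitions recover the intended flags
    exactly; intended flags are included as ``intended_*`` columns.
    Raises :class:`ConfigError` before sampling if any individual's binary
    outcome probability would exceed 1.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    if zone_covariates is None:
        zone_covariates = gen_zone_covariates(len(zone_exposures), rng)
    n = config.n_individuals
    zdf = zone_exposures.merge(zone_covariates, on="zone_id", validate="one_to_one")
    zidx = rng.integers(0, len(zdf), size=n)
    zone_id = zdf["zone_id"].to_numpy()[zidx]
    age = rng.uniform(AGE_MIN, AGE_MAX, size=n)
    female = (rng.random(n) < 0.52).astype(float)
    race = _RACE_LEVELS[rng.choice(4, size=n, p=_RACE_PROBS / _RACE_PROBS.sum())]
    income_band = rng.choice(np.arange(1, 6), size=n, p=_INCOME_PROBS / _INCOME_PROBS.sum()).astype(float)
    pct_white = zdf["pct_nonhispanic_white"].to_numpy()[zidx]
    log_income = np.log(zdf["median_income"].to_numpy()[zidx])

    def tert_dummies(char: str) -> tuple[np.ndarray, np.ndarray]:
        t = zdf[f"tertile_{char}"].to_numpy()[zidx]
        return (t == 2).astype(float), (t == 3).astype(float)

    binary_p: dict[str, np.ndarray] = {}
    for key, ch in config.binary_channels.items():
        t2, t3 = tert_dummies(ch.characteristic)
        logp = (
            math.log(ch.baseline_prevalence)
            + ch.log_pr_tertile2 * t2
            + ch.log_pr_tertile3 * t3
            + _covariate_log_term(
                config.covariate_log_effects, age, female, race, income_band, pct_white, log_income
            )
        )
        p = np.exp(logp)
        if (p > 1.0).any():
            raise ConfigError(
                f"{key}: generated probability up to {p.max():.4f} exceeds 1; "
                "shrink the configured effects"
            )
        binary_p[key] = p

    bmi_cov = _covariate_log_term(
        config.covariate_effects_bmi, age, female, race, income_band, pct_white, log_income
    )
    if config.bmi_mode == "linear":
        t2, t3 = tert_dummies(config.bmi_characteristic)
        bmi = (
            config.bmi_baseline
            + config.effect_bmi_tertile2 * t2
            + config.effect_bmi_tertile3 * t3
            + bmi_cov
            + rng.normal(0.0, config.bmi_noise_sd, size=n)
        )
        obesity = None  # derived from the encoded BMI below
    else:
        p_ob = binary_p["obesity"]
        u = np.clip(rng.random(n), 1e-12, 1.0 - 1e-12)
        obesity = u < p_ob
        sd = config.bmi_noise_sd if config.bmi_noise_sd > 0 else 6.0
        bmi = 30.0 + sd * (ndtri(p_ob) - ndtri(u))

    # encode BMI as weight/height
    height = np.clip(rng.normal(167.0, 9.0, size=n), 145.0, 200.0)
    bmi = np.clip(bmi, 12.0, 75.0)
    weight = bmi * (height / 100.0) ** 2
    derived_bmi = weight / (height / 100.0) ** 2
    if obesity is None:
        obesity = derived_bmi >= 30.0
    else:
        # float round-trip may flip boundary cases; nudge weight to agree
        bad = (derived_bmi >= 30.0) != obesity
        if bad.any():
            target = np.where(obesity, 30.0 + 1e-6, 30.0 - 1e-6)
            weight[bad] = target[bad] * (height[bad] / 100.0) ** 2

    # hypertension raw measures
    if "hypertension" in binary_p:
        htn = rng.random(n) < binary_p["hypertension"]
    else:
        htn = np.zeros(n, dtype=bool)
    med_route = htn & (rng.random(n) < 0.3)
    elev = htn & ~med_route
    which = rng.integers(0, 3, size=n)  # 0 sbp, 1 dbp, 2 both
    sbp_up = elev & (which != 1)
    dbp_up = elev & (which != 0)
    sbp_mean = np.where(sbp_up, rng.uniform(132.0, 165.0, n), rng.uniform(100.0, 128.0, n))
    dbp_mean = np.where(dbp_up, rng.uniform(82.0, 100.0, n), rng.uniform(60.0, 78.0, n))
    ds = rng.uniform(0.0, 4.0, n)
    dd = rng.uniform(0.0, 4.0, n)

    # diabetes raw measures
    if "diabetes" in binary_p:
        dia = rng.random(n) < binary_p["diabetes"]
    else:
        dia = np.zeros(n, dtype=bool)
    selfreport_route = dia & (rng.random(n) < 0.5)
    hba1c = np.where(
        dia & ~selfreport_route,
        rng.uniform(6.6, 9.5, n),
        rng.uniform(4.8, 6.4, n),
    )

    df = pd.DataFrame(
        {
            "person_id": [f"p{i:06d}" for i in range(n)],
            "zone_id": zone_id,
            "age": age,
            "sex": np.where(female == 1.0, "female", "male"),
            "race_ethnicity": race,
            "income_band": [f"b{int(b)}" for b in income_band],
            "weight_kg": weight,
            "height_cm": height,
            "sbp_1": sbp_mean + ds,
            "sbp_2": sbp_mean - ds,
            "dbp_1": dbp_mean + dd,
            "dbp_2": dbp_mean - dd,
            "htn_medication": med_route,
            "hba1c": hba1c,
            "diabetes_selfreport": selfreport_route,
            "exam_weight": rng.lognormal(0.0, config.weight_lognorm_sd, n),
            "intended_obesity": obesity,
            "intended_hypertension": htn,
            "intended_diabetes": dia,
        }
    )
    return df


# -- packaged scenarios ---------------------------------------------------


def subcohort_scenario(**overrides) -> ScenarioConfig:
    """The smaller analytic sample: ~1384 zones, ~17,000 individuals.

    Default effect sizes follow the happy-tweet contrasts of the main
    results table (BMI -0.65 / -0.85 kg/m^2; hypertension PR 0.92 / 0.94;
    diabetes PR 1.02 / 0.90), with baseline prevalences matching the
    weighted sample (hypertension 49%, diabetes 12.6%).
    """
    params: dict = dict(
        n_zones=1384,
        n_individuals=17048,
        bmi_characteristic="happy",
        effect_bmi_tertile2=-0.65,
        effect_bmi_tertile3=-0.85,
        binary_channels={
            "hypertension": BinaryChannel(
                characteristic="happy",
                baseline_prevalence=0.49,
                log_pr_tertile2=math.log(0.92),
                log_pr_tertile3=math.log(0.94),
            ),
            "diabetes": BinaryChannel(
                characteristic="happy",
                baseline_prevalence=0.126,
                log_pr_tertile2=math.log(1.02),
                log_pr_tertile3=math.log(0.90),
            ),
        },
    )
    params.update(overrides)
    return ScenarioConfig(**params)


def full_cohort_scenario(**overrides) -> ScenarioConfig:
    """The larger analytic sample: ~2116 zones, ~29,000 individuals."""
    params: dict = dict(
        n_zones=2116,
        n_individuals=29201,
        bmi_characteristic="happy",
        effect_bmi_tertile2=-0.53,
        effect_bmi_tertile3=-0.79,
        binary_channels={
            "hypertension": BinaryChannel(
                characteristic="happy",
                baseline_prevalence=0.481,
                log_pr_tertile2=math.log(0.94),
                log_pr_tertile3=math.log(0.94),
            ),
            "diabetes": BinaryChannel(
                characteristic="happy",
                baseline_prevalence=0.121,
                log_pr_tertile2=math.log(0.99),
                log_pr_tertile3=math.log(0.87),
            ),
        },
    )
    params.update(overrides)
    return ScenarioConfig(**params)
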