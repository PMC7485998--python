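"""Synthetic-data generator: determinism, tiling, rate convergence, validation."""

import math

import numpy as np
import pytest

from tweethood.classify import write_tweets_jsonl
from tweethood.geo import point_in_polygon
from tweethood.synthetic import (
    BinaryChannel,
    ConfigError,
    PhraseBank,
    ScenarioConfig,
    default_phrase_banks,
    gen_population,
    gen_training_corpus,
    gen_tweets,
    gen_zone_grid,
    gen_zone_rates,
    subcohort_scenario,
    true_exposures,
)


def small_config(**kw):
    params = dict(n_zones=9, n_individuals=200, tweets_per_zone=50.0, seed=5)
    params.update(kw)
    return ScenarioConfig(**params)


# -- zone grid ------------------------------------------------------------


def test_grid_four_quadrants_tile_unit_square():
    zones = gen_zone_grid(4)
    assert len(zones) == 4
    widths = [(z.bbox[2] - z.bbox[0]) * (z.bbox[3] - z.bbox[1]) for z in zones]
    assert sum(widths) == pytest.approx(1.0, abs=1e-12)
    assert len({z.zone_id for z in zones}) == 4


def test_grid_nine_unit_squares_are_interior_disjoint():
    zones = gen_zone_grid(9, (0.0, 0.0, 3.0, 3.0))
    assert len(zones) == 9
    for i, a in enumerate(zones):
        assert (a.bbox[2] - a.bbox[0]) == pytest.approx(1.0)
        for b in zones[i + 1 :]:
            # interiors disjoint: bbox overlap has zero area
            ox = min(a.bbox[2], b.bbox[2]) - max(a.bbox[0], b.bbox[0])
            oy = min(a.bbox[3], b.bbox[3]) - max(a.bbox[1], b.bbox[1])
            assert min(ox, oy) <= 1e-12


def test_grid_non_square_count_still_tiles():
    zones = gen_zone_grid(7, (0.0, 0.0, 2.0, 1.0))
    area = sum((z.bbox[2] - z.bbox[0]) * (z.bbox[3] - z.bbox[1]) for z in zones)
    assert len(zones) == 7
    assert area == pytest.approx(2.0, abs=1e-12)


def test_grid_rejects_degenerate_extent():
    with pytest.raises(ValueError):
        gen_zone_grid(4, (0.0, 0.0, 0.0, 1.0))


# -- tweets ---------------------------------------------------------------


def test_every_tweet_lies_inside_its_zone():
    cfg = small_config()
    zones = gen_zone_grid(cfg.n_zones)
    tweets, truth = gen_tweets(zones, cfg)
    by_zone = {z.zone_id: z for z in zones}
    assert len(tweets) == len(truth)
    for tweet, (_, zid, _, _) in zip(tweets, truth.itertuples(index=False)):
        assert point_in_polygon((tweet.lon, tweet.lat), by_zone[zid].rings)


def test_zero_happy_rate_zone_has_no_happy_tweets():
    cfg = small_config(true_happy_rates=[0.0] * 9)
    zones = gen_zone_grid(cfg.n_zones)
    _, truth = gen_tweets(zones, cfg)
    assert (truth["category"] != "happy").all()


def test_tweet_stream_is_byte_identical_under_fixed_seed(tmp_path):
    cfg = small_config()
    zones = gen_zone_grid(cfg.n_zones)
    paths = []
    for name in ("a.jsonl", "b.jsonl"):
        tweets, _ = gen_tweets(zones, cfg, rng=np.random.default_rng(cfg.seed))
        p = tmp_path / name
        write_tweets_jsonl(tweets, p)
        paths.append(p.read_bytes())
    assert paths[0] == paths[1]


def test_category_shares_converge_to_configured_rates():
    """Per-zone happy share within 3 binomial SE of the configured rate."""
    cfg = small_config(n_zones=4, tweets_per_zone=10000.0, tweets_dispersion=1e9,
                      duplicate_rate=0.0, jobpost_rate=0.0,
                      true_happy_rates=[0.10, 0.19, 0.25, 0.40])
    zones = gen_zone_grid(4)
    _, truth = gen_tweets(zones, cfg)
    for zid, rate in zip([z.zone_id for z in zones], cfg.true_happy_rates):
        sub = truth[truth["zone_id"] == zid]
        share = (sub["category"] == "happy").mean()
        se = math.sqrt(rate * (1 - rate) / len(sub))
        assert abs(share - rate) <= 3 * se


def test_missing_phrase_bank_category_raises():
    cfg = small_config()
    banks = default_phrase_banks()
    del banks["happy"]
    with pytest.raises(ConfigError, match="happy"):
        gen_tweets(gen_zone_grid(cfg.n_zones), cfg, banks=banks)


def test_empty_phrase_bank_rejected():
    with pytest.raises(ConfigError):
        PhraseBank(category="happy", templates=())


# -- training corpus ------------------------------------------------------


def test_corpus_label_share_within_binomial_error():
    corpus = gen_training_corpus(1000, 0.5, seed=3)
    n_happy = sum(1 for _, lab in corpus if lab == "happy")
    assert abs(n_happy - 500) <= 3 * math.sqrt(1000 * 0.25)


def test_corpus_extremes_and_determinism():
    assert all(lab == "happy" for _, lab in gen_training_corpus(50, 1.0, seed=1))
    assert gen_training_corpus(100, 0.3, seed=9) == gen_training_corpus(100, 0.3, seed=9)
    with pytest.raises(ValueError):
        gen_training_corpus(1, 0.5)


# -- population -----------------------------------------------------------


def test_null_effects_give_flat_prevalence_across_tertiles():
    cfg = small_config(
        n_zones=30,
        n_individuals=30000,
        effect_bmi_tertile2=0.0,
        effect_bmi_tertile3=0.0,
        binary_channels={
            "hypertension": BinaryChannel(characteristic="happy", baseline_prevalence=0.3)
        },
        covariate_log_effects={},
    )
    rng = np.random.default_rng(2)
    exposures = true_exposures(gen_zone_rates(cfg, rng))
    pop = gen_population(exposures, cfg, rng=rng)
    merged = pop.merge(exposures[["zone_id", "tertile_happy"]], on="zone_id")
    prev = merged.groupby("tertile_happy")["intended_hypertension"].mean()
    for t in (1, 2, 3):
        assert prev.loc[t] == pytest.approx(0.3, abs=0.02)


def test_large_log_pr_recovered_by_empirical_prevalence_ratio():
    cfg = small_config(
        n_zones=30,
        n_individuals=60000,
        binary_channels={
            "hypertension": BinaryChannel(
                characteristic="happy",
                baseline_prevalence=0.3,
                log_pr_tertile3=math.log(0.5),
            )
        },
        covariate_log_effects={},
    )
    rng = np.random.default_rng(4)
    exposures = true_exposures(gen_zone_rates(cfg, rng))
    pop = gen_population(exposures, cfg, rng=rng)
    merged = pop.merge(exposures[["zone_id", "tertile_happy"]], on="zone_id")
    prev = merged.groupby("tertile_happy")["intended_hypertension"].mean()
    assert prev.loc[3] / prev.loc[1] == pytest.approx(0.5, abs=0.03)


def test_zero_noise_bmi_constant_within_tertile():
    cfg = small_config(
        n_zones=9,
        n_individuals=500,
        bmi_noise_sd=0.0,
        effect_bmi_tertile2=1.0,
        effect_bmi_tertile3=2.0,
        covariate_effects_bmi={},
    )
    rng = np.random.default_rng(6)
    exposures = true_exposures(gen_zone_rates(cfg, rng))
    pop = gen_population(exposures, cfg, rng=rng)
    merged = pop.merge(exposures[["zone_id", "tertile_happy"]], on="zone_id")
    bmi = merged["weight_kg"] / (merged["height_cm"] / 100) ** 2
    spread = bmi.groupby(merged["tertile_happy"]).agg(lambda s: s.max() - s.min())
    assert (spread < 1e-9).all()
    means = bmi.groupby(merged["tertile_happy"]).mean()
    assert means.loc[2] - means.loc[1] == pytest.approx(1.0, abs=1e-9)
    assert means.loc[3] - means.loc[1] == pytest.approx(2.0, abs=1e-9)


def test_probability_above_one_is_a_configuration_error():
    # surfaced through pydantic validation, still a ValueError with the bound
    with pytest.raises(ValueError, match="exceeds 1"):
        ScenarioConfig(
            n_zones=9,
            n_individuals=100,
            binary_channels={
                "hypertension": BinaryChannel(
                    characteristic="happy",
                    baseline_prevalence=0.8,
                    log_pr_tertile3=math.log(1.5),
                )
            },
        )


def test_bmi_mode_cross_constraints():
    with pytest.raises(ValueError, match="obesity"):
        ScenarioConfig(
            n_zones=9,
            n_individuals=10,
            bmi_mode="linear",
            binary_channels={
                "obesity": BinaryChannel(
                    characteristic="happy", baseline_prevalence=0.3, log_pr_tertile3=-0.1
                )
            },
        )
    with pytest.raises(ValueError, match="BMI tertile effects"):
        ScenarioConfig(
            n_zones=9,
            n_individuals=10,
            bmi_mode="obesity_coupled",
            effect_bmi_tertile3=-0.5,
            binary_channels={
                "obesity": BinaryChannel(characteristic="happy", baseline_prevalence=0.3)
            },
        )


def test_explicit_rate_list_must_match_zone_count():
    with pytest.raises(ValueError, match="n_zones"):
        ScenarioConfig(n_zones=4, n_individuals=10, true_happy_rates=[0.1, 0.2])


def test_packaged_scenarios_are_valid_and_sized():
    sub = subcohort_scenario()
    assert (sub.n_zones, sub.n_individuals) == (1384, 17048)
    assert sub.effect_bmi_tertile3 == pytest.approx(-0.85)
    assert math.exp(sub.binary_channels["hypertension"].log_pr_tertile2) == pytest.approx(0.92)
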