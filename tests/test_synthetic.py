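import numpy as np
import pytest

from hmfuse.synthetic import (
    GROUPS,
    ConfigurationError,
    GroundTruth,
    MetabolitePattern,
    StudyConfig,
    default_config,
    simulate_spectrum,
    simulate_study,
)


# ---------------------------------------------------------------- determinism
def test_same_seed_gives_bit_identical_study():
    cfg1 = default_config(seed=100, n_per_group=4)
    cfg1.n_points = 256
    cfg2 = default_config(seed=100, n_per_group=4)
    cfg2.n_points = 256
    a1, b1, t1 = simulate_study(cfg1)
    a2, b2, t2 = simulate_study(cfg2)
    assert np.array_equal(a1.intensities, a2.intensities)
    assert np.array_equal(b1.intensities, b2.intensities)
    for blk in t1.concentrations:
        assert t1.concentrations[blk].equals(t2.concentrations[blk])


def test_different_seed_differs():
    cfg1 = default_config(seed=100, n_per_group=4)
    cfg2 = default_config(seed=101, n_per_group=4)
    cfg1.n_points = cfg2.n_points = 256
    a1, _, _ = simulate_study(cfg1)
    a2, _, _ = simulate_study(cfg2)
    assert not np.array_equal(a1.intensities, a2.intensities)


# ---------------------------------------------------------------- trivial limit
def _noise_free_config():
    def lib():
        return [
            MetabolitePattern("m", [(5.0, 0.1, 1.0, "gaussian")], 1.0),
            MetabolitePattern("w", [(7.0, 0.1, 1.0, "gaussian")], 1.0),
        ]

    cfg = StudyConfig(
        n_per_group=4,
        n_points=256,
        ppm_range=(0.5, 9.0),
        metabolite_library={"blockA": lib(), "blockB": lib()},
        # m: peripheral, w: neurological with severity
        effect_map={
            "m": {"P10": 2.0, "N10": 2.0, "N14": 2.0},
            "w": {"N10": 1.5, "N14": 1.7},
        },
        shift_jitter_sd=0.0,
        baseline_amplitude=0.0,
        noise_sd=0.0,
        seed=0,
        biological_sd=0.0,
    )
    return cfg


def test_noise_free_spectra_identical_to_template():
    cfg = _noise_free_config()
    block_a, _, _ = simulate_study(cfg)
    ppm = block_a.ppm
    template = sum(p.template(ppm) for p in cfg.metabolite_library["blockA"])
    controls = np.isin(block_a.groups, ["C10", "C14", "P14"])
    assert controls.sum() == 12
    for row in block_a.intensities[controls]:
        assert np.allclose(row, template, atol=1e-12)


def test_effect_factors_scale_concentrations_exactly_without_noise():
    cfg = _noise_free_config()
    _, _, truth = simulate_study(cfg)
    conc = truth.concentrations["blockA"]
    groups = np.array([s.split("-")[0] for s in conc.index])
    base = conc["m"][groups == "C10"].iloc[0]
    assert np.allclose(conc["m"][groups == "P10"], 2.0 * base)
    assert np.allclose(conc["m"][groups == "P14"], base)
    assert np.allclose(conc["w"][groups == "N14"], 1.7 * base)


def test_constant_jitter_moves_peak_by_that_many_ppm():
    pat = MetabolitePattern("m", [(4.0, 0.05, 1.0, "gaussian")], 1.0)
    ppm = np.linspace(0.5, 9.0, 4096)
    s0 = simulate_spectrum([1.0], [pat], [0.0], None, 0.0, 0, ppm)
    s1 = simulate_spectrum([1.0], [pat], [0.03], None, 0.0, 0, ppm)
    d = ppm[np.argmax(s1.intensity)] - ppm[np.argmax(s0.intensity)]
    assert abs(d - 0.03) < 2 * (ppm[1] - ppm[0])


# ---------------------------------------------------------------- validation
def test_default_config_is_valid():
    default_config(seed=0).validate()


@pytest.mark.parametrize(
    "mutate, message",
    [
        (lambda c: setattr(c, "n_per_group", 3), "n_per_group"),
        (lambda c: setattr(c, "ppm_range", (9.0, 0.5)), "ppm_range"),
        (lambda c: c.metabolite_library.pop("blockB"), "two blocks"),
        (lambda c: setattr(c, "groups", ("C10",) * 6), "groups"),
        (lambda c: c.effect_map.update(ghost={"P10": 2.0}), "not in library"),
        (lambda c: c.effect_map["lactate"].update(BAD=1.0), "unknown"),
        (lambda c: c.effect_map["lactate"].update(P10=-1.0), "must be > 0"),
        (lambda c: c.effect_map["lactate"].update(P14=9.0), "P14"),
        (
            lambda c: c.effect_map.update(
                # N14 back to control for every peripheral metabolite
                lactate={"P10": 2.0, "N10": 2.0},
                tyrosine={"P10": 0.5, "N10": 0.5},
                glutamine={"N10": 1.52, "N14": 1.52},
                myo_inositol={"N10": 0.74, "N14": 0.74},
                valine={"N10": 0.86, "N14": 0.86},
                formate={},
                glutamate={},
            ),
            "peripheral",
        ),
        (
            lambda c: c.effect_map.update(
                # every N10/N14 effect now also touches P10 or only N14:
                # no metabolite altered in the N groups alone remains
                glutamine={"P10": 1.52, "N10": 1.52, "N14": 1.52},
                myo_inositol={"P10": 1.25},
                valine={"P10": 1.28},
                acetate={},
                creatine={"N14": 1.50},
                citrate={"N14": 0.62},
                alanine={"N14": 0.48},
            ),
            "neurological",
        ),
        (
            lambda c: [
                c.effect_map.update({m: {g: 1.3 for g in ("N10", "N14")}})
                for m in ("creatine", "citrate", "alanine")
            ],
            "severity",
        ),
        (
            lambda c: setattr(c, "exchange_metabolites", ("ghost",)),
            "exchange metabolite",
        ),
        (
            lambda c: setattr(c, "biological_sd_overrides", {"ghost": 0.1}),
            "biological_sd_overrides",
        ),
        (
            lambda c: setattr(c, "biological_sd_overrides", {"glucose": -0.1}),
            "must be >= 0",
        ),
    ],
)
def test_invalid_configs_are_rejected(mutate, message):
    cfg = default_config(seed=0)
    mutate(cfg)
    with pytest.raises(ConfigurationError, match=message):
        cfg.validate()


def test_metabolite_pattern_validation():
    with pytest.raises(ConfigurationError):
        MetabolitePattern("m", [], 1.0).validate((0.5, 9.0))
    with pytest.raises(ConfigurationError):
        MetabolitePattern("m", [(10.0, 0.1, 1.0, "gaussian")], 1.0).validate((0.5, 9.0))
    with pytest.raises(ConfigurationError):
        MetabolitePattern("m", [(5.0, 0.1, 1.0, "triangle")], 1.0).validate((0.5, 9.0))
    with pytest.raises(ConfigurationError):
        MetabolitePattern("m", [(5.0, 0.1, 1.0, "gaussian")], -1.0).validate((0.5, 9.0))


# ---------------------------------------------------------------- round trips
def test_config_yaml_round_trip(tmp_path):
    cfg = default_config(seed=42)
    path = tmp_path / "cfg.yaml"
    cfg.write_yaml(path)
    back = StudyConfig.read_yaml(path)
    assert back.to_dict() == cfg.to_dict()
    back.validate()
    # round-tripped config draws the same study
    a1, _, _ = simulate_study(cfg)
    a2, _, _ = simulate_study(back)
    assert np.array_equal(a1.intensities, a2.intensities)


def test_ground_truth_json_round_trip(tmp_path, tiny_study):
    _, _, _, truth = tiny_study
    path = tmp_path / "gt.json"
    truth.to_json(path)
    back = GroundTruth.from_json(path)
    # JSON turns tuples into lists; compare structure after normalization
    norm = {
        k: {b: [list(e) for e in v] for b, v in per.items()}
        for k, per in truth.contrasts.items()
    }
    assert back.contrasts == norm
    assert back.discriminatory_ppm == truth.discriminatory_ppm
    for blk, df in truth.concentrations.items():
        assert np.allclose(back.concentrations[blk].to_numpy(), df.to_numpy())


# ---------------------------------------------------------------- structure
def test_study_shape_and_metadata(tiny_study):
    cfg, block_a, block_b, truth = tiny_study
    n = cfg.n_per_group * len(GROUPS)
    assert block_a.intensities.shape == (n, cfg.n_points)
    assert block_b.intensities.shape == (n, cfg.n_points)
    assert sorted(set(block_a.groups)) == sorted(GROUPS)
    assert block_a.sample_ids == block_b.sample_ids
    # planted contrasts mention both blocks for the P10 vs N10 contrast
    c = truth.contrasts["P10_vs_N10"]
    assert c["blockA"] and c["blockB"]


def test_exchange_term_anticorrelated_between_blocks():
    cfg = default_config(seed=100, n_per_group=14)
    cfg.n_points = 256
    _, _, truth = simulate_study(cfg)
    ca = truth.concentrations["blockA"]
    cb = truth.concentrations["blockB"]
    groups = np.array([s.split("-")[0] for s in ca.index])
    ctl = groups == "C10"
    # within one group the shared exchange metabolite is anti-correlated
    # across blocks, the inert reference is not
    la, lb = np.log(ca["glutamine"][ctl]), np.log(cb["glutamine"][ctl])
    r_exch = np.corrcoef(la, lb)[0, 1]
    ga, gb = np.log(ca["glucose"][ctl]), np.log(cb["glucose"][ctl])
    r_glc = np.corrcoef(ga, gb)[0, 1]
    assert r_exch < -0.5
    assert r_glc > 0.5
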