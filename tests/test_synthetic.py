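"""Synthetic catalog, noise model and benchmark-experiment generators."""

import math
import random

import pytest

from medscreen import (
    InvalidInputError,
    NoiseModel,
    corrupt_text,
    edit_distance,
    generate_catalog,
    generate_experiment,
    load_catalog,
    normalize_name,
    write_experiment,
)


def test_generate_catalog_deterministic():
    assert generate_catalog(10, seed=1) == generate_catalog(10, seed=1)
    assert generate_catalog(10, seed=1) != generate_catalog(10, seed=2)


def test_generate_catalog_dosage_variants_collapse():
    names = generate_catalog(200, seed=3)
    catalog, report = load_catalog(names)
    assert report.duplicates_removed > 0  # variants exercised the dedup path
    for entry in catalog.entries:
        assert "(" not in entry  # every dosage parenthetical was stripped


def test_generate_catalog_all_names_parseable():
    for name in generate_catalog(1000, seed=7):
        assert name and normalize_name(name)


def test_generate_catalog_rejects_bad_size():
    with pytest.raises(InvalidInputError):
        generate_catalog(0, seed=1)


def test_corrupt_text_zero_rates_identity():
    model = NoiseModel(seed=5)
    for text in ("Acer cap.", "약품정 500", ""):
        assert corrupt_text(text, model) == text


def test_corrupt_text_full_substitution_disjoint_alphabet():
    # input drawn from digits; substitution alphabet is ascii letters
    model = NoiseModel(sub_rate=1.0, seed=11)
    text = "0123456789"
    out = corrupt_text(text, model)
    assert len(out) == len(text)
    assert edit_distance(text, out) == len(text)


def test_corrupt_text_deterministic_per_seed_and_input():
    model = NoiseModel(sub_rate=0.3, del_rate=0.1, ins_rate=0.1, seed=42)
    assert corrupt_text("Bacelu tab.", model) == corrupt_text("Bacelu tab.", model)
    other = NoiseModel(sub_rate=0.3, del_rate=0.1, ins_rate=0.1, seed=43)
    assert corrupt_text("Bacelu tab.", model) != corrupt_text("Bacelu tab.", other)


def test_corrupt_text_substitution_calibration():
    """Mean substitution count over many seeds sits inside the binomial
    99% band (n=100 characters, p=0.05, 300 trials)."""
    n, p, trials = 100, 0.05, 300
    text = "x" * n
    total = 0
    for seed in range(trials):
        out = corrupt_text(text, NoiseModel(sub_rate=p, seed=seed))
        assert len(out) == n
        total += sum(a != b for a, b in zip(text, out))
    mean = total / trials
    half_width = 2.576 * math.sqrt(n * p * (1 - p) / trials)
    assert abs(mean - n * p) <= half_width


def test_noise_model_validation():
    with pytest.raises(InvalidInputError):
        NoiseModel(sub_rate=0.8, del_rate=0.4)
    with pytest.raises(InvalidInputError):
        NoiseModel(sub_rate=-0.1)


def test_experiment_design_invariants(clean_experiment):
    design = clean_experiment.design
    assert len(design.package_a) == len(design.package_b) == 8
    assert len(design.planted_pairs) == 3
    for a, b in design.planted_pairs:
        assert a in design.package_a and b in design.package_b
        assert a not in design.package_c and b not in design.package_c
    # decoy pairs never touch the packages
    packages = {n.casefold() for pkg in ("A", "B", "C") for n in design.package(pkg)}
    planted = {frozenset((a.casefold(), b.casefold()))
               for a, b in design.planted_pairs}
    for key in clean_experiment.table.pairs:
        if key not in planted:
            assert not (key & packages)


def test_experiment_produces_150_fixtures(clean_experiment):
    assert len(clean_experiment.bags) == 150  # 3 packages x 5 conditions x 10
    assert len({b.bag_id for b in clean_experiment.bags}) == 150
    assert all(len(clean_experiment.manifest["bags"][b.bag_id]["expected_names"]) == 8
               for b in clean_experiment.bags)


def test_experiment_catalog_contains_all_package_names(clean_experiment):
    exp = clean_experiment
    for label in ("A", "B", "C"):
        for name in exp.design.package(label):
            assert name in exp.catalog


def test_experiment_fixture_files_byte_identical(tmp_path):
    dirs = []
    for run in ("one", "two"):
        out = tmp_path / run
        write_experiment(generate_experiment(9, replicates=2), out)
        dirs.append(out)
    first, second = dirs
    files_a = sorted(p.relative_to(first) for p in first.rglob("*") if p.is_file())
    files_b = sorted(p.relative_to(second) for p in second.rglob("*") if p.is_file())
    assert files_a == files_b
    for rel in files_a:
        assert (first / rel).read_bytes() == (second / rel).read_bytes()


def test_noise_scale_zero_means_clean_tokens(clean_experiment):
    exp = clean_experiment
    reading = next(b for b in exp.bags if b.bag_id == "A_font5_rep01")
    expected = exp.manifest["bags"]["A_font5_rep01"]["expected_names"]
    joined = " ".join(reading.texts())
    for name in expected:
        assert name in joined


def test_accuracy_degrades_with_substitution_rate():
    """Seed-averaged package accuracy is non-increasing in sub_rate."""
    from medscreen import accepted_names, extract_drug_names, package_accuracy

    rates = (0.0, 0.05, 0.1, 0.2)
    means = []
    rng = random.Random(0)
    raw = generate_catalog(30, seed=5, dosage_variant_fraction=0.0)
    catalog, _ = load_catalog(raw)
    names = catalog.entries[:8]
    texts = [w for n in names for w in n.split(" ")]
    for rate in rates:
        scores = []
        for _ in range(50):
            base_seed = rng.randrange(2**31)
            noisy = [corrupt_text(t, NoiseModel(sub_rate=rate, seed=base_seed + i))
                     for i, t in enumerate(texts)]
            extracted = accepted_names(extract_drug_names(noisy, catalog))
            scores.append(package_accuracy(names, extracted))
        means.append(sum(scores) / len(scores))
    assert all(means[i] >= means[i + 1] - 1e-9 for i in range(len(means) - 1))
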