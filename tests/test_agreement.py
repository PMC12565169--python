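"""Two-reader reliability: ICC(2,1), Bland-Altman, simulated second reader."""

import numpy as np
import pytest

from wristt1 import (agreement_summary, bland_altman, estimate_all_structures,
                     icc_two_reader, reader_perturbation, reliability_band,
                     signal_table)
from wristt1.roi import EmptyROIError


def icc21_anova_oracle(values):
    """ICC(2,1) from explicit two-way ANOVA mean squares."""
    v = np.asarray(values, float)
    n, k = v.shape
    grand = v.mean()
    ms_rows = k * np.sum((v.mean(axis=1) - grand) ** 2) / (n - 1)
    ms_cols = n * np.sum((v.mean(axis=0) - grand) ** 2) / (k - 1)
    resid = v - v.mean(axis=1, keepdims=True) - v.mean(axis=0, keepdims=True) + grand
    ms_err = np.sum(resid ** 2) / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err
                                 + k * (ms_cols - ms_err) / n)


def test_identical_readers_icc_one(rng):
    r1 = rng.normal(1000, 150, size=12)
    icc, ci = icc_two_reader(np.column_stack([r1, r1]))
    assert icc == pytest.approx(1.0, abs=1e-9)
    assert reliability_band(icc) == "excellent"


def test_pure_noise_reader_icc_near_zero(rng):
    r1 = rng.normal(1000, 1.0, size=200)            # tiny subject variance
    r2 = r1 + rng.normal(0, 300.0, size=200)        # huge reader noise
    icc, _ = icc_two_reader(np.column_stack([r1, r2]))
    assert abs(icc) < 0.1
    assert reliability_band(max(icc, 0.0)) == "poor"


def test_icc_matches_anova_oracle(rng):
    v = np.array([[1000, 1010], [950, 940], [1100, 1120],
                  [870, 860], [1020, 1035], [990, 1000.0]])
    icc, _ = icc_two_reader(v)
    assert icc == pytest.approx(icc21_anova_oracle(v), abs=1e-10)
    for _ in range(10):
        w = rng.normal(1000, 120, size=(8, 1)) + rng.normal(0, 30, size=(8, 2))
        icc_w, _ = icc_two_reader(w)
        assert icc_w == pytest.approx(icc21_anova_oracle(w), abs=1e-10)


def test_icc_input_validation(rng):
    with pytest.raises(ValueError):
        icc_two_reader(rng.normal(size=(4, 2)))     # too few subjects
    bad = rng.normal(size=(6, 2))
    bad[2, 1] = np.nan
    with pytest.raises(ValueError):                 # no imputation
        icc_two_reader(bad)


def test_icc_shift_invariance(rng):
    v = rng.normal(1000, 100, size=(10, 2))
    icc0, _ = icc_two_reader(v)
    icc1, _ = icc_two_reader(v + 500.0)             # common constant: unchanged
    assert icc1 == pytest.approx(icc0, abs=1e-9)


def test_bland_altman_closed_forms():
    # constant offset: bias 10, zero-width limits
    v = np.column_stack([np.arange(5.0) + 10.0, np.arange(5.0)])
    bias, loa = bland_altman(v)
    assert bias == 10.0 and loa == (10.0, 10.0)
    # d = (-1, +1): bias 0, limits +/- 1.96*sqrt(2)
    v2 = np.array([[0.0, 1.0], [1.0, 0.0]])
    bias2, loa2 = bland_altman(v2)
    assert bias2 == 0.0
    assert loa2[1] == pytest.approx(1.96 * np.sqrt(2))
    # identical readers: bias 0, limits (0, 0)
    v3 = np.column_stack([np.arange(4.0), np.arange(4.0)])
    assert bland_altman(v3) == (0.0, (0.0, 0.0))
    with pytest.raises(ValueError):
        bland_altman(np.array([[1.0, 2.0]]))


def test_bland_altman_bias_shifts_with_one_reader(rng):
    v = rng.normal(1000, 100, size=(10, 2))
    bias0, _ = bland_altman(v)
    shifted = v.copy()
    shifted[:, 0] += 25.0
    bias1, _ = bland_altman(shifted)
    assert bias1 - bias0 == pytest.approx(25.0)


def test_agreement_summary_bands(rng):
    v = rng.normal(1000, 150, size=(15, 1)) + rng.normal(0, 10, size=(15, 2))
    res = agreement_summary(v)
    assert res.icc_ci95[0] <= res.icc <= res.icc_ci95[1] <= 1.0
    assert res.reliability_band in ("poor", "moderate", "good", "excellent")
    assert res.loa95[0] <= res.bias <= res.loa95[1]


def test_zero_jitter_reproduces_reader_one(noisy_study):
    t1 = signal_table(noisy_study).means
    t2 = reader_perturbation(noisy_study, 0, 123).means
    assert np.array_equal(t1.to_numpy(), t2.to_numpy())


def test_jitter_deterministic(noisy_study):
    a = reader_perturbation(noisy_study, 2, 9).means
    b = reader_perturbation(noisy_study, 2, 9).means
    assert np.array_equal(a.to_numpy(), b.to_numpy())


def test_destructive_jitter_raises(noisy_study):
    # erosion by many pixels wipes out the thin structures
    with pytest.raises(EmptyROIError):
        for seed in range(10):
            reader_perturbation(noisy_study, 12, seed)


def test_small_jitter_agreement_profile(protocol, prior):
    """20-patient re-reads with 1-px contour jitter: high reliability overall,
    lowest for the smallest structure.

    Run at the full acquisition matrix — at reduced resolution the median
    nerve is only a dozen pixels and a 1-px contour shift is no longer a
    small perturbation. Even at full resolution the median nerve, being the
    smallest ROI bordered by tissues of very different T1, sits near the
    moderate/good boundary while every larger structure is comfortably good
    or excellent — the same ordering reliability studies of this design show.
    """
    from wristt1 import render_phantom, sample_subject_truth
    rng = np.random.default_rng(17)
    readings = {s: [] for s in ("TCL", "MN", "SFCT", "SCF", "MTE", "GCW")}
    for i in range(20):
        truth = sample_subject_truth(f"p{i}", "patient", False, prior, rng,
                                     noise_sigma=0.3)
        study = render_phantom(truth, protocol, rng)
        f1 = estimate_all_structures(signal_table(study), protocol)
        f2 = estimate_all_structures(reader_perturbation(study, 1, rng),
                                     protocol)
        for s in readings:
            assert f1[s].valid and f2[s].valid
            readings[s].append((f1[s].t1_ms, f2[s].t1_ms))
    iccs = {s: icc_two_reader(np.asarray(pairs))[0]
            for s, pairs in readings.items()}
    for s, icc in iccs.items():
        assert icc >= 0.5, (s, icc)                       # nothing below moderate
    good_or_better = [s for s, icc in iccs.items() if icc >= 0.75]
    assert len(good_or_better) >= 5, iccs                 # at most one exception
    assert iccs["GCW"] >= 0.9                             # whole-wrist: excellent


def test_icc_degrades_with_jitter(protocol, prior):
    """Median ICC across structures is non-increasing in jitter magnitude."""
    from wristt1 import render_phantom, sample_subject_truth
    structures = ("TCL", "MN", "SFCT", "SCF", "MTE", "GCW")
    med_icc = []
    for jitter in (1, 2):
        rng = np.random.default_rng(23)  # same subjects, same reader stream
        readings = {s: [] for s in structures}
        for i in range(10):
            truth = sample_subject_truth(f"p{i}", "patient", False, prior, rng,
                                         noise_sigma=0.3)
            study = render_phantom(truth, protocol, rng)
            f1 = estimate_all_structures(signal_table(study), protocol)
            f2 = estimate_all_structures(reader_perturbation(study, jitter, rng),
                                         protocol)
            for s in structures:
                if f1[s].valid and f2[s].valid:
                    readings[s].append((f1[s].t1_ms, f2[s].t1_ms))
        med_icc.append(np.median([icc_two_reader(np.asarray(p))[0]
                                  for p in readings.values()]))
    assert med_icc[1] <= med_icc[0]
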