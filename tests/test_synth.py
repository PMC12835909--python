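"""Synthetic generator: beat model, presets, rendering and cohort output."""

import json

import numpy as np
import pytest
from scipy import stats as sstats

from pdfecg.errors import ParamError
from pdfecg.fiducials import measure_pr_interval, measure_qrs_duration, \
    measure_ventricular_rate
from pdfecg.synth import (
    CLASS_LABELS,
    BeatModelParams,
    class_preset,
    generate_cohort,
    jitter_params,
    random_interval_params,
    synthesize_ecg,
)


def test_zero_noise_signal_exactly_periodic():
    params = BeatModelParams(rate_bpm=75.0, noise_sigma_uV=0.0)
    truth = synthesize_ecg(params, seed=0)
    x = truth.record.leads["II"].samples
    period = int(round(500 * 60 / 75.0))              # 400 samples
    r = truth.fiducials["II"].r_peaks
    a, b = r[0], r[1]
    w = 150
    np.testing.assert_allclose(x[a - w:a + w], x[a + period - w:a + period + w],
                               atol=1e-9)


def test_three_beats_in_strip_at_75_bpm():
    truth = synthesize_ecg(BeatModelParams(rate_bpm=75.0), seed=1)
    assert truth.fiducials["II"].r_peaks.size == 3


def test_same_seed_identical_samples():
    a = synthesize_ecg(BeatModelParams(), seed=42)
    b = synthesize_ecg(BeatModelParams(), seed=42)
    for name in a.record.leads:
        np.testing.assert_array_equal(a.record.leads[name].samples,
                                      b.record.leads[name].samples)


def test_infeasible_params_rejected():
    with pytest.raises(ParamError):
        BeatModelParams(rate_bpm=110.0, pr_ms=220.0, qrs_ms=190.0)
    with pytest.raises(ParamError):
        BeatModelParams(pr_ms=30.0)


def test_ground_truth_closure():
    """Programmed intervals equal intervals recomputed from true fiducials."""
    params = BeatModelParams(pr_ms=172.0, qrs_ms=118.0, rate_bpm=68.0)
    truth = synthesize_ecg(params, seed=3)
    sets = list(truth.fiducials.values())
    assert measure_qrs_duration(sets) == pytest.approx(params.qrs_ms, abs=1e-6)
    assert measure_pr_interval(sets) == pytest.approx(params.pr_ms, abs=1e-6)
    # R peaks are integer sample indices, so rate closure is exact only up to
    # the 2 ms index quantum
    assert measure_ventricular_rate(sets) == pytest.approx(params.rate_bpm,
                                                           abs=0.1)


def test_class_presets_valid_and_deterministic():
    for label in CLASS_LABELS:
        a, b = class_preset(label), class_preset(label)
        assert a == b
        synthesize_ecg(a, seed=0)                     # must be synthesizable
    with pytest.raises(KeyError):
        class_preset("HLHS")


def test_class_templates_far_apart_relative_to_jitter(rng):
    """Pairwise preset distance >> within-class jitter, in parameter space."""
    def amp_vector(params):
        return np.array([params.lead_amplitudes[lead][w]
                         for lead in sorted(params.lead_amplitudes)
                         for w in ("P", "Q", "R", "S", "T")])

    templates = {lab: amp_vector(class_preset(lab)) for lab in CLASS_LABELS}
    jitter_d = [np.linalg.norm(amp_vector(jitter_params(class_preset(lab), rng))
                               - templates[lab])
                for lab in CLASS_LABELS for _ in range(5)]
    jitter_sd = float(np.std(jitter_d) + np.mean(jitter_d))
    labs = list(CLASS_LABELS)
    for i in range(len(labs)):
        for j in range(i + 1, len(labs)):
            d = np.linalg.norm(templates[labs[i]] - templates[labs[j]])
            assert d > 10 * jitter_sd


def test_random_interval_params_within_ranges(rng):
    for _ in range(50):
        p = random_interval_params(rng)
        assert 120 <= p.pr_ms <= 220
        assert 80 <= p.qrs_ms <= 180
        assert 50 <= p.rate_bpm <= 110


def test_cohort_counts_and_determinism(tmp_path):
    idx1 = generate_cohort(2, 3, master_seed=5, out_dir=tmp_path / "a")
    idx2 = generate_cohort(2, 3, master_seed=5, out_dir=tmp_path / "b")
    pdfs = sorted((tmp_path / "a").glob("*.pdf"))
    assert len(pdfs) == 2 * 3 * 5                     # patients x ecgs x classes
    assert len(sorted((tmp_path / "a").glob("*.manifest.json"))) == 30
    assert idx1.read_text().replace("a/", "") == idx2.read_text().replace("b/", "")
    # sidecars byte-identical across regenerations
    for p in sorted((tmp_path / "a").glob("*.manifest.json")):
        q = tmp_path / "b" / p.name
        assert p.read_bytes() == q.read_bytes()


def test_cohort_interval_distribution_matches_programme(tmp_path):
    """Patient-level PR jitter is Normal(preset, 4 ms) by construction."""
    from pdfecg.synth import _PRESETS
    prs = []
    for pi in range(60):
        prng = np.random.default_rng(9000 + pi)
        prs.append(jitter_params(class_preset("ToF"), prng).pr_ms)
    stat = sstats.kstest(prs, "norm", args=(_PRESETS["ToF"]["pr"], 4.0))
    assert stat.pvalue > 0.01
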