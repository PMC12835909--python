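"""Shared fixtures: rendered synthetic pages reused across test modules."""

import numpy as np
import pytest

from pdfecg.synth import (
    BeatModelParams,
    RenderOptions,
    apply_artifacts,
    render_pdf,
    synthesize_ecg,
)


@pytest.fixture(scope="session")
def clean_truth():
    """One default synthetic ECG (75 bpm, PR 160 ms, QRS 100 ms)."""
    return synthesize_ecg(BeatModelParams(), seed=11)


@pytest.fixture(scope="session")
def clean_page(clean_truth):
    """Rendered clean page: (pdf bytes, renderer manifest)."""
    return render_pdf(clean_truth)


@pytest.fixture(scope="session")
def artifact_page():
    """Page carrying all three artifact types plus the truth behind it."""
    truth = synthesize_ecg(BeatModelParams(), seed=23)
    truth = apply_artifacts(
        truth,
        label_overlap=("V2",),
        cross_lead_overlap=(("V2", "V3"),),
        baseline_shift_mm={"V5": 3.0},
    )
    data, manifest = render_pdf(truth)
    return truth, data, manifest


@pytest.fixture(scope="session")
def unlabeled_page(clean_truth):
    return render_pdf(clean_truth, options=RenderOptions(draw_labels=False))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
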