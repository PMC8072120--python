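"""Shared fixtures: synthetic specimens and cohorts (generated, never stored).

Cohort fixtures are session-scoped because generating and warping a cohort
is the expensive part of the suite; every consumer treats them as
read-only.
"""
from __future__ import annotations

import pytest
from hypothesis import settings

import petalign as pa
from petalign.pipeline import process_cohort

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def frame():
    return pa.build_frame()


@pytest.fixture(scope="session")
def distal_specimen():
    return pa.generate_specimen(
        pa.SpecimenParams(distal_amp=0.6), seed=1, specimen_id="distal-1"
    )


@pytest.fixture(scope="session")
def plain_specimen():
    return pa.generate_specimen(pa.SpecimenParams(), seed=2, specimen_id="plain-1")


@pytest.fixture(scope="session")
def four_mode_results():
    """40-specimen pure-mode cohort processed end-to-end from raw images."""
    cohort = pa.generate_cohort(pa.four_mode_cohort(10, master_seed=7))
    rois, frm = process_cohort(cohort)
    calls = [pa.classify_specimen(r, frm) for r in rois]
    return cohort, rois, frm, calls


@pytest.fixture(scope="session")
def gradient_results():
    """60-specimen cohort with independent distal/proximal gradient amplitudes."""
    cohort = pa.generate_cohort(pa.gradient_cohort(6, 10, master_seed=21))
    rois, frm = process_cohort(cohort)
    model = pa.PatternPCA().fit_rois(rois)
    return cohort, rois, frm, model


@pytest.fixture(scope="session")
def homology_pair():
    """Same pigment pattern, deliberately different petal shapes."""
    shared = dict(distal_amp=0.5, proximal_amp=0.25)
    pa_params = pa.SpecimenParams(
        lobe_rx=75, lobe_ry=112, tube_len=135, taper=0.8,
        serration_depth=2.5, **shared,
    )
    pb_params = pa.SpecimenParams(
        lobe_rx=100, lobe_ry=105, tube_len=100, taper=0.68,
        serration_depth=3.5, **shared,
    )
    return (
        pa.generate_specimen(pa_params, seed=11, specimen_id="shape-a"),
        pa.generate_specimen(pb_params, seed=12, specimen_id="shape-b"),
    )
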