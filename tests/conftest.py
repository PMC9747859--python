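"""Shared fixtures: small deterministic images plus one session-scoped
end-to-end run of the three bundled thorax fixtures (the expensive part,
computed once and reused by pipeline, metrics and acceptance tests)."""

from __future__ import annotations

import numpy as np
import pytest

import ccsmar as cm
from ccsmar.metrics import default_rois
from ccsmar.synthetic import FIXTURE_SPECS, AcquisitionSpec, PhantomSpec, generate_phantom, make_fixture_pair


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture(scope="session")
def clean_phantom() -> cm.CTImage:
    """Metal-free reference thorax slice (default 256² grid)."""
    return generate_phantom(PhantomSpec(metal_width_mm=0.0))


@pytest.fixture(scope="session")
def small_phantom() -> cm.CTImage:
    """A 64² thorax slice for fast unit tests."""
    return generate_phantom(PhantomSpec(shape=(64, 64), metal_width_mm=0.0))


@pytest.fixture(scope="session")
def fixture_runs() -> dict:
    """Run the full correction on the three bundled fixtures once.

    Returns, per fixture name, the reference, corrupted and corrected
    scans, the transplanted reference, the truth masks, the provenance
    record and the quality report.
    """
    runs = {}
    for name, spec in FIXTURE_SPECS.items():
        ct_ref, ct_art, masks = make_fixture_pair(spec, AcquisitionSpec(seed=spec.seed))
        ct_cor, prov = cm.run_ccs_mar(ct_art, cm.MARConfig())
        ref_t = cm.transplant_metal_pixels(ct_ref, ct_art, masks["metal"])
        report = cm.evaluate_mar(ct_ref, ct_art, ct_cor, masks["metal"], default_rois())
        runs[name] = {
            "ref": ct_ref,
            "art": ct_art,
            "cor": ct_cor,
            "ref_t": ref_t,
            "masks": masks,
            "prov": prov,
            "report": report,
        }
    return runs


@pytest.fixture(scope="session")
def clean_run(clean_phantom) -> tuple[cm.CTImage, dict]:
    """Full pipeline applied to a metal-free slice (near-identity case)."""
    return cm.run_ccs_mar(clean_phantom, cm.MARConfig())
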