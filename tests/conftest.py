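from __future__ import annotations

import pytest

from regioprot.io_formats import PsmRecord


def make_psm(
    peptide: str = "GTISAITEK",
    region: str = "thalamus",
    replicate: str = "rat1",
    slice_index: int = 5,
    spectrum_id: str = "spec1",
    modifications: tuple = (),
    charge: int = 2,
    precursor_mz: float = 460.258,
    ion_score: float = 55.0,
    threshold_score: float = 40.0,
    n_b: int = 5,
    n_y: int = 8,
    candidates: tuple = ("P1",),
) -> PsmRecord:
    rec = PsmRecord(
        region=region,
        replicate_id=replicate,
        slice_index=slice_index,
        spectrum_id=spectrum_id,
        peptide_sequence=peptide,
        modifications=modifications,
        charge=charge,
        precursor_mz=precursor_mz,
        ion_score=ion_score,
        threshold_score=threshold_score,
        n_b_matched=n_b,
        n_y_matched=n_y,
        candidate_accessions=candidates,
    )
    rec.validate()
    return rec


@pytest.fixture
def psm_factory():
    return make_psm
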