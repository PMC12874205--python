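import numpy as np
import pytest

from fucostoich.constants import SearchConstants
from fucostoich.ingest import ChannelLayout, PSMRecord, ProteinDB

GLYCO = SearchConstants().glyco_tag_mass


@pytest.fixture
def layout() -> ChannelLayout:
    return ChannelLayout(
        channel_names=("126", "127", "128", "129", "130", "131"),
        condition=("control",) * 3 + ("treated",) * 3,
        replicate=(1, 2, 3, 1, 2, 3),
    )


@pytest.fixture
def toy_db() -> ProteinDB:
    db = ProteinDB()
    db.add("P00001", "AAANKSAAA")
    db.add("P00002", "MKAAANGSAAAKLMNGTAAR")
    return db


def make_psm(
    peptide="AAANGSAAAK",
    protein_id="P00002",
    mods=None,
    is_decoy=False,
    reporters=(100, 100, 100, 200, 200, 200),
    spectrum_id="scan1",
    features=None,
) -> PSMRecord:
    if mods is None:
        mods = [(4, GLYCO)]
    if features is None:
        features = [2.5, 0.4, 0, 1.0, 0.5, 1.0, len(peptide), len(mods), 2]
    return PSMRecord(
        spectrum_id=spectrum_id,
        peptide=peptide,
        protein_id=protein_id,
        mod_positions=list(mods),
        is_decoy=is_decoy,
        features=np.asarray(features, dtype=float),
        reporters=np.asarray(reporters, dtype=float),
    )
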