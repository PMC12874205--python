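"""End-to-end runs: ingest -> identify -> quantify on in-memory objects."""

from __future__ import annotations

from dataclasses import dataclass

from .constants import SearchConstants
from .identify import FilterReport, IdentifiedPSM, identify_psms
from .ingest import ChannelLayout, PSMRecord, ProteinDB
from .quantify import StoichiometryEstimate, quantify_psms


@dataclass
class QuantifyResult:
    estimates: list[StoichiometryEstimate]
    report: FilterReport
    identified: list[IdentifiedPSM]
    excluded_low_intensity: list[tuple[str, str]]


def run_quantify(
    psms: list[PSMRecord],
    db: ProteinDB,
    layout: ChannelLayout,
    constants: SearchConstants | None = None,
) -> QuantifyResult:
    """Select glyco-PSMs, control FDR, and quantify stoichiometries."""
    constants = constants or SearchConstants()
    identified, report = identify_psms(psms, db, constants)
    estimates, excluded = quantify_psms(identified, layout)
    return QuantifyResult(
        estimates=estimates,
        report=report,
        identified=identified,
        excluded_low_intensity=excluded,
    )
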