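"""Input parsing and the internal data model.

The pipeline starts downstream of the database search: its inputs are a
tab-separated PSM table (one row per peptide-spectrum match, carrying the
search engine's discriminant features and six TMT reporter intensities),
a protein FASTA for rolling peptide-level modification positions up to
protein coordinates, a YAML channel layout assigning the six TMT channels
to control/treated replicates, and optional per-site annotation tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import yaml
from Bio import SeqIO

from .constants import N_CHANNELS

__all__ = [
    "FEATURE_NAMES",
    "PSMRecord",
    "ChannelLayout",
    "ProteinDB",
    "AnnotationMap",
    "IngestError",
    "SiteMappingError",
    "DEFAULT_DIALECT",
    "read_psm_table",
    "write_psm_table",
    "read_fasta",
    "read_layout",
    "read_annotations",
    "map_site",
]


class IngestError(ValueError):
    """Fatal problem with an input file."""


class SiteMappingError(ValueError):
    """A PSM could not be placed on its protein."""


#: Fixed feature order used to assemble matrices for LDA rescoring.
FEATURE_NAMES = (
    "xcorr",
    "dcorr",
    "missed_cleavages",
    "adjusted_ppm",
    "frac_ions_matched",
    "mass_accuracy",
    "peptide_length",
    "n_mods",
    "charge",
)

_PEPTIDE_RE = re.compile(r"^[A-Z]+$")


@dataclass
class PSMRecord:
    """One peptide-spectrum match.

    ``mod_positions`` holds (1-based position within the peptide, mass
    delta in Da) pairs. ``features`` follows :data:`FEATURE_NAMES` order.
    ``reporters`` are the six TMT reporter intensities in the channel
    order given by the table dialect.
    """

    spectrum_id: str
    peptide: str
    protein_id: str
    mod_positions: list[tuple[int, float]]
    is_decoy: bool
    features: np.ndarray
    reporters: np.ndarray
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not _PEPTIDE_RE.match(self.peptide):
            raise IngestError(f"invalid peptide string: {self.peptide!r}")
        for pos, _delta in self.mod_positions:
            if not (1 <= pos <= len(self.peptide)):
                raise IngestError(
                    f"mod position {pos} outside peptide of length {len(self.peptide)}"
                )
        self.features = np.asarray(self.features, dtype=float)
        if self.features.shape != (len(FEATURE_NAMES),):
            raise IngestError(
                f"feature vector must have {len(FEATURE_NAMES)} entries"
            )
        self.reporters = np.asarray(self.reporters, dtype=float)
        if self.reporters.shape != (N_CHANNELS,):
            raise IngestError(f"expected {N_CHANNELS} reporter intensities")
        if (self.reporters < 0).any():
            raise IngestError("reporter intensities must be non-negative")


@dataclass(frozen=True)
class ChannelLayout:
    """Assignment of the six TMT channels to condition and replicate."""

    channel_names: tuple[str, ...]
    condition: tuple[str, ...]  # "control" / "treated" per channel
    replicate: tuple[int, ...]  # 1..3 per channel

    def __post_init__(self) -> None:
        if not (
            len(self.channel_names) == len(self.condition) == len(self.replicate) == N_CHANNELS
        ):
            raise IngestError(f"layout must describe exactly {N_CHANNELS} channels")
        for cond in ("control", "treated"):
            reps = sorted(r for c, r in zip(self.condition, self.replicate) if c == cond)
            if reps != [1, 2, 3]:
                raise IngestError(
                    f"condition {cond!r} must have replicates 1,2,3 exactly once (got {reps})"
                )

    def indices(self, cond: str) -> list[int]:
        """Channel indices for one condition, ordered by replicate."""
        pairs = [
            (rep, i)
            for i, (c, rep) in enumerate(zip(self.condition, self.replicate))
            if c == cond
        ]
        return [i for _rep, i in sorted(pairs)]

    @property
    def control_indices(self) -> list[int]:
        return self.indices("control")

    @property
    def treated_indices(self) -> list[int]:
        return self.indices("treated")

    def to_dict(self) -> dict:
        return {
            "channels": [
                {"name": n, "condition": c, "replicate": r}
                for n, c, r in zip(self.channel_names, self.condition, self.replicate)
            ]
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ChannelLayout":
        try:
            chans = d["channels"]
            return cls(
                channel_names=tuple(str(ch["name"]) for ch in chans),
                condition=tuple(str(ch["condition"]) for ch in chans),
                replicate=tuple(int(ch["replicate"]) for ch in chans),
            )
        except (KeyError, TypeError) as exc:
            raise IngestError(f"malformed channel layout: {exc}") from exc


class ProteinDB(dict):
    """Accession -> uppercase protein sequence."""

    def add(self, accession: str, sequence: str) -> None:
        if accession in self:
            raise IngestError(f"duplicate accession in FASTA: {accession}")
        if not sequence:
            raise IngestError(f"empty sequence for accession {accession}")
        self[accession] = sequence.upper()


ANNOTATION_CATEGORIES = {
    "compartment": None,  # free vocabulary
    "domain": None,
    "secondary_structure": {"helix", "sheet", "coil"},
    "disorder": {"ordered", "disordered"},
}


class AnnotationMap(dict):
    """(accession, 1-based site) -> {category: set of labels}."""

    def add(self, accession: str, site: int, category: str, label: str) -> None:
        if category not in ANNOTATION_CATEGORIES:
            raise IngestError(
                f"unknown annotation category {category!r}; "
                f"expected one of {sorted(ANNOTATION_CATEGORIES)}"
            )
        allowed = ANNOTATION_CATEGORIES[category]
        if allowed is not None and label not in allowed:
            raise IngestError(
                f"label {label!r} not allowed for category {category!r} ({sorted(allowed)})"
            )
        if site < 1:
            raise IngestError(f"site must be a positive integer, got {site}")
        self.setdefault((accession, site), {}).setdefault(category, set()).add(label)


# --- PSM table I/O ----------------------------------------------------------

#: Logical name -> column header in the default table dialect.
DEFAULT_DIALECT: dict[str, str] = {
    "spectrum_id": "spectrum_id",
    "peptide": "peptide",
    "protein": "protein",
    "mods": "mods",
    "decoy": "decoy",
    "xcorr": "xcorr",
    "dcorr": "dcorr",
    "missed_cleavages": "missed_cleavages",
    "adjusted_ppm": "ppm",
    "frac_ions_matched": "frac_ions_matched",
    "mass_accuracy": "mass_accuracy",
    "peptide_length": "length",
    "n_mods": "n_mods",
    "charge": "charge",
    "reporters": [f"reporter_{i}" for i in range(1, N_CHANNELS + 1)],
}

_REQUIRED_KEYS = [
    "spectrum_id", "peptide", "protein", "mods", "decoy",
    "xcorr", "dcorr", "missed_cleavages", "adjusted_ppm",
    "frac_ions_matched", "peptide_length", "n_mods", "charge",
]


def _parse_mods(text: str) -> list[tuple[int, float]]:
    text = text.strip()
    if not text or text in ("-", "."):
        return []
    out = []
    for item in text.split(";"):
        pos_s, delta_s = item.split(":")
        out.append((int(pos_s), float(delta_s)))
    return out


def _format_mods(mods: Iterable[tuple[int, float]]) -> str:
    return ";".join(f"{pos}:{delta:.4f}" for pos, delta in mods)


def read_psm_table(
    path: str | Path,
    dialect: Mapping | None = None,
) -> tuple[list[PSMRecord], list[tuple[int, str]]]:
    """Read a tab-separated PSM table.

    Returns (records, report) where *report* lists (1-based data-row
    number, reason) for rows rejected because a numeric field failed to
    parse. Missing required columns and an empty file are fatal.
    """
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline()
        if not header_line.strip():
            raise IngestError(f"{path}: empty PSM table")
        header = header_line.rstrip("\n").split("\t")
        col_index = {name: i for i, name in enumerate(header)}

        needed = [dialect[k] for k in _REQUIRED_KEYS] + list(dialect["reporters"])
        has_mass_accuracy = dialect.get("mass_accuracy") in col_index
        for col in needed:
            if col not in col_index:
                raise IngestError(f"{path}: missing required column {col!r}")

        records: list[PSMRecord] = []
        report: list[tuple[int, str]] = []
        for row_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")

            def get(key: str) -> str:
                return cells[col_index[dialect[key]]]

            try:
                mods = _parse_mods(get("mods"))
                reporters = [float(cells[col_index[c]]) for c in dialect["reporters"]]
                adjusted_ppm = float(get("adjusted_ppm"))
                mass_accuracy = (
                    float(cells[col_index[dialect["mass_accuracy"]]])
                    if has_mass_accuracy
                    else adjusted_ppm
                )
                features = [
                    float(get("xcorr")),
                    float(get("dcorr")),
                    float(get("missed_cleavages")),
                    adjusted_ppm,
                    float(get("frac_ions_matched")),
                    mass_accuracy,
                    float(get("peptide_length")),
                    float(get("n_mods")),
                    float(get("charge")),
                ]
                rec = PSMRecord(
                    spectrum_id=get("spectrum_id"),
                    peptide=get("peptide"),
                    protein_id=get("protein"),
                    mod_positions=mods,
                    is_decoy=bool(int(get("decoy"))),
                    features=np.array(features),
                    reporters=np.array(reporters),
                )
            except (ValueError, IndexError) as exc:
                report.append((row_no, str(exc)))
                continue
            records.append(rec)
    if not records and not report:
        raise IngestError(f"{path}: PSM table has a header but no rows")
    return records, report


def write_psm_table(
    records: Iterable[PSMRecord],
    path: str | Path,
    dialect: Mapping | None = None,
    extra_columns: Mapping[str, list] | None = None,
) -> None:
    """Write PSMRecords in the table dialect (round-trips with the reader)."""
    dialect = dict(DEFAULT_DIALECT if dialect is None else dialect)
    header = [dialect[k] for k in _REQUIRED_KEYS]
    header.insert(header.index(dialect["frac_ions_matched"]) + 1, dialect["mass_accuracy"])
    header += list(dialect["reporters"])
    extra = dict(extra_columns or {})
    header += list(extra)
    rows = []
    for i, rec in enumerate(records):
        f = dict(zip(FEATURE_NAMES, rec.features))
        row = [
            rec.spectrum_id,
            rec.peptide,
            rec.protein_id,
            _format_mods(rec.mod_positions),
            str(int(rec.is_decoy)),
        ]
        # repr of Python floats round-trips exactly
        row += [
            repr(float(f[name]))
            for name in (
                "xcorr", "dcorr", "missed_cleavages", "adjusted_ppm",
                "frac_ions_matched", "mass_accuracy", "peptide_length",
                "n_mods", "charge",
            )
        ]
        row += [repr(float(x)) for x in rec.reporters]
        row += [str(extra[k][i]) for k in extra]
        rows.append("\t".join(row))
    Path(path).write_text("\t".join(header) + "\n" + "\n".join(rows) + ("\n" if rows else ""))


# --- FASTA ------------------------------------------------------------------

def _accession_from_header(header_id: str) -> str:
    # UniProt style: sp|P01234|NAME -> P01234
    if "|" in header_id:
        parts = header_id.split("|")
        if len(parts) >= 3 and parts[1]:
            return parts[1]
    return header_id


def read_fasta(path: str | Path) -> ProteinDB:
    """Load a protein FASTA into an accession -> sequence map."""
    path = Path(path)
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise IngestError(f"{path}:{line_no}: not FASTA (expected '>' header)")
            break
        else:
            raise IngestError(f"{path}: empty FASTA")
    db = ProteinDB()
    for record in SeqIO.parse(str(path), "fasta"):
        db.add(_accession_from_header(record.id), str(record.seq))
    return db


# --- Channel layout ---------------------------------------------------------

def read_layout(path: str | Path) -> ChannelLayout:
    """Read the YAML channel layout (names, condition, replicate)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, Mapping):
        raise IngestError(f"{path}: layout YAML must be a mapping")
    return ChannelLayout.from_dict(data)


# --- Annotations ------------------------------------------------------------

def read_annotations(path: str | Path) -> AnnotationMap:
    """Read a TSV with columns accession, site, category, label."""
    path = Path(path)
    amap = AnnotationMap()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["accession", "site", "category", "label"]
        if header[: len(expected)] != expected:
            raise IngestError(f"{path}: annotation header must be {expected}")
        for line_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split("\t")
            try:
                acc, site_s, category, label = cells[:4]
                amap.add(acc, int(site_s), category, label)
            except (ValueError, IngestError) as exc:
                raise IngestError(f"{path}:{line_no}: {exc}") from exc
    return amap


# --- Reporter correction and shared peptides ---------------------------------

def apply_reporter_correction(
    psms: Iterable[PSMRecord], matrix: np.ndarray | None = None
) -> None:
    """Correct reporter intensities for channel cross-talk, in place.

    ``matrix`` is the 6x6 mixing matrix M with observed = M @ true
    (e.g. an isotope-impurity matrix from the label lot sheet). The
    default is the identity, i.e. no correction. Corrected intensities
    are clipped at zero.
    """
    if matrix is None:
        return
    M = np.asarray(matrix, dtype=float)
    if M.shape != (N_CHANNELS, N_CHANNELS):
        raise IngestError(f"correction matrix must be {N_CHANNELS}x{N_CHANNELS}")
    for psm in psms:
        psm.reporters = np.clip(np.linalg.solve(M, psm.reporters), 0.0, None)


def resolve_shared_peptides(psms: Iterable[PSMRecord], db: ProteinDB) -> None:
    """Re-assign peptides occurring in several proteins, in place.

    The representative accession is the alphabetically first one whose
    sequence contains the peptide; PSMs with more than one match are
    flagged ``shared``.
    """
    cache: dict[str, list[str]] = {}
    for psm in psms:
        if psm.peptide not in cache:
            cache[psm.peptide] = sorted(
                acc for acc, seq in db.items() if psm.peptide in seq
            )
        matches = cache[psm.peptide]
        if not matches:
            continue
        psm.protein_id = matches[0]
        if len(matches) > 1:
            psm.flags.add("shared")


# --- Site mapping -----------------------------------------------------------

def map_site(
    psm: PSMRecord,
    db: ProteinDB,
    mod_position: int | None = None,
) -> int:
    """Map a peptide-level modification position to protein coordinates.

    Returns the 1-based protein position of the modified residue, using
    the leftmost occurrence of the peptide in the protein; if the peptide
    occurs more than once the PSM is flagged ``ambiguous``. The modified
    residue must be asparagine.
    """
    if mod_position is None:
        if len(psm.mod_positions) != 1:
            raise SiteMappingError(
                f"{psm.spectrum_id}: mod_position required when the PSM has "
                f"{len(psm.mod_positions)} modifications"
            )
        mod_position = psm.mod_positions[0][0]
    if psm.protein_id not in db:
        raise SiteMappingError(f"{psm.spectrum_id}: unknown protein {psm.protein_id}")
    protein = db[psm.protein_id]
    start = protein.find(psm.peptide)
    if start < 0:
        raise SiteMappingError(
            f"{psm.spectrum_id}: peptide {psm.peptide} not found in {psm.protein_id}"
        )
    if protein.find(psm.peptide, start + 1) >= 0:
        psm.flags.add("ambiguous")
    if psm.peptide[mod_position - 1] != "N":
        raise SiteMappingError(
            f"{psm.spectrum_id}: modified residue at peptide position "
            f"{mod_position} is {psm.peptide[mod_position - 1]}, not N"
        )
    return start + mod_position  # start is 0-based -> 1-based site
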