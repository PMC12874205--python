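"""Synthetic split-and-treat TMT datasets with known ground truth.

The generator inverts the measurement workflow: for a glycopeptide with
true core-fucosylation stoichiometry s, the control half of the split
sample carries s of the copies tagged, while the FUT8-treated half
carries s + c·(1−s) of them, where c is the conversion completeness of
the in-vitro reaction (c = 1 means every eligible site was fucosylated).
Reporter intensities are proportional to tagged copies per replicate,
perturbed by multiplicative log-normal channel noise. The expected
measured ratio s / (s + c·(1−s)) is exposed as a closed-form oracle.

Decoy PSMs — and optionally "false target" PSMs drawn from the decoy
feature distribution but labeled as targets — are embedded alongside
true targets so that target-decoy FDR control can be exercised against
known labels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import yaml

from .constants import SearchConstants
from .ingest import ChannelLayout, PSMRecord, ProteinDB, write_psm_table
from .quantify import GlycopeptideKey, StoichiometryEstimate

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "SyntheticDataset",
    "FEATURE_PRESETS",
    "DEFAULT_LAYOUT",
    "generate_dataset",
    "write_dataset",
    "closed_form_bias",
    "recovery_report",
]

DEFAULT_LAYOUT = ChannelLayout(
    channel_names=("126", "127", "128", "129", "130", "131"),
    condition=("control", "control", "control", "treated", "treated", "treated"),
    replicate=(1, 2, 3, 1, 2, 3),
)

# Per-feature (target mean, decoy mean, shared sd) for the five
# search-quality features drawn from Gaussians. The remaining features
# (missed cleavages, peptide length, n mods, charge) come from the
# generated peptides themselves.
FEATURE_PRESETS: dict[str, dict[str, tuple[float, float, float]]] = {
    # realistic overlap: decoys and weak targets mix in the tails
    "overlapping": {
        "xcorr": (3.0, 2.0, 0.65),
        "dcorr": (0.42, 0.20, 0.13),
        "adjusted_ppm": (1.2, 2.8, 1.2),
        "frac_ions_matched": (0.55, 0.38, 0.12),
        "mass_accuracy": (1.2, 2.8, 1.2),
    },
    # near-perfect separation: every true target clears the FDR cut
    "clean": {
        "xcorr": (5.0, 1.5, 0.30),
        "dcorr": (0.60, 0.10, 0.05),
        "adjusted_ppm": (0.8, 4.0, 0.6),
        "frac_ions_matched": (0.70, 0.25, 0.06),
        "mass_accuracy": (0.8, 4.0, 0.6),
    },
}

_NON_KR = "ACDEFGHILMNPQSTVWY"
_SEQUON_X = "ACDEFGHILMQSTVWY"  # +1 residue: no P (sequon), no K/R (tryptic)
_STOICH_QUANTUM = 2.0 ** -20


@dataclass(frozen=True)
class SimulationParams:
    """Generator settings; the seed is mandatory for reproducibility.

    ``stoich_dist`` is ("uniform",), ("beta", a, b) or ("fixed", values);
    sampled stoichiometries are quantized to multiples of 2^-20 so the
    noiseless measurement model is exact in floating point.
    ``psms_per_glycopeptide`` is ("fixed", k) or ("one_plus_poisson", lam).
    """

    seed: int
    n_glycopeptides: int = 200
    stoich_dist: tuple = ("uniform",)
    conversion_completeness: float = 1.0
    psms_per_glycopeptide: tuple = ("one_plus_poisson", 1.0)
    base_intensity: float = 2.0 ** 20
    sigma: float = 0.07
    decoy_fraction: float = 0.3
    false_target_fraction: float = 0.0
    feature_model: str = "overlapping"
    peptide_length_range: tuple[int, int] = (9, 18)
    glyco_tag_mass: float = SearchConstants().glyco_tag_mass

    def __post_init__(self) -> None:
        if not (0.0 < self.conversion_completeness <= 1.0):
            raise ValueError("conversion_completeness must be in (0, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        for name in ("decoy_fraction", "false_target_fraction"):
            if not (0.0 <= getattr(self, name) < 1.0):
                raise ValueError(f"{name} must be in [0, 1)")
        if self.n_glycopeptides < 1:
            raise ValueError("n_glycopeptides must be >= 1")
        if self.feature_model not in FEATURE_PRESETS:
            raise ValueError(
                f"feature_model must be one of {sorted(FEATURE_PRESETS)}"
            )
        lo, hi = self.peptide_length_range
        if lo < 9 or hi < lo:
            raise ValueError("peptide_length_range must satisfy 9 <= lo <= hi")


@dataclass
class GroundTruth:
    """True stoichiometries and per-PSM target/false labels."""

    stoichiometry: dict[GlycopeptideKey, float]
    psm_is_true: dict[str, bool]  # spectrum_id -> genuinely correct match
    conversion_completeness: float


@dataclass
class SyntheticDataset:
    psms: list[PSMRecord]
    db: ProteinDB
    layout: ChannelLayout
    truth: GroundTruth
    params: SimulationParams


def closed_form_bias(s: float, c: float) -> float:
    """Expected measured ratio for true stoichiometry s at completeness c.

    Control signal ∝ s, treated signal ∝ s + c·(1−s), so the measured
    stoichiometry converges to s / (s + c·(1−s)); unbiased iff c = 1.
    """
    if not (0.0 <= s <= 1.0):
        raise ValueError("s must be in [0, 1]")
    if not (0.0 < c <= 1.0):
        raise ValueError("c must be in (0, 1]")
    denom = s + c * (1.0 - s)
    if denom == 0.0:
        raise ValueError("undefined ratio: s = 0 with c = 0")
    return s / denom


def _sample_stoichiometries(params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    kind = params.stoich_dist[0]
    n = params.n_glycopeptides
    if kind == "uniform":
        raw = rng.random(n)
    elif kind == "beta":
        _, a, b = params.stoich_dist
        raw = rng.beta(a, b, size=n)
    elif kind == "fixed":
        values = np.asarray(params.stoich_dist[1], dtype=float)
        if values.size != n:
            raise ValueError("fixed stoichiometry list length != n_glycopeptides")
        return values  # caller-supplied values pass through unquantized
    else:
        raise ValueError(f"unknown stoichiometry distribution {kind!r}")
    return np.round(raw / _STOICH_QUANTUM) * _STOICH_QUANTUM


def _n_psms(params: SimulationParams, rng: np.random.Generator) -> int:
    kind = params.psms_per_glycopeptide[0]
    if kind == "fixed":
        return int(params.psms_per_glycopeptide[1])
    if kind == "one_plus_poisson":
        return 1 + int(rng.poisson(params.psms_per_glycopeptide[1]))
    raise ValueError(f"unknown PSM-count distribution {kind!r}")


def _random_glycopeptide(
    rng: np.random.Generator, params: SimulationParams
) -> tuple[str, int]:
    """Tryptic-looking peptide with one embedded sequon; returns (seq, N pos)."""
    lo, hi = params.peptide_length_range
    length = int(rng.integers(lo, hi + 1))
    seq = list(rng.choice(list(_NON_KR), size=length))
    # occasional internal K/R so the missed-cleavage feature is meaningful
    n_internal_kr = int(rng.binomial(2, 0.15))
    # 1-based N position; +2 residue must stay clear of the tryptic C-terminus
    npos = int(rng.integers(2, length - 2))
    seq[npos - 1] = "N"
    seq[npos] = str(rng.choice(list(_SEQUON_X)))
    seq[npos + 1] = str(rng.choice(["S", "T", "C"], p=[0.45, 0.45, 0.10]))
    sequon_idx = {npos - 1, npos, npos + 1}
    free = [i for i in range(length - 1) if i not in sequon_idx]
    for i in rng.choice(free, size=min(n_internal_kr, len(free)), replace=False):
        seq[int(i)] = str(rng.choice(["K", "R"]))
    seq[-1] = str(rng.choice(["K", "R"]))  # tryptic C-terminus
    return "".join(seq), npos


def _embed_in_protein(
    peptide: str, rng: np.random.Generator, max_tries: int = 50
) -> str:
    for _ in range(max_tries):
        prefix = "".join(rng.choice(list(_NON_KR), size=int(rng.integers(4, 16))))
        prefix += str(rng.choice(["K", "R"]))  # tryptic boundary before peptide
        suffix = "".join(rng.choice(list(_NON_KR), size=int(rng.integers(5, 21))))
        protein = prefix + peptide + suffix
        if protein.count(peptide) == 1:
            return protein
    raise RuntimeError(f"could not embed peptide {peptide} uniquely")


def _draw_features(
    rng: np.random.Generator,
    preset: dict[str, tuple[float, float, float]],
    is_target_like: bool,
    peptide: str,
    n_mods: int,
) -> np.ndarray:
    idx = 0 if is_target_like else 1

    def draw(name: str) -> float:
        t_mean, d_mean, sd = preset[name]
        return float(rng.normal((t_mean, d_mean)[idx], sd))

    missed = sum(1 for r in peptide[:-1] if r in "KR")
    charge = float(rng.choice([2, 3, 4], p=[0.5, 0.4, 0.1]))
    return np.array(
        [
            draw("xcorr"),
            draw("dcorr"),
            float(missed),
            draw("adjusted_ppm"),
            min(max(draw("frac_ions_matched"), 0.0), 1.0),
            draw("mass_accuracy"),
            float(len(peptide)),
            float(n_mods),
            charge,
        ]
    )


def _reporters(
    s: float,
    params: SimulationParams,
    layout: ChannelLayout,
    rng: np.random.Generator,
) -> np.ndarray:
    B = params.base_intensity
    c = params.conversion_completeness
    control_val = B * s
    treated_val = B * (s + c * (1.0 - s))
    out = np.empty(len(layout.channel_names))
    out[layout.control_indices] = control_val
    out[layout.treated_indices] = treated_val
    if params.sigma > 0:
        out *= np.exp(rng.normal(0.0, params.sigma, size=out.size))
    return out


def generate_dataset(params: SimulationParams) -> SyntheticDataset:
    """Generate a PSM table, FASTA, layout, and ground truth.

    Deterministic for a given ``params`` (including the seed): the same
    parameters always produce byte-identical outputs.
    """
    rng = np.random.default_rng(params.seed)
    layout = DEFAULT_LAYOUT
    preset = FEATURE_PRESETS[params.feature_model]
    db = ProteinDB()
    truth_stoich: dict[GlycopeptideKey, float] = {}
    psm_is_true: dict[str, bool] = {}
    psms: list[PSMRecord] = []
    scan = 0
    seen_peptides: set[str] = set()

    def unique_glycopeptide() -> tuple[str, int]:
        for _ in range(200):
            pep, npos = _random_glycopeptide(rng, params)
            if pep not in seen_peptides:
                seen_peptides.add(pep)
                return pep, npos
        raise RuntimeError("failed to generate a unique glycopeptide")

    def make_psm(
        accession: str, peptide: str, npos: int, s: float,
        is_decoy: bool, target_like: bool,
    ) -> PSMRecord:
        nonlocal scan
        scan += 1
        mods = [(npos, params.glyco_tag_mass)]
        return PSMRecord(
            spectrum_id=f"scan{scan:06d}",
            peptide=peptide,
            protein_id=accession,
            mod_positions=mods,
            is_decoy=is_decoy,
            features=_draw_features(rng, preset, target_like, peptide, len(mods)),
            reporters=_reporters(s, params, layout, rng),
        )

    # true target glycopeptides
    stoich = _sample_stoichiometries(params, rng)
    n_true_psms = 0
    for i in range(params.n_glycopeptides):
        peptide, npos = unique_glycopeptide()
        accession = f"SYNT{i:05d}"
        protein = _embed_in_protein(peptide, rng)
        db.add(accession, protein)
        site = protein.index(peptide) + npos
        key = GlycopeptideKey(peptide, accession, site)
        truth_stoich[key] = float(stoich[i])
        for _ in range(_n_psms(params, rng)):
            psm = make_psm(accession, peptide, npos, float(stoich[i]),
                           is_decoy=False, target_like=True)
            psm_is_true[psm.spectrum_id] = True
            psms.append(psm)
            n_true_psms += 1

    # decoy-distributed PSMs: labeled decoys, plus false targets at a known rate
    n_decoys = int(round(params.decoy_fraction * n_true_psms))
    n_false = int(round(params.false_target_fraction * n_true_psms))
    for j in range(n_decoys + n_false):
        is_false_target = j >= n_decoys
        peptide, npos = unique_glycopeptide()
        accession = (f"FALS{j - n_decoys:05d}" if is_false_target
                     else f"DECY{j:05d}")
        protein = _embed_in_protein(peptide, rng)
        db.add(accession, protein)
        s_fake = float(rng.random())
        psm = make_psm(accession, peptide, npos, s_fake,
                       is_decoy=not is_false_target, target_like=False)
        if is_false_target:
            psm_is_true[psm.spectrum_id] = False
        psms.append(psm)

    order = rng.permutation(len(psms))
    psms = [psms[i] for i in order]
    truth = GroundTruth(
        stoichiometry=truth_stoich,
        psm_is_true=psm_is_true,
        conversion_completeness=params.conversion_completeness,
    )
    return SyntheticDataset(psms=psms, db=db, layout=layout, truth=truth, params=params)


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit the dataset in the formats the pipeline ingests."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "psms": outdir / "psms.tsv",
        "fasta": outdir / "proteins.fasta",
        "layout": outdir / "layout.yaml",
        "truth": outdir / "truth.tsv",
    }
    write_psm_table(dataset.psms, paths["psms"])
    with open(paths["fasta"], "w") as fh:
        for acc in sorted(dataset.db):
            fh.write(f">{acc}\n{dataset.db[acc]}\n")
    with open(paths["layout"], "w") as fh:
        yaml.safe_dump(dataset.layout.to_dict(), fh, sort_keys=False)
    with open(paths["truth"], "w") as fh:
        fh.write("accession\tsite\tpeptide\ttrue_stoichiometry\n")
        for key in sorted(dataset.truth.stoichiometry):
            fh.write(
                f"{key.accession}\t{key.site}\t{key.peptide}\t"
                f"{dataset.truth.stoichiometry[key]!r}\n"
            )
    return paths


def recovery_report(
    truth: GroundTruth,
    estimates: Iterable[StoichiometryEstimate],
) -> tuple["pd.DataFrame", dict]:
    """Per-glycopeptide recovery errors against the closed-form expectation.

    The error is estimate − s/(s + c·(1−s)); with c = 1 this is simply
    estimate − s. Missing keys are reported, not fatal.
    """
    import pandas as pd

    c = truth.conversion_completeness
    est_by_key = {e.key: e for e in estimates}
    rows = []
    missing = []
    for key, s in sorted(truth.stoichiometry.items()):
        expected = closed_form_bias(s, c) if (s > 0 or c > 0) else float("nan")
        e = est_by_key.get(key)
        if e is None:
            missing.append(key)
            continue
        rows.append(
            {
                "accession": key.accession,
                "site": key.site,
                "peptide": key.peptide,
                "true_s": s,
                "expected_ratio": expected,
                "estimate": e.stoichiometry,
                "error": e.stoichiometry - expected,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["accession", "site", "peptide", "true_s",
                 "expected_ratio", "estimate", "error"],
    )
    err = df["error"].to_numpy() if len(df) else np.empty(0)
    summary = {
        "n_matched": int(len(df)),
        "n_missing": len(missing),
        "bias": float(err.mean()) if err.size else float("nan"),
        "mae": float(np.abs(err).mean()) if err.size else float("nan"),
        "rmse": float(np.sqrt((err ** 2).mean())) if err.size else float("nan"),
    }
    return df, summary
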