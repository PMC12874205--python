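"""Stoichiometry from TMT reporter intensities of accepted glyco-PSMs.

The split-and-treat design labels three replicates of the untreated
(control) half and three replicates of the FUT8-saturated (treated) half
in one TMT sixplex. Because the treated half carries the tag on every
eligible site, the physiological core-fucosylation stoichiometry of a
glycopeptide is the ratio of its control reporter signal to its treated
reporter signal within the same spectrum. Redundant PSMs of the same
unique glycopeptide are aggregated by the median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .identify import IdentifiedPSM
from .ingest import ChannelLayout, PSMRecord

__all__ = [
    "GlycopeptideKey",
    "StoichiometryEstimate",
    "within_spectrum_relative",
    "psm_ratio",
    "aggregate_glycopeptide",
    "quantify_psms",
    "estimates_to_frame",
    "compare_conditions",
    "benjamini_hochberg",
]


class GlycopeptideKey(NamedTuple):
    """Unique glycopeptide: sequence plus protein glycosite.

    Charge states and missed-cleavage variants sharing the same
    (peptide, accession, site) collapse into one key before aggregation.
    """

    peptide: str
    accession: str
    site: int


def within_spectrum_relative(reporters: np.ndarray) -> np.ndarray:
    """Six channel intensities as fractions of their within-spectrum sum."""
    r = np.asarray(reporters, dtype=float)
    total = r.sum()
    if total <= 0:
        raise ValueError("all-zero reporters: PSM is low-intensity")
    return r / total


def median_ratio_scaling(psms: Iterable[PSMRecord]) -> np.ndarray:
    """Per-channel median-ratio normalization factors (diagnostic only).

    Reference per spectrum is the geometric mean of the positive
    channels; the factor for a channel is the median across spectra of
    channel/reference. Off by default in the pipeline: the control and
    treated halves intentionally differ in composition, so loading
    normalization would distort the stoichiometry.
    """
    rows = [p.reporters for p in psms if p.reporters.sum() > 0]
    if not rows:
        raise ValueError("no quantifiable PSMs")
    R = np.vstack(rows)
    with np.errstate(divide="ignore"):
        logs = np.where(R > 0, np.log(np.where(R > 0, R, 1.0)), np.nan)
    ref = np.exp(np.nanmean(logs, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        ratios = R / ref[:, None]
    return np.nanmedian(ratios, axis=0)


def psm_ratio(
    psm: PSMRecord, layout: ChannelLayout
) -> tuple[float, np.ndarray]:
    """Control/treated ratio for one PSM.

    Returns (overall ratio, per-replicate ratios). The overall ratio is
    the sum of the three control channels over the sum of the three
    treated channels — identical to the ratio of summed within-spectrum
    relative intensities, since the per-spectrum normalization cancels.
    Replicate ratios pair control and treated channels by replicate
    index; a zero treated channel yields NaN for that replicate.
    """
    r = np.asarray(psm.reporters, dtype=float)
    if r.shape != (len(layout.channel_names),):
        raise ValueError("reporter/layout length mismatch")
    if r.sum() <= 0:
        raise ValueError("all-zero reporters: PSM is low-intensity")
    control = r[layout.control_indices]
    treated = r[layout.treated_indices]
    treated_sum = treated.sum()
    if treated_sum <= 0:
        raise ValueError("zero treated signal: ratio undefined")
    overall = control.sum() / treated_sum
    with np.errstate(divide="ignore", invalid="ignore"):
        reps = np.where(treated > 0, control / treated, np.nan)
    return float(overall), reps


@dataclass
class StoichiometryEstimate:
    """Per-unique-glycopeptide stoichiometry with replicate detail."""

    key: GlycopeptideKey
    stoichiometry: float           # median ratio clipped to [0, 1]
    raw_ratio: float               # unclipped median ratio
    mean_ratio: float              # mean of per-replicate medians (alt estimator)
    replicate_ratios: np.ndarray   # per-replicate medians across PSMs
    cv: float                      # sample sd / mean of replicate medians
    n_psms: int
    flags: set[str] = field(default_factory=set)


def aggregate_glycopeptide(
    key: GlycopeptideKey,
    overall_ratios: Iterable[float],
    replicate_ratios: Iterable[np.ndarray],
    flags: set[str] | None = None,
) -> StoichiometryEstimate:
    """Median-aggregate the PSM-level ratios of one unique glycopeptide.

    The stoichiometry is the median of per-PSM overall ratios, clipped
    to [0, 1] (flag ``clipped`` when the raw median exceeds 1).
    Replicate ratios are per-replicate medians across PSMs, and the CV
    is their sample standard deviation (n-1 denominator) over their mean.
    """
    ratios = np.asarray(list(overall_ratios), dtype=float)
    if ratios.size == 0:
        raise ValueError("no contributing PSMs")
    rep_matrix = np.vstack(list(replicate_ratios))
    flags = set(flags or ())

    raw = float(np.median(ratios))
    stoich = raw
    if raw > 1.0:
        stoich = 1.0
        flags.add("clipped")
    with np.errstate(all="ignore"):
        rep_medians = np.nanmedian(rep_matrix, axis=0)
    finite = rep_medians[np.isfinite(rep_medians)]
    if finite.size >= 2 and finite.mean() > 0:
        cv = float(finite.std(ddof=1) / finite.mean())
    else:
        cv = float("nan")
    return StoichiometryEstimate(
        key=key,
        stoichiometry=stoich,
        raw_ratio=raw,
        mean_ratio=float(finite.mean()) if finite.size else float("nan"),
        replicate_ratios=rep_medians,
        cv=cv,
        n_psms=int(ratios.size),
        flags=flags,
    )


def quantify_psms(
    identified: list[IdentifiedPSM],
    layout: ChannelLayout,
    two_stage: bool = False,
) -> tuple[list[StoichiometryEstimate], list[tuple[str, str]]]:
    """Group accepted PSMs by unique glycopeptide and aggregate.

    A PSM with several glyco sites contributes once per site
    (flag ``multi-glyco`` carried through). With ``two_stage`` the median
    is taken per charge state first, then across charge states; default
    is a single median over all redundant PSMs. Returns (estimates, list
    of (spectrum_id, reason) for PSMs excluded from quantification).
    """
    groups: dict[GlycopeptideKey, dict] = {}
    excluded: list[tuple[str, str]] = []
    for ident in identified:
        try:
            overall, reps = psm_ratio(ident.psm, layout)
        except ValueError as exc:
            ident.psm.flags.add("low-intensity")
            excluded.append((ident.psm.spectrum_id, str(exc)))
            continue
        charge = float(ident.psm.features[-1])
        for accession, site, _pep_pos in ident.sites:
            key = GlycopeptideKey(ident.psm.peptide, accession, site)
            g = groups.setdefault(key, {"entries": [], "flags": set()})
            g["entries"].append((charge, overall, reps))
            g["flags"] |= ident.psm.flags
    estimates = []
    for key, g in groups.items():
        entries = g["entries"]
        if two_stage:
            by_charge: dict[float, list] = {}
            for charge, overall, reps in entries:
                by_charge.setdefault(charge, []).append((overall, reps))
            n_psms = len(entries)
            entries = []
            for charge, items in sorted(by_charge.items()):
                ratios = np.array([o for o, _ in items])
                reps = np.vstack([r for _, r in items])
                with np.errstate(all="ignore"):
                    entries.append(
                        (charge, float(np.median(ratios)), np.nanmedian(reps, axis=0))
                    )
            est = aggregate_glycopeptide(
                key, [o for _, o, _ in entries], [r for _, _, r in entries], g["flags"]
            )
            est.n_psms = n_psms
        else:
            est = aggregate_glycopeptide(
                key, [o for _, o, _ in entries], [r for _, _, r in entries], g["flags"]
            )
        estimates.append(est)
    estimates.sort(key=lambda e: e.key)
    return estimates, excluded


def estimates_to_frame(estimates: list[StoichiometryEstimate]) -> pd.DataFrame:
    """Tabular view of stoichiometry estimates (one row per glycopeptide)."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "accession": e.key.accession,
                "site": e.key.site,
                "peptide": e.key.peptide,
                "stoichiometry": e.stoichiometry,
                "raw_ratio": e.raw_ratio,
                "mean_ratio": e.mean_ratio,
                "rep1": e.replicate_ratios[0],
                "rep2": e.replicate_ratios[1],
                "rep3": e.replicate_ratios[2],
                "cv": e.cv,
                "n_psms": e.n_psms,
                "flags": ";".join(sorted(e.flags)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "accession", "site", "peptide", "stoichiometry", "raw_ratio",
            "mean_ratio", "rep1", "rep2", "rep3", "cv", "n_psms", "flags",
        ],
    )


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up adjusted q-values; NaN p-values stay NaN."""
    p = np.asarray(pvalues, dtype=float)
    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        m = int(ok.sum())
        ps = p[ok]
        order = np.argsort(ps, kind="stable")
        ranked = ps[order] * m / (np.arange(m) + 1)
        ranked = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(ranked, 1.0)
        q[ok] = out
    return q


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        return float("nan")
    if a.std(ddof=0) == 0 and b.std(ddof=0) == 0:
        return 1.0  # degenerate-variance rule
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def compare_conditions(
    table_a: list[StoichiometryEstimate],
    table_b: list[StoichiometryEstimate],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Cross-condition comparison on the intersection of glycopeptide keys.

    Returns (comparison, only_in_a, only_in_b). The comparison carries
    delta = B - A, log2 stoichiometry ratio, a Welch two-sample t-test
    p-value on the replicate ratios, and BH-adjusted q-values across all
    compared keys.
    """
    a_by_key = {e.key: e for e in table_a}
    b_by_key = {e.key: e for e in table_b}
    common = sorted(set(a_by_key) & set(b_by_key))

    rows = []
    for key in common:
        ea, eb = a_by_key[key], b_by_key[key]
        sa, sb = ea.stoichiometry, eb.stoichiometry
        with np.errstate(divide="ignore", invalid="ignore"):
            log2_ratio = float(np.log2(sb / sa)) if sa > 0 and sb > 0 else float("nan")
        rows.append(
            {
                "accession": key.accession,
                "site": key.site,
                "peptide": key.peptide,
                "stoich_a": sa,
                "stoich_b": sb,
                "delta": sb - sa,
                "log2_ratio": log2_ratio,
                "p": _welch_p(ea.replicate_ratios, eb.replicate_ratios),
            }
        )
    comp = pd.DataFrame(
        rows,
        columns=[
            "accession", "site", "peptide", "stoich_a", "stoich_b",
            "delta", "log2_ratio", "p",
        ],
    )
    comp["q"] = benjamini_hochberg(comp["p"].to_numpy()) if len(comp) else []

    def _only(table, keys):
        return estimates_to_frame([e for e in table if e.key in keys])

    only_a = _only(table_a, set(a_by_key) - set(b_by_key))
    only_b = _only(table_b, set(b_by_key) - set(a_by_key))
    return comp, only_a, only_b
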