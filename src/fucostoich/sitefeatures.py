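"""Sequence and structural context of quantified glycosites.

Covers the site-level analytics used to ask what distinguishes high-
from low-stoichiometry core-fucosylation sites: 13-residue windows
around the modified asparagine, hydropathy (GRAVY, Kyte-Doolittle),
aromatic-residue counts, isoelectric point, quartile grouping by
stoichiometry (P1 lowest .. P4 highest), Mann-Whitney group
comparisons, binomial log-odds motif enrichment, relative position
within the protein, and annotation-based group summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .constants import (
    AMINO_ACIDS,
    DEFAULT_AROMATIC_SET,
    EMBOSS_PKA,
    KYTE_DOOLITTLE,
)
from .ingest import AnnotationMap, ProteinDB
from .quantify import StoichiometryEstimate, benjamini_hochberg

__all__ = [
    "SiteContext",
    "thirteen_mer",
    "aligned_window",
    "gravy",
    "aromatic_count",
    "isoelectric_point",
    "relative_position",
    "quartile_groups",
    "mann_whitney",
    "significance_stars",
    "motif_scores",
    "group_summary",
    "site_context_table",
]

WINDOW_HALF = 6  # 13-mer: site +/- 6
MISSING = "-"


def thirteen_mer(db: ProteinDB, accession: str, site: int) -> str:
    """Window of up to 13 residues centered on the site (no padding)."""
    protein = db[accession]
    if not (1 <= site <= len(protein)):
        raise ValueError(f"site {site} out of range for {accession}")
    return protein[max(0, site - 1 - WINDOW_HALF): min(len(protein), site + WINDOW_HALF)]


def aligned_window(db: ProteinDB, accession: str, site: int) -> str:
    """Exactly-13-character window with '-' padding at the termini.

    Used for position-aligned motif counting; positions past either
    terminus are marked missing rather than dropped.
    """
    protein = db[accession]
    if not (1 <= site <= len(protein)):
        raise ValueError(f"site {site} out of range for {accession}")
    out = []
    for offset in range(-WINDOW_HALF, WINDOW_HALF + 1):
        pos = site + offset
        out.append(protein[pos - 1] if 1 <= pos <= len(protein) else MISSING)
    return "".join(out)


def gravy(seq: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    if not seq:
        raise ValueError("empty sequence")
    try:
        return sum(KYTE_DOOLITTLE[r] for r in seq) / len(seq)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r} in sequence") from exc


def aromatic_count(seq: str, aromatic: frozenset = DEFAULT_AROMATIC_SET) -> int:
    """Number of aromatic residues (default set {F, W, Y})."""
    return sum(1 for r in seq if r in aromatic)


def _net_charge(seq: str, ph: float, pka: Mapping[str, float]) -> float:
    pos = 1.0 / (1.0 + 10 ** (ph - pka["n_term"]))
    neg = -1.0 / (1.0 + 10 ** (pka["c_term"] - ph))
    for r in seq:
        if r in ("K", "R", "H"):
            pos += 1.0 / (1.0 + 10 ** (ph - pka[r]))
        elif r in ("D", "E", "C", "Y"):
            neg -= 1.0 / (1.0 + 10 ** (pka[r] - ph))
    return pos + neg


def isoelectric_point(
    seq: str, pka: Mapping[str, float] | None = None, tol: float = 1e-4
) -> float:
    """pH at which the Henderson-Hasselbalch net charge crosses zero.

    Bisection over pH 0..14 with the EMBOSS pKa set by default. This is
    a standard pKa-model pI, an approximation to learned predictors.
    """
    if not seq or any(r not in KYTE_DOOLITTLE for r in seq):
        raise ValueError("sequence must be non-empty standard residues")
    pka = dict(EMBOSS_PKA if pka is None else pka)
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if _net_charge(seq, mid, pka) > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def relative_position(site: int, protein_length: int) -> float:
    """Fractional position of the site in the full-length protein."""
    if not (1 <= site <= protein_length):
        raise ValueError(f"site {site} out of range 1..{protein_length}")
    return site / protein_length


# --- quartile grouping -------------------------------------------------------

def quartile_groups(
    estimates: Sequence[StoichiometryEstimate],
) -> tuple[dict, set]:
    """Split sites into four groups P1..P4 by ascending stoichiometry.

    Group sizes are as equal as possible; with n = 4q + r the first r
    groups receive one extra member. Ties spanning a boundary keep their
    stable-sort order and the affected keys are returned as flagged.
    Returns (key -> 'P1'..'P4', set of tie-flagged keys).
    """
    n = len(estimates)
    if n < 4:
        raise ValueError(f"need at least 4 sites to form quartiles, got {n}")
    order = sorted(range(n), key=lambda i: estimates[i].stoichiometry)  # stable
    q, r = divmod(n, 4)
    sizes = [q + (1 if g < r else 0) for g in range(4)]
    labels: dict = {}
    bounds = np.cumsum([0] + sizes)
    values = [estimates[i].stoichiometry for i in order]
    tied: set = set()
    for g in range(4):
        lo, hi = bounds[g], bounds[g + 1]
        for j in range(lo, hi):
            labels[estimates[order[j]].key] = f"P{g + 1}"
        # flag ties straddling this boundary
        if 0 < lo < n and values[lo - 1] == values[lo]:
            v = values[lo]
            for j in range(n):
                if values[j] == v:
                    tied.add(estimates[order[j]].key)
    return labels, tied


# --- Mann-Whitney ------------------------------------------------------------

EXACT_LIMIT = 12  # exact enumeration when n1+n2 <= this and no ties


def mann_whitney(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    U is computed from rank sums with midranks for ties. The p-value is
    exact (full enumeration of rankings) when the pooled sample size is
    at most 12 and there are no ties; otherwise the normal approximation
    with tie correction and continuity correction is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


STAR_THRESHOLDS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    """Figure-legend stars: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    if not np.isfinite(p):
        return ""
    for cutoff, stars in STAR_THRESHOLDS:
        if p < cutoff:
            return stars
    return "ns"


# --- motif enrichment --------------------------------------------------------

@dataclass
class MotifMatrix:
    """Signed binomial log-odds per (position, residue).

    Positive scores mark over-representation in the foreground relative
    to the background, negative scores under-representation; the
    magnitude is the -log10 binomial tail probability.
    """

    positions: list[int]                 # -6..+6 without 0
    scores: pd.DataFrame                 # index positions, columns residues
    foreground_counts: pd.DataFrame
    background_counts: pd.DataFrame


def motif_scores(
    foreground: Sequence[str],
    background: Sequence[str],
    pseudocount: float = 0.5,
) -> MotifMatrix:
    """Position-specific residue enrichment around the glycosite.

    Inputs are 13-character windows aligned on the modified N at the
    center ('-' marks positions beyond a terminus, reducing the count n
    at that position). For each flanking position and residue, with n
    foreground windows covering the position, k of them carrying the
    residue, and q the pseudocounted background frequency, the score is
    -log10 P(Binom(n, q) >= k) when k/n exceeds q and
    +log10 P(Binom(n, q) <= k) otherwise.
    """
    if not foreground:
        raise ValueError("no foreground windows")
    if not background:
        raise ValueError("no background windows")
    width = 2 * WINDOW_HALF + 1
    for w in list(foreground) + list(background):
        if len(w) != width:
            raise ValueError(f"windows must be exactly {width} characters, got {len(w)}")

    positions = [p for p in range(-WINDOW_HALF, WINDOW_HALF + 1) if p != 0]
    residues = list(AMINO_ACIDS)
    fg_counts = pd.DataFrame(0, index=positions, columns=residues)
    bg_counts = pd.DataFrame(0, index=positions, columns=residues)
    for counts, windows in ((fg_counts, foreground), (bg_counts, background)):
        for w in windows:
            for p in positions:
                r = w[p + WINDOW_HALF]
                if r in KYTE_DOOLITTLE:
                    counts.loc[p, r] += 1

    scores = pd.DataFrame(0.0, index=positions, columns=residues)
    n_res = len(residues)
    for p in positions:
        n = int(fg_counts.loc[p].sum())
        bg_n = int(bg_counts.loc[p].sum())
        if n == 0 or bg_n == 0:
            continue
        for r in residues:
            k = int(fg_counts.loc[p, r])
            q = (bg_counts.loc[p, r] + pseudocount) / (bg_n + pseudocount * n_res)
            if k / n > q:
                tail = stats.binom.sf(k - 1, n, q)  # P(X >= k)
                scores.loc[p, r] = -math.log10(max(tail, 1e-300))
            else:
                tail = stats.binom.cdf(k, n, q)  # P(X <= k)
                scores.loc[p, r] = math.log10(max(tail, 1e-300))
    return MotifMatrix(
        positions=positions,
        scores=scores,
        foreground_counts=fg_counts,
        background_counts=bg_counts,
    )


# --- annotation group summaries ----------------------------------------------

def group_summary(
    estimates: Sequence[StoichiometryEstimate],
    annotations: AnnotationMap,
    category: str,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-label stoichiometry summaries and pairwise Mann-Whitney tests.

    A site carrying several labels in the category contributes to each.
    Pairwise p-values are BH-adjusted across all label pairs. Returns
    (summary table, pairwise-test table).
    """
    groups: dict[str, list[float]] = {}
    seen_category = False
    for e in estimates:
        ann = annotations.get((e.key.accession, e.key.site), {})
        if category in ann:
            seen_category = True
            for label in ann[category]:
                groups.setdefault(label, []).append(e.stoichiometry)
    if not seen_category:
        raise ValueError(f"category {category!r} absent from annotations")

    summary = pd.DataFrame(
        [
            {
                "label": label,
                "n": len(vals),
                "mean": float(np.mean(vals)),
                "median": float(np.median(vals)),
            }
            for label, vals in sorted(groups.items())
        ]
    )

    labels = sorted(groups)
    rows = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            u, p = mann_whitney(groups[la], groups[lb])
            rows.append({"label_a": la, "label_b": lb, "U": u, "p": p})
    pairwise = pd.DataFrame(rows, columns=["label_a", "label_b", "U", "p"])
    if len(pairwise):
        pairwise["q"] = benjamini_hochberg(pairwise["p"].to_numpy())
        pairwise["stars"] = [significance_stars(p) for p in pairwise["p"]]
    else:
        pairwise["q"] = []
        pairwise["stars"] = []
    return summary, pairwise


# --- site context table ------------------------------------------------------

@dataclass
class SiteContext:
    accession: str
    site: int
    window: str
    gravy: float
    aromatic_count: int
    pI: float
    relative_position: float
    stoichiometry: float
    quartile: str | None = None
    annotations: dict | None = None


def site_context_table(
    estimates: Sequence[StoichiometryEstimate],
    db: ProteinDB,
    annotations: AnnotationMap | None = None,
    aromatic: frozenset = DEFAULT_AROMATIC_SET,
) -> pd.DataFrame:
    """One row of sequence context per quantified glycosite."""
    quartiles: dict = {}
    if len(estimates) >= 4:
        quartiles, _tied = quartile_groups(estimates)
    rows = []
    for e in estimates:
        acc, site = e.key.accession, e.key.site
        window = thirteen_mer(db, acc, site)
        ann = (annotations or {}).get((acc, site), {})
        rows.append(
            {
                "accession": acc,
                "site": site,
                "peptide": e.key.peptide,
                "window": window,
                "gravy": gravy(window),
                "aromatic_count": aromatic_count(window, aromatic),
                "pI": isoelectric_point(window),
                "relative_position": relative_position(site, len(db[acc])),
                "stoichiometry": e.stoichiometry,
                "quartile": quartiles.get(e.key, ""),
                "annotations": ";".join(
                    f"{cat}={label}"
                    for cat in sorted(ann)
                    for label in sorted(ann[cat])
                ),
            }
        )
    return pd.DataFrame(rows)
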