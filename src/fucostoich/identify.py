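"""Glycopeptide PSM selection, LDA rescoring, and target-decoy FDR control.

Selection proceeds in the fixed order: (1) keep PSMs carrying the
fucosyl-GlcNAc mass tag on asparagine, (2) require a valid N-glycosylation
sequon at the mapped protein site (+2 must be S/T/C; proline at +1
excluded by default), (3) require peptide length strictly greater than
seven residues, (4) rescore the surviving population with a Fisher
linear discriminant over the search-engine quality features and accept
target PSMs above the score threshold at which the target-decoy
estimated FDR is <= alpha (default 1%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import SearchConstants
from .ingest import PSMRecord, ProteinDB, SiteMappingError, map_site

__all__ = [
    "LDAModel",
    "FilterReport",
    "IdentifiedPSM",
    "is_glyco_psm",
    "glyco_mod_positions",
    "validate_sequon",
    "length_filter",
    "fit_lda",
    "score_psms",
    "fdr_threshold",
    "identify_psms",
]


def glyco_mod_positions(psm: PSMRecord, k: SearchConstants) -> list[int]:
    """1-based peptide positions carrying the glyco tag on an N residue."""
    out = []
    for pos, delta in psm.mod_positions:
        if (
            abs(delta - k.glyco_tag_mass) <= k.mod_mass_tolerance
            and psm.peptide[pos - 1] == "N"
        ):
            out.append(pos)
    return out


def is_glyco_psm(psm: PSMRecord, k: SearchConstants) -> tuple[bool, int | None]:
    """Whether the PSM carries the glyco tag; position of the first tag."""
    positions = glyco_mod_positions(psm, k)
    return (bool(positions), positions[0] if positions else None)


def validate_sequon(
    db: ProteinDB,
    accession: str,
    site: int,
    require_no_proline_plus1: bool = True,
) -> bool:
    """Check the N-glycosylation consensus N-X-[S/T/C] at a protein site.

    The residue at ``site`` must be N and the residue two positions
    downstream must be S, T, or C; by default proline at +1 disqualifies
    the site (canonical sequon definition).
    """
    protein = db[accession]
    if not (1 <= site <= len(protein)):
        raise ValueError(f"site {site} out of range for {accession} (length {len(protein)})")
    if protein[site - 1] != "N":
        return False
    if site + 2 > len(protein):
        return False
    if protein[site + 1] not in "STC":
        return False
    if require_no_proline_plus1 and protein[site] == "P":
        return False
    return True


def length_filter(
    psms: list[PSMRecord], k: SearchConstants | None = None
) -> list[PSMRecord]:
    """Keep PSMs whose peptide is strictly longer than seven residues."""
    k = k or SearchConstants()
    cutoff = k.min_peptide_length_exclusive
    return [p for p in psms if len(p.peptide) > cutoff]


# --- LDA rescoring ----------------------------------------------------------

@dataclass
class LDAModel:
    """Ridge-stabilized two-class Fisher discriminant.

    Features are standardized internally; constant features are dropped.
    The orientation is fixed so that targets score higher than decoys on
    average, and the offset centers the class-mean midpoint at zero.
    """

    feature_mask: np.ndarray   # boolean, which input features survived
    mu: np.ndarray             # per-feature mean (kept features)
    sd: np.ndarray             # per-feature sd (kept features)
    weights: np.ndarray        # in standardized space
    offset: float
    mean_target: np.ndarray    # standardized class means, kept for inspection
    mean_decoy: np.ndarray
    pooled_scatter: np.ndarray

    @property
    def weights_original(self) -> np.ndarray:
        """Weights on the original (unstandardized) feature scale."""
        w = np.zeros(self.feature_mask.size)
        w[self.feature_mask] = self.weights / self.sd
        return w

    def score(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.feature_mask.size:
            raise ValueError(
                f"expected {self.feature_mask.size} features, got {X.shape[1]}"
            )
        Z = (X[:, self.feature_mask] - self.mu) / self.sd
        return Z @ self.weights + self.offset


def fit_lda(features: np.ndarray, is_target: np.ndarray) -> LDAModel:
    """Fit the Fisher discriminant separating target from decoy PSMs.

    weights ∝ (Sw + εI)^-1 (mean_target - mean_decoy) with ε = 1e-6 ·
    trace(Sw)/d, computed on standardized features.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(is_target, dtype=bool)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    n_t, n_d = int(y.sum()), int((~y).sum())
    if n_t < 2 or n_d < 2:
        raise ValueError(f"need >= 2 samples per class (targets={n_t}, decoys={n_d})")
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    mask = sd > 0
    if not mask.any():
        raise ValueError("all features are constant")
    Z = (X[:, mask] - mu[mask]) / sd[mask]

    Zt, Zd = Z[y], Z[~y]
    mt, md = Zt.mean(axis=0), Zd.mean(axis=0)
    # pooled within-class scatter (unbiased per-class covariances)
    St = np.cov(Zt, rowvar=False, ddof=1)
    Sd = np.cov(Zd, rowvar=False, ddof=1)
    St = np.atleast_2d(St)
    Sd = np.atleast_2d(Sd)
    Sw = ((n_t - 1) * St + (n_d - 1) * Sd) / (n_t + n_d - 2)
    d = Sw.shape[0]
    trace = np.trace(Sw)
    eps = 1e-6 * (trace / d if trace > 0 else 1.0)
    w = np.linalg.solve(Sw + eps * np.eye(d), mt - md)
    if w @ (mt - md) < 0:  # orientation: targets score higher
        w = -w
    offset = -float(w @ ((mt + md) / 2.0))
    return LDAModel(
        feature_mask=mask,
        mu=mu[mask],
        sd=sd[mask],
        weights=w,
        offset=offset,
        mean_target=mt,
        mean_decoy=md,
        pooled_scatter=Sw,
    )


def score_psms(model: LDAModel, psms: list[PSMRecord]) -> np.ndarray:
    """Discriminant score w·x + offset for each PSM."""
    if not psms:
        return np.empty(0)
    X = np.vstack([p.features for p in psms])
    return model.score(X)


# --- target-decoy FDR -------------------------------------------------------

def fdr_threshold(
    scores: np.ndarray,
    is_decoy: np.ndarray,
    alpha: float,
    plus_one: bool = False,
) -> tuple[float, np.ndarray, float]:
    """Lowest score threshold with target-decoy estimated FDR <= alpha.

    At threshold t the FDR estimate is #decoys(score >= t) / #targets
    (score >= t), optionally with a +1 in the numerator. Candidate
    thresholds are the observed scores, swept from high to low, so score
    ties are accepted or rejected as a block. Returns (threshold,
    boolean mask of accepted target PSMs, estimated FDR at the
    threshold); when no threshold satisfies the bound the accepted set
    is empty and the threshold is +inf.
    """
    scores = np.asarray(scores, dtype=float)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    if scores.shape != is_decoy.shape:
        raise ValueError("scores and is_decoy must have the same shape")
    if (~is_decoy).sum() == 0:
        raise ValueError("no target PSMs")

    candidates = np.unique(scores)[::-1]  # high to low
    correction = 1 if plus_one else 0
    best_t = np.inf
    best_fdr = 0.0
    for t in candidates:
        above = scores >= t
        n_dec = int((above & is_decoy).sum())
        n_tgt = int((above & ~is_decoy).sum())
        if n_tgt == 0:
            continue
        fdr = (n_dec + correction) / n_tgt
        if fdr <= alpha:
            best_t = t
            best_fdr = fdr
    accepted = (scores >= best_t) & ~is_decoy
    return float(best_t), accepted, float(best_fdr)


# --- full identification stage ----------------------------------------------

@dataclass
class IdentifiedPSM:
    """An accepted glyco-PSM with its discriminant score and mapped sites."""

    psm: PSMRecord
    score: float
    # (accession, 1-based protein site, 1-based peptide position) per glyco tag
    sites: list[tuple[str, int, int]]


@dataclass
class FilterReport:
    """Counts of PSMs removed at each selection stage."""

    n_input: int = 0
    n_non_glyco: int = 0
    n_bad_sequon: int = 0
    n_short: int = 0
    n_below_fdr: int = 0
    n_accepted: int = 0
    threshold: float = float("nan")
    estimated_fdr: float = float("nan")

    def check(self) -> None:
        removed = self.n_non_glyco + self.n_bad_sequon + self.n_short + self.n_below_fdr
        if removed + self.n_accepted != self.n_input:
            raise AssertionError("filter-report stage counts do not sum to input")

    def to_rows(self) -> list[tuple[str, float]]:
        return [
            ("input", self.n_input),
            ("removed_non_glyco", self.n_non_glyco),
            ("removed_bad_sequon", self.n_bad_sequon),
            ("removed_short_peptide", self.n_short),
            ("removed_below_fdr", self.n_below_fdr),
            ("accepted", self.n_accepted),
            ("score_threshold", self.threshold),
            ("estimated_fdr", self.estimated_fdr),
        ]


def identify_psms(
    psms: list[PSMRecord],
    db: ProteinDB,
    k: SearchConstants | None = None,
) -> tuple[list[IdentifiedPSM], FilterReport]:
    """Run the full selection: glyco tag -> sequon -> length -> LDA/FDR.

    The FDR threshold is computed on the glyco-filtered population
    (targets and decoys together); decoys are never reported. In
    peptide-level mode (``k.fdr_peptide_level``) thresholding applies to
    the best-scoring PSM per peptide and acceptance propagates to all
    PSMs of accepted peptides.
    """
    k = k or SearchConstants()
    report = FilterReport(n_input=len(psms))

    survivors: list[tuple[PSMRecord, list[tuple[str, int, int]]]] = []
    for psm in psms:
        positions = glyco_mod_positions(psm, k)
        if not positions:
            report.n_non_glyco += 1
            continue
        if len(positions) > 1:
            psm.flags.add("multi-glyco")
        sites: list[tuple[str, int, int]] = []
        try:
            for pos in positions:
                site = map_site(psm, db, pos)
                if validate_sequon(db, psm.protein_id, site, k.require_no_proline_plus1):
                    sites.append((psm.protein_id, site, pos))
        except (SiteMappingError, ValueError):
            sites = []
        if not sites:
            report.n_bad_sequon += 1
            continue
        if len(psm.peptide) <= k.min_peptide_length_exclusive:
            report.n_short += 1
            continue
        survivors.append((psm, sites))

    if not survivors:
        report.check()
        return [], report

    kept = [p for p, _ in survivors]
    X = np.vstack([p.features for p in kept])
    is_target = np.array([not p.is_decoy for p in kept])
    model = fit_lda(X, is_target)
    scores = model.score(X)

    if k.fdr_peptide_level:
        # best PSM per (peptide, decoy status) defines the peptide score
        best: dict[tuple[str, bool], int] = {}
        for i, p in enumerate(kept):
            key = (p.peptide, p.is_decoy)
            if key not in best or scores[i] > scores[best[key]]:
                best[key] = i
        idx = np.array(sorted(best.values()))
        t, acc_pep, fdr = fdr_threshold(
            scores[idx], ~is_target[idx], k.fdr_alpha, k.fdr_plus_one
        )
        accepted_peptides = {kept[i].peptide for i, a in zip(idx, acc_pep) if a}
        accepted_mask = np.array(
            [not p.is_decoy and p.peptide in accepted_peptides for p in kept]
        )
    else:
        t, accepted_mask, fdr = fdr_threshold(
            scores, ~is_target, k.fdr_alpha, k.fdr_plus_one
        )

    report.threshold = t
    report.estimated_fdr = fdr
    identified = [
        IdentifiedPSM(psm=p, score=float(s), sites=sites)
        for (p, sites), s, a in zip(survivors, scores, accepted_mask)
        if a
    ]
    report.n_accepted = len(identified)
    report.n_below_fdr = len(survivors) - len(identified)
    report.check()
    return identified, report
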