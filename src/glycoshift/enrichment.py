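"""Susceptibility statistics: exact 2x2 enrichment, multiplicity contrasts,
sequon motif enrichment and the NxS-fraction-versus-multiplicity correlation.

All categorical contrasts are two-sided Fisher exact tests; the headline
effect size is *fold enrichment* — the hit fraction in the selected set over
the hit fraction in the background — with the odds ratio reported alongside.
Group multiplicity comparisons use the Mann-Whitney test, exact (full
labeling enumeration, tie-safe) for small groups and the tie-corrected normal
approximation otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sequons import AROMATIC, NXS, GlycoSite

#: residue positions reported around the Asn (0 excluded: the Asn is fixed)
MOTIF_POSITIONS = tuple(p for p in range(-5, 6) if p != 0)


# ---------------------------------------------------------------------------
# Fisher exact enrichment
# ---------------------------------------------------------------------------

def fisher_two_sided(table: np.ndarray | Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    The two-sided p sums hypergeometric probabilities of all tables (with the
    same margins) no more probable than the observed one. Degenerate margins
    (an empty row or column) carry no information: p = 1.
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


@dataclass(frozen=True)
class EnrichmentResult:
    """A 2x2 set-vs-background contingency test.

    ``table`` rows are (in set, not in set), columns (hit, non-hit).
    fold_enrichment = (hit fraction in set) / (hit fraction in background),
    where the background *includes* the set.
    """

    table: tuple[tuple[int, int], tuple[int, int]]
    set_hits: int
    set_total: int
    bg_hits: int
    bg_total: int
    fold_enrichment: float
    odds_ratio: float
    p_value: float

    def as_row(self) -> dict:
        return {
            "set_hits": self.set_hits,
            "set_total": self.set_total,
            "bg_hits": self.bg_hits,
            "bg_total": self.bg_total,
            "fold_enrichment": self.fold_enrichment,
            "odds_ratio": self.odds_ratio,
            "p_value": self.p_value,
        }


def fisher_enrichment(
    set_hits: int, set_total: int, bg_hits: int, bg_total: int
) -> EnrichmentResult:
    """Exact enrichment of hits in a set against a background that contains it."""
    if set_total <= 0:
        raise ValueError("set_total must be positive")
    if bg_total < set_total:
        raise ValueError("background smaller than the set")
    if not 0 <= set_hits <= set_total:
        raise ValueError("set_hits outside [0, set_total]")
    if not set_hits <= bg_hits <= bg_total - (set_total - set_hits):
        raise ValueError("inconsistent margins: set is not a subset of the background")
    if bg_hits == 0:
        raise ValueError("no hits in the background: enrichment undefined")
    a = set_hits
    b = set_total - set_hits
    c = bg_hits - set_hits
    d = (bg_total - set_total) - c
    table = ((a, b), (c, d))
    fold = (a / set_total) / (bg_hits / bg_total)
    if b * c == 0:
        odds = np.inf if a * d > 0 else np.nan
    else:
        odds = (a * d) / (b * c)
    return EnrichmentResult(
        table=table,
        set_hits=a,
        set_total=set_total,
        bg_hits=bg_hits,
        bg_total=bg_total,
        fold_enrichment=fold,
        odds_ratio=float(odds),
        p_value=fisher_two_sided(table),
    )


# ---------------------------------------------------------------------------
# multiplicity
# ---------------------------------------------------------------------------

def multiplicity_enrichment(
    decreased_proteins: Iterable[str],
    profiles: pd.DataFrame,
    thresholds: Sequence[int] = (1, 2, 3, 4),
) -> dict[int, EnrichmentResult]:
    """Enrichment of high-multiplicity glycoproteins among the decreased ones.

    The background is every glycoprotein (multiplicity >= 1) in *profiles*;
    a hit at threshold k is multiplicity >= k, so the k = 1 row is the whole
    decreased set and its fold enrichment is exactly 1 by construction.
    """
    decreased = set(decreased_proteins)
    if not decreased:
        raise ValueError("empty decreased set")
    glyco = profiles[profiles["multiplicity"] >= 1]
    missing = decreased - set(glyco.index)
    if missing:
        raise ValueError(
            f"decreased protein(s) not glycoproteins in the background: {sorted(missing)[:5]}"
        )
    dec_mult = glyco.loc[sorted(decreased), "multiplicity"]
    out = {}
    for k in thresholds:
        set_hits = int((dec_mult >= k).sum())
        bg_hits = int((glyco["multiplicity"] >= k).sum())
        if bg_hits == 0:
            # nothing reaches this threshold anywhere: no signal by definition
            a, b = set_hits, len(dec_mult) - set_hits
            out[int(k)] = EnrichmentResult(
                table=((a, b), (0, len(glyco) - len(dec_mult))),
                set_hits=a,
                set_total=len(dec_mult),
                bg_hits=0,
                bg_total=len(glyco),
                fold_enrichment=0.0,
                odds_ratio=float("nan"),
                p_value=1.0,
            )
            continue
        out[int(k)] = fisher_enrichment(
            set_hits=set_hits,
            set_total=len(dec_mult),
            bg_hits=bg_hits,
            bg_total=len(glyco),
        )
    return out


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    mean_b: float
    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    method: str  # "exact" or "asymptotic"


#: exact enumeration is used when the labeling count stays below this
_MAX_EXACT_LABELINGS = 500_000


def multiplicity_group_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> GroupComparison:
    """Two-sided Mann-Whitney comparison of two multiplicity distributions.

    Small groups (min size <= 8 and a tractable labeling count) get an exact
    p by enumerating every assignment of the pooled values to the two groups
    and counting assignments whose U statistic is at least as far from its
    null mean as the observed one; ties are handled by midranks, which the
    enumeration shares. Larger groups fall back to the tie-corrected normal
    approximation.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)  # midranks under ties
    u_obs = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)
    mu = n_a * n_b / 2
    if min(n_a, n_b) <= 8 and comb(n_a + n_b, n_a) <= _MAX_EXACT_LABELINGS:
        dist = _u_distribution(ranks, n_a)
        # small tolerance so midrank arithmetic does not miss exact ties
        p = float(np.mean(np.abs(dist - mu) >= abs(u_obs - mu) - 1e-9))
        method = "exact"
    else:
        p = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
        )
        method = "asymptotic"
    return GroupComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        n_a=n_a,
        n_b=n_b,
        u_statistic=u_obs,
        p_value=min(p, 1.0),
        method=method,
    )


def _u_distribution(ranks: np.ndarray, n_a: int) -> np.ndarray:
    """U statistic of group A over every labeling of the pooled observations."""
    idx = np.fromiter(
        (i for c in combinations(range(ranks.size), n_a) for i in c), dtype=np.intp
    ).reshape(-1, n_a)
    return ranks[idx].sum(axis=1) - n_a * (n_a + 1) / 2


# ---------------------------------------------------------------------------
# sequon motif enrichment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifEnrichment:
    """One positional sequence feature contrasted between site sets."""

    position: int
    feature: str  # a residue letter or a residue-class name
    n_decreased_with: int
    n_decreased_total: int
    n_unchanged_with: int
    n_unchanged_total: int
    fold_enrichment: float
    p_value: float

    def as_row(self) -> dict:
        return {
            "position": self.position,
            "feature": self.feature,
            "n_decreased_with": self.n_decreased_with,
            "n_decreased_total": self.n_decreased_total,
            "n_unchanged_with": self.n_unchanged_with,
            "n_unchanged_total": self.n_unchanged_total,
            "fold_enrichment": self.fold_enrichment,
            "p_value": self.p_value,
        }


@dataclass
class MotifAnalysis:
    features: list[MotifEnrichment]
    logo_decreased: pd.DataFrame = field(repr=False)
    logo_unchanged: pd.DataFrame = field(repr=False)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame([f.as_row() for f in self.features])


def _motif_feature(
    position: int,
    feature: str,
    dec_with: int,
    dec_total: int,
    unch_with: int,
    unch_total: int,
) -> MotifEnrichment:
    table = (
        (dec_with, dec_total - dec_with),
        (unch_with, unch_total - unch_with),
    )
    dec_frac = dec_with / dec_total if dec_total else np.nan
    unch_frac = unch_with / unch_total if unch_total else np.nan
    fold = dec_frac / unch_frac if unch_frac else np.inf if dec_frac else np.nan
    return MotifEnrichment(
        position=position,
        feature=feature,
        n_decreased_with=dec_with,
        n_decreased_total=dec_total,
        n_unchanged_with=unch_with,
        n_unchanged_total=unch_total,
        fold_enrichment=float(fold),
        p_value=fisher_two_sided(table),
    )


def _residue_at(site: GlycoSite, position: int) -> str | None:
    """Residue at a position relative to the Asn (None when outside the protein)."""
    idx = 5 + position  # context is an 11-mer with the Asn at index 5
    if not site.context or not 0 <= idx < len(site.context):
        return None
    res = site.context[idx]
    return None if res == "-" else res


def sequon_position_enrichment(
    decreased_sites: Sequence[GlycoSite],
    unchanged_sites: Sequence[GlycoSite],
    positions: Sequence[int] = MOTIF_POSITIONS,
) -> MotifAnalysis:
    """Positional residue enrichment between decreased and unchanged sites.

    Emits the two headline features first — a non-aromatic residue (anything
    but Phe/Tyr/His/Trp) at position -2 and a Ser at position +2 (the NxS
    motif) — then a Fisher test for every residue seen at every position, and
    per-series position x residue count matrices for logo-style output.
    Sites whose -2 position falls outside the protein are excluded from
    -2-dependent features only.
    """
    if not decreased_sites or not unchanged_sites:
        raise ValueError("both site sets must be non-empty")

    features: list[MotifEnrichment] = []

    dec_m2 = [s for s in decreased_sites if s.minus2_aromatic is not None]
    unch_m2 = [s for s in unchanged_sites if s.minus2_aromatic is not None]
    if dec_m2 and unch_m2:
        features.append(
            _motif_feature(
                -2,
                "non_aromatic",
                sum(not s.minus2_aromatic for s in dec_m2),
                len(dec_m2),
                sum(not s.minus2_aromatic for s in unch_m2),
                len(unch_m2),
            )
        )
    features.append(
        _motif_feature(
            2,
            "S",
            sum(s.plus2_residue == "S" for s in decreased_sites),
            len(decreased_sites),
            sum(s.plus2_residue == "S" for s in unchanged_sites),
            len(unchanged_sites),
        )
    )

    logo_dec = _logo_counts(decreased_sites, positions)
    logo_unch = _logo_counts(unchanged_sites, positions)
    for pos in positions:
        dec_total = int(logo_dec.loc[pos].sum())
        unch_total = int(logo_unch.loc[pos].sum())
        if dec_total == 0 or unch_total == 0:
            continue
        residues = sorted(
            set(logo_dec.columns[logo_dec.loc[pos] > 0])
            | set(logo_unch.columns[logo_unch.loc[pos] > 0])
        )
        for res in residues:
            features.append(
                _motif_feature(
                    pos,
                    res,
                    int(logo_dec.at[pos, res]),
                    dec_total,
                    int(logo_unch.at[pos, res]),
                    unch_total,
                )
            )
    return MotifAnalysis(features, logo_dec, logo_unch)


def _logo_counts(sites: Sequence[GlycoSite], positions: Sequence[int]) -> pd.DataFrame:
    residues = sorted(set("ACDEFGHIKLMNPQRSTVWY"))
    counts = pd.DataFrame(0, index=list(positions), columns=residues, dtype=int)
    for site in sites:
        for pos in positions:
            res = _residue_at(site, pos)
            if res is not None and res in counts.columns:
                counts.at[pos, res] += 1
    counts.index.name = "position"
    return counts


# ---------------------------------------------------------------------------
# NxS fraction vs multiplicity correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CorrelationResult:
    points: tuple[tuple[float, float], ...]  # (multiplicity bin x, percentage)
    r: float
    p_value: float
    n_bins: int


def _pearson(points: list[tuple[float, float]]) -> tuple[float, float]:
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    # a flat series carries no trend: define r = 0 rather than propagate NaN
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return 0.0, 1.0
    r, p = stats.pearsonr(xs, ys)
    return float(r), float(p)


def nxs_multiplicity_correlation(
    decreased_sites: Sequence[GlycoSite],
    unchanged_sites: Sequence[GlycoSite],
    profiles: pd.DataFrame,
    min_bin_size: int = 3,
    cap: int = 8,
    mode: str = "fraction_of_nxs",
) -> dict[str, CorrelationResult]:
    """Correlate NxS glycopeptide fate with parent-protein multiplicity.

    Sites are binned by their protein's multiplicity (1, 2, ..., cap-1, with
    >= cap pooled; the pooled bin sits at x = cap). Two point constructions:

    * ``fraction_of_nxs`` (default) — per bin, the percentage of NxS sites
      that belong to each series (decreased or unchanged). This follows the
      published construction: NxS sites on high-multiplicity proteins are
      more often decreased.
    * ``nxs_share_of_series`` — per bin and series, the percentage of the
      series' sites whose sequon class is NxS.

    Bins with fewer than *min_bin_size* sites in a series' denominator are
    dropped for that series; fewer than 3 usable bins is an error. Pearson r
    and its two-sided p are computed per series over (bin x, percentage).
    """
    if mode not in ("fraction_of_nxs", "nxs_share_of_series"):
        raise ValueError(f"unknown mode {mode!r}")
    mult = profiles["multiplicity"]

    def bin_of(site: GlycoSite) -> int:
        if site.protein_id not in mult.index:
            raise ValueError(f"site {site.key}: no multiplicity profile")
        return int(min(int(mult[site.protein_id]), cap))

    series_sites = {"decreased": list(decreased_sites), "unchanged": list(unchanged_sites)}
    bins = sorted(
        {bin_of(s) for sites in series_sites.values() for s in sites if bin_of(s) >= 1}
    )
    out: dict[str, CorrelationResult] = {}
    for name, own_sites in series_sites.items():
        points: list[tuple[float, float]] = []
        for b in bins:
            if mode == "fraction_of_nxs":
                denom_sites = [
                    s
                    for sites in series_sites.values()
                    for s in sites
                    if s.sequon_class == NXS and bin_of(s) == b
                ]
                hits = sum(
                    1 for s in own_sites if s.sequon_class == NXS and bin_of(s) == b
                )
            else:
                denom_sites = [s for s in own_sites if bin_of(s) == b]
                hits = sum(1 for s in denom_sites if s.sequon_class == NXS)
            if len(denom_sites) < min_bin_size:
                continue
            points.append((float(b), 100.0 * hits / len(denom_sites)))
        if len(points) < 3:
            raise ValueError(
                f"series {name!r}: only {len(points)} usable multiplicity bins (need >= 3)"
            )
        r, p = _pearson(points)
        out[name] = CorrelationResult(tuple(points), r, p, len(points))
    return out


# ---------------------------------------------------------------------------
# annotation-set enrichment
# ---------------------------------------------------------------------------

def annotation_set_enrichment(
    decreased_features: Iterable[str],
    all_features: Iterable[str],
    membership: set[str],
    feature_to_protein: Mapping[str, str],
) -> EnrichmentResult:
    """Enrichment of an annotation set (e.g. IgSF-CAM) among decreased features.

    Features map to proteins through *feature_to_protein*; a feature is a hit
    when its protein belongs to *membership*. The background is *all_features*
    (which must contain the decreased set)."""
    decreased = list(decreased_features)
    background = list(all_features)
    if not decreased:
        raise ValueError("empty decreased feature set")
    missing = set(decreased) - set(background)
    if missing:
        raise ValueError(f"decreased features missing from background: {sorted(missing)[:5]}")

    def is_hit(feature: str) -> bool:
        protein = feature_to_protein.get(feature)
        return protein is not None and protein in membership

    bg_hits = sum(map(is_hit, background))
    if bg_hits == 0:
        raise ValueError("annotation set does not intersect the background")
    return fisher_enrichment(
        set_hits=sum(map(is_hit, decreased)),
        set_total=len(decreased),
        bg_hits=bg_hits,
        bg_total=len(background),
    )
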