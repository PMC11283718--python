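"""DNA stable-isotope probing: fraction classification and enrichment analysis.

After isopycnic (CsCl) density-gradient centrifugation, DNA from taxa
that assimilated a ¹³C-labelled substrate equilibrates at a higher
buoyant density (BD).  The analysis here follows the classic banding
approach: fractions are classified into a *heavy* band (default BD
1.73–1.75 g/ml) and a *light* band (1.70–1.72 g/ml) — both intervals
closed — and the evidence for label incorporation is the share of a
target gene's total copies (over *all* fractions of a gradient) that
falls in the heavy band, compared between ¹³C and ¹²C treatments.

Shares are computed per replicate gradient and summarised as mean ± sd
over replicates; treatment comparisons use two-sided Welch t-tests on
the per-replicate shares.  Amplicon sequence variants (ASVs) are called
¹³C-labelled when their mean relative abundance in the focal fraction
group exceeds every other group with all pairwise p-values below a
threshold (default 0.001).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Fraction",
    "FractionProfile",
    "EnrichmentStat",
    "AsvEnrichmentCall",
    "HEAVY_BAND",
    "LIGHT_BAND",
    "classify_fractions",
    "heavy_share",
    "share_partition",
    "enrichment_stat",
    "compare_shares",
    "call_labeled_asvs",
]

HEAVY_BAND: tuple[float, float] = (1.73, 1.75)
LIGHT_BAND: tuple[float, float] = (1.70, 1.72)

_BD_RANGE = (1.60, 1.85)


@dataclass(frozen=True)
class Fraction:
    fraction_id: str
    buoyant_density: float  # g/ml
    copies: Mapping[str, float]  # gene -> copies per g soil

    def __post_init__(self) -> None:
        bd = self.buoyant_density
        if not (_BD_RANGE[0] < bd < _BD_RANGE[1]):
            raise ValueError(f"fraction {self.fraction_id}: BD {bd} outside plausible range")
        for gene, c in self.copies.items():
            if c < 0 or c != c:
                raise ValueError(f"fraction {self.fraction_id}: copies for {gene} must be >= 0")


@dataclass
class FractionProfile:
    """One replicate gradient: ordered fractions with BD and gene copies."""

    treatment: str
    replicate: str
    fractions: list[Fraction]

    def __post_init__(self) -> None:
        ids = [f.fraction_id for f in self.fractions]
        if len(ids) != len(set(ids)):
            raise ValueError("fraction ids must be unique within a profile")

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for f in self.fractions:
            for g in f.copies:
                seen.setdefault(g)
        return list(seen)


@dataclass(frozen=True)
class EnrichmentStat:
    """Heavy-band share of one gene's copies in one treatment group."""

    gene: str
    treatment: str
    heavy_share: float  # mean over replicates, percent
    sd: float
    per_replicate: tuple[float, ...]

    def __post_init__(self) -> None:
        for s in self.per_replicate:
            if not (math.isnan(s) or 0 <= s <= 100):
                raise ValueError("per-replicate shares must lie in [0, 100]")


@dataclass(frozen=True)
class AsvEnrichmentCall:
    asv_id: str
    taxonomy: str
    group_means: Mapping[str, float]  # fraction group -> mean rel. abundance %
    p_values: Mapping[str, float]  # other group -> Welch p vs focal
    labeled: bool


def classify_fractions(
    profile: FractionProfile,
    heavy_band: tuple[float, float] = HEAVY_BAND,
    light_band: tuple[float, float] = LIGHT_BAND,
    overrides: Mapping[str, str] | None = None,
) -> dict[str, str]:
    """Assign each fraction to heavy / light / excluded by buoyant density.

    Band intervals are closed on both ends.  ``overrides`` maps fraction
    ids to forced classes, the mechanism for gradient-specific
    exceptions that band rules cannot express.
    """
    for lo, hi in (heavy_band, light_band):
        if lo > hi:
            raise ValueError("band bounds must be ordered")
    if heavy_band[0] <= light_band[1] and light_band[0] <= heavy_band[1]:
        raise ValueError(f"bands overlap: heavy={heavy_band}, light={light_band}")
    overrides = dict(overrides or {})
    for cls in overrides.values():
        if cls not in ("heavy", "light", "excluded"):
            raise ValueError(f"override class {cls!r} invalid")

    out: dict[str, str] = {}
    for f in profile.fractions:
        if f.fraction_id in overrides:
            out[f.fraction_id] = overrides[f.fraction_id]
        elif heavy_band[0] <= f.buoyant_density <= heavy_band[1]:
            out[f.fraction_id] = "heavy"
        elif light_band[0] <= f.buoyant_density <= light_band[1]:
            out[f.fraction_id] = "light"
        else:
            out[f.fraction_id] = "excluded"
    return out


def share_partition(
    profile: FractionProfile, gene: str, classes: Mapping[str, str]
) -> dict[str, float]:
    """Percent of a gene's total copies in each class; sums to 100.

    Total of zero copies over all fractions makes every share NaN
    (undefined) rather than 0.
    """
    sums = {"heavy": 0.0, "light": 0.0, "excluded": 0.0}
    total = 0.0
    for f in profile.fractions:
        if f.fraction_id not in classes:
            raise KeyError(f"fraction {f.fraction_id!r} has no class")
        c = float(f.copies.get(gene, 0.0))
        sums[classes[f.fraction_id]] += c
        total += c
    if total == 0:
        return {k: math.nan for k in sums}
    return {k: 100.0 * v / total for k, v in sums.items()}


def heavy_share(profile: FractionProfile, gene: str, classes: Mapping[str, str]) -> float:
    """Heavy-band percent of the gene's copies for one replicate gradient."""
    return share_partition(profile, gene, classes)["heavy"]


def enrichment_stat(
    profiles: Sequence[FractionProfile],
    gene: str,
    heavy_band: tuple[float, float] = HEAVY_BAND,
    light_band: tuple[float, float] = LIGHT_BAND,
    overrides: Mapping[str, str] | None = None,
) -> EnrichmentStat:
    """Group heavy-share summary (mean ± sd over replicate gradients)."""
    if not profiles:
        raise ValueError("no profiles supplied")
    treatments = {p.treatment for p in profiles}
    if len(treatments) > 1:
        raise ValueError(f"profiles span multiple treatments: {sorted(treatments)}")
    shares = []
    for p in profiles:
        cls = classify_fractions(p, heavy_band, light_band, overrides)
        shares.append(heavy_share(p, gene, cls))
    arr = np.array(shares, dtype=float)
    return EnrichmentStat(
        gene=gene,
        treatment=profiles[0].treatment,
        heavy_share=float(np.nanmean(arr)),
        sd=float(np.nanstd(arr, ddof=1)) if arr.size > 1 else math.nan,
        per_replicate=tuple(shares),
    )


def compare_shares(a: EnrichmentStat, b: EnrichmentStat) -> float:
    """Two-sided Welch t-test p-value on per-replicate heavy shares."""
    xa = np.asarray(a.per_replicate, dtype=float)
    xb = np.asarray(b.per_replicate, dtype=float)
    xa, xb = xa[~np.isnan(xa)], xb[~np.isnan(xb)]
    if xa.size < 2 or xb.size < 2:
        raise ValueError("compare_shares needs >= 2 replicate shares per group")
    if np.ptp(xa) == 0 and np.ptp(xb) == 0 and xa.mean() == xb.mean():
        return 1.0  # identical constant groups: no evidence of difference
    _, p = stats.ttest_ind(xa, xb, equal_var=False)
    return float(p)


def call_labeled_asvs(
    table: pd.DataFrame,
    focal_group: str,
    alpha: float = 0.001,
    transform: str | None = None,
) -> list[AsvEnrichmentCall]:
    """Call ¹³C-labelled ASVs from a fraction-group abundance table.

    ``table`` is long-form with columns ``asv_id``, ``taxonomy``,
    ``fraction_group``, ``replicate``, ``relative_abundance_pct``.  An
    ASV is labelled iff its mean relative abundance in ``focal_group``
    exceeds its mean in every other group *and* every pairwise Welch
    test against the other groups gives p < ``alpha``.

    ``transform="arcsine"`` applies the arcsine-square-root variance
    stabiliser to the proportions before testing.
    """
    required = {"asv_id", "taxonomy", "fraction_group", "replicate", "relative_abundance_pct"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"ASV table is missing columns: {sorted(missing)}")
    groups = sorted(table["fraction_group"].unique())
    if focal_group not in groups:
        raise ValueError(f"focal group {focal_group!r} not in table (groups: {groups})")

    def _tvals(x: np.ndarray) -> np.ndarray:
        if transform == "arcsine":
            return np.arcsin(np.sqrt(np.clip(x / 100.0, 0, 1)))
        if transform is not None:
            raise ValueError(f"unknown transform {transform!r}")
        return x

    # replicate roster per group, so ASVs absent from a group count as zeros
    roster = {
        g: sorted(gsub["replicate"].unique()) for g, gsub in table.groupby("fraction_group")
    }

    calls: list[AsvEnrichmentCall] = []
    for asv_id, sub in table.groupby("asv_id", sort=True):
        taxonomy = str(sub["taxonomy"].iloc[0])
        by_group: dict[str, np.ndarray] = {}
        for g in groups:
            gsub = sub[sub["fraction_group"] == g].set_index("replicate")
            vals = [
                float(gsub.at[rep, "relative_abundance_pct"]) if rep in gsub.index else 0.0
                for rep in roster[g]
            ]
            by_group[g] = np.array(vals, dtype=float)
        focal = by_group.get(focal_group, np.array([]))
        means = {g: float(v.mean()) if v.size else math.nan for g, v in by_group.items()}
        pvals: dict[str, float] = {}
        labeled = focal.size >= 2
        for g in groups:
            if g == focal_group:
                continue
            other = by_group.get(g, np.array([]))
            if other.size < 2 or focal.size < 2:
                pvals[g] = math.nan
                labeled = False
                continue
            fa, ob = _tvals(focal), _tvals(other)
            if np.ptp(fa) == 0 and np.ptp(ob) == 0 and fa.mean() == ob.mean():
                p = 1.0
            else:
                _, p = stats.ttest_ind(fa, ob, equal_var=False)
            pvals[g] = float(p)
            if not (means[focal_group] > means.get(g, math.inf)) or not (p < alpha):
                labeled = False
        calls.append(
            AsvEnrichmentCall(
                asv_id=str(asv_id),
                taxonomy=taxonomy,
                group_means=means,
                p_values=pvals,
                labeled=labeled,
            )
        )
    return calls
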