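"""Partition arrA abundances into SOAsRB vs non-S-oxidizing reducer shares.

Metagenome quantification tables (Salmon-style: one abundance per arrA
sequence per sample, TPM-like units) are labelled through the genome
screen — an explicit per-genome screen result takes precedence, with a
genus-list fallback for lineages whose *arr* genes are phylogenetically
conserved — and reduced to community shares: the percent of total arrA
abundance carried by putative SOAsRB, by non-S-oxidizing reducers, per
genus, and the top-N SOAsRB genera.  Abundances are treated as already
normalised within a sample; only within-sample shares are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .screen import ScreenResult

__all__ = [
    "CommunityShares",
    "AggregateShares",
    "classify_quant",
    "shares",
    "aggregate_samples",
]

QUANT_COLUMNS = ("arrA_id", "genome_id", "genus", "sample_id", "abundance")

_CLASS_LABELS = {"SOAsRB": "SOAsRB", "nonSox_AsR": "nonSox"}


@dataclass(frozen=True)
class CommunityShares:
    """Per-sample shares of total arrA abundance."""

    sample_id: str
    soasrb_share: float  # percent
    nonsox_share: float
    unclassified_share: float
    genus_shares: Mapping[str, float]  # genus -> percent of total arrA
    top_genera: pd.DataFrame  # top-N SOAsRB genera, ranked
    undefined: bool = False


@dataclass(frozen=True)
class AggregateShares:
    class_mean: Mapping[str, float]
    class_sd: Mapping[str, float]
    genus_mean: Mapping[str, float]
    genus_sd: Mapping[str, float]
    p_value: float | None  # SOAsRB vs non-S-ox shares across samples
    n_samples: int


def _check_columns(records: pd.DataFrame) -> None:
    missing = set(QUANT_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"quant table is missing columns: {sorted(missing)}")
    if (records["abundance"] < 0).any():
        raise ValueError("abundances must be >= 0")
    if records.duplicated(subset=["arrA_id", "sample_id"]).any():
        raise ValueError("(arrA_id, sample_id) pairs must be unique")


def classify_quant(
    records: pd.DataFrame,
    screen_results: Mapping[str, ScreenResult | str] | None = None,
    soasrb_genera: Iterable[str] = (),
    nonsox_genera: Iterable[str] = (),
) -> pd.DataFrame:
    """Label each arrA record SOAsRB / nonSox / unclassified.

    Precedence: a per-genome screen class (``screen_results`` maps
    genome id to a :class:`~soasr.screen.ScreenResult` or a class
    string) overrides genus-list membership; genus lists catch records
    whose genome was not screened.  Records resolving to neither are
    labelled ``unclassified`` and left in the table so the unresolved
    fraction stays visible.
    """
    _check_columns(records)
    screen_results = screen_results or {}
    soasrb_set = set(soasrb_genera)
    nonsox_set = set(nonsox_genera)

    def _label(row) -> str:
        res = screen_results.get(row["genome_id"])
        if res is not None:
            cls = res.screen_class if isinstance(res, ScreenResult) else str(res)
            return _CLASS_LABELS.get(cls, "unclassified")
        if row["genus"] in soasrb_set:
            return "SOAsRB"
        if row["genus"] in nonsox_set:
            return "nonSox"
        return "unclassified"

    out = records.copy()
    out["label"] = out.apply(_label, axis=1)
    return out


def shares(labeled: pd.DataFrame, sample_id: str, top_n: int = 10) -> CommunityShares:
    """Community shares for one sample from a labelled quant table.

    Shares are 100 × class (or genus) abundance / total arrA abundance
    of the sample.  Top-N SOAsRB genera are ranked by share with ties
    broken alphabetically.  A zero total flags the result undefined.
    """
    if "label" not in labeled.columns:
        raise ValueError("table has no 'label' column; run classify_quant first")
    sub = labeled[labeled["sample_id"] == sample_id]
    if sub.empty:
        raise ValueError(f"sample {sample_id!r} not in table")
    total = float(sub["abundance"].sum())
    if total == 0:
        return CommunityShares(
            sample_id, math.nan, math.nan, math.nan, {}, pd.DataFrame(), undefined=True
        )

    by_label = sub.groupby("label")["abundance"].sum() / total * 100.0
    genus_shares = (sub.groupby("genus")["abundance"].sum() / total * 100.0).to_dict()

    soasrb = sub[sub["label"] == "SOAsRB"]
    top = (
        (soasrb.groupby("genus")["abundance"].sum() / total * 100.0)
        .rename("share_pct")
        .reset_index()
        .sort_values(["share_pct", "genus"], ascending=[False, True], kind="mergesort")
        .head(top_n)
        .reset_index(drop=True)
    )
    return CommunityShares(
        sample_id=sample_id,
        soasrb_share=float(by_label.get("SOAsRB", 0.0)),
        nonsox_share=float(by_label.get("nonSox", 0.0)),
        unclassified_share=float(by_label.get("unclassified", 0.0)),
        genus_shares=genus_shares,
        top_genera=top,
    )


def aggregate_samples(share_list: Sequence[CommunityShares]) -> AggregateShares:
    """Across-sample mean ± sd and the SOAsRB-vs-nonSox test.

    The test is a paired two-sided t-test on per-sample (SOAsRB,
    non-S-ox) share pairs — the two shares of a sample are intrinsically
    paired since they partition the same total.  With fewer than two
    samples the test is unavailable (``p_value`` is None).
    """
    valid = [s for s in share_list if not s.undefined]
    if not valid:
        raise ValueError("no defined samples to aggregate")

    soasrb = np.array([s.soasrb_share for s in valid])
    nonsox = np.array([s.nonsox_share for s in valid])
    uncls = np.array([s.unclassified_share for s in valid])

    def _sd(x: np.ndarray) -> float:
        return float(x.std(ddof=1)) if x.size > 1 else math.nan

    genera = sorted({g for s in valid for g in s.genus_shares})
    gmat = {g: np.array([s.genus_shares.get(g, 0.0) for s in valid]) for g in genera}

    if len(valid) >= 2:
        if np.ptp(soasrb - nonsox) == 0:
            # constant difference: degenerate paired test
            p = 1.0 if soasrb[0] == nonsox[0] else 0.0
        else:
            _, p = stats.ttest_rel(soasrb, nonsox)
            p = float(p)
    else:
        p = None

    return AggregateShares(
        class_mean={
            "SOAsRB": float(soasrb.mean()),
            "nonSox": float(nonsox.mean()),
            "unclassified": float(uncls.mean()),
        },
        class_sd={"SOAsRB": _sd(soasrb), "nonSox": _sd(nonsox), "unclassified": _sd(uncls)},
        genus_mean={g: float(v.mean()) for g, v in gmat.items()},
        genus_sd={g: _sd(v) for g, v in gmat.items()},
        p_value=p,
        n_samples=len(valid),
    )
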