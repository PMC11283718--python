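"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator is a pure function of its config plus a NumPy random
generator (or integer seed): rerunning with the same seed reproduces the
output byte for byte.  The generators emulate the study conditions the
analysis modules were built for —

* **Incubations**: linear product-formation kinetics, optionally locked
  to the 4 As(III) : 2 SO4²⁻ stoichiometry of thiosulfate-driven
  arsenate reduction, with additive Gaussian measurement noise truncated
  at zero and an optional lag phase before the linear phase.
* **SIP gradients**: per-taxon DNA mass follows a discretised Gaussian
  over the buoyant-density grid; ¹³C-labelled, metabolically active taxa
  shift by +Δ g/ml; per-fraction qPCR copies get multiplicative
  lognormal assay noise.  Gene channels (SSU rRNA, arrA) and the ASV
  relative-abundance table derive from the same taxon composition.
* **Genomes**: annotated gene sets with or without motif-bearing arrA,
  arrDE operon flanks, SOX gene sets and reverse/reductive dsrA, exactly
  the feature combinations the screening rules discriminate.
* **Quant tables**: per-arrA abundances drawn to match a configured
  SOAsRB / non-S-oxidizing composition exactly (no-noise mode) or with
  Dirichlet jitter.

Scenario factory functions encode the operating points reported for the
original incubation experiments (transfer-culture rates 26 and 13 μM/d;
donor-comparison maxima 38, 45 and control 1.4 μM/g dw/d; site
potentials 43 down to 4.4 μM/g dw/d; heavy-band shares 16% and 15%;
community composition 87% / 13%).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .kinetics import IncubationSeries
from .screen import AMINO_ACIDS, GeneRecord, GenomeAnnotation, find_motif, default_dsr_references
from .sip import FractionProfile, Fraction
from .thermo import ReactionSpec, soasr_reaction

__all__ = [
    "TreatmentSpec",
    "IncubationConfig",
    "stoichiometric_treatment",
    "simulate_incubation",
    "transfer_culture_config",
    "donor_comparison_config",
    "site_potential_config",
    "TaxonSpec",
    "SipTreatmentSpec",
    "SipConfig",
    "DEFAULT_BD_GRID",
    "default_sip_config",
    "simulate_sip",
    "simulate_asv_table",
    "expected_heavy_share",
    "solve_labeled_fraction",
    "two_taxon_community",
    "GenomeSpec",
    "GenomeSimConfig",
    "simulate_genomes",
    "all_combinations_genome_specs",
    "QuantGroupSpec",
    "QuantSimConfig",
    "simulate_quant",
    "write_truth",
]


def _rng(seed: np.random.Generator | int) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def write_truth(path, truth: Mapping[str, object]) -> None:
    """Write a flat ground-truth sidecar as JSON."""
    with open(path, "w") as fh:
        json.dump(dict(truth), fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# Incubation kinetics


@dataclass(frozen=True)
class TreatmentSpec:
    """True kinetics of one treatment: signed slopes per analyte.

    ``lag_days`` delays the linear phase: c(t) = c0 + rate·max(t−lag, 0).
    ``noise_sd`` is the additive Gaussian measurement sd, per analyte or
    one value for all.
    """

    name: str
    rates: Mapping[str, float]
    c0: Mapping[str, float]
    noise_sd: Mapping[str, float] | float = 0.0
    lag_days: float = 0.0

    def sd(self, analyte: str) -> float:
        if isinstance(self.noise_sd, Mapping):
            return float(self.noise_sd.get(analyte, 0.0))
        return float(self.noise_sd)


@dataclass(frozen=True)
class IncubationConfig:
    treatments: tuple[TreatmentSpec, ...]
    timepoints: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0)
    replicates: int = 5
    site: str = "FK"
    basis: str = "volume"

    def __post_init__(self) -> None:
        if any(t < 0 for t in self.timepoints):
            raise ValueError("negative incubation times are not allowed")
        for tr in self.treatments:
            sds = tr.noise_sd.values() if isinstance(tr.noise_sd, Mapping) else [tr.noise_sd]
            if any(s < 0 for s in sds):
                raise ValueError(f"{tr.name}: noise sd must be >= 0")

    def truth(self) -> dict[str, float]:
        return {
            f"{self.site}/{tr.name}/{an}": rate
            for tr in self.treatments
            for an, rate in tr.rates.items()
        }


def stoichiometric_treatment(
    name: str,
    asv_reduction_rate: float,
    reaction: ReactionSpec | None = None,
    c0_asv: float = 1000.0,
    noise_sd: Mapping[str, float] | float = 0.0,
    lag_days: float = 0.0,
) -> TreatmentSpec:
    """Treatment whose product slopes are locked to a reaction's stoichiometry.

    The arsenate depletion rate is ``asv_reduction_rate`` (μM/d, given
    positive); arsenite production matches it 1:1 and sulfate production
    follows the reaction's product coefficients (2 SO4²⁻ per 4 As(III)
    for the shipped thiosulfate couple).
    """
    rxn = reaction if reaction is not None else soasr_reaction()
    _, c_asIII = rxn.product("H3AsO3")
    _, c_so4 = rxn.product("SO4^2-")
    r = float(asv_reduction_rate)
    return TreatmentSpec(
        name=name,
        rates={"As(V)": -r, "As(III)": r, "SO4": r * c_so4 / c_asIII},
        c0={"As(V)": c0_asv, "As(III)": 0.0, "SO4": 0.0},
        noise_sd=noise_sd,
        lag_days=lag_days,
    )


def simulate_incubation(
    config: IncubationConfig, rng: np.random.Generator | int
) -> list[IncubationSeries]:
    """Draw replicate incubation series for every treatment in the config.

    Noise is additive Gaussian, truncated at zero (concentrations cannot
    be negative); with zero noise the series are exactly linear after
    the lag.
    """
    gen = _rng(rng)
    t = np.asarray(config.timepoints, dtype=float)
    out: list[IncubationSeries] = []
    for tr in config.treatments:
        eff_t = np.maximum(t - tr.lag_days, 0.0)
        for rep in range(1, config.replicates + 1):
            conc = {}
            for analyte, rate in tr.rates.items():
                clean = tr.c0.get(analyte, 0.0) + rate * eff_t
                sd = tr.sd(analyte)
                noisy = clean + gen.normal(0.0, sd, size=t.shape) if sd > 0 else clean
                conc[analyte] = np.maximum(noisy, 0.0)
            out.append(
                IncubationSeries(
                    site=config.site,
                    treatment=tr.name,
                    replicate=f"r{rep}",
                    timepoints=t,
                    concentrations=conc,
                    basis=config.basis,
                )
            )
    return out


def transfer_culture_config(
    replicates: int = 3,
    noise_sd: Mapping[str, float] | None = None,
) -> IncubationConfig:
    """Serially transferred As+S enrichment at the reported product rates.

    Arsenite appears at 26 μM/d and sulfate at 13 μM/d (the 2:1 product
    stoichiometry); measurement sd defaults to 2 μM for As species and
    3 μM for sulfate.  The initial arsenate pool is sized so the
    substrate never limits over the 30-day window.
    """
    sd = dict(noise_sd) if noise_sd is not None else {"As(V)": 2.0, "As(III)": 2.0, "SO4": 3.0}
    return IncubationConfig(
        treatments=(
            stoichiometric_treatment("As+S_transfer", 26.0, c0_asv=1000.0, noise_sd=sd),
        ),
        timepoints=(0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0),
        replicates=replicates,
        site="FK",
        basis="volume",
    )


def donor_comparison_config(replicates: int = 3) -> IncubationConfig:
    """Heterotrophic vs chemoautotrophic vs no-donor arsenate reduction.

    True maximum As(V) depletion slopes: 38 μM/g dw/d with thiosulfate,
    45 with acetate, 1.4 without an added donor; donor treatments start
    reducing after a 3-day lag.  Noise sd is 2 μM/g dw for donor
    treatments and 10% of the slope for the slow control.
    """
    c0 = 500.0
    return IncubationConfig(
        treatments=(
            TreatmentSpec(
                "thiosulfate", {"As(V)": -38.0}, {"As(V)": c0}, noise_sd=2.0, lag_days=3.0
            ),
            TreatmentSpec("acetate", {"As(V)": -45.0}, {"As(V)": c0}, noise_sd=2.0, lag_days=3.0),
            TreatmentSpec("no_donor", {"As(V)": -1.4}, {"As(V)": c0}, noise_sd=0.14),
        ),
        timepoints=tuple(float(d) for d in range(0, 11)),
        replicates=replicates,
        site="FK",
        basis="dry_weight",
    )


#: True maximum As(V) depletion slopes (μM/g dw/d) of the six-site
#: potential survey; CSWK tops the range at 43, XKS bottoms it at 4.4.
SITE_POTENTIALS: dict[str, float] = {
    "CSWK": 43.0,
    "FK": 30.0,
    "FK2": 22.0,
    "HJ": 15.0,
    "TXX": 8.0,
    "XKS": 4.4,
}


def site_potential_config(
    replicates: int = 3, noise_sd: float = 4.0
) -> dict[str, IncubationConfig]:
    """One config per site for the multi-site potential experiment."""
    out = {}
    for site, rate in SITE_POTENTIALS.items():
        out[site] = IncubationConfig(
            treatments=(
                TreatmentSpec(
                    "As+S", {"As(V)": -rate}, {"As(V)": 600.0}, noise_sd=noise_sd, lag_days=3.0
                ),
            ),
            timepoints=tuple(float(d) for d in range(0, 11)),
            replicates=replicates,
            site=site,
            basis="dry_weight",
        )
    return out


# ---------------------------------------------------------------------------
# SIP gradients


@dataclass(frozen=True)
class TaxonSpec:
    """One community member: relative abundance, label status, gene dosage."""

    taxon_id: str
    taxonomy: str
    abundance: float  # relative, need not be normalised
    labeled: bool  # does this taxon assimilate the 13C substrate?
    gene_weights: Mapping[str, float] = field(default_factory=lambda: {"SSU": 1.0})


@dataclass(frozen=True)
class SipTreatmentSpec:
    """A gradient treatment: isotope, per-gene total copies, activity.

    ``activity`` scales what fraction of each labelled taxon's DNA
    actually incorporated the label (1.0 = full incorporation under the
    treatment's substrates; controls missing a substrate incorporate
    proportionally less).
    """

    name: str
    isotope: str  # "13C" | "12C"
    total_copies: Mapping[str, float]
    activity: float = 1.0

    def __post_init__(self) -> None:
        if self.isotope not in ("13C", "12C"):
            raise ValueError(f"isotope must be 13C or 12C, got {self.isotope!r}")
        if not (0.0 <= self.activity <= 1.0):
            raise ValueError("activity must be in [0, 1]")


@dataclass(frozen=True)
class SipConfig:
    treatments: tuple[SipTreatmentSpec, ...]
    community: tuple[TaxonSpec, ...]
    bd_grid: tuple[float, ...] = tuple(np.linspace(1.69, 1.76, 12).round(6))  # = DEFAULT_BD_GRID
    mu_unlabeled: float = 1.71  # g/ml, centre of the unlabelled DNA band
    sigma_bd: float = 0.008  # g/ml, within-taxon density spread
    delta_bd: float = 0.035  # g/ml, density shift of fully labelled DNA
    lognormal_sigma: float = 0.15  # qPCR assay noise (log scale)
    replicates: int = 3

    def __post_init__(self) -> None:
        grid = np.asarray(self.bd_grid)
        if not np.all(np.diff(grid) > 0):
            raise ValueError("bd_grid must be strictly increasing")
        if self.lognormal_sigma < 0 or self.sigma_bd <= 0:
            raise ValueError("noise parameters out of range")


def _grid_weights(grid: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    """Discretised Gaussian over the fraction grid, normalised to 1.

    Mass falling outside the grid is truncated at the edges (renormalised
    over the grid), with a warning when the band centre itself leaves the
    grid.
    """
    if mu < grid[0] or mu > grid[-1]:
        warnings.warn(
            f"band centre {mu:.4f} g/ml outside the fraction grid "
            f"[{grid[0]:.4f}, {grid[-1]:.4f}]; mass truncated at grid edges",
            stacklevel=2,
        )
    w = np.exp(-0.5 * ((grid - mu) / sigma) ** 2)
    total = w.sum()
    if total == 0:
        # centre far off-grid: park all mass in the nearest edge fraction
        w = np.zeros_like(grid)
        w[0 if mu < grid[0] else -1] = 1.0
        return w
    return w / total


def _gene_fraction_weights(config: SipConfig, treatment: SipTreatmentSpec, gene: str) -> np.ndarray:
    """No-noise copy distribution of one gene channel over the grid."""
    grid = np.asarray(config.bd_grid)
    w0 = _grid_weights(grid, config.mu_unlabeled, config.sigma_bd)
    w1 = _grid_weights(grid, config.mu_unlabeled + config.delta_bd, config.sigma_bd)
    num = np.zeros_like(grid)
    denom = 0.0
    for tx in config.community:
        wt = tx.abundance * float(tx.gene_weights.get(gene, 0.0))
        if wt == 0:
            continue
        a = treatment.activity if (tx.labeled and treatment.isotope == "13C") else 0.0
        num += wt * (a * w1 + (1 - a) * w0)
        denom += wt
    if denom == 0:
        raise ValueError(f"no community member carries gene {gene!r}")
    return num / denom


def labeled_mass_fraction(config: SipConfig, treatment: SipTreatmentSpec, gene: str) -> float:
    """Fraction of a gene channel's DNA that is isotopically shifted."""
    if treatment.isotope != "13C":
        return 0.0
    num = denom = 0.0
    for tx in config.community:
        wt = tx.abundance * float(tx.gene_weights.get(gene, 0.0))
        denom += wt
        if tx.labeled:
            num += wt * treatment.activity
    return num / denom if denom else math.nan


def expected_heavy_share(
    config: SipConfig,
    treatment: SipTreatmentSpec,
    gene: str,
    heavy_band: tuple[float, float] = (1.73, 1.75),
) -> float:
    """Closed-form no-noise heavy-band mass percent for one gene channel."""
    grid = np.asarray(config.bd_grid)
    w = _gene_fraction_weights(config, treatment, gene)
    mask = (grid >= heavy_band[0]) & (grid <= heavy_band[1])
    return 100.0 * float(w[mask].sum())


def _band_masses(
    grid: np.ndarray, mu0: float, sigma: float, delta: float, heavy_band: tuple[float, float]
) -> tuple[float, float]:
    mask = (grid >= heavy_band[0]) & (grid <= heavy_band[1])
    h0 = float(_grid_weights(grid, mu0, sigma)[mask].sum())
    h1 = float(_grid_weights(grid, mu0 + delta, sigma)[mask].sum())
    return h0, h1


#: Default 12-fraction buoyant-density grid, 1.69–1.76 g/ml.
DEFAULT_BD_GRID: tuple[float, ...] = tuple(np.linspace(1.69, 1.76, 12).round(6))


def solve_labeled_fraction(
    target_heavy_pct: float,
    bd_grid: Sequence[float] = DEFAULT_BD_GRID,
    mu_unlabeled: float = 1.71,
    sigma_bd: float = 0.008,
    delta_bd: float = 0.035,
    heavy_band: tuple[float, float] = (1.73, 1.75),
) -> float:
    """Labelled mass fraction p that puts ``target_heavy_pct`` in the heavy band.

    The heavy-band mass is linear in p: p·h1 + (1−p)·h0, with h0/h1 the
    discretised Gaussian heavy-band masses of the unshifted and shifted
    components, so p = (target − h0)/(h1 − h0).
    """
    grid = np.asarray(bd_grid, dtype=float)
    h0, h1 = _band_masses(grid, mu_unlabeled, sigma_bd, delta_bd, heavy_band)
    p = (target_heavy_pct / 100.0 - h0) / (h1 - h0)
    if not (0.0 <= p <= 1.0):
        raise ValueError(
            f"target {target_heavy_pct}% unreachable: baseline {100*h0:.2f}%, "
            f"fully labelled {100*h1:.2f}%"
        )
    return p


def two_taxon_community(
    p_ssu: float, p_arr: float, labeled_taxonomy: str = "Sulfuricella", genes: tuple[str, str] = ("SSU", "arrA")
) -> tuple[TaxonSpec, TaxonSpec]:
    """Minimal labelled/unlabelled pair hitting two labelled-mass fractions.

    The labelled taxon's relative abundance equals ``p_ssu``; its arrA
    dosage is solved so the arrA channel's labelled mass fraction equals
    ``p_arr``.
    """
    if not (0 < p_ssu < 1 and 0 < p_arr < 1):
        raise ValueError("labelled fractions must be in (0, 1)")
    ssu, arr = genes
    w_labeled_arr = p_arr * (1 - p_ssu) / ((1 - p_arr) * p_ssu)
    return (
        TaxonSpec(
            "ASV_L", labeled_taxonomy, p_ssu, labeled=True,
            gene_weights={ssu: 1.0, arr: w_labeled_arr},
        ),
        TaxonSpec(
            "ASV_U", "Unlabeled_background", 1 - p_ssu, labeled=False,
            gene_weights={ssu: 1.0, arr: 1.0},
        ),
    )


def default_sip_config(
    target_ssu_heavy_pct: float = 16.0,
    target_arra_heavy_pct: float = 15.0,
    replicates: int = 3,
    lognormal_sigma: float = 0.15,
    include_controls: bool = True,
) -> SipConfig:
    """Gradient setup at the reported labelled-treatment operating points.

    The labelled-taxon abundance and arrA dosage are solved so the
    no-noise heavy-band (1.73–1.75 g/ml) mass equals the target SSU and
    arrA percentages in the fully active ¹³C-As+S treatment.  Total
    copies per gradient follow the reported per-treatment SSU loads;
    single-substrate controls get proportionally reduced incorporation.
    """
    base = SipConfig(treatments=(), community=())
    p_ssu_total = solve_labeled_fraction(
        target_ssu_heavy_pct, base.bd_grid, base.mu_unlabeled, base.sigma_bd, base.delta_bd
    )
    p_arr_total = solve_labeled_fraction(
        target_arra_heavy_pct, base.bd_grid, base.mu_unlabeled, base.sigma_bd, base.delta_bd
    )
    community = two_taxon_community(p_ssu_total, p_arr_total)
    arr_copies = 1.0e5
    treatments = [
        SipTreatmentSpec("13C-As+S", "13C", {"SSU": 1.4e7, "arrA": arr_copies}, activity=1.0),
        SipTreatmentSpec("12C-As+S", "12C", {"SSU": 2.1e7, "arrA": arr_copies}, activity=1.0),
    ]
    if include_controls:
        treatments += [
            SipTreatmentSpec("13C-As", "13C", {"SSU": 3.5e6, "arrA": arr_copies}, activity=3 / 16),
            SipTreatmentSpec("13C-S", "13C", {"SSU": 1.1e6, "arrA": arr_copies}, activity=4 / 16),
        ]
    return replace(
        base,
        treatments=tuple(treatments),
        community=community,
        replicates=replicates,
        lognormal_sigma=lognormal_sigma,
    )


def simulate_sip(
    config: SipConfig, rng: np.random.Generator | int
) -> tuple[list[FractionProfile], dict[str, float]]:
    """Draw replicate gradient profiles for every treatment.

    Returns the profiles and a truth map with the no-noise heavy-band
    share per (treatment, gene).
    """
    gen = _rng(rng)
    grid = np.asarray(config.bd_grid)
    profiles: list[FractionProfile] = []
    truth: dict[str, float] = {}
    for tr in config.treatments:
        genes = list(tr.total_copies)
        clean = {g: tr.total_copies[g] * _gene_fraction_weights(config, tr, g) for g in genes}
        for g in genes:
            truth[f"{tr.name}/{g}/heavy_share_pct"] = expected_heavy_share(config, tr, g)
        for rep in range(1, config.replicates + 1):
            fracs = []
            for i, bd in enumerate(grid):
                copies = {}
                for g in genes:
                    noise = (
                        math.exp(gen.normal(0.0, config.lognormal_sigma))
                        if config.lognormal_sigma > 0
                        else 1.0
                    )
                    copies[g] = float(clean[g][i] * noise)
                fracs.append(Fraction(f"F{i+1:02d}", float(bd), copies))
            profiles.append(FractionProfile(treatment=tr.name, replicate=f"r{rep}", fractions=fracs))
    return profiles, truth


def simulate_asv_table(
    config: SipConfig,
    rng: np.random.Generator | int,
    heavy_band: tuple[float, float] = (1.73, 1.75),
    light_band: tuple[float, float] = (1.70, 1.72),
    gene: str = "SSU",
) -> pd.DataFrame:
    """ASV relative abundances per fraction group, from the same community.

    For each treatment and replicate, per-taxon copies per fraction are
    drawn with the same density model and lognormal noise as the gene
    channels; relative abundances are then summed within the heavy and
    light bands, giving one long-form row per (ASV, fraction group,
    replicate).  Groups are named ``<treatment>_heavy`` / ``_light``.
    """
    gen = _rng(rng)
    grid = np.asarray(config.bd_grid)
    w0 = _grid_weights(grid, config.mu_unlabeled, config.sigma_bd)
    w1 = _grid_weights(grid, config.mu_unlabeled + config.delta_bd, config.sigma_bd)
    bands = {
        "heavy": (grid >= heavy_band[0]) & (grid <= heavy_band[1]),
        "light": (grid >= light_band[0]) & (grid <= light_band[1]),
    }
    rows = []
    for tr in config.treatments:
        for rep in range(1, config.replicates + 1):
            taxon_copies = {}
            for tx in config.community:
                wt = tx.abundance * float(tx.gene_weights.get(gene, 0.0))
                a = tr.activity if (tx.labeled and tr.isotope == "13C") else 0.0
                clean = wt * (a * w1 + (1 - a) * w0)
                noise = np.exp(gen.normal(0.0, config.lognormal_sigma, size=grid.shape))
                taxon_copies[tx.taxon_id] = clean * noise
            for band, mask in bands.items():
                band_totals = {t: c[mask].sum() for t, c in taxon_copies.items()}
                total = sum(band_totals.values())
                for tx in config.community:
                    rows.append(
                        {
                            "asv_id": tx.taxon_id,
                            "taxonomy": tx.taxonomy,
                            "fraction_group": f"{tr.name}_{band}",
                            "replicate": f"r{rep}",
                            "relative_abundance_pct": 100.0 * band_totals[tx.taxon_id] / total,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Genomes


@dataclass(frozen=True)
class GenomeSpec:
    """Feature flags for one synthetic genome."""

    genome_id: str
    genus: str = "GenusA"
    has_arrA: bool = True
    motif: bool = True
    has_arrB: bool = True
    flank: bool = True  # arrDE genes around the arr operon
    sox: str = "none"  # none | partial | full
    dsr: str = "none"  # none | reverse | reductive
    n_background: int = 15
    taxonomy: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.motif and not self.has_arrA:
            raise ValueError(f"{self.genome_id}: motif without arrA is contradictory")
        if self.flank and not self.has_arrA:
            raise ValueError(f"{self.genome_id}: arrDE flank without arrA is contradictory")
        if self.sox not in ("none", "partial", "full"):
            raise ValueError(f"{self.genome_id}: sox must be none|partial|full")
        if self.dsr not in ("none", "reverse", "reductive"):
            raise ValueError(f"{self.genome_id}: dsr must be none|reverse|reductive")


@dataclass(frozen=True)
class GenomeSimConfig:
    genomes: tuple[GenomeSpec, ...]
    protein_length: int = 250
    gene_nt_length: int = 900
    intergenic_nt: int = 100
    dsr_mutation_rate: float = 0.1  # fraction of sites mutated from the seed


_SOX_FULL = ("soxX", "soxY", "soxZ", "soxA", "soxB", "soxC", "soxD")
_SOX_PARTIAL = ("soxX", "soxY", "soxZ", "soxA", "soxC")  # lacks soxB (and soxD)


def _random_protein(gen: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(AMINO_ACIDS))[gen.integers(0, 20, size=length)])


def _scrub_motif(seq: str) -> str:
    chars = list(seq)
    while True:
        hits = find_motif("".join(chars))
        if not hits:
            return "".join(chars)
        chars[hits[0] - 1] = "A"  # break the R/K anchor


def _mutate(gen: np.random.Generator, seq: str, rate: float) -> str:
    chars = list(seq)
    n = max(1, round(rate * len(chars)))
    positions = gen.choice(len(chars), size=n, replace=False)
    for pos in positions:
        alternatives = AMINO_ACIDS.replace(chars[pos], "")
        chars[pos] = alternatives[gen.integers(0, len(alternatives))]
    return "".join(chars)


def simulate_genomes(
    config: GenomeSimConfig, rng: np.random.Generator | int
) -> list[GenomeAnnotation]:
    """Build annotated genomes matching each spec's feature flags exactly.

    ArrA proteins contain (or provably lack) the R/KGRY motif by
    construction; dsrA proteins are mutated copies of the shipped
    synthetic reference seeds at the configured distance; background
    genes carry family ``other``.  Coordinates are 1-based, inclusive
    and non-overlapping on a single contig.
    """
    gen = _rng(rng)
    refs = default_dsr_references()
    genomes = []
    for spec in config.genomes:
        genes: list[tuple[str, str | None, str | None, str | None]] = []
        # (family-or-None, protein, ko) tuples in contig order
        plan: list[tuple[str | None, str | None]] = []
        half = spec.n_background // 2
        plan += [("other", None)] * half

        if spec.has_arrA:
            arr_block: list[tuple[str | None, str | None]] = []
            prot = _scrub_motif(_random_protein(gen, config.protein_length))
            if spec.motif:
                pos = int(gen.integers(10, config.protein_length - 10))
                anchor = "RK"[int(gen.integers(0, 2))]
                prot = prot[:pos] + anchor + "GRY" + prot[pos + 4 :]
            if spec.flank:
                arr_block.append(("arrD", None))
            arr_block.append(("arrA", prot))
            if spec.has_arrB:
                arr_block.append(("arrB", None))
            if spec.flank:
                arr_block.append(("arrE", None))
            plan += arr_block

        if spec.sox != "none":
            for fam in _SOX_FULL if spec.sox == "full" else _SOX_PARTIAL:
                plan.append((fam, None))

        if spec.dsr != "none":
            label = "reverse_or_oxidative" if spec.dsr == "reverse" else "reductive"
            seed_seq = refs[label][0]
            plan.append(("dsrA", _mutate(gen, seed_seq, config.dsr_mutation_rate)))
            plan.append(("dsrB", None))

        plan += [("other", None)] * (spec.n_background - half)

        records = []
        pos_nt = 1
        for i, (family, prot) in enumerate(plan, start=1):
            start = pos_nt
            end = start + config.gene_nt_length - 1
            pos_nt = end + 1 + config.intergenic_nt
            if family == "other":
                strand = "+-"[int(gen.integers(0, 2))]
                prot = _random_protein(gen, config.protein_length)
            else:
                strand = "+"
            records.append(
                GeneRecord(
                    gene_id=f"{spec.genome_id}_g{i:03d}",
                    genome_id=spec.genome_id,
                    contig=f"{spec.genome_id}_ctg1",
                    start=start,
                    end=end,
                    strand=strand,
                    family=family,
                    ko=None,
                    protein=prot,
                )
            )
        genomes.append(
            GenomeAnnotation(genome_id=spec.genome_id, genes=records, taxonomy=spec.taxonomy or ("Bacteria", spec.genus))
        )
    return genomes


def all_combinations_genome_specs() -> tuple[GenomeSpec, ...]:
    """The 12-genome fixture: {motif, no-motif} × {flank, no-flank} × {soxB, rdsr, none}."""
    specs = []
    for motif in (True, False):
        for flank in (True, False):
            for sulfur in ("soxB", "rdsr", "none"):
                gid = f"G_{'m' if motif else 'x'}_{'f' if flank else 'x'}_{sulfur}"
                specs.append(
                    GenomeSpec(
                        genome_id=gid,
                        motif=motif,
                        flank=flank,
                        sox="full" if sulfur == "soxB" else "none",
                        dsr="reverse" if sulfur == "rdsr" else "none",
                    )
                )
    return tuple(specs)


def expected_screen_class(spec: GenomeSpec, require_arrb: bool = True) -> str:
    """Truth-table class implied by a genome spec's feature flags."""
    reducer = (
        spec.has_arrA
        and spec.motif
        and spec.flank
        and (spec.has_arrB or not require_arrb)
    )
    oxidizer = spec.sox == "full" or spec.dsr == "reverse"
    if reducer and oxidizer:
        return "SOAsRB"
    if reducer:
        return "nonSox_AsR"
    if oxidizer:
        return "sulfur_oxidizer_only"
    return "neither"


# ---------------------------------------------------------------------------
# Quant tables


@dataclass(frozen=True)
class QuantGroupSpec:
    """One abundance class: its share and the arrA sequences carrying it."""

    label: str  # "SOAsRB" | "nonSox" | arbitrary genus label
    share_pct: float
    members: tuple[tuple[str, str, str], ...]  # (arrA_id, genome_id, genus)


@dataclass(frozen=True)
class QuantSimConfig:
    groups: tuple[QuantGroupSpec, ...]
    samples: tuple[str, ...] = ("S01",)
    total_abundance: float = 1.0e4  # TPM-like units per sample
    dirichlet_concentration: float | None = None  # None = no noise

    def __post_init__(self) -> None:
        total = sum(g.share_pct for g in self.groups)
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"group shares sum to {total}, not 100")
        if not all(g.members for g in self.groups):
            raise ValueError("every group needs at least one member sequence")


def simulate_quant(config: QuantSimConfig, rng: np.random.Generator | int) -> pd.DataFrame:
    """Per-arrA abundance records matching the configured composition.

    No-noise mode reproduces the composition exactly in every sample;
    with a Dirichlet concentration, per-sample group proportions are
    drawn from Dirichlet(concentration × share-vector), so larger
    concentrations shrink the across-sample spread.
    """
    gen = _rng(rng)
    base = np.array([g.share_pct / 100.0 for g in config.groups])
    rows = []
    for sample in config.samples:
        if config.dirichlet_concentration is None:
            props = base
        else:
            props = gen.dirichlet(config.dirichlet_concentration * base)
        for g, p in zip(config.groups, props):
            per_member = config.total_abundance * p / len(g.members)
            for arr_id, genome_id, genus in g.members:
                rows.append(
                    {
                        "arrA_id": arr_id,
                        "genome_id": genome_id,
                        "genus": genus,
                        "sample_id": sample,
                        "abundance": per_member,
                    }
                )
    return pd.DataFrame(rows)
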