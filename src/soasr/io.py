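"""Readers and writers for the package's tabular and sequence dialects.

TSV is the canonical interchange format (CSV is accepted on input via
delimiter sniffing); floats are written at full precision with a period
decimal separator.  Sequence data use standard formats: GFF3 for gene
coordinates (attribute ``ID`` carries the gene id), FASTA for protein
sequences keyed by gene id, and a gene→family/KO TSV for annotation
labels.  Salmon-style ``quant.sf`` tables are accepted for arrA
abundances (only ``Name`` and ``TPM`` are consumed).
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .kinetics import IncubationSeries
from .screen import GeneRecord, GenomeAnnotation
from .sip import Fraction, FractionProfile
from .thermo import ChemicalSpecies, ReactionSpec

__all__ = [
    "read_table",
    "write_table",
    "read_incubation_tsv",
    "write_incubation_tsv",
    "read_geochem_tsv",
    "read_fraction_tsv",
    "write_fraction_tsv",
    "read_asv_tsv",
    "read_species_tsv",
    "write_species_tsv",
    "read_reaction_config",
    "write_genome_files",
    "read_genome_files",
    "read_quant_sf",
    "read_quant_mapping",
    "assemble_quant_records",
]

INCUBATION_COLUMNS = ("site", "treatment", "replicate", "time_d", "analyte", "value", "unit", "basis")
FRACTION_COLUMNS = ("treatment", "replicate", "fraction_id", "buoyant_density_g_per_ml", "gene", "copies_per_g")
ASV_COLUMNS = ("asv_id", "taxonomy", "fraction_group", "replicate", "relative_abundance_pct")


def read_table(path, required: Sequence[str] = ()) -> pd.DataFrame:
    """Read a TSV (or sniffed CSV) table, checking required columns."""
    df = pd.read_csv(path, sep=None, engine="python")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(repr(c) for c in missing)}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# -- incubation series ------------------------------------------------------

def read_incubation_tsv(path) -> list[IncubationSeries]:
    """Long-form incubation table → replicate series objects.

    Mixed units or bases within one (site, treatment, replicate) series
    are an error.
    """
    df = read_table(path, INCUBATION_COLUMNS)
    out = []
    for (site, treatment, replicate), sub in df.groupby(
        ["site", "treatment", "replicate"], sort=True
    ):
        if sub["basis"].nunique() > 1:
            raise ValueError(
                f"{path}: mixed basis within series {site}/{treatment}/{replicate}"
            )
        conc = {}
        times = None
        for analyte, asub in sub.groupby("analyte"):
            if asub["unit"].nunique() > 1:
                raise ValueError(
                    f"{path}: mixed units for {analyte!r} in series {site}/{treatment}/{replicate}"
                )
            asub = asub.sort_values("time_d")
            t = asub["time_d"].to_numpy(dtype=float)
            if times is None:
                times = t
            elif not np.array_equal(times, t):
                raise ValueError(
                    f"{path}: analytes on different time grids in series "
                    f"{site}/{treatment}/{replicate}"
                )
            conc[str(analyte)] = asub["value"].to_numpy(dtype=float)
        out.append(
            IncubationSeries(
                site=str(site),
                treatment=str(treatment),
                replicate=str(replicate),
                timepoints=times,
                concentrations=conc,
                basis=str(sub["basis"].iloc[0]),
            )
        )
    return out


def write_incubation_tsv(series: Iterable[IncubationSeries], path) -> None:
    rows = []
    for s in series:
        unit = "uM" if s.basis == "volume" else "uM_per_g_dw"
        for analyte, vec in s.concentrations.items():
            for t, v in zip(s.timepoints, vec):
                rows.append(
                    {
                        "site": s.site,
                        "treatment": s.treatment,
                        "replicate": s.replicate,
                        "time_d": t,
                        "analyte": analyte,
                        "value": v,
                        "unit": unit,
                        "basis": s.basis,
                    }
                )
    write_table(pd.DataFrame(rows, columns=list(INCUBATION_COLUMNS)), path)


def read_geochem_tsv(path) -> pd.DataFrame:
    return read_table(path, ("site", "parameter", "value"))


# -- SIP fractions ----------------------------------------------------------

def read_fraction_tsv(path) -> list[FractionProfile]:
    df = read_table(path, FRACTION_COLUMNS)
    out = []
    for (treatment, replicate), sub in df.groupby(["treatment", "replicate"], sort=True):
        fracs = []
        for (fid, bd), fsub in sub.groupby(["fraction_id", "buoyant_density_g_per_ml"], sort=True):
            copies = dict(zip(fsub["gene"], fsub["copies_per_g"].astype(float)))
            fracs.append(Fraction(str(fid), float(bd), copies))
        fracs.sort(key=lambda f: f.buoyant_density)
        out.append(FractionProfile(str(treatment), str(replicate), fracs))
    return out


def write_fraction_tsv(profiles: Iterable[FractionProfile], path) -> None:
    rows = []
    for p in profiles:
        for f in p.fractions:
            for gene, c in f.copies.items():
                rows.append(
                    {
                        "treatment": p.treatment,
                        "replicate": p.replicate,
                        "fraction_id": f.fraction_id,
                        "buoyant_density_g_per_ml": f.buoyant_density,
                        "gene": gene,
                        "copies_per_g": c,
                    }
                )
    write_table(pd.DataFrame(rows, columns=list(FRACTION_COLUMNS)), path)


def read_asv_tsv(path) -> pd.DataFrame:
    return read_table(path, ASV_COLUMNS)


# -- thermodynamics ---------------------------------------------------------

def _format_ox(states: Mapping[str, int] | None) -> str:
    if not states:
        return ""
    return ";".join(f"{el}:{st}" for el, st in states.items())


def _parse_ox(text: str) -> dict[str, int] | None:
    text = (text or "").strip()
    if not text:
        return None
    out = {}
    for part in text.split(";"):
        el, st = part.split(":")
        out[el.strip()] = int(st)
    return out


def read_species_tsv(path) -> dict[str, ChemicalSpecies]:
    df = read_table(path, ("name", "formula", "charge", "dGf0_kJ_per_mol"))
    species = {}
    for _, row in df.iterrows():
        ox = _parse_ox(str(row.get("oxidation_states", "")) if "oxidation_states" in df.columns else "")
        species[str(row["name"])] = ChemicalSpecies(
            name=str(row["name"]),
            formula=str(row["formula"]),
            charge=int(row["charge"]),
            dGf0=float(row["dGf0_kJ_per_mol"]),
            oxidation_states=ox,
        )
    return species


def write_species_tsv(species: Mapping[str, ChemicalSpecies], path) -> None:
    rows = []
    for sp in species.values():
        formula = "".join(
            f"{el}{n if n > 1 else ''}" for el, n in sp.formula.items()
        )
        rows.append(
            {
                "name": sp.name,
                "formula": formula,
                "charge": sp.charge,
                "dGf0_kJ_per_mol": sp.dGf0,
                "oxidation_states": _format_ox(sp.oxidation_states),
            }
        )
    write_table(pd.DataFrame(rows), path)


def read_reaction_config(config: Mapping, species: Mapping[str, ChemicalSpecies]) -> ReactionSpec:
    """Build a reaction from a {reactants: {name: coeff}, products: …} mapping."""
    def _side(block: Mapping[str, float]):
        out = []
        for name, coeff in block.items():
            if name not in species:
                raise ValueError(f"species {name!r} not in species table")
            out.append((species[name], float(coeff)))
        return out

    for key in ("reactants", "products"):
        if key not in config:
            raise ValueError(f"reaction config is missing {key!r}")
    return ReactionSpec(reactants=_side(config["reactants"]), products=_side(config["products"]))


# -- genome annotations -----------------------------------------------------

def write_genome_files(genome: GenomeAnnotation, outdir) -> dict[str, Path]:
    """Write one genome as GFF3 + protein FASTA + family/KO TSV.

    Files are ``<genome_id>.gff3``, ``<genome_id>.faa`` and
    ``<genome_id>.tsv`` under ``outdir``; returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gid = genome.genome_id
    paths = {
        "gff3": outdir / f"{gid}.gff3",
        "faa": outdir / f"{gid}.faa",
        "tsv": outdir / f"{gid}.tsv",
    }

    with open(paths["gff3"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.genes:
            fh.write(
                "\t".join(
                    [
                        g.contig,
                        "soasr_sim",
                        "gene",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        f"ID={g.gene_id}",
                    ]
                )
                + "\n"
            )

    records = [
        SeqRecord(Seq(g.protein), id=g.gene_id, description="")
        for g in genome.genes
        if g.protein
    ]
    SeqIO.write(records, str(paths["faa"]), "fasta")

    rows = [
        {"gene_id": g.gene_id, "family": g.family or "", "ko": g.ko or ""}
        for g in genome.genes
    ]
    write_table(pd.DataFrame(rows), paths["tsv"])
    return paths


def read_genome_files(
    gff3_path, faa_path, family_tsv_path, genome_id: str | None = None,
    taxonomy: Sequence[str] = (),
) -> GenomeAnnotation:
    """Assemble a genome annotation from GFF3, protein FASTA and family TSV."""
    gid = genome_id or Path(gff3_path).stem
    db = gffutils.create_db(
        str(gff3_path), dbfn=":memory:", from_string=False, force=True,
        keep_order=True, merge_strategy="create_unique",
    )
    proteins = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(faa_path), "fasta")}
    fam = read_table(family_tsv_path, ("gene_id",))
    fam = fam.set_index("gene_id")

    genes = []
    for feat in db.all_features():
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        family = None
        ko = None
        if gene_id in fam.index:
            raw_fam = fam.at[gene_id, "family"] if "family" in fam.columns else ""
            raw_ko = fam.at[gene_id, "ko"] if "ko" in fam.columns else ""
            family = str(raw_fam) if raw_fam and not pd.isna(raw_fam) else None
            ko = str(raw_ko) if raw_ko and not pd.isna(raw_ko) else None
        genes.append(
            GeneRecord(
                gene_id=gene_id,
                genome_id=gid,
                contig=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand,
                family=family,
                ko=ko,
                protein=proteins.get(gene_id),
            )
        )
    return GenomeAnnotation(genome_id=gid, genes=genes, taxonomy=tuple(taxonomy))


# -- quant tables -----------------------------------------------------------

def read_quant_sf(path, sample_id: str) -> pd.DataFrame:
    """Read a Salmon quant.sf-dialect table; only Name and TPM are used."""
    df = read_table(path, ("Name", "TPM"))
    return pd.DataFrame(
        {"arrA_id": df["Name"].astype(str), "sample_id": sample_id, "abundance": df["TPM"].astype(float)}
    )


def read_quant_mapping(path) -> pd.DataFrame:
    return read_table(path, ("arrA_id", "genome_id", "genus"))


def assemble_quant_records(quants: Iterable[pd.DataFrame], mapping: pd.DataFrame) -> pd.DataFrame:
    """Join per-sample quant tables with the arrA→genome/genus mapping."""
    allq = pd.concat(list(quants), ignore_index=True)
    merged = allq.merge(mapping, on="arrA_id", how="left", validate="many_to_one")
    merged["genome_id"] = merged["genome_id"].fillna("")
    merged["genus"] = merged["genus"].fillna("")
    return merged[["arrA_id", "genome_id", "genus", "sample_id", "abundance"]]
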