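"""Screen synthetic genomes for sulfur-oxidizing arsenate reducers.

Builds the 12-genome fixture covering every combination of
{motif, no-motif} × {arrDE flank, none} × {soxB, reverse-dsr, none} and
applies the classification rules.
"""

from soasr.screen import screen_genome
from soasr.simulate import GenomeSimConfig, all_combinations_genome_specs, simulate_genomes

cfg = GenomeSimConfig(genomes=all_combinations_genome_specs())
genomes = simulate_genomes(cfg, 11)

print(f"{'genome':16s} {'motif':>5s} {'flank':>5s} {'S-ox':>5s}  class")
for genome in genomes:
    res = screen_genome(genome)
    ev = res.evidence
    print(f"{genome.genome_id:16s} {str(ev.motif_ok):>5s} {str(ev.arrDE_flank):>5s} "
          f"{str(ev.sulfur_oxidizer):>5s}  {res.screen_class}")
# SOAsRB requires *both* a functional respiratory arr operon (motif-bearing
# arrA inside an arrDE-flanked arrAB cluster) and a sulfur-oxidation marker
# (soxB or reverse-type dsrA); each requirement alone gives a partial class.
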