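"""Generate a synthetic two-species CNV study and inspect its truth.

Builds a pair of species genomes that share gene content but differ by
planted gene-family duplications, derives long-read-like (complete) and
short-read-like (collapse-prone) assemblies, and designs the probe set.
"""

from cnvconcord import SimConfig, derive_assemblies, design_probes, generate_genomes

cfg = SimConfig(
    seed=1,
    genome_length=120_000,
    n_genes=24,
    n_cnv_regions=12,
    collapse_probability=0.5,
    noise_sd=0.3,
)

genome_a, genome_b, annotation, truth = generate_genomes(cfg)
a_long, a_short = derive_assemblies(genome_a, truth, cfg)
b_long, b_short = derive_assemblies(genome_b, truth, cfg)
probes = design_probes(genome_a, annotation, cfg)

print(f"species A genome: {len(genome_a):,} bp   species B genome: {len(genome_b):,} bp")
print(f"short-read assemblies: A {len(a_short):,} bp, B {len(b_short):,} bp "
      "(shorter where families collapsed)")
print(f"probes: {len(probes)} ({(probes['klass'] == 'genic').sum()} genic, "
      f"{(probes['klass'] == 'intergenic').sum()} intergenic)")
print("\nplanted truth (copies per species, collapse flags):")
print(truth.to_string(index=False))
# Each row is one gene family: copies_a/copies_b are the planted copy
# numbers, collapsed_* says whether the short-read-like assembly merged
# the copies into one. log2(copies_a/copies_b) is what the array and the
# hit ratios should recover.
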