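"""Compare the three copy-number views: aCGH vs long-read vs short-read.

Computes inter-species log2 ratios per platform on the multi-copy
probes, their pairwise Pearson correlations, and the Euler-region counts
of species-biased call sets.
"""

import json

from cnvconcord import RunConfig, SimConfig, run_full

cfg = RunConfig(
    sim=SimConfig(
        seed=1,
        genome_length=120_000,
        n_genes=24,
        n_cnv_regions=12,
        collapse_probability=0.5,
        noise_sd=0.3,
    )
)
report = run_full(cfg)

print("pairwise Pearson r (all multicopy probes):")
for pair, r in report["correlations"]["all_multicopy"].items():
    print(f"  {pair:28s} r = {r['r']:+.3f}  (t = {r['t']:.1f}, df = {r['df']})")
print("\nEuler regions, species-A-biased probes:")
print(json.dumps(report["euler"]["a"]["probes"], indent=2))
# Half the families are collapsed in the short-read assemblies, so the
# short-read hit ratio flattens to 0 at those loci: r(aCGH, long-read)
# stays near 1 while r(aCGH, short-read) drops — the central
# observation this package exists to reproduce.
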