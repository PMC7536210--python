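"""Screen core genes for selection with K2P distances and NG86 Ka/Ks.

Four genomes diverge from a shared ancestor; every gene evolves under
purifying selection (dN/dS = 0.05) except rps3 (dN/dS = 2). The screen
should flag rps3 pairs — mirroring the signature of positive or relaxed
selection on the mitochondrial ribosomal protein gene.
"""

import warnings

from mitocomp import selection_screen
from mitocomp.molevol import per_gene_means
from mitocomp.synthetic import DivergencePlan, default_spec, evolve_set, generate_genome

spec = default_spec(seed=2)
spec.length = 40_000
spec.genes = [g for g in spec.genes if g.ftype in ("core_pcg", "rrna", "rnpB")]
spec.introns, spec.repeats, spec.tandems = [], [], []
ancestor, _ = generate_genome(spec)

plan = DivergencePlan(rate=0.12, kappa=1.0, default_dnds=0.05, gene_dnds={"rps3": 2.0})
genomes, _ = evolve_set(ancestor, "((A:1,B:1):0.3,(C:1,D:1):0.3)r;", plan, seed=3)

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    table = selection_screen(genomes)

print("per-gene means over all species pairs (sorted by K2P):")
print(per_gene_means(table).round(4).head(8))
flagged = table[table["positive_selection"]]
print(f"\npairs flagged Ka/Ks > 1: {len(flagged)}")
print(flagged[["gene", "sp1", "sp2", "ka", "ks", "ka_ks"]].round(4).to_string(index=False))
print()
print("Only rps3 pairs exceed Ka/Ks = 1; every other gene sits well below 1,")
print("the classic signature of purifying selection on mitochondrial PCGs.")
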