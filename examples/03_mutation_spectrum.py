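"""Outgroup-polarized mutation spectrum and equilibrium GC prediction.

Simulates three strains, projects the two ingroup-vs-outgroup alignments
into a three-way alignment, polarizes ingroup differences by parsimony, and
prints the collapsed directional spectrum, the equilibrium GC the rates
imply, and the GC→AT vs AT→GC chi-square. Under the default AT-biased
spectrum, equilibrium GC (~33%) sits below the observed GC (~40%): the
genome is still drifting toward AT.
"""

from endosym import (
    AncestorSpec,
    EvolutionParams,
    align_pair,
    directional_chi_square,
    equilibrium_gc,
    evolve_tree,
    generate_ancestor,
    indel_direction_and_homopolymers,
    polarize,
    project_threeway,
    spectrum,
)

ancestor = generate_ancestor(
    AncestorSpec(genome_length=100_000, n_genes=85, mean_cds_length=850,
                 n_duplicated_genes=2, rng_seed=7)
)
params = EvolutionParams(seed=8, indel_rate=2e-5, gene_loss_rate_per_phase=())
leaves, _ = evolve_tree(ancestor, params)

a1 = align_pair(leaves["KR01"], leaves["NZ27"])
a2 = align_pair(leaves["FK01"], leaves["NZ27"])
threeway = project_threeway(a1, a2, "NZ27")

pv = polarize(threeway, ("KR01", "FK01"), "NZ27", tuple(leaves["NZ27"].features))
anc_seq = threeway.ungapped("NZ27")
table = spectrum(pv, anc_seq)

print(f"polarized SNPs: {len(pv.snps)}  (unpolarizable: {pv.n_unpolarizable}, "
      f"shared/stem: {pv.n_shared})")
print("collapsed spectrum (% of per-site rates):")
for cls, pct in table.collapsed_pct.items():
    print(f"  {cls}: {pct:5.1f}%")
gc_obs = 100 * (anc_seq.count("G") + anc_seq.count("C")) / len(anc_seq)
print(f"equilibrium GC: {equilibrium_gc(table):.1f}%  "
      f"vs observed GC: {gc_obs:.1f}%")
chi, p = directional_chi_square(table)
print(f"GC→AT vs AT→GC chi-square: {chi:.1f} (p = {p:.2e})")
n_ins, n_del, net, hp = indel_direction_and_homopolymers(pv, anc_seq)
print(f"polarized indels: {n_ins} insertions, {n_del} deletions, "
      f"net {net:+d} bp")
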