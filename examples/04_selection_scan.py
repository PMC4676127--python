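"""Branch-specific dN/dS with bootstrap and a foreground-branch test.

Simulates a codon alignment on the fixed 5-taxon tree (dog, human, cat,
tiger, cheetah) with an elevated omega on the cheetah branch, reconstructs
ancestral sequences by parsimony, counts substitutions with the
Nei-Gojobori method, bootstraps the branch rates and tests the cheetah
branch against the pooled background.
"""

from bkit.phylo import five_taxon_tree
from bkit.selscan import branch_dnds, foreground_test, supergene_bootstrap
from bkit.syndata import CodonSimSpec, simulate_codon_alignment

tree = five_taxon_tree(branch_length=0.05, omega={"cheetah": 2.0})
alignment, truth = simulate_codon_alignment(
    CodonSimSpec(tree=tree, n_codons=2000, kappa=2.0, seed=42))
print("simulated per-branch substitutions (truth):")
print(truth.to_string(index=False))

table = branch_dnds(tree, alignment)
print("\nestimated branch rates (NG86 on parsimony ancestors):")
print(table[["branch", "Nd", "Sd", "dN", "dS", "omega"]].round(4).to_string(index=False))

boot = supergene_bootstrap(alignment, tree, B=200, seed=1)
print("\nbootstrap omega quantiles (200 codon-column replicates):")
print(boot["quantiles"].round(3).to_string(index=False))

res = foreground_test(alignment, tree, foreground="cheetah", B=199, seed=2)
print(f"\nforeground test: omega(cheetah) = {res.omega_foreground:.2f} vs "
      f"background {res.omega_background:.2f}; "
      f"T = {res.statistic:.2f}, p = {res.p_value:.3f}")
print("a small p supports elevated nonsynonymous accumulation on the "
      "cheetah branch, as planted")
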