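"""Linkage-disequilibrium pruning: drop redundant variants at r² > 0.2.

The default fixture plants 7 proxies copying index SNPs at haplotype copy
probability 0.775 (dosage r² ≈ 0.6); greedy pruning in ascending-p order
should keep the 21 index SNPs and drop the 7 proxies.
"""

from mirpgs.assoc import snp_association
from mirpgs.ld import greedy_prune, ld_matrix, priority_by_pvalue
from mirpgs.simulate import default_config, simulate

matrix = simulate(default_config(seed=1))
assoc = snp_association(matrix)
result = greedy_prune(ld_matrix(matrix), priority_by_pvalue(assoc), threshold=0.2)

print(f"{matrix.n_variants} variants in, {len(result.kept)} kept, "
      f"{len(result.dropped)} excluded for high LD:")
for row in result.log[~result.log["kept"]].itertuples():
    print(f"  {row.rsid:>17} dropped — r² = {row.r2:.2f} with kept partner {row.excluded_by}")
print()
print("Every dropped variant is a planted proxy sitting above the r² = 0.2 "
      "exclusion threshold with its own parent; the more strongly associated "
      "member of each pair (smaller p) is the one retained.")
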