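"""Replicate-free differential expression on pooled libraries.

Simulates two pooled RNA-seq libraries with 200 genes differentially
expressed at 4-fold among 5,000, runs TMM normalization and the exact
Poisson-based (Audic-Claverie) test, and scores the calls against the
generator's truth table.
"""

from aphidfit.de import de_contrast, tmm_factors, venn_partition
from aphidfit.synthdata import CountSimSpec, simulate_counts

matrix, truth = simulate_counts(CountSimSpec(), seed=1)
factors = tmm_factors(matrix)
print("TMM factors:", factors.factors.round(4).to_dict())

result = de_contrast(matrix, "A", "B", factors)
called = result[result["call"] != "ns"]
recall = truth.loc[called.index, "is_de"].sum() / truth["is_de"].sum()
false_calls = int((~truth.loc[called.index, "is_de"]).sum())
print(f"called {len(called)} genes (up {sum(called['call'] == 'up')},"
      f" down {sum(called['call'] == 'down')})")
print(f"recall = {recall:.1%}, false calls = {false_calls}")
print(
    "\nA gene is called only when its TMM-normalized expression ratio is"
    " >= 2 and the BH-adjusted exact-test p-value is < 0.001 - the stringent"
    " double threshold appropriate when each condition is a single pooled"
    " library. Nearly all 4-fold genes are recovered with ~zero false calls."
)

# set comparison across two simulated contrasts
m2, _ = simulate_counts(CountSimSpec(), seed=2)
r2 = de_contrast(m2, "A", "B")
sets = venn_partition({"host1": result, "host2": r2})
print("\nVenn partition across contrasts:",
      {("&".join(sorted(k))): v for k, v in sets.partition.items()})
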