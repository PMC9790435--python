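"""Define fire regimes by complete-linkage clustering and check recovery.

Clusters the normalised characteristics of burned cells into K = 5
regimes, compares the labels with the planted truth (adjusted Rand
index) and prints the dendrogram cut-height diagnostics used to judge
the choice of K.
"""

from fireregimes.clustering import cut_height_diagnostics
from fireregimes.scenarios import clustering_recovery

res = clustering_recovery(seed=1)
print(f"clustered {res['n_cells']} burned cells into 5 regimes")
print(f"adjusted Rand index vs planted labels: {res['ari']:.3f}")
print("\ncut-height diagnostics (relative height of each K-cluster cut):")
print(cut_height_diagnostics(res["linkage"], k_range=range(2, 9)).round(3))
print("\nAn ARI of 1.0 means the clustering reproduced the planted regimes "
      "exactly; the cut heights collapse sharply once the five planted "
      "regimes are separated.")
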