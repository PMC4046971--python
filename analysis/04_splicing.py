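"""Test the top-two-isoform ratio for memory of the source tissue.

Simulates per-gene counts of the most abundant isoform against the
top-two total, with a handful of genes whose isoform balance in iPSC
lines follows the adult tissue rather than ESC (splicing memory), applies
the two-quantifier agreement filter, and classifies the isoform fraction
under the same five hypotheses as whole-gene expression via a
beta-binomial likelihood.
"""

import argparse
import json
import os

import numpy as np
import pandas as pd

from ipscvar import diff_expression as de

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--n-genes", type=int, default=300)
parser.add_argument("--out", default="results/splicing.json")
args = parser.parse_args()

rng = np.random.default_rng(args.seed)
labels = np.array(["adult"] * 6 + ["iPSC"] * 9 + ["ESC"] * 4)
n_genes = args.n_genes
n_memory = max(n_genes // 60, 3)

gene_ids = [f"g{j:04d}" for j in range(n_genes)]
base_p = rng.uniform(0.35, 0.75, n_genes)
p_mat = np.tile(base_p[:, None], (1, len(labels)))
memory_genes = rng.choice(n_genes, n_memory, replace=False)
for j in memory_genes:  # adult = iPSC != ESC on the isoform fraction
    shift = 0.25 * rng.choice([-1, 1])
    p_mat[j, labels != "ESC"] = np.clip(base_p[j] + shift, 0.05, 0.95)

totals = rng.poisson(200, size=(n_genes, len(labels))) + 1
iso1 = rng.binomial(totals, p_mat)

# two quantifiers disagree on the isoform ranking for a random 10% of genes
disagree = set(rng.choice(n_genes, n_genes // 10, replace=False))
agreement = pd.DataFrame({
    "gene_id": gene_ids * 2,
    "quantifier": ["cufflinks"] * n_genes + ["miso"] * n_genes,
    "iso1": ["t1"] * n_genes + ["t2" if j in disagree else "t1" for j in range(n_genes)],
    "iso2": ["t2"] * n_genes + ["t1" if j in disagree else "t2" for j in range(n_genes)],
})

out = de.isoform_ratio_test(
    iso1, totals, labels, agreement=agreement, gene_ids=gene_ids, p_threshold=1e-3
)
res = out["results"]
tested_memory = [gene_ids[j] for j in memory_genes
                 if gene_ids[j] in set(res["gene_id"])]
called_tm = res.loc[res["category"] == "TM", "gene_id"]
recovered = len(set(called_tm) & set(tested_memory))
summary = {
    "n_genes": n_genes,
    "n_excluded_disagreement": out["n_excluded_disagreement"],
    "n_tested": out["n_tested"],
    "n_planted_memory": n_memory,
    "n_planted_memory_tested": len(tested_memory),
    "n_memory_recovered": recovered,
    "n_false_memory_calls": int(len(set(called_tm) - set(tested_memory))),
    "category_counts": res["category"].value_counts().to_dict(),
}
os.makedirs(os.path.dirname(args.out) or ".", exist_ok=True)
with open(args.out, "w") as fh:
    json.dump(summary, fh, indent=2)

print(f"{out['n_excluded_disagreement']} genes dropped by the "
      "quantifier-agreement filter; "
      f"{out['n_tested']} isoform ratios tested")
print(f"splicing memory: {recovered}/{len(tested_memory)} planted genes "
      f"recovered, {summary['n_false_memory_calls']} false memory calls — "
      "isoform-level memory is detectable but, at realistic planted rates, "
      "involves only a handful of genes.")
print(f"wrote {args.out}")
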