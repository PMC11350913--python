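#!/usr/bin/env python
"""Map expression gains and losses onto the species tree (Dollo parsimony).

Each gene's presence/absence pattern is explained by a single acquisition
at the branch above the MRCA of the expressing species plus the minimal
set of subsequent losses.  Writes per-branch acquisition/loss counts and
the gene lists behind them.
"""

import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from phylotestis import SpeciesTree, aggregate_gainloss, binarize, read_expression_table

BASE = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    os.makedirs(BASE, exist_ok=True)
    matrix = read_expression_table(os.path.join(BASE, "fixtures", "expression.tsv"))
    tree = SpeciesTree.default()
    counts, gene_lists = aggregate_gainloss(binarize(matrix), tree)

    counts.to_csv(os.path.join(BASE, "gainloss.tsv"), sep="\t", index_label="branch")
    with open(os.path.join(BASE, "gainloss_genes.json"), "w") as fh:
        json.dump(gene_lists, fh, indent=1, sort_keys=True)

    print("branch: acquisitions / losses (non-zero branches)")
    for branch in counts.index:
        g, l = counts.loc[branch, "gains"], counts.loc[branch, "losses"]
        if g or l:
            print(f"  {branch}: {g} / {l}")
    print(f"tables -> {os.path.relpath(BASE)}/gainloss.tsv, gainloss_genes.json")


if __name__ == "__main__":
    main()
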