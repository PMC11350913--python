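#!/usr/bin/env python
"""Binarize the RPKM matrix and classify clade-specific expression.

Loads results/fixtures/expression.tsv, scores presence at RPKM >= 1 and
labels each gene's cross-species pattern (universal, Mammalia-, Theria-,
Eutheria- or Marsupialia-specific).  Writes the per-gene labels and prints
the category table; on the planted fixture the 22 marsupial-stem and 15
therian-stem genes should come back exactly.
"""

import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from phylotestis import binarize, classify_pattern, read_expression_table, universal_set

BASE = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    os.makedirs(BASE, exist_ok=True)
    matrix = read_expression_table(os.path.join(BASE, "fixtures", "expression.tsv"))
    pam = binarize(matrix, cutoff=1.0)
    categories = classify_pattern(pam)
    out = os.path.join(BASE, "expression_categories.tsv")
    categories.to_csv(out, sep="\t", header=["category"], index_label="gene_id")

    print(f"{len(matrix.gene_ids)} genes x {len(matrix.species)} species, cutoff RPKM >= 1")
    print(f"universal (expressed in all 10 species): {len(universal_set(pam))}")
    for category, n in categories.value_counts().items():
        print(f"  {category}: {n}")
    print(f"per-gene labels -> {os.path.relpath(out)}")


if __name__ == "__main__":
    main()
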