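#!/usr/bin/env python
"""Replicate study: how well is the stem omega contrast recovered?

Simulates the ARHGAP28-like locus (611 codons, stem omegas 0.39/0.10)
across many seeds, re-estimates both stem omegas through the full
reconstruction pipeline and reports the estimate distribution plus the
fraction of replicates where the selection-asymmetry exact test detects
the planted shift (one-sided p < 0.05).  Detection power is an output of
the experiment, not an assumption.
"""

import argparse
import os
import sys

import numpy as np
import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from phylotestis import selection_asymmetry_test, simulate_codon_alignment, stem_dnds
from phylotestis.scenarios import omega_shift_locus_params

BASE = os.path.join(os.path.dirname(__file__), "..", "results")


def main():
    os.makedirs(BASE, exist_ok=True)
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--replicates", type=int, default=100)
    args = parser.parse_args()

    rng = np.random.default_rng(args.seed)
    rows = []
    for rep in range(args.replicates):
        params = omega_shift_locus_params(int(rng.integers(0, 2**31 - 1)))
        aln, _ = simulate_codon_alignment(params)
        eu = stem_dnds(aln, params.tree, "Eutheria")
        ma = stem_dnds(aln, params.tree, "Marsupialia")
        p = selection_asymmetry_test(eu, ma).p_one_sided
        rows.append(
            {"replicate": rep, "eutherian_stem_omega": eu.omega,
             "marsupial_stem_omega": ma.omega, "p_one_sided": p}
        )
    table = pd.DataFrame(rows)
    out = os.path.join(BASE, "stem_omega_recovery.tsv")
    table.to_csv(out, sep="\t", index=False, float_format="%.5g")

    med_eu = table["eutherian_stem_omega"].median()
    med_ma = table["marsupial_stem_omega"].median()
    power = (table["p_one_sided"] < 0.05).mean()
    print(f"{args.replicates} replicates, 611 codons, planted stem omegas 0.39 / 0.10")
    print(f"median estimates: Eutheria stem {med_eu:.3f}, Marsupialia stem {med_ma:.3f}")
    print(f"asymmetry detected (one-sided p < 0.05) in {100 * power:.0f}% of replicates")
    print(f"per-replicate table -> {os.path.relpath(out)}")


if __name__ == "__main__":
    main()
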