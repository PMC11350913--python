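#!/usr/bin/env python
"""Generate the synthetic study inputs.

Emits a complete fixture set under results/fixtures/: a 100-gene RPKM
matrix with 22 marsupial-stem and 15 therian-stem expression gains planted
over a universal background, three codon alignments on the fixed 10-species
tree — ARHGAP28-like (611 codons, stem omegas 0.39/0.10) plus two control
loci without a stem shift (745 and 752 codons, matching SYNM and PDZRN3
lengths) — the species tree, the ground truth and a hash manifest.
"""

import argparse
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from phylotestis import write_fixture_set
from phylotestis.scenarios import (
    expression_study_scenario,
    omega_shift_locus_params,
    uniform_omega_locus_params,
)

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "fixtures")


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    scenario = expression_study_scenario(seed=args.seed, n_genes=100)
    loci = {
        "ARHGAP28_like": omega_shift_locus_params(args.seed, n_codons=611),
        "SYNM_like": uniform_omega_locus_params(args.seed + 1, n_codons=745),
        "PDZRN3_like": uniform_omega_locus_params(args.seed + 2, n_codons=752),
    }
    manifest = write_fixture_set(OUT, scenario, loci)
    print(f"wrote {len(manifest)} files to {os.path.relpath(OUT)}:")
    for name, digest in sorted(manifest.items()):
        print(f"  {name}  sha256:{digest[:12]}")


if __name__ == "__main__":
    main()
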