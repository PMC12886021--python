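#!/usr/bin/env python
"""Demonstrate read-level quantification against generator ground truth.

Simulates a handful of FASTQ libraries (miRNA insert + 3' adapter + 12-bp
UMI, with PCR duplicates), runs the UMI-deduplicating quantifier, and
reports per-sample QC plus agreement with the planted molecule counts.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from uroevmir.quant import ReadLayout, quantify_sample
from uroevmir.simulate import generate_reference, simulate_fastq_sample, write_fastq

ADAPTER = "AGATCGGAAGAGCACACGTC"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-samples", type=int, default=4)
    ap.add_argument("--n-mirnas", type=int, default=100)
    ap.add_argument("--n-molecules", type=int, default=20_000)
    ap.add_argument("--outdir", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    fastq_dir = args.outdir / "fastq"
    fastq_dir.mkdir(exist_ok=True)

    ref = generate_reference(args.n_mirnas, seed=args.seed, min_length=20)
    ref.write_fasta(args.outdir / "reference.fasta")
    layout = ReadLayout(ADAPTER)
    rng = np.random.default_rng(args.seed)

    rows = []
    for i in range(args.n_samples):
        abundance = rng.dirichlet(np.full(args.n_mirnas, 0.5))
        reads, truth = simulate_fastq_sample(
            ref, abundance, args.n_molecules, ADAPTER,
            duplication_rate=1.5, seed=int(rng.integers(0, 2**31 - 1)))
        path = fastq_dir / f"sample_{i}.fastq"
        write_fastq(reads, path)
        counts, qc = quantify_sample(str(path), ref, layout)
        exact = int((counts.loc[truth.index] == truth).all())
        rows.append({"sample": f"sample_{i}", **qc,
                     "matches_ground_truth": exact})
    qc_table = pd.DataFrame(rows)
    qc_table.to_csv(args.outdir / "quantifier_qc.tsv", sep="\t", index=False)
    print(qc_table.to_string(index=False))
    n_ok = qc_table.matches_ground_truth.sum()
    print(f"\n{n_ok}/{len(qc_table)} samples reproduce the planted molecule "
          "counts exactly after UMI deduplication")


if __name__ == "__main__":
    main()
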