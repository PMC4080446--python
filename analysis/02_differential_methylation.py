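#!/usr/bin/env python
"""Call differentially methylated genes.

Applies the moderated d statistic with permutation FDR (200 label
permutations) to the cohort from step 01 and classifies each gene's group
mean as hypo-/mid-/hypermethylated. The called genes are the seeds for the
network stages.
"""

import argparse

from epinet import io_formats as io, sam_fdr


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--fdr", type=float, default=0.05)
    ap.add_argument("--out", default="results/differential_methylation.tsv")
    args = ap.parse_args()

    meth = io.read_matrix(f"{args.data}/methylation.tsv",
                          f"{args.data}/methylation_groups.tsv")
    res = sam_fdr(meth, n_perm=200, fdr_cutoff=args.fdr, rng_seed=args.seed)
    res.to_csv(args.out, sep="\t", index_label="gene")
    called = res.index[res["called"]]
    io.write_gene_set(called, "results/seed_genes.txt")

    truth = io.read_gene_set(f"{args.data}/truth_differential.txt")
    tp = len(set(called) & truth)
    print(f"called {len(called)} genes at q < {args.fdr} (s0 = "
          f"{res.attrs['s0']:.4g})")
    print(f"sensitivity vs planted truth: {tp / len(truth):.3f}; "
          f"false calls: {len(called) - tp}")
    print("control-group classes:",
          res["class_control"].value_counts().to_dict())


if __name__ == "__main__":
    main()
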