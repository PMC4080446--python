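#!/usr/bin/env python
"""Quantify the methylation-expression relationship.

Pairs every shared gene's case-group mean beta with its case-group mean
expression, reports the Spearman correlation, fits the least-squares line
and flags genes inside the 95% prediction band.
"""

import argparse

from epinet import (fit_line, flag_within_interval, gene_level_pairs,
                    io_formats as io)
from epinet.methexpr import plot_fit


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", default="results/data")
    ap.add_argument("--group", default="case")
    args = ap.parse_args()

    meth = io.read_matrix(f"{args.data}/methylation.tsv",
                          f"{args.data}/methylation_groups.tsv")
    expr = io.read_matrix(f"{args.data}/expression.tsv",
                          f"{args.data}/expression_groups.tsv")
    pairs = gene_level_pairs(meth, expr, group=args.group)
    fit = fit_line(pairs)
    flags, n_within = flag_within_interval(fit, pairs)
    pairs.assign(within_interval=flags).to_csv(
        "results/meth_expr_pairs.tsv", sep="\t", index_label="gene"
    )
    plot_fit(fit, pairs, "results/meth_expr.png")
    print(f"{fit.n} genes with both methylation and expression")
    print(f"spearman rho = {fit.spearman_rho:.4f} (p = {fit.spearman_p:.3g})")
    print(f"fitted line: y = {fit.slope:.3f}x + {fit.intercept:.3f} "
          f"(residual sd {fit.resid_sd:.3f})")
    print(f"{n_within}/{fit.n} genes ({n_within / fit.n:.1%}) inside the "
          f"95% prediction interval")


if __name__ == "__main__":
    main()
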