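#!/usr/bin/env python
"""Compactness comparisons across gene classes from GFF3 models.

Generates three gene-model groups (GSR-like compact, low-regulated,
background sprawling), then runs the comparisons: intronless-fraction
z-tests, Kruskal-Wallis + Dunn on intron number and total intron length
(intronless excluded), and the Mann-Whitney top-vs-bottom-50%-by-FC test
on total intron length.
"""

import argparse
import itertools
from pathlib import Path

import numpy as np
import pandas as pd

from rhizotox.architecture import (architecture_table, compare_intron_metrics,
                                   intronless_fraction_test, parse_gene_models,
                                   split_by_fc_test)
from rhizotox.synthetic import generate_gene_models, substream


GROUPS = {
    "gsr": {"n": 200, "intron_count": {"geometric_mean": 1.0},
            "intron_length": {"uniform_int": (60, 400)}},
    "low_regulated": {"n": 200, "intron_count": {"geometric_mean": 2.0},
                      "intron_length": {"uniform_int": (150, 900)}},
    "background": {"n": 200, "intron_count": {"geometric_mean": 3.5},
                   "intron_length": {"uniform_int": (300, 1500)}},
}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    gff3, truth = generate_gene_models(GROUPS, seed=args.seed)
    data = args.out / "data"
    data.mkdir(parents=True, exist_ok=True)
    (data / "gene_models.gff3").write_text(gff3)
    models = {m.gene_id: m for m in parse_gene_models(gff3_text=gff3)}
    groups = {label: [models[g] for g in truth.index[truth["group"] == label]]
              for label in GROUPS}
    architecture_table(list(models.values())).to_csv(
        args.out / "architecture.tsv", sep="\t")

    for a, b in itertools.combinations(GROUPS, 2):
        res = intronless_fraction_test(groups[a], groups[b])
        print(f"intronless {a} {100 * res.fraction_a:.1f}% vs {b} "
              f"{100 * res.fraction_b:.1f}%: z = {res.z:.2f}, p = {res.p:.3g}")

    for metric in ("intron_count", "total_intron_length"):
        (h, p), dunn, _ = compare_intron_metrics(groups, metric)
        print(f"{metric}: Kruskal-Wallis H = {h:.2f}, p = {p:.3g}")
        print(dunn.to_string(index=False, float_format=lambda v: f"{v:.3g}"))

    # FC split within the GSR-like group: higher FC -> shorter introns
    rng = substream(args.seed, 10)
    gsr_models = groups["gsr"]
    lengths = np.array([m.total_intron_length for m in gsr_models], dtype=float)
    ranks = lengths.argsort().argsort()
    fc = pd.Series(2.0 + 6.0 * (1.0 - ranks / len(ranks))
                   + rng.normal(0, 0.8, len(ranks)),
                   index=[m.gene_id for m in gsr_models])
    res = split_by_fc_test(gsr_models, fc)
    print(f"top vs bottom 50% by FC, total intron length: U = {res.u:.0f}, "
          f"p = {res.p:.3g} (means {res.mean_top:.0f} vs {res.mean_bottom:.0f})")


if __name__ == "__main__":
    main()
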