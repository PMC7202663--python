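#!/usr/bin/env python
"""De novo filtering, per-class mutation rates, and the deletion fold change
between the TLS-dead-like and wild-type-like cohorts.

Reads results/sim/<genotype>/ (run 01_simulate.py first); writes
results/rates.tsv, results/deletion_sizes.tsv and prints the headline rates.
"""

import argparse
from pathlib import Path

import pandas as pd

from tmejsig.ma_rates import estimate_rates, filter_de_novo, fold_change, size_distribution
from tmejsig.seq_utils import RefGenome
from tmejsig.variant_io import normalize_deletion, read_variant_table


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim-dir", default="results/sim")
    ap.add_argument("--out-dir", default="results")
    args = ap.parse_args()
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables, all_events = [], []
    for d in sorted(Path(args.sim_dir).iterdir()):
        ref = RefGenome(d / "reference.fa")
        records = read_variant_table(d / "variants.tsv", ref=ref)
        kept, rejected = filter_de_novo(records)
        lines = pd.read_csv(d / "lines.tsv", sep="\t")
        tables.append(estimate_rates(kept, lines, ref=ref))
        all_events += [
            normalize_deletion(ref, r)
            for r in kept
            if r.deletion_size >= 50 and not r.is_snv
        ]
        print(f"{d.name}: kept {len(kept)}, rejected {len(rejected)}")
    table = pd.concat(tables, ignore_index=True)
    table.to_csv(out / "rates.tsv", sep="\t", index=False)
    for _, row in table[table.n_mutations > 0].iterrows():
        print(
            f"  {row.genotype:>10} {row.var_class:<22} "
            f"{row.rate:.4f}/generation [{row.ci_low:.4f}, {row.ci_high:.4f}]"
        )
    dele = table[table.var_class == "deletion_50_500"].set_index("genotype")
    if {"wild_type", "tls_dead"} <= set(dele.index):
        fc = fold_change(
            int(dele.loc["tls_dead", "n_mutations"]), dele.loc["tls_dead", "total_generations"],
            int(dele.loc["wild_type", "n_mutations"]), dele.loc["wild_type", "total_generations"],
        )
        print(
            f"deletion fold change tls_dead vs wild_type: {fc['ratio']:.1f}x "
            f"[{fc['ci_low']:.1f}, {fc['ci_high']:.1f}]"
        )
    dist = size_distribution(all_events)
    dist["sizes"].to_csv(out / "deletion_sizes.tsv", sep="\t", index=False)
    print(f"median deletion size: {dist['median']:.0f} bp (n={len(dist['sizes'])})")


if __name__ == "__main__":
    main()
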