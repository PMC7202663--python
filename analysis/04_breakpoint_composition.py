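#!/usr/bin/env python
"""Breakpoint base-composition profiles (+/-100 bp, mirrored orientation) for
all deletions and for the with-insert subset; flags 3-SD outliers.

Writes results/composition_all.tsv, results/composition_with_insert.tsv
(+ .json, + PNGs) and prints flagged positions.
"""

import argparse
from pathlib import Path

from tmejsig.breakpoint_composition import composition_profile, flag_outliers, render_profile
from tmejsig.seq_utils import RefGenome
from tmejsig.variant_io import normalize_deletion, read_variant_table


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--sim-dir", default="results/sim/tls_dead")
    ap.add_argument("--out-dir", default="results")
    ap.add_argument("--orientation", choices=["mirrored", "top_strand"], default="mirrored")
    args = ap.parse_args()
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    d = Path(args.sim_dir)
    ref = RefGenome(d / "reference.fa")
    records = read_variant_table(d / "variants.tsv", ref=ref)
    events = [
        normalize_deletion(ref, r)
        for r in records
        if r.deletion_size >= 50 and not r.is_snv
    ]
    for subset in ("all", "with_insert"):
        profile = composition_profile(events, ref, orientation=args.orientation, subset=subset)
        profile.to_tsv(out / f"composition_{subset}.tsv")
        profile.to_json(out / f"composition_{subset}.json")
        render_profile(profile, out / f"composition_{subset}.png")
        flags = flag_outliers(profile, k=3)
        print(f"{subset}: {profile.n_junctions} junctions, {len(flags)} positions beyond 3 SD")
        for b, p, r, side in flags[:8]:
            print(f"  {b} at {p:+d}: r={r:.2f} ({side})")


if __name__ == "__main__":
    main()
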