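#!/usr/bin/env python
"""Lesion-frequency arithmetic and the qua1466 G4 motif scan.

Translates per-generation deletion rates into per-base frequencies of
replication-blocking lesions (assuming every unbypassed lesion leaves one
50-500 bp deletion), and scans the qua1466 G-quadruplex-capable sequence.
Writes results/lesion_frequency.json and results/qua1466_g4.bed.
"""

import argparse
import json
from dataclasses import asdict
from pathlib import Path

from tmejsig.ma_rates import lesion_frequency
from tmejsig.seq_utils import scan_g4, write_bed

QUA1466 = "GGGAGGGCGGGCGGG"  # chrIV:11,326,500-11,326,514


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--out-dir", default="results")
    ap.add_argument("--divisions-per-generation", type=float, default=10)
    ap.add_argument("--genome-size", type=float, default=1e8)
    args = ap.parse_args()
    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scenarios = {
        # ~0.1 deletion/generation when only Rev1/Rev3-dependent bypass is lost
        "rev1_rev3_dependent": 0.1,
        # ~1 deletion/generation when all TLS activity is lost
        "tls_dead": 1.0,
    }
    payload = {}
    for name, rate in scenarios.items():
        lf = lesion_frequency(rate, args.divisions_per_generation, args.genome_size)
        payload[name] = asdict(lf)
        print(
            f"{name}: {rate} deletions/generation over "
            f"{args.divisions_per_generation:.0f} divisions of {args.genome_size:.0e} bases "
            f"-> 1 lesion per {lf.bases_per_event:.0e} bases"
        )
    with open(out / "lesion_frequency.json", "w") as fh:
        json.dump(payload, fh, indent=1)
    hits = scan_g4(QUA1466)
    write_bed(hits, "chrIV_qua1466_local", out / "qua1466_g4.bed")
    print(f"qua1466: {len(hits)} G4 motif spanning bases {hits[0].start}-{hits[0].end}")


if __name__ == "__main__":
    main()
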