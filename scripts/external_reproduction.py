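#!/usr/bin/env python
"""Reproduce the real-trial headline statistics from the deposited data.

The plot-level flowering phenotypes of the 188-RIL bean family are deposited
externally (Figshare) and the GBS genotypes/linkage map are distributed
with the population's genotyping resources; none of that data ships with
this package.  Once downloaded and converted to the
CSV formats documented in ``beanqtl.io`` (genotypes.csv, map.csv,
phenotypes.csv, weather.csv), this script runs the full pipeline on them:
spatial adjustment, multi-site heritability, SIM/CIM scans with the
genome-wide threshold, the QTL x Site model, the QTL-EC model, and the three
evaluations (whole-data fit, parental hold-out, leave-one-site-out).

Usage:
    python scripts/external_reproduction.py --data <dir with the four CSVs> \
        --out <output dir>
"""

import argparse
from pathlib import Path

from beanqtl import cli, io


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, required=True)
    ap.add_argument("--out", type=Path, required=True)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg = io.PipelineConfig(outdir=str(args.out), seed=args.seed)
    args.out.mkdir(parents=True, exist_ok=True)
    for name in ("genotypes.csv", "map.csv", "phenotypes.csv", "weather.csv"):
        src = args.data / name
        if not src.exists():
            raise SystemExit(f"missing input: {src} (see beanqtl.io for the format)")
        (args.out / name).write_bytes(src.read_bytes())

    for stage in ("adjust", "herit", "scan", "fitqtl", "fitec", "predict", "validate"):
        rc = cli.COMMANDS[stage](cfg)
        print(f"stage {stage}: done" if rc is None else f"stage {stage}: {rc}")


if __name__ == "__main__":
    main()
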