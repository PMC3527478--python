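#!/usr/bin/env python
"""Pearson screens between biotic summaries and soil chemistry.

Correlates (site, date)-level alpha diversity and site-level temporal beta /
TLA slope against the chemistry variables, log(x+1)-transforming everything
except pH.  Writes results/correlations.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

import lagbeta as lb
from lagbeta.pipeline import RunConfig, _correlation_screens


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=Path("results/data"))
    parser.add_argument("--tla", type=Path, default=Path("results/tla.csv"))
    parser.add_argument("--out", type=Path, default=Path("results/correlations.csv"))
    args = parser.parse_args()

    fp = lb.read_fingerprint(args.data_dir / "fingerprint.csv")
    md = lb.read_metadata(args.data_dir / "metadata.csv")
    chem = lb.read_chemistry(args.data_dir / "chemistry.csv")
    data = lb.align(fp, md, chem)
    config = RunConfig(
        fingerprint=str(args.data_dir / "fingerprint.csv"),
        metadata=str(args.data_dir / "metadata.csv"),
        chemistry=str(args.data_dir / "chemistry.csv"),
    )
    beta = lb.temporal_beta_table(data.fingerprint, data.metadata)
    tla = pd.read_csv(args.tla, comment="#", index_col=0)
    screen = _correlation_screens(data, beta, tla, config)
    screen.to_csv(args.out, index=False)

    strongest = screen.dropna(subset=["r"]).reindex(
        screen["r"].abs().sort_values(ascending=False).index
    )
    print("strongest correlations:")
    print(strongest.head(8).round(3).to_string(index=False))
    print(f"wrote {args.out}")


if __name__ == "__main__":
    main()
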