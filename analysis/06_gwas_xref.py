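#!/usr/bin/env python
"""Cross-reference the synthetic GWAS catalog against the audited probe
flags: what fraction of association studies rests on at least one probe
confounded by unprobed variation?
"""

import argparse
import json
from pathlib import Path

from refaudit.pipeline import stage_gwas_xref


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data-dir", type=Path, default=Path("results/data"))
    parser.add_argument("--flags", type=Path, default=Path("results/audit.flags.tsv"))
    parser.add_argument("--out", type=Path, default=Path("results/gwas_xref.tsv"))
    args = parser.parse_args()

    summary = stage_gwas_xref(
        args.data_dir / "gwas.tsv", args.flags, args.data_dir / "probes.tsv",
        args.out,
    )
    print(f"GWAS cross-reference: {summary['n_affected']}/{summary['n_studies']} "
          f"studies ({100 * summary['affected_fraction']:.0f}%) have a hit on a "
          f"flagged probe")
    truth = json.loads((args.data_dir / "truth.json").read_text())
    print(f"  planted affected set: {len(truth['affected_studies'])} studies")


if __name__ == "__main__":
    main()
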