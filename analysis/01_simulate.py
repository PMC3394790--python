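#!/usr/bin/env python
"""Generate the synthetic study: a 1,000-marker block-structured diploid
cohort with planted probe problems, site anomalies, ROH, two discordant
caller views, and a GWAS catalog with a planted affected-study set.

Writes all pipeline inputs plus truth.json under results/data/.
"""

import argparse
import json
from pathlib import Path

from refaudit.synthetic import StudySpec, generate_study


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out-dir", type=Path, default=Path("results/data"))
    args = parser.parse_args()

    spec = StudySpec()
    truth = generate_study(args.out_dir, seed=args.seed, spec=spec)

    n_planted = sum(1 for fl in truth["probe_flags"].values() if fl)
    print(f"wrote synthetic study to {args.out_dir} (seed {args.seed})")
    print(f"  cohort: {spec.n_samples} samples, "
          f"{spec.n_blocks * spec.markers_per_block} markers in "
          f"{spec.n_blocks} true blocks")
    print(f"  probes: {len(truth['probe_flags'])} "
          f"({n_planted} with planted problems)")
    print(f"  planted polyallelic sites: {len(truth['polyallelic_sites'])}")
    print(f"  planted ROH: {len(truth['roh'])} segments")
    print(f"  caller views: {len(truth['concordance']['shared'])} shared / "
          f"{len(truth['concordance']['unique_a'])}+"
          f"{len(truth['concordance']['unique_b'])} unique sites")
    print(f"  affected GWAS studies: {len(truth['affected_studies'])}")
    (args.out_dir / "study_seed.json").write_text(
        json.dumps({"seed": args.seed}) + "\n"
    )


if __name__ == "__main__":
    main()
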