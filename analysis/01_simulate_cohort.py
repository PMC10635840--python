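#!/usr/bin/env python
"""Simulate a demonstration eNose cohort and write it to disk.

Writes a long-format recording CSV (+ JSON sidecar with the generating
settings) and the subject metadata table under results/.  The demo
cohort is deliberately smaller than the study-sized default (full-size
raw traces are ~300 MB of CSV); the downstream analysis scripts
regenerate the study-sized cohort in memory instead of reading this.
"""

import argparse
from pathlib import Path

import breathdisc as bd
from breathdisc.io import write_recordings


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-copd", type=int, default=120)
    ap.add_argument("--n-cancer", type=int, default=40)
    ap.add_argument("--n-incident", type=int, default=8)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    spec = bd.CohortSpec(n_copd=args.n_copd, n_cancer=args.n_cancer,
                         n_incident=args.n_incident, seed=args.seed)
    recordings, metadata = bd.generate_cohort(spec)
    write_recordings(recordings, args.out / "recordings.csv",
                     sidecar={"seed": spec.seed,
                              "effect_size": spec.effect_size,
                              "n_copd": spec.n_copd,
                              "n_cancer": spec.n_cancer,
                              "n_incident": spec.n_incident})
    metadata.to_csv(args.out / "metadata.csv", index=False)

    counts = metadata["class_label"].value_counts()
    print(f"wrote {len(recordings)} recordings for {len(metadata)} subjects "
          f"to {args.out}/recordings.csv")
    print(f"  COPD {counts.get('COPD', 0)}, incident COPD "
          f"{counts.get('COPD_INCIDENT_CANCER', 0)}, "
          f"lung cancer {counts.get('LUNG_CANCER', 0)}")


if __name__ == "__main__":
    main()
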