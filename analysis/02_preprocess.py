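#!/usr/bin/env python
"""Apply the snippet validity and exclusion rules.

Reads the simulated per-frame AU series, trims the 1-s buffers of
instructed snippets, marks occluded snippets invalid and applies the two
block-level exclusion rules (spontaneous: more than half missing wipes the
embodiment; instructed: five or fewer valid snippets wipes it).  Writes
``scratch/cohort/snippets_valid.csv`` and the per-phase exclusion summary
to ``results/exclusions.json``.
"""

import json
from pathlib import Path

from facemimic.preprocess import exclusion_summary, preprocess_records, read_au_series, write_validity

ROOT = Path(__file__).resolve().parent.parent


def main():
    indir = ROOT / "scratch" / "cohort"
    records = read_au_series(indir / "au_series.csv")
    preprocess_records(records)
    write_validity(records, indir)
    summary = exclusion_summary(records)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "exclusions.json").write_text(json.dumps(summary, indent=1))
    for phase, s in summary.items():
        print(f"{phase}: excluded {s['n_excluded']}/{s['n_snippets']} "
              f"snippets ({100 * s['fraction_excluded']:.1f}%)")


if __name__ == "__main__":
    main()
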