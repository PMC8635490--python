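#!/usr/bin/env python
"""Simulate the synthetic study cohort.

Generates the default design — 45 participants in 3 humanlikeness groups,
4 embodiments, 2 phases, 12 snippets (2 x 6 emotions) per embodiment per
phase at 30 fps — and writes the raw study files (per-frame AU series,
agent stimuli, questionnaire, manifest, ground truth) under
``scratch/cohort/``.  Raw files are large; every later stage reads them
from there and writes only compact tables under ``results/``.

Run from the repository root: ``python analysis/01_simulate.py [--seed 1]``.
"""

import argparse
import json
from pathlib import Path

from facemimic import CohortConfig, QuestionnaireModel, ResponseParams, generate_cohort
from facemimic.cohort import write_cohort

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "cohort")
    args = ap.parse_args()

    cohort = generate_cohort(CohortConfig(), ResponseParams(),
                             QuestionnaireModel(), seed=args.seed)
    write_cohort(cohort, args.out)

    n_spont = sum(r.phase == "spontaneous" for r in cohort.records)
    n_instr = len(cohort.records) - n_spont
    n_occl = sum(r.occluded for r in cohort.records)
    print(f"cohort seed {args.seed}: {len(cohort.records)} snippets "
          f"({n_spont} spontaneous, {n_instr} instructed), "
          f"{n_occl} occluded; files under {args.out}")
    (args.out / "run_info.json").write_text(json.dumps({"seed": args.seed}))


if __name__ == "__main__":
    main()
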