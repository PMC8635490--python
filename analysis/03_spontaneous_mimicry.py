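#!/usr/bin/env python
"""Detect spontaneous mimicry and compute per-embodiment rates.

For every valid spontaneous snippet, checks whether the target emotion's
AU pattern was active for at least 3 consecutive frames (100 ms) inside
the rapid (0-1000 ms) and controlled (1000-5000 ms) reaction windows, then
divides mimicked trials by valid snippets per participant x embodiment.
Writes ``results/mimicry_rates.csv`` and prints the embodiment means.
"""

from pathlib import Path

from facemimic.cli import _load_records_with_validity
from facemimic.spontaneous import mimicry_rates

ROOT = Path(__file__).resolve().parent.parent


def main():
    records = _load_records_with_validity(ROOT / "scratch" / "cohort", buffer=0)
    rates = mimicry_rates(records)
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    rates.to_csv(out / "mimicry_rates.csv", index=False)
    print(f"{len(rates)} participant x embodiment x window rates")
    means = rates.groupby(["window", "embodiment"])["rate"].mean()
    print((100 * means).round(1).to_string())


if __name__ == "__main__":
    main()
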