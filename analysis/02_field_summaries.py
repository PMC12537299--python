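"""Annual roll-up tables for the synthetic survey: captures, recapture
rates, CPUE, and prosomal-width distributions per subregion-year.

Reads results/data/ written by 01_simulate_surveys.py (regenerate it first
if missing) and writes results/annual_summary.csv and
results/size_summary.csv.
"""

import pathlib
import subprocess
import sys

from straitpop import read_capture_events, read_effort_records, size_summary, summarize


def main(out_root="results"):
    root = pathlib.Path(out_root)
    if not (root / "data" / "events.csv").exists():
        subprocess.run([sys.executable, "analysis/01_simulate_surveys.py", out_root], check=True)
    events = read_capture_events(root / "data" / "events.csv")
    efforts = read_effort_records(root / "data" / "efforts.csv")

    annual = summarize(events, efforts)
    annual.to_csv(root / "annual_summary.csv", index=False)
    print("Annual roll-up (captures, recapture rate, CPUE):\n")
    print(annual.to_string(index=False))

    sizes = size_summary(events)
    sizes.to_csv(root / "size_summary.csv", index=False)
    print("\nProsomal width (cm) five-number summaries:\n")
    print(sizes.to_string(index=False))


if __name__ == "__main__":
    main(*sys.argv[1:])
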