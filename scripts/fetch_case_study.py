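"""OPTIONAL: fetch the archived NYC yellow-cab tipping data and reproduce
the tip-suggestion threshold analysis.

This script needs network access and ~1 GB of scratch space; nothing in the
package or its test suite depends on it.  The archive is the AEA deposit for
the default-tip study (AEJ: Applied 2013-0098):

    https://www.aeaweb.org/aej/app/data/0603/2013-0098_data.zip

Sample construction, mirroring the original study's restrictions: rides from
the single card vendor, January 2009, no tolls/taxes/surcharges, weekdays
6am-4pm or weekends 6am-8pm, fares in $5-$25.  The running variable is the
fare, the outcome is the tip as a percentage of the fare, and the policy
threshold is the $15 switch from dollar to percentage default suggestions.

With the full sample the expected headline results are: IK bandwidth near
4.5, a tip-percentage jump of roughly 2.1 points at $15, an optimal
threshold near $11.1, and a conservative (alpha=0.05) threshold near $11.7.

Usage:
    python scripts/fetch_case_study.py --workdir scratch/taxi --out taxi_report.json
"""

from __future__ import annotations

import argparse
import json
import sys
import urllib.request
import zipfile
from pathlib import Path

import pandas as pd

import rdthresh as rt

URL = "https://www.aeaweb.org/aej/app/data/0603/2013-0098_data.zip"
THRESHOLD = 15.0


def download(workdir: Path) -> Path:
    workdir.mkdir(parents=True, exist_ok=True)
    target = workdir / "2013-0098_data.zip"
    if not target.exists():
        print(f"downloading {URL} ...", file=sys.stderr)
        urllib.request.urlretrieve(URL, target)
    return target


def build_sample(archive: Path, workdir: Path) -> Path:
    """Extract and filter the ride-level data into a two-column CSV.

    The archive layout is the depositor's; adjust the member name and column
    mapping here if the deposit is reorganized.
    """
    out = workdir / "taxi_jan2009.csv"
    if out.exists():
        return out
    with zipfile.ZipFile(archive) as zf:
        members = [m for m in zf.namelist() if m.lower().endswith((".csv", ".dta"))]
        print("archive members:", members, file=sys.stderr)
        raise SystemExit(
            "inspect the archive members above, then adapt build_sample() to "
            "the ride-level file and its column names before re-running"
        )
    return out


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--workdir", type=Path, default=Path("scratch/taxi"))
    parser.add_argument("--out", type=Path, default=Path("scratch/taxi_report.json"))
    args = parser.parse_args()
    archive = download(args.workdir)
    sample = build_sample(archive, args.workdir)
    data, report = rt.read_dataset(sample, c=THRESHOLD)
    print(f"loaded: {report}", file=sys.stderr)
    rep = rt.analyze(
        data,
        rt.AnalysisConfig(outcome_is_pct_of_x=True),
    )
    rep = {k: v for k, v in rep.items() if not k.startswith("_")}
    args.out.write_text(json.dumps(rep, indent=2, sort_keys=True) + "\n")
    print(json.dumps({
        "bandwidth": rep["bandwidth"],
        "late": rep["late"],
        "c_star": rep["policy"]["c_star"],
        "c_alpha": rep["policy"]["c_alpha"],
        "gains": rep["policy"].get("gains"),
    }, indent=2))


if __name__ == "__main__":
    main()
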