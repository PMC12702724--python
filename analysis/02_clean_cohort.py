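#!/usr/bin/env python
"""Apply the breath-removal rules to the simulated cohort.

Rules run per participant: work-rate ramp filter, absolute physiological
bounds (strict inequalities), 15-breath moving-window 3-sigma outlier
removal, then the 30-s-gap participant exclusion. Writes
results/cleaned/ and results/cleaning_reports.json and prints the removal
accounting.
"""

import argparse
import json
from pathlib import Path

from cpet_entropy import clean
from cpet_entropy.data_model import read_manifest, write_manifest

parser = argparse.ArgumentParser()
parser.add_argument("--cohort", type=Path, default=Path("results/cohort"))
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

cohort = read_manifest(args.cohort / "manifest.csv")
reports = {}
survivors = []
for s in cohort:
    rep = clean(s)
    reports[s.meta.participant_id] = rep
    if not rep.excluded:
        survivors.append(rep.surviving)

write_manifest(survivors, args.out / "cleaned")
(args.out / "cleaning_reports.json").write_text(
    json.dumps({pid: r.to_dict() for pid, r in reports.items()}, indent=1)
)

by_rule: dict[str, int] = {}
for rep in reports.values():
    for key, n in rep.removed_by_rule.items():
        rule = key.split("/")[0]
        by_rule[rule] = by_rule.get(rule, 0) + n
excluded = [pid for pid, r in reports.items() if r.excluded]
print(f"cleaned {len(cohort)} participants; {len(excluded)} excluded by the 30-s gap rule")
for rule, n in sorted(by_rule.items()):
    print(f"  {rule}: {n} observations removed")
for pid in excluded:
    print(f"  excluded: {pid} ({reports[pid].exclusion_reason})")
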