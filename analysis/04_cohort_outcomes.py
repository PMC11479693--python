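#!/usr/bin/env python
"""Pooled clinical rates and exact ICSI vs ICSI-AOA comparisons.

Recomputes fertilization, blastocyst, positive-hCG and live-birth rates
from the per-patient cycle table, runs two-sided Fisher exact tests between
arms, and checks every patient's study eligibility.  Writes
results/cohort_outcomes.tsv and results/arm_comparisons.json.
"""

import json
from pathlib import Path

import pandas as pd

from ffworkup import datasets, outcomes

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cycles = datasets.fixtures()["cycles"]
    report = outcomes.compare_arms(cycles)
    rows = []
    for kind, entry in report.items():
        for arm_key in ("icsi", "icsi_aoa"):
            s = entry[arm_key]
            if s is None:
                continue
            rows.append({"rate": kind, "arm": arm_key.upper(),
                         "numerator": s.numerator, "denominator": s.denominator,
                         "percent": s.percent})
    frame = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "cohort_outcomes.tsv", sep="\t", index=False)
    payload = {
        kind: {"p_value": entry["p_value"], "significant": entry["significant"]}
        for kind, entry in report.items()
    }
    (OUT / "arm_comparisons.json").write_text(json.dumps(payload, indent=1))

    print(frame.to_string(index=False))
    for kind, entry in report.items():
        if entry["p_value"] is None:
            print(f"{kind}: not comparable (one arm lacks the denominator)")
        else:
            print(f"{kind}: Fisher p = {entry['p_value']:.2e}"
                  f" ({'significant' if entry['significant'] else 'ns'})")

    eligible = sorted(
        {c.patient_id for c in cycles}
        - {pid for pid in {c.patient_id for c in cycles}
           if not outcomes.eligibility([c for c in cycles if c.patient_id == pid])}
    )
    print(f"{len(eligible)}/19 patients meet the inclusion rule "
          "(>=1 ICSI cycle, >=4 MII, fertilization <= 1/3).")


if __name__ == "__main__":
    main()
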