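#!/usr/bin/env python
"""Test-retest reproducibility and reliability of the reference methods.

Per region and method: mean DVR per session, percent bias, VAR (SD of
per-subject biases), and the two-session one-way ICC — the per-region
reliability table — plus the pooled per-method summary under both
aggregations (mean of regional statistics, and statistics of the pooled
region-by-subject data).
"""

import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
PIPELINE = ROOT / "scratch" / "pipeline"
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    for method in ("lref", "srtm"):
        report = pd.read_csv(PIPELINE / f"test_retest_{method}.tsv", sep="\t")
        report.to_csv(RESULTS / f"test_retest_{method}.tsv", sep="\t",
                      index=False)
        print(f"\n{method.upper()} per-region test-retest "
              f"(reference: cerebellum white matter):")
        print(report.round(3).to_string(index=False))
    pooled = json.loads((PIPELINE / "test_retest_summary.json").read_text())
    (RESULTS / "test_retest_summary.json").write_text(
        json.dumps(pooled, indent=1)
    )
    for method, stats in pooled.items():
        print(f"\n{method.upper()} pooled: "
              f"ICC(regional mean) = {stats['icc_regional_mean']:.3f}, "
              f"bias = {stats['bias_pct_regional_mean']:+.2f}%, "
              f"VAR = {stats['var_pct_regional_mean']:.2f}%")


if __name__ == "__main__":
    main()
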