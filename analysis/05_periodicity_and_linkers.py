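#!/usr/bin/env python
"""Nucleosome-repeat periodicity and linker preference of methylation.

Estimates the repeat length from the autocorrelation of the detrended
aggregate track over a uniformly occupied domain with dyads every 165 bp,
runs the no-dyad white-noise control, and measures the linker/core
methylation-rate ratio with a read-bootstrap confidence interval.

Finding: the repeat length is recovered at 165 bp and the no-dyad control
shows no peak above the permutation band; linker adenines are methylated
about (linker/core accessibility) times more often than core adenines.
"""

import sys
from pathlib import Path

import pandas as pd

REPO = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(REPO / "src"))

from sirspread import evaluation as ev  # noqa: E402
from sirspread import scenarios as sc  # noqa: E402
from sirspread.inference import linker_enrichment  # noqa: E402
from sirspread.perread import binarize_calls  # noqa: E402

results = REPO / "results"
results.mkdir(exist_ok=True)

per = ev.periodicity_recovery(seed=2024)
s = sc.periodicity_scenario(seed=2024)
calls = binarize_calls(s.simulate().subset(sc.SIM))
link = linker_enrichment(calls, s.annotation.nucleosome_dyads[sc.SIM], seed=2024)

row = {
    **per,
    "linker_core_ratio": link.ratio,
    "linker_core_ci_low": link.ci_low,
    "linker_core_ci_high": link.ci_high,
    "linker_rate": link.linker_rate,
    "core_rate": link.core_rate,
}
pd.DataFrame([row]).to_csv(results / "05_periodicity_linkers.tsv", sep="\t", index=False)
print(
    f"repeat length {per['estimated_repeat_bp']} bp (true {per['true_repeat_bp']}); "
    f"control significant: {per['control_significant']}; "
    f"linker/core ratio {link.ratio:.2f} [{link.ci_low:.2f}, {link.ci_high:.2f}]"
)
print(f"table: {results}/05_periodicity_linkers.tsv")
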