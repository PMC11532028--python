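"""Simulate the three study cohorts used throughout the analysis.

Generates exposure (micronutrient-scale GWAS, n = 64,979), mediator
(metabolite-scale GWAS, n = 8,299) and outcome (case-control-scale GWAS,
n = 184,683) summary statistics under the default causal model
(theta_xm = 0.5, theta_my = -0.1, theta_direct = -0.25, mediated
proportion 1/6) and writes them with the ground truth to results/sim/.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from mrmediate.simulate import SimulationConfig, simulate_sumstats
from mrmediate.sumstats import write_sumstats

OUT = Path(__file__).resolve().parents[1] / "results" / "sim"
SEED = 17


def main():
    cfg = SimulationConfig(seed=SEED)
    exposure, mediator, outcome, truth = simulate_sumstats(cfg)
    OUT.mkdir(parents=True, exist_ok=True)
    for name, ss in (("exposure", exposure), ("mediator", mediator),
                     ("outcome", outcome)):
        write_sumstats(ss, OUT / f"{name}.tsv")
        print(f"{name}: {len(ss)} SNPs (n = {ss.records['n'].iloc[0]:.0f})")
    truth_d = {r["quantity"]: r["value"] for _, r in
               truth.summary().iterrows()}
    with open(OUT / "truth.json", "w") as fh:
        json.dump(truth_d, fh, indent=1)
    print("ground truth:", {k: round(v, 4) for k, v in truth_d.items()})


if __name__ == "__main__":
    main()
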