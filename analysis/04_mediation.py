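"""Two-step mediation on the simulated trio from 01_simulate_cohorts.

Reads the cohorts back from results/sim/ (run 01 first; regenerates them
if absent), estimates beta1 (exposure -> mediator), beta2 (mediator ->
outcome on overlap-excluded instruments), the total effect, and the
product-of-coefficients mediated effect with delta-method CI.  Writes
results/mediation.json and prints the decomposition against the truth.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from mrmediate.mediation import run_mediation
from mrmediate.simulate import SimulationConfig, simulate_sumstats
from mrmediate.sumstats import TraitMeta, read_sumstats

BASE = Path(__file__).resolve().parents[1] / "results"
SEED = 17


def load_cohorts():
    sim = BASE / "sim"
    if (sim / "truth.json").exists():
        exp = read_sumstats(sim / "exposure.tsv",
                            TraitMeta("sim-exposure"), sep="\t")
        med = read_sumstats(sim / "mediator.tsv",
                            TraitMeta("sim-mediator"), sep="\t")
        out = read_sumstats(sim / "outcome.tsv",
                            TraitMeta("sim-outcome", trait_type="binary"),
                            sep="\t")
        truth = json.load(open(sim / "truth.json"))
        return exp, med, out, truth
    exp, med, out, t = simulate_sumstats(SimulationConfig(seed=SEED))
    return exp, med, out, {r["quantity"]: r["value"]
                           for _, r in t.summary().iterrows()}


def main():
    exposure, mediator, outcome, truth = load_cohorts()
    res = run_mediation(exposure, mediator, outcome, seed=SEED)
    BASE.mkdir(parents=True, exist_ok=True)
    with open(BASE / "mediation.json", "w") as fh:
        json.dump(res.to_dict(), fh, indent=1)

    print(f"beta1 (exposure->mediator): {res.beta1:.3f} (se {res.se1:.3f}, "
          f"{res.nsnp_step1} SNPs)   [truth {truth['beta1_true']:.3f}]")
    print(f"beta2 (mediator->outcome): {res.beta2:.3f} (se {res.se2:.3f}, "
          f"{res.nsnp_step2} SNPs, {res.n_excluded_snps} excluded for "
          f"exposure overlap)   [truth {truth['beta2_true']:.3f}]")
    print(f"total effect: {res.beta_total:.3f} (se {res.se_total:.3f})   "
          f"[truth {truth['total_true']:.3f}]")
    print(f"mediated effect (beta1*beta2): {res.indirect:.4f} "
          f"({res.indirect_ci_low:.4f}, {res.indirect_ci_high:.4f})   "
          f"[truth {truth['indirect_true']:.4f}]")
    print(f"mediated proportion: {100 * res.proportion:.1f}% "
          f"({100 * res.proportion_ci_low:.2f}%, "
          f"{100 * res.proportion_ci_high:.2f}%)   "
          f"[truth {100 * truth['proportion_true']:.1f}%]")
    for step, rep in res.reports.items():
        print(f"  {step}: Q {rep.q_stat:.3f} (p {rep.q_pval:.3f}), "
              f"egger intercept p "
              f"{rep.egger_intercept_p if rep.egger_intercept_p is None else round(rep.egger_intercept_p, 3)}, "
              f"PRESSO p {rep.presso_global_p}")


if __name__ == "__main__":
    main()
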