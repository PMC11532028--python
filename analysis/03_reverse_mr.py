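"""Reverse-direction MR: does the disease causally shift the exposure?

Gives the disease its own instrument panel (no path back to the nutrient)
and runs the screen machinery with the roles swapped.  Expectation: no
significant reverse effect, supporting a unidirectional interpretation of
the forward result.  Writes results/screen_reverse.tsv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from mrmediate.screen import ScreenConfig, render_report, reverse_mr
from mrmediate.simulate import SimulationConfig, simulate_sumstats

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 23


def main():
    # the generator's "exposure" table plays the disease here: it owns the
    # instruments, and the "outcome" table is the unaffected nutrient
    disease, _, nutrient, _ = simulate_sumstats(SimulationConfig(
        m=12, m_med=0, theta_xm=0.0, theta_my=0.0, theta_direct=0.0,
        n_x=184_683, n_y=64_979, seed=SEED))
    row = reverse_mr(disease, nutrient, ScreenConfig(seed=SEED))
    OUT.mkdir(parents=True, exist_ok=True)
    render_report([row], OUT / "screen_reverse.tsv")
    est = row.estimates.get("ivw")
    if est is None:
        print(f"reverse MR: {row.status}")
    else:
        print(f"reverse IVW: OR {est.or_:.3f} "
              f"({est.or_low:.3f}-{est.or_high:.3f}), p {est.pval:.3f} "
              f"-> {'significant' if est.pval < 0.05 else 'null, as expected'}")


if __name__ == "__main__":
    main()
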