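"""Informative-hypothesis Bayes factors for the arm difference over time.

Loads the stored full-model chains (from 03_fit_growth_model.py), computes
predicted arm trajectories at reference covariates, and evaluates per outcome
and wave the directional hypothesis that the intervention arm does better
(fewer concentration/disruptive problems, more prosocial behaviour) against
its complement, with encompassing-prior Bayes factors and posterior model
probabilities. Writes results/bf.csv and the trajectory figure.
"""

import sys
from pathlib import Path

from mvgrowth.model import load_samples
from mvgrowth.posterior import bf_report, trajectory_figure

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    if not (RESULTS / "samples.csv").exists():
        sys.exit("results/samples.csv not found - run 03_fit_growth_model.py first")
    samples = load_samples(RESULTS / "samples.csv", RESULTS / "samples.json")
    table = bf_report(samples)
    table.to_csv(RESULTS / "bf.csv", index=False)
    show = table.copy()
    for col in ("control", "gbg", "difference", "BF1", "BF2", "BF12", "PMP1", "PMP2"):
        show[col] = show[col].round(3)
    print(show.drop(columns="clamped").to_string(index=False))
    trajectory_figure(samples, path=str(RESULTS / "trajectories.png"))
    print(f"\nwrote bf.csv and trajectories.png under {RESULTS}")


if __name__ == "__main__":
    main()
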