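"""Sensitivity of MIMLwel to the width scale μ and cluster fraction α.

Evaluates the 5 × 5 grid μ ∈ {0.2,…,1.0} × α ∈ {0.02,…,0.1} at weak-label
ratio 0.8 and reports the best cell per metric. The published choice is
μ = 1.0, α = 0.1 (the grid's corner); the expectation is that performance
improves toward larger μ and α within these ranges. Single-repetition
5-fold CV keeps the 25-cell grid around a minute.

Usage: python analysis/04_param_grid.py [--seed 0] (after 01_simulate.py)
"""

import argparse
import json
from pathlib import Path

from weakmiml.datamodel import load_dataset
from weakmiml.evaluation import param_grid

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    dataset = load_dataset(RESULTS / "synthetic_dataset.json")
    out = param_grid(dataset, wlr=0.8, folds=5, reps=1, seed=args.seed)

    doc = {
        "grid": {
            f"mu={mu:g},alpha={a:g}": res.mean
            for (mu, a), res in out["grid"].items()
        },
        "argmax": {m: {"mu": pt[0], "alpha": pt[1]}
                   for m, pt in out["argmax"].items()},
    }
    (RESULTS / "param_grid.json").write_text(json.dumps(doc, indent=2))

    print("micro-F1 over the mu x alpha grid (rows mu, cols alpha):")
    alphas = sorted({a for _, a in out["grid"]})
    mus = sorted({mu for mu, _ in out["grid"]})
    print("        " + "".join(f"{a:>8g}" for a in alphas))
    for mu in mus:
        cells = "".join(
            f"{out['grid'][(mu, a)].mean['micro_f1']:>8.3f}" for a in alphas
        )
        print(f"mu={mu:<4g}{cells}")
    for metric, pt in out["argmax"].items():
        print(f"best {metric}: mu={pt[0]:g}, alpha={pt[1]:g}")
    print("full grid in results/param_grid.json")


if __name__ == "__main__":
    main()
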