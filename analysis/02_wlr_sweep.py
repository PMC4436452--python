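"""Weak-label-ratio sweep of MIMLwel on the synthetic dataset.

For each ratio in {0.2, 0.4, 0.6, 0.8} the training folds of a repeated
10-fold cross-validation keep only that fraction of true positives per
label; held-out bags are always scored against their full annotation. The
expected picture, mirroring the motivating study's trend, is monotone:
more retained supervision, better Hamming loss / macro-F1 / micro-F1.

Three repetitions (rather than ten) keep the desk runtime around a minute;
the protocol is otherwise the published one.

Usage: python analysis/02_wlr_sweep.py [--seed 0] (after 01_simulate.py)
"""

import argparse
import json
from pathlib import Path

from weakmiml.datamodel import load_dataset
from weakmiml.evaluation import wlr_sweep

RESULTS = Path(__file__).resolve().parent.parent / "results"
RATIOS = (0.2, 0.4, 0.6, 0.8)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--reps", type=int, default=3)
    args = ap.parse_args()

    dataset = load_dataset(RESULTS / "synthetic_dataset.json")
    results = wlr_sweep(
        dataset, {"method": "mimlwel"}, ratios=RATIOS,
        folds=10, reps=args.reps, seed=args.seed,
    )

    table = {}
    print(f"MIMLwel, 10-fold CV x {args.reps} reps (mean ± std per fold-cell)")
    print(f"{'W.L.R.':>7} {'HL↓':>16} {'maF1↑':>16} {'miF1↑':>16}")
    for ratio, res in zip(RATIOS, results):
        row = {
            m: {"mean": res.mean[m], "std": res.std[m]}
            for m in ("hamming_loss", "macro_f1", "micro_f1")
        }
        table[f"{ratio:g}"] = row
        print(
            f"{ratio:>6.0%} "
            f"{row['hamming_loss']['mean']:.3f} ± {row['hamming_loss']['std']:.3f}  "
            f"{row['macro_f1']['mean']:.3f} ± {row['macro_f1']['std']:.3f}  "
            f"{row['micro_f1']['mean']:.3f} ± {row['micro_f1']['std']:.3f}"
        )
    (RESULTS / "wlr_sweep.json").write_text(json.dumps(table, indent=2))

    mif1 = [table[f"{r:g}"]["micro_f1"]["mean"] for r in RATIOS]
    trend = "monotone increase" if all(
        a <= b + 1e-9 for a, b in zip(mif1, mif1[1:])
    ) else "NOT monotone"
    print(f"micro-F1 across ratios: {trend}; table in results/wlr_sweep.json")


if __name__ == "__main__":
    main()
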