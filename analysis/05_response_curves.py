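#!/usr/bin/env python
"""Stage 5 — response-curve and importance figures.

Plots the per-variable response curves (ensemble mean with 95% band) and
the importance ranking from stage 4.  Writes PNGs under
results/run/figures/ and prints where each habitat response peaks.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

OUT = Path(__file__).resolve().parent.parent / "results" / "run"
FIG = OUT / "figures"


def main() -> None:
    FIG.mkdir(parents=True, exist_ok=True)
    curves = pd.read_csv(OUT / "response_curves.csv")
    imp = pd.read_csv(OUT / "importance.csv")

    variables = list(curves["variable"].unique())
    ncol = 3
    nrow = (len(variables) + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3 * nrow), squeeze=False)
    for ax, var in zip(axes.ravel(), variables):
        sub = curves[curves["variable"] == var]
        ax.fill_between(sub["value"], sub["lo95"], sub["hi95"], alpha=0.3)
        ax.plot(sub["value"], sub["mean"])
        ax.set_title(var, fontsize=9)
        ax.set_ylabel("p(occurrence)")
        peak = sub["value"].iloc[sub["mean"].to_numpy().argmax()]
        print(f"{var:<18} response peaks at {peak:.1f}")
    for ax in axes.ravel()[len(variables):]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(FIG / "response_curves.png", dpi=120)

    fig2, ax2 = plt.subplots(figsize=(5, 3))
    ax2.barh(imp["variable"], imp["mean"], xerr=imp["sd"])
    ax2.invert_yaxis()
    ax2.set_xlabel("normalized importance (AUC drop)")
    fig2.tight_layout()
    fig2.savefig(FIG / "importance.png", dpi=120)
    print(f"wrote figures under {FIG}")


if __name__ == "__main__":
    main()
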