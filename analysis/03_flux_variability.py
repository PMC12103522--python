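"""Flux variability with and without the expression layer.

Runs FVA for both models at their own growth optima and compares per-reaction
ranges on the shared (metabolic) reactions.  Expression costs resolve the
isozyme degeneracy that leaves the metabolism-only analog free to split flux
arbitrarily, so the expression-coupled ranges collapse.
"""

import argparse
from pathlib import Path

import pandas as pd

from meomics.me_core import flux_variability, maximize_growth
from meomics.synthetic_data import MinicellParams, make_minicell


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", default="results/03_fva")
    args = ap.parse_args()
    out = Path(args.outdir)
    out.mkdir(parents=True, exist_ok=True)

    me, m_analog = make_minicell(MinicellParams(seed=args.seed))
    sol_me = maximize_growth(me, bisect_tol=1e-9)
    sol_m = maximize_growth(m_analog, bisect_tol=1e-9)
    fva_me = flux_variability(me, sol_me.mu_star)
    fva_m = flux_variability(m_analog, sol_m.mu_star)

    shared = fva_m.table.index
    paired = pd.DataFrame(
        {
            "range_me": fva_me.table.loc[shared, "range"],
            "range_m": fva_m.table.loc[shared, "range"],
        }
    )
    paired["reduction"] = paired["range_m"] - paired["range_me"]
    paired.to_csv(out / "fva_comparison.tsv", sep="\t")
    fva_me.table.to_csv(out / "fva_me_full.tsv", sep="\t")

    n_reduced = int((paired["reduction"] > 1e-6).sum())
    print(
        f"FVA at mu*_me={sol_me.mu_star:.4f}, mu*_m={sol_m.mu_star:.4f}: "
        f"{n_reduced}/{len(paired)} shared reactions have strictly smaller "
        "ranges under expression coupling"
    )
    print(
        "largest degeneracy resolved: "
        + paired["reduction"].idxmax()
        + f" ({paired['reduction'].max():.3f} mmol/gDW/h)"
    )


if __name__ == "__main__":
    main()
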