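"""Search-term robustness grid over the synthetic term sets.

Refits the SVAR for every combination of one term per construct
(5 x 5 x 5 = 125 submodels), tabulates the contemporaneous coefficients,
and summarises sign stability per relationship.  Writes results/grid.csv
and results/grid_summary.csv.
"""
import argparse
from pathlib import Path

from trendsvar import RunConfig, run_grid, summarize_grid
from trendsvar.cli import _load_term_sets
from trendsvar.report import write_grid_csv


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=str, default="results/data")
    ap.add_argument("--out-dir", type=str, default="results")
    args = ap.parse_args()

    sets = _load_term_sets(Path(args.data_dir), RunConfig())
    grid = run_grid(sets)
    summary = summarize_grid(grid)
    print(f"{grid.n_combos} submodels, {grid.betas.size} coefficients")
    print(summary.to_string(index=False))

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_grid_csv(grid, out / "grid.csv")
    summary.to_csv(out / "grid_summary.csv", index=False)
    print(f"wrote {out / 'grid.csv'} and {out / 'grid_summary.csv'}")


if __name__ == "__main__":
    main()
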