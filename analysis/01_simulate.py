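"""Generate the synthetic study dataset.

Simulates the three-construct search-interest system (VA, GC, GP) at the
reference point estimates over 168 months from 2004-01, injects the five
attack-month spikes, derives five search terms per construct, and writes
one Trends-dialect CSV per construct under results/data/.
"""
import argparse
from pathlib import Path

from trendsvar import simulate_term_sets, worked_example, write_trends_csv


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out-dir", type=str, default="results/data")
    args = ap.parse_args()

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sets = simulate_term_sets(
        worked_example.params(), terms_per_construct=5, n_months=168, seed=args.seed
    )
    for label, terms in sets.items():
        write_trends_csv(terms, out / f"{label}.csv")
        print(f"{label}: {len(terms)} terms x {len(terms[0].values)} months -> {out / (label + '.csv')}")
    print(f"done; ground truth is the reference parameter set (beta21={worked_example.BETA_TRIPLE[0]}, "
          f"beta31={worked_example.BETA_TRIPLE[1]}, beta32={worked_example.BETA_TRIPLE[2]})")


if __name__ == "__main__":
    main()
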