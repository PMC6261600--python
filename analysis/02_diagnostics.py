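"""Pre-fit diagnostics on the synthetic panel.

Builds the composite log-scale panel from results/data/, runs the ADF
stationarity test per construct (constant + trend) and the AIC lag-order
scan, and writes results/diagnostics.json.
"""
import argparse
import json
from pathlib import Path

from trendsvar import RunConfig, select_lag
from trendsvar.cli import _load_panel


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data-dir", type=str, default="results/data")
    ap.add_argument("--out-dir", type=str, default="results")
    ap.add_argument("--p-max", type=int, default=4)
    args = ap.parse_args()

    panel = _load_panel(Path(args.data_dir), RunConfig())
    rep = select_lag(panel, p_max=args.p_max)
    for label, (stat, p) in rep.adf.items():
        verdict = "stationary" if p <= 0.05 else "unit root not rejected"
        print(f"ADF {label}: stat={stat:.2f} p={p:.4f} ({verdict})")
    print(f"AIC by lag: " + ", ".join(f"{p}:{a:.3f}" for p, a in rep.aic_by_lag.items()))
    print(f"chosen lag: {rep.chosen_lag} (fitted dynamics stable: {rep.stable})")

    out = Path(args.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = {
        "adf": {k: {"statistic": v[0], "p_value": v[1]} for k, v in rep.adf.items()},
        "aic_by_lag": rep.aic_by_lag,
        "chosen_lag": rep.chosen_lag,
        "stable": rep.stable,
    }
    (out / "diagnostics.json").write_text(json.dumps(payload, indent=2))


if __name__ == "__main__":
    main()
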