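#!/usr/bin/env python
"""Stage 4: the full G range - slow-power amplification and spectral shape.

Sweeps G from zero connectivity to 0.99 (N = 100 units, full-network sum),
recording the summed-activity PSD, the low-band power curve, the fitted
low-frequency power-law exponent, and the Lorentzian knee of the isolated
(zero-connectivity) case.  Writes ``gain_sweep_spectra.csv`` and
``gain_sweep_summary.csv``.
"""

import argparse
from pathlib import Path

import pandas as pd

from critnet import spectral as sp
from critnet.experiments import gain_sweep


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--duration", type=float, default=800.0)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    res = gain_sweep(g_values=(0.0, 0.5, 0.8, 0.9, 0.95, 0.99),
                     duration=args.duration, seed=args.seed)
    long = []
    rows = []
    for G, est in res["spectra"].items():
        for f, p in zip(est.freqs, est.power):
            long.append((G, f, p))
        fit = sp.fit_powerlaw(est, 0.1, 10.0)
        rows.append(dict(G=G, exponent_0p1_10=fit.exponent,
                         low_band_power=res["low_band_power"][G],
                         high_band_rel_to_zero=res["high_band_rel"][G]))
    pd.DataFrame(long, columns=["G", "freq_hz", "power"]).to_csv(
        args.out / "gain_sweep_spectra.csv", index=False)
    tab = pd.DataFrame(rows)
    knee = sp.fit_lorentzian(res["spectra"][0.0], refine=True)
    tab.to_csv(args.out / "gain_sweep_summary.csv", index=False)
    print(tab.round(3).to_string(index=False))
    print(f"\nzero-connectivity Lorentzian knee: {knee.knee_freq:.2f} Hz "
          f"(1/(2 pi tau) = {sp.knee_from_tau(0.02):.2f} Hz)")
    print("-> slow-band power rises by orders of magnitude as G -> 1 while the "
          "near-critical low-frequency slope approaches the scale-free -2.")


if __name__ == "__main__":
    main()
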