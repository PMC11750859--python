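#!/usr/bin/env python
"""K+-channel inactivation and use-dependent spike broadening.

Compares the inactivating, non-inactivating and 90/10-mixture K+-channel
variants under 50 Hz trains: first/last half-durations at the soma and the
10th bouton (use-dependent broadening) and whether an afterdischarge
follows.  The core mechanistic contrast: with cumulative K+-channel
inactivation spikes broaden across the train; without it they do not, and
no afterdischarge is triggered even by longer/stronger stimulation.

Writes results/04_variant_broadening.csv.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

from mossyfiber.analysis import (
    afterdischarge_summary,
    annotate_half_durations,
    detect_spikes,
)
from mossyfiber.channels import load_profile
from mossyfiber.morphology import build_mossy_fiber
from mossyfiber.protocols import preset
from mossyfiber.solver import run

RESULTS = Path(__file__).resolve().parents[1] / "results"
PANELS = ["fig3a", "fig3c", "fig3e", "fig3g", "fig3i"]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--kinetics", default="generic")
    args = ap.parse_args()

    profile = load_profile(args.kinetics)
    model = build_mossy_fiber()
    rows = []
    for name in PANELS:
        prot = preset(name)
        ts = run(model, prot, profile=profile)
        row = dict(panel=name, variant=prot.variant,
                   mixture_fraction=(prot.mixture_fraction
                                     if prot.variant == "mixture" else None),
                   n_pulses=prot.n_pulses, el_target_mv=prot.el_target_mv)
        for site in ("soma", "bouton_10"):
            evs = detect_spikes(ts.time_ms, ts[site])
            annotate_half_durations(ts.time_ms, ts[site], evs)
            train = [e for e in evs if e.t_peak_ms <= prot.train_end_ms]
            if train:
                row[f"{site}_first_hd_ms"] = train[0].half_duration_ms
                row[f"{site}_last_hd_ms"] = train[-1].half_duration_ms
                row[f"{site}_broadening"] = (train[-1].half_duration_ms
                                             / train[0].half_duration_ms)
        evs_b = detect_spikes(ts.time_ms, ts["bouton_10"])
        summ = afterdischarge_summary(evs_b, prot.train_end_ms,
                                      window_ms=prot.t_post_ms)
        row["afterdischarge"] = summ.present
        row["afterdischarge_freq_hz"] = summ.frequency_hz
        rows.append(row)
        print(f"{name} [{prot.variant}]: soma broadening "
              f"{row.get('soma_broadening', float('nan')):.3f}, "
              f"afterdischarge={summ.present}")

    df = pd.DataFrame(rows)
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "04_variant_broadening.csv"
    df.to_csv(out, index=False)
    print(f"\nwrote {out}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
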