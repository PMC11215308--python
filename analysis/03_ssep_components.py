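#!/usr/bin/env python
"""Average the simulated SSEP epochs per group and animal, extract the
P1/N1 components, and compare peak-to-peak amplitude and latency
between the control and diabetic groups (8 animals per group).

Writes results/03_ssep_summary.csv.
"""

from pathlib import Path

import pandas as pd

from neurovasc import metabolic_stats as ms
from neurovasc import ssep_analysis as ssa
from neurovasc import synthetic_data as sd

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
N_ANIMALS = 8

GROUPS = {
    "control": dict(scale=1.0, latency_ms=8.56),
    "hfd_stz": dict(scale=135.0 / 518.1, latency_ms=8.58),
}


def animal_result(group: str, scale: float, latency_ms: float, seed: int):
    cfg = sd.SSEPSimConfig(seed=seed, p1_amp_uV=340.0 * scale,
                           n1_amp_uV=178.1 * scale,
                           p1_latency_ms=latency_ms,
                           n1_latency_ms=latency_ms + 6.44)
    eps = sd.gen_ssep_epochs(cfg)
    avg = ssa.average_epochs(eps)
    return ssa.extract_components(avg, eps.sampling_rate_hz, eps.stim_onset_index)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for gi, (group, p) in enumerate(GROUPS.items()):
        for a in range(N_ANIMALS):
            res = animal_result(group, p["scale"], p["latency_ms"], 200 + 10 * gi + a)
            rows.append(dict(group=group, animal=a,
                             amplitude_pp_uV=res.amplitude_pp_uV,
                             latency_ms=res.latency_ms))
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "03_ssep_summary.csv", index=False)

    amp = ms.group_summary({g: df[df.group == g].amplitude_pp_uV for g in GROUPS})
    lat = ms.group_summary({g: df[df.group == g].latency_ms for g in GROUPS})
    print(df.groupby("group")[["amplitude_pp_uV", "latency_ms"]].mean().round(2))
    print(f"\nAmplitude: control vs HFD/STZ Welch t = {amp.t_statistic:.1f}, "
          f"p = {amp.p_value:.2e} (diabetic response strongly attenuated)")
    print(f"Latency:   Welch t = {lat.t_statistic:.2f}, p = {lat.p_value:.3f} "
          "(no meaningful conduction delay)")


if __name__ == "__main__":
    main()
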