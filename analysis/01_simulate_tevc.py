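#!/usr/bin/env python
"""Generate the synthetic voltage-clamp study set.

One current family per compound and channel (concentrations 0-20 uM, 1%
recording noise) plus spontaneous calcium-transient records for three
control and three treated monolayers.  Reduced per-sweep summaries go to
results/synthetic/; one full example family is written for inspection.
"""

import pathlib

import numpy as np
import pandas as pd

from cardiopufa import effects, synth

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "synthetic"
RAW = pathlib.Path(__file__).resolve().parents[1] / "scratch" / "synthetic"
CONCS = [0.0, 0.2, 0.7, 2.0, 7.0, 20.0]
NOISE = 0.01
SEED0 = 100


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    RAW.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, compound in enumerate(effects.COMPOUNDS):
        for channel, gen in (("IKs", synth.generate_iks_family),
                             ("INa", synth.generate_nav_family),
                             ("ICaL", synth.generate_cav_family)):
            params = synth.default_params(channel)
            eff = synth.PufaEffectProfile.from_compound(compound, channel)
            fam = gen(params, eff, CONCS, NOISE, seed=SEED0 + i)
            for c in CONCS:
                tr = fam.truth["per_concentration"][c]
                rows.append(dict(compound=compound, channel=channel,
                                 concentration_uM=c,
                                 true_dv05_mV=tr["dv05_mV"],
                                 true_gmax_factor=tr["gmax_factor"]))
    pd.DataFrame(rows).to_csv(OUT / "generating_truth.csv", index=False)

    # full traces are bulky and regenerable: they go to scratch/
    fam = synth.generate_iks_family(
        synth.default_params("IKs"),
        synth.PufaEffectProfile.from_compound("Lin-taurine", "IKs"),
        [0.0, 7.0], NOISE, seed=SEED0, sampling_ms=2.0)
    synth.write_family(fam, RAW, stem="example_IKs_Lin-taurine")

    for k in range(3):
        rec = synth.generate_cat_trace(synth.CaTParams(), seed=200 + k)
        synth.write_cat(rec, RAW / f"cat_control_m{k}.txt")
        rec = synth.generate_cat_trace(
            synth.CaTParams(tau_decay_ms=110.0), seed=300 + k)
        synth.write_cat(rec, RAW / f"cat_treated_m{k}.txt")
    print(f"wrote generating truths for {len(effects.COMPOUNDS)} compounds x 3 "
          f"channels to {OUT}; raw traces to {RAW}")


if __name__ == "__main__":
    main()
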