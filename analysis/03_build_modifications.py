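#!/usr/bin/env python
"""Translate measured 7 uM effects into model-level modification sets.

Writes one YAML per compound and concentration (0.7, 2, 7 uM; the
sub-maximal levels via Hill interpolation), plus the closed-form
single-channel recapitulation table (predicted V0.5 and scale under each
modification) to results/modifications/.
"""

import pathlib

import pandas as pd

from cardiopufa import effects, synth

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "modifications"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for compound in effects.COMPOUNDS:
        for conc in (0.7, 2.0, 7.0):
            ms = effects.modification_set(compound, conc)
            stem = compound.replace(" ", "_") + f"_{conc:g}uM.yaml"
            effects.save_modset(ms, OUT / stem)
            for cid, m in ms.channels.items():
                params = synth.default_params(cid)
                pred = effects.predict_clamp_response(params, m)
                rows.append(dict(
                    compound=compound, concentration_uM=conc, channel=cid,
                    dv05_act_mV=m.dv05_act, dv05_inact_mV=m.dv05_inact,
                    g_factor=m.g_factor,
                    predicted_v05_act_mV=pred["v05_act"],
                    predicted_v05_inact_mV=pred.get("v05_inact")))
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "single_channel_recapitulation.csv", index=False)
    sel = df[(df.concentration_uM == 7.0) & (df.channel == "IKs")]
    print("7 uM IKs modifications (dV05, g):")
    print(sel[["compound", "dv05_act_mV", "g_factor"]].to_string(index=False))


if __name__ == "__main__":
    main()
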