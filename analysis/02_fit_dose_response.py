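#!/usr/bin/env python
"""Fit the synthetic families and compare recovered effects to the
generating truth.

For each compound: IKs tail G-V Boltzmann fits (dV05, Gmax ratio), INa/ICaL
availability fits, and the Hill fit of the 0 mV dose response.  Writes
results/fit_recovery.csv and prints the largest recovery errors.
"""

import pathlib

import numpy as np
import pandas as pd

from cardiopufa import effects, synth, tevc
from cardiopufa.hill import fit_hill

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
CONCS = [0.0, 0.2, 0.7, 2.0, 7.0, 20.0]
NOISE = 0.01


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, compound in enumerate(effects.COMPOUNDS):
        pi = synth.default_params("IKs")
        eff = synth.PufaEffectProfile.from_compound(compound, "IKs")
        fam = synth.generate_iks_family(pi, eff, CONCS, NOISE, seed=100 + i)
        s = tevc.analyze_activation_family(fam)
        for _, r in s.table.iterrows():
            c = r.concentration_uM
            rows.append(dict(compound=compound, channel="IKs",
                             concentration_uM=c,
                             dv05_mV=r.dv05_mV, true_dv05_mV=eff.dv05(c),
                             gmax_ratio=r.gmax_ratio,
                             true_gmax_factor=eff.gmax_factor(c)))
        pn = synth.default_params("INa")
        effn = synth.PufaEffectProfile.from_compound(compound, "INa")
        famn = synth.generate_nav_family(pn, effn, CONCS, NOISE, seed=150 + i)
        sn = tevc.analyze_availability_family(famn)
        for _, r in sn.table.iterrows():
            c = r.concentration_uM
            rows.append(dict(compound=compound, channel="INa",
                             concentration_uM=c,
                             dv05_mV=r.dv05_mV, true_dv05_mV=effn.dv05(c),
                             gmax_ratio=r.gmax_ratio,
                             true_gmax_factor=effn.gmax_factor(c)))
    df = pd.DataFrame(rows)
    df["dv05_err_mV"] = df.dv05_mV - df.true_dv05_mV
    df["gmax_rel_err"] = df.gmax_ratio / df.true_gmax_factor - 1.0
    df.to_csv(OUT / "fit_recovery.csv", index=False)

    km_rows = []
    for compound in effects.COMPOUNDS:
        for channel in effects.CHANNELS:
            h = effects.fixture(compound).hill[channel]
            if h.km_uM is None or h.km_above_range:
                continue
            x = np.array(CONCS[1:])
            y = np.array([effects.hill_ratio_truth(compound, channel, c)
                          for c in x])
            fit = fit_hill(x, y)
            km_rows.append(dict(compound=compound, channel=channel,
                                km_true_uM=h.km_uM, km_fit_uM=fit.km,
                                n_fit=fit.n, adj_r2=fit.adj_r2))
    pd.DataFrame(km_rows).to_csv(OUT / "km_recovery.csv", index=False)

    print("worst |dV05| recovery error (mV):", df.dv05_err_mV.abs().max().round(3))
    print("worst Gmax ratio relative error:", df.gmax_rel_err.abs().max().round(4))
    kdf = pd.DataFrame(km_rows)
    print("worst Km relative error:",
          (kdf.km_fit_uM / kdf.km_true_uM - 1).abs().max().round(4))


if __name__ == "__main__":
    main()
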