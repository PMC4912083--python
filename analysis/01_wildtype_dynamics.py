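#!/usr/bin/env python
"""Wild-type IL-1 responses: the nuclear pp38 pulse, the step-like
cytosolic/membrane pp38, and pMKK activation/deactivation across doses.

Writes trajectories, a feature table and the two dose figures under
results/01_wildtype/.
"""

from pathlib import Path

from il1p38 import SolverSettings, build_default_model, default_parameters, dose_similarity
from il1p38.experiments import run_dose_scan
from il1p38.figures import figure_dose_response, figure_pmkk_dynamics

OUT = Path("results/01_wildtype")
DOSES = [100.0, 10.0, 1.0, 0.1, 0.01, 0.0]


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    base = build_default_model(default_parameters())
    settings = SolverSettings()
    panel = run_dose_scan(base, DOSES, settings)

    for res in panel:
        res.trajectory.to_tidy_frame().to_csv(OUT / f"trajectory_{res.label}.csv",
                                              index=False)
    feats = panel.features_frame()
    feats.to_csv(OUT / "features.csv", index=False)

    figure_dose_response(base, settings, DOSES).savefig(OUT / "dose_response.png", dpi=150)
    figure_pmkk_dynamics(base, settings, DOSES).savefig(OUT / "pmkk_dynamics.png", dpi=150)

    wt = panel["dose_100"]
    f = wt.features["pp38_nuc"]
    print("Wild type, 100 nM IL-1:")
    print(f"  nuclear pp38: {f.response_class}, basal {f.basal_value:.3f} nM, "
          f"peak {f.peak_value:.1f} nM at {f.peak_time:.0f} s, back in the 1% "
          f"basal band at {f.time_to_basal:.0f} s")
    f = wt.features["pp38_cyt"]
    print(f"  cytosolic pp38: {f.response_class}, basal {f.basal_value:.2f} nM, "
          f"peak {f.peak_value:.2f} nM at {f.peak_time:.0f} s")
    f = wt.features["pMKK"]
    print(f"  pMKK: {f.response_class}, basal {f.basal_value:.3f} nM, "
          f"peak {f.peak_value:.1f} nM at {f.peak_time:.0f} s")
    sim = dose_similarity(wt.trajectory, panel["dose_1"].trajectory, "pp38_nuc")
    print(f"  nuclear time courses at 100 vs 1 nM IL-1: similarity {sim:.3f} "
          "(the response is insensitive across this 100-fold dose range)")
    tiny = panel["dose_0.01"].features["pp38_nuc"]
    print(f"  at 0.01 nM the pulse is later and lower: {tiny.peak_value:.1f} nM "
          f"at {tiny.peak_time:.0f} s")
    print(f"wrote trajectories, features.csv and figures to {OUT}/")


if __name__ == "__main__":
    main()
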