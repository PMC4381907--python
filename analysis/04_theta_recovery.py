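#!/usr/bin/env python
"""Identifiability of the two-theta KCNE1 change from GV/FV data.

Fits the theta_IC and theta_AO factors back from GV/FV tables of the
perturbed model with every intrinsic rate held fixed: first from
noiseless simulator tables (exact round trip), then from tables extracted
out of noisy synthetic recordings and averaged over replicates, the way
multi-cell datasets are averaged in practice.

Usage: python analysis/04_theta_recovery.py [seed] [n_replicates]
Writes results/theta_recovery.json.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from iksgate import default_kcnq1
from iksgate.analysis import extract_fv, extract_gv
from iksgate.kcne1 import apply_perturbation, kcne1_default_perturbation, recover_perturbation
from iksgate.simulate import steady_state_curves
from iksgate.synth import AcquisitionSpec, ExperimentDesign, generate_experiment

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    seed = int(sys.argv[1]) if len(sys.argv) > 1 else 0
    n_rep = int(sys.argv[2]) if len(sys.argv) > 2 else 10
    OUT.mkdir(exist_ok=True)
    baseline = default_kcnq1()
    perturbed = apply_perturbation(baseline, kcne1_default_perturbation())
    volts = [float(v) for v in range(-120, 101, 10)]

    tab = steady_state_curves(perturbed, volts, 60.0, 4000.0)
    exact = recover_perturbation(tab, tab, baseline)
    print("Noiseless round trip (truth: theta_IC x20, theta_AO x5):")
    print(
        f"  theta_IC x{exact.factors['theta_ic']:.3f}, "
        f"theta_AO x{exact.factors['theta_ao']:.3f} "
        f"(identifiable: {exact.identifiable})"
    )

    gvs, fvs = [], []
    for rep in range(n_rep):
        acq = AcquisitionSpec(
            seed=seed + rep, current_noise_sd=0.02, fluor_noise_sd=0.02
        )
        recs, man = generate_experiment(
            ExperimentDesign(kind="kcne1_pair", test_voltages_mv=tuple(volts)),
            baseline,
            acq,
        )
        fam = [r for r in recs.values() if r.meta.get("condition") == "perturbed"]
        tail_start = acq.prepulse_ms + man["pulse_ms"]
        gvs.append(extract_gv(fam, tail_start).set_index("voltage_mV"))
        fvs.append(extract_fv(fam, acq.prepulse_ms, tail_start).set_index("voltage_mV"))
    gv_avg = pd.concat(gvs).groupby(level=0)[["gv_raw", "gv_norm"]].mean().reset_index()
    fv_avg = pd.concat(fvs).groupby(level=0)[["fv_raw", "fv_norm"]].mean().reset_index()
    noisy = recover_perturbation(gv_avg, fv_avg, baseline)
    print(f"From {n_rep} replicate-averaged noisy experiments (2% noise):")
    print(
        f"  theta_IC x{noisy.factors['theta_ic']:.3f} "
        f"(se {noisy.stderr['theta_ic']:.3f}), "
        f"theta_AO x{noisy.factors['theta_ao']:.3f} "
        f"(se {noisy.stderr['theta_ao']:.3f})"
    )
    print(
        "  note: above open-probability saturation the theta_AO likelihood "
        "flattens; its estimate has a heavy upper tail at this noise level"
    )

    out = {
        "truth": {"theta_ic": 20.0, "theta_ao": 5.0},
        "noiseless": exact.factors,
        "noisy_averaged": noisy.factors,
        "noisy_stderr": noisy.stderr,
        "seed": seed,
        "n_replicates": n_rep,
    }
    (OUT / "theta_recovery.json").write_text(json.dumps(out, indent=2) + "\n")


if __name__ == "__main__":
    sys.exit(main())
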