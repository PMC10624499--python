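#!/usr/bin/env python
"""Generate the synthetic two-sample GWAS datasets for every analysis arm.

Emulates the study design at its real scales: a lipid exposure GWAS
(n = 188,577) against a binary disease-risk GWAS (n = 41,505), a
whole-blood cis-eQTL drug-target arm (n = 31,684) with AR(1) LD blocks kept
only to a liberal r² threshold, and a reverse-causation arm where the
binary trait is the exposure.  Ground truth is known for every arm, so the
downstream drivers can report estimation error, not just estimates.

Summary-statistics tables, LD matrices and truth sidecars go to
scratch/synthetic/ (bulky, regenerable); a compact design summary goes to
results/synthetic_design.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from lipidmr.simulate import SimulationConfig, simulate_study

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "scratch" / "synthetic"
RESULTS = ROOT / "results"

SEED = 20230917

#: True causal effects per arm (log-OR per SD for the binary outcome).
ARMS = {
    # lipid arm: 118 independent genome-wide instruments, GLGC-like scale
    "hdl_like_lipid": SimulationConfig(
        J=118, theta=float(np.log(1.14)), n_x=188_577, n_y=41_505,
        outcome_type="binary", seed=SEED,
    ),
    # null lipid arm (LDL-C-like in this design: no effect on risk)
    "ldl_like_lipid": SimulationConfig(
        J=99, theta=0.0, n_x=188_577, n_y=41_505,
        outcome_type="binary", seed=SEED + 1,
    ),
    # protective drug-target arm: cis instruments in moderate LD
    "rac2_like_gene": SimulationConfig(
        J=12, theta=float(np.log(0.86)), n_x=31_684, n_y=41_505,
        ld_spec=("ar1", 0.6, 6), outcome_type="binary", seed=SEED + 2,
    ),
    # null drug-target arm (HMGCR-like: no effect on risk)
    "hmgcr_like_gene": SimulationConfig(
        J=10, theta=0.0, n_x=31_684, n_y=41_505,
        ld_spec=("ar1", 0.6, 5), outcome_type="binary", seed=SEED + 3,
    ),
    # reverse arm: disease liability as exposure, lipid as outcome
    "reverse_ms_to_lipid": SimulationConfig(
        J=118, theta=0.0, n_x=41_505, n_y=188_577,
        outcome_type="continuous", seed=SEED + 4,
    ),
}


def main():
    RESULTS.mkdir(parents=True, exist_ok=True)
    rows = []
    for label, cfg in ARMS.items():
        study = simulate_study(cfg, exposure_name=label, outcome_name="disease")
        study.write(DATA / label)
        rows.append(
            {
                "arm": label,
                "J": cfg.J,
                "true_theta": cfg.theta,
                "true_or": float(np.exp(cfg.theta)) if cfg.outcome_type == "binary" else np.nan,
                "n_exposure": int(cfg.n_x),
                "n_outcome": int(cfg.n_y),
                "ld": "ar1" if cfg.ld_spec else "independent",
                "outcome_type": cfg.outcome_type,
            }
        )
        print(f"{label}: J={cfg.J}, true theta={cfg.theta:+.4f} -> {DATA / label}")
    design = pd.DataFrame(rows)
    design.to_csv(RESULTS / "synthetic_design.tsv", sep="\t", index=False, float_format="%.6g")
    print(f"\ndesign summary -> {RESULTS / 'synthetic_design.tsv'}")


if __name__ == "__main__":
    main()
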