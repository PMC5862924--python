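#!/usr/bin/env python
"""Full synthetic tomography scan at the compact-source geometry.

Runs the complete chain on the spiral cochlea phantom — Fresnel contrast
formation with source blur and counting noise, flat/dark correction, MBA+BAC
retrieval, ring suppression and Ram-Lak filtered backprojection — then
estimates resolution by even/odd-split Fourier shell correlation with the
1/2-bit criterion and the bone-vs-air SNR on the central slice.

Artifacts (phantom, stacks, volume, metrics.json, fsc_curve.csv) land in
results/full_scan/.
"""

import csv
from pathlib import Path

from propct.config import load_config
from propct.pipeline import run_pipeline

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results" / "full_scan"


def main() -> None:
    cfg = load_config(ROOT / "configs" / "mucls_guineapig.yaml")
    cfg.output_dir = RESULTS
    art = run_pipeline(cfg)

    fsc_res = art["fsc"]
    with open(RESULTS / "fsc_curve.csv", "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["freq_cyc_per_voxel", "fsc", "half_bit_threshold"])
        w.writerows(zip(fsc_res.shell_freqs, fsc_res.fsc, fsc_res.threshold))

    m = art["metrics"]
    print(f"volume: {art['volume'].mu_grid.shape} at {cfg.phantom.voxel_um} um voxels")
    print(
        f"even/odd FSC: crossover {m['fsc_crossover_cyc_per_voxel']:.3f} cyc/voxel "
        f"-> half-period resolution {m['fsc_half_period_um']:.1f} um"
    )
    print(f"SNR (bone vs air, central slice): {m['snr_bone_air']:.1f}")
    print(f"artifacts in {RESULTS} (config hash {m['config_hash']})")


if __name__ == "__main__":
    main()
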