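#!/usr/bin/env python
"""Defocus-series analysis: contrast gain versus resolution loss.

Simulates the compact-source defocus experiment on the synthetic cochlea
phantom: for three source-to-detector distances (z_eff = 85.5, 351.4 and
844.0 mm) a bone edge target is Fresnel-propagated and a noisy phantom
projection is analyzed by its angularly averaged PSD. Writes one PSD CSV per
distance plus results/defocus_summary.csv.

Expected behaviour (and what this script verifies by printing the measured
ordering): the edge overshoot and the mid-frequency PSD grow with distance
(phase contrast builds up), while the frequency at which the spectrum sinks
into the noise floor falls (penumbral source blur grows with magnification).
The shortest distance is, to good approximation, a pure absorption image
with no edge enhancement.
"""

import csv
from pathlib import Path

from propct import ConeBeamGeometry, PhantomParams
from propct.config import PipelineConfig, SimulationConfig
from propct.pipeline import run_defocus_series

RESULTS = Path(__file__).resolve().parents[1] / "results"
Z02_LIST = [3856.5, 4156.5, 4856.5]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cfg = PipelineConfig(
        geometry=ConeBeamGeometry(3769.0, 4856.5, 6.5, 25.0, source_fwhm_um=98.0),
        phantom=PhantomParams(grid_size=96, voxel_um=5.0, seed=0),
        simulation=SimulationConfig(n_angles=1, mean_counts=1e4),
        seed=0,
    )
    res = run_defocus_series(cfg, Z02_LIST)

    summary = []
    for r in res["records"]:
        tag = f"{r['z_eff_mm']:.0f}mm"
        with open(RESULTS / f"defocus_psd_{tag}.csv", "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["freq_cyc_per_um", "normalized_psd"])
            w.writerows(zip(r["psd"].freqs, r["psd"].power))
        summary.append({
            "z02_mm": r["z02_mm"],
            "z_eff_mm": r["z_eff_mm"],
            "fresnel_number": r["fresnel_number"],
            "edge_overshoot": r["edge_overshoot"],
            "psd_mid_band": r["psd_mid_band"],
            "psd_rolloff_cyc_per_um": r["psd_rolloff_cyc_per_um"],
        })
        print(
            f"z_eff={r['z_eff_mm']:7.1f} mm  F_eff={r['fresnel_number']:6.3f}  "
            f"overshoot={r['edge_overshoot']:.4f}  mid-PSD={r['psd_mid_band']:.3e}  "
            f"rolloff={r['psd_rolloff_cyc_per_um']:.4f} cyc/um"
        )
    with open(RESULTS / "defocus_summary.csv", "w", newline="") as f:
        w = csv.DictWriter(f, fieldnames=list(summary[0]))
        w.writeheader()
        w.writerows(summary)

    over = [s["edge_overshoot"] for s in summary]
    mid = [s["psd_mid_band"] for s in summary]
    roll = [s["psd_rolloff_cyc_per_um"] for s in summary]
    print(
        "\nordering with distance: overshoot "
        + ("non-decreasing" if over == sorted(over) else "NOT monotone")
        + ", mid-band PSD "
        + ("non-decreasing" if mid == sorted(mid) else "NOT monotone")
        + ", rolloff "
        + ("non-increasing" if roll == sorted(roll, reverse=True) else "NOT monotone")
    )


if __name__ == "__main__":
    main()
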