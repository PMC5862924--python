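#!/usr/bin/env python
"""Effective parallel-beam geometry of the three instrument configurations.

Derives magnification, effective propagation distance, effective pixel size
and Fresnel number for the compact-source scan, the two liquid-metal-jet
setups, and every stop of the compact-source defocus series. Writes
results/geometry_table.csv and results/defocus_geometry.csv.

Key findings (printed when run): the compact-source geometry reaches
F_eff ~ 0.61 — the direct-contrast regime where single-distance phase
retrieval applies — while the same detector on the liquid-metal-jet source
sits at F_eff ~ 3.46 (weak edge enhancement); swapping in the coarse flat
panel at high magnification recovers F_eff ~ 1.69 at the same effective
pixel.
"""

import csv
from pathlib import Path

import numpy as np

from propct import ConeBeamGeometry

RESULTS = Path(__file__).resolve().parents[1] / "results"

INSTRUMENTS = {
    "mucls_scmos": ConeBeamGeometry(3769.0, 4856.5, 6.5, 25.0, source_fwhm_um=98.0),
    "lmj_scmos": ConeBeamGeometry(247.0, 317.8, 6.5, 9.25, source_fwhm_um=10.0),
    "lmj_flatpanel": ConeBeamGeometry(120.0, 1783.0, 74.8, 9.25, source_fwhm_um=10.0),
}


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    rows = []
    for name, geom in INSTRUMENTS.items():
        s = geom.summary()
        s["instrument"] = name
        rows.append(s)
        print(
            f"{name:>14}: M={s['magnification']:.4f}  z_eff={s['z_eff_mm']:.1f} mm  "
            f"p_eff={s['p_eff_um']:.3f} um  F_eff={s['fresnel_number']:.4f}"
        )
    with open(RESULTS / "geometry_table.csv", "w", newline="") as f:
        writer = csv.DictWriter(f, fieldnames=list(rows[0]))
        writer.writeheader()
        writer.writerows(rows)

    # compact-source defocus series: z02 swept 3856.5 -> 4956.5 mm in 50 mm steps
    defocus_rows = []
    for z02 in np.arange(3856.5, 4956.5 + 1, 50.0):
        g = ConeBeamGeometry(3769.0, float(z02), 6.5, 25.0)
        defocus_rows.append({
            "z02_mm": z02,
            "z_eff_mm": g.effective_distance_mm,
            "p_eff_um": g.effective_pixel_um,
            "fresnel_number": g.fresnel_number,
        })
    with open(RESULTS / "defocus_geometry.csv", "w", newline="") as f:
        writer = csv.DictWriter(f, fieldnames=list(defocus_rows[0]))
        writer.writeheader()
        writer.writerows(defocus_rows)
    first, last = defocus_rows[0], defocus_rows[-1]
    print(
        f"\ndefocus series: z_eff {first['z_eff_mm']:.1f} -> {last['z_eff_mm']:.1f} mm, "
        f"F_eff {first['fresnel_number']:.2f} -> {last['fresnel_number']:.3f} "
        f"({len(defocus_rows)} stops written to defocus_geometry.csv)"
    )


if __name__ == "__main__":
    main()
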