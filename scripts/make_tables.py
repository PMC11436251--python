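"""Regenerate the bundled spectral tables under src/glucosens/data/.

The tables are *representative* NIR optical properties for a three-layer
forearm skin model and for a 2% intralipid phantom on a 10-nm grid over
1000-1700 nm.  Two entries are pinned to published anchor values used
throughout the pipeline:

  * dermis mu_a(1314 nm) = 2.05 mm^-1
  * dermis mu_s(1314 nm) = 13.0 mm^-1

Everything else is constructed from smooth, literature-shaped curves:
a water-like absorption spectrum (coarse nodes, linearly interpolated)
plus a flat background, and a Mie-type power law for scattering.  The
tables are editable package data; runs can point at alternative CSVs.
"""

from pathlib import Path

import numpy as np
import pandas as pd

OUT = Path(__file__).resolve().parents[1] / "src" / "glucosens" / "data"

# Coarse water absorption curve, mm^-1 (approximate Hale&Querry/Kou shape).
WATER_NODES_NM = np.array(
    [1000, 1050, 1100, 1150, 1200, 1250, 1300, 1350, 1400, 1450,
     1500, 1550, 1600, 1650, 1700], dtype=float
)
WATER_MUA_MM = np.array(
    [0.040, 0.020, 0.017, 0.060, 0.105, 0.090, 0.120, 0.250, 1.20, 2.90,
     2.10, 1.05, 0.65, 0.50, 0.55], dtype=float
)

GRID = np.arange(1000.0, 1700.0 + 1e-9, 10.0)
ANCHOR_NM = 1314.0
DERMIS_MUA_ANCHOR = 2.05   # mm^-1, pinned
DERMIS_MUS_ANCHOR = 13.0   # mm^-1, pinned


def water_mua(lam):
    return np.interp(lam, WATER_NODES_NM, WATER_MUA_MM)


def build_skin() -> pd.DataFrame:
    rows = []
    # mu_a: flat background + water fraction; dermis offset solves the anchor.
    dermis_offset = DERMIS_MUA_ANCHOR - 0.7 * water_mua(ANCHOR_NM)
    for lam in GRID:
        w = water_mua(lam)
        mua_dermis = dermis_offset + 0.7 * w
        layer_rows = {
            "epidermis": (0.9 * mua_dermis, 15.0 * ANCHOR_NM / lam),
            "dermis": (mua_dermis, DERMIS_MUS_ANCHOR * ANCHOR_NM / lam),
            "subcutis": (0.7 * mua_dermis, 12.0 * ANCHOR_NM / lam),
        }
        for layer, (mua, mus) in layer_rows.items():
            rows.append(
                {
                    "wavelength_nm": lam,
                    "layer": layer,
                    "mu_a_mm-1": round(mua, 6),
                    "mu_s_mm-1": round(mus, 6),
                    "g": 0.9,
                    "n": 1.4,
                }
            )
    return pd.DataFrame(rows)


def build_intralipid() -> pd.DataFrame:
    rows = []
    for lam in GRID:
        # 2% intralipid: reduced scattering ~2.0 mm^-1 at 750 nm with a
        # lambda^-2.4 slope; g linear in wavelength (van Staveren shape).
        mus_prime = 2.0 * (750.0 / lam) ** 2.4
        g = min(max(1.1 - 0.58e-3 * lam, 0.0), 0.9)
        mus = mus_prime / (1.0 - g)
        rows.append(
            {
                "wavelength_nm": lam,
                "layer": "intralipid_2pct",
                "mu_a_mm-1": round(water_mua(lam), 6),
                "mu_s_mm-1": round(mus, 6),
                "g": round(g, 6),
                "n": 1.33,
            }
        )
    return pd.DataFrame(rows)


# Representative glucose-induced absorption change, mm^-1 per mmol/L:
# negligible below ~1350 nm, a broad positive hump toward the
# combination-band region. Coarse nodes, linearly interpolated.
GLUCOSE_DMUA_NODES_NM = np.array(
    [1000, 1100, 1200, 1300, 1350, 1400, 1450, 1500, 1550, 1600, 1650, 1700],
    dtype=float,
)
GLUCOSE_DMUA = np.array(
    [1e-6, 2e-6, 5e-6, 8e-6, 1.5e-5, 4e-5, 6e-5, 8e-5, 1.0e-4, 1.2e-4, 1.0e-4, 9e-5],
    dtype=float,
)


def build_glucose_absorption() -> pd.DataFrame:
    vals = np.interp(GRID, GLUCOSE_DMUA_NODES_NM, GLUCOSE_DMUA)
    return pd.DataFrame(
        {"wavelength_nm": GRID, "dmua_dCg_mm-1_per_mmolL": np.round(vals, 9)}
    )


if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    build_skin().to_csv(OUT / "skin_three_layer.csv", index=False)
    build_intralipid().to_csv(OUT / "intralipid_2pct.csv", index=False)
    build_glucose_absorption().to_csv(OUT / "glucose_absorption.csv", index=False)
    print("wrote", OUT)
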