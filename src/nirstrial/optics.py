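"""Shared optical constants and helpers for the dual-wavelength system.

The extinction table ships as an editable CSV inside the package; values are
decadic specific extinction coefficients scaled so that, with source-detector
distances in mm, the Beer-Lambert system yields concentration changes in
umol/l.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

CHROMOPHORES = ("o2hb", "hhb")

#: differential pathlength factors per wavelength (dimensionless)
DEFAULT_DPF = {760.0: 6.75, 870.0: 6.50}

DEFAULT_WAVELENGTHS = (760.0, 870.0)

DEFAULT_DISTANCE_MM = 12.5


def load_extinction_table() -> pd.DataFrame:
    """Load the packaged extinction-coefficient table as a tidy DataFrame."""
    ref = resources.files("nirstrial.data") / "extinction_coefficients.csv"
    with ref.open("r") as fh:
        return pd.read_csv(fh, comment="#")


def extinction_matrix(wavelengths=DEFAULT_WAVELENGTHS) -> np.ndarray:
    """2x2 extinction matrix, rows = wavelengths, cols = (o2hb, hhb).

    Units: 1/(umol/l)/mm.
    """
    tab = load_extinction_table()
    out = np.empty((len(wavelengths), len(CHROMOPHORES)))
    for i, wl in enumerate(wavelengths):
        for j, chrom in enumerate(CHROMOPHORES):
            sel = tab[(tab.wavelength_nm == int(round(wl))) & (tab.chromophore == chrom)]
            if len(sel) != 1:
                raise ValueError(f"no unique extinction entry for {wl} nm / {chrom}")
            out[i, j] = float(sel.epsilon_per_uM_per_mm.iloc[0])
    return out


def absorbance_system(extinction: np.ndarray, distance_mm: float, dpf: dict,
                      wavelengths=DEFAULT_WAVELENGTHS) -> np.ndarray:
    """Full 2x2 coupling matrix K with dA = K @ dC (dC in umol/l).

    K[lambda, chrom] = eps(lambda, chrom) * distance * DPF(lambda).
    """
    extinction = np.asarray(extinction, dtype=float)
    if extinction.shape != (2, 2):
        raise ValueError("extinction matrix must be 2x2 (wavelength x chromophore)")
    dpf_vec = np.array([dpf[wl] for wl in wavelengths], dtype=float)
    return extinction * distance_mm * dpf_vec[:, None]


def check_invertible(matrix: np.ndarray, max_cond: float = 1e3) -> None:
    """Raise if the 2x2 system is singular or badly conditioned."""
    det = np.linalg.det(matrix)
    if abs(det) < 1e-300:
        raise ValueError("extinction system is singular")
    cond = np.linalg.cond(matrix)
    if cond > max_cond:
        raise ValueError(f"extinction system condition number {cond:.3g} exceeds {max_cond:.3g}")
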