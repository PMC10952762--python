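"""Derived hydrochemical determinands.

Free (un-ionised) ammonia is derived from total ammoniacal nitrogen, pH and
temperature through the NH4+/NH3 acid-base equilibrium, using the empirical
freshwater pKa of Emerson et al. (1975):

    pKa(T) = 0.09018 + 2729.92 / T_Kelvin
    NH3-N  = NH4-N * 1 / (1 + 10**(pKa - pH))

Dissolved-organic and particulate nutrient fractions come from simple
difference arithmetic on co-timestamped measurements; small negative
differences (analytical noise near detection limits) are clamped to zero
and flagged.
"""
from __future__ import annotations

import warnings

import numpy as np

__all__ = ["free_ammonia_fraction", "derive_free_ammonia",
           "derive_nutrient_fractions"]

_T_MIN_C, _T_MAX_C = -5.0, 45.0


def free_ammonia_fraction(ph, temp_c):
    """Fraction of total ammoniacal N present as NH3 at given pH and T (degC)."""
    ph = np.asarray(ph, dtype=float)
    temp_c = np.asarray(temp_c, dtype=float)
    pka = 0.09018 + 2729.92 / (temp_c + 273.15)
    return 1.0 / (1.0 + 10.0 ** (pka - ph))


def derive_free_ammonia(nh4, ph, temp_c):
    """NH3-N concentration (mg/L) from NH4-N, pH and temperature.

    Out-of-range temperatures (outside (-5, 45) degC) yield missing values
    with a warning; negative NH4-N inputs are invalid and yield NaN.
    Accepts scalars or arrays; returns a float for scalar input.
    """
    nh4 = np.asarray(nh4, dtype=float)
    ph_a = np.asarray(ph, dtype=float)
    temp_a = np.asarray(temp_c, dtype=float)
    scalar = nh4.ndim == 0 and ph_a.ndim == 0 and temp_a.ndim == 0
    nh4, ph_a, temp_a = np.broadcast_arrays(nh4, ph_a, temp_a)

    out = nh4 * free_ammonia_fraction(ph_a, temp_a)
    bad_t = ~((temp_a > _T_MIN_C) & (temp_a < _T_MAX_C))
    if np.any(bad_t & np.isfinite(temp_a)):
        warnings.warn(
            "temperature outside (-5, 45) degC: free ammonia set missing",
            stacklevel=2)
    out = np.where(bad_t | (nh4 < 0), np.nan, out)
    return float(out) if scalar else out


def derive_nutrient_fractions(tn, tdn, no3, nh4, tdp, srp):
    """Particulate N, dissolved organic N and dissolved organic P by difference.

        PN  = TN  - TDN
        DON = TDN - NO3-N - NH4-N
        DOP = TDP - SRP

    Any missing input makes the dependent fraction missing.  Negative
    differences are clamped to zero; the returned ``clamped`` dict flags,
    per fraction, which elements were clamped.  Accepts scalars or arrays.
    """
    tn, tdn, no3, nh4, tdp, srp = [np.asarray(x, dtype=float)
                                   for x in (tn, tdn, no3, nh4, tdp, srp)]
    scalar = all(a.ndim == 0 for a in (tn, tdn, no3, nh4, tdp, srp))
    tn, tdn, no3, nh4, tdp, srp = np.broadcast_arrays(
        tn, tdn, no3, nh4, tdp, srp)

    raw = {
        "PN": tn - tdn,
        "DON": tdn - no3 - nh4,
        "DOP": tdp - srp,
    }
    fractions = {}
    clamped = {}
    for name, value in raw.items():
        neg = value < 0
        clamped[name] = neg & np.isfinite(value)
        value = np.where(neg, 0.0, value)
        fractions[name] = float(value) if scalar else value
        if scalar:
            clamped[name] = bool(clamped[name])
    return fractions, clamped
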