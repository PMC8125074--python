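"""Tracer mass-balance uptake rates from particulate-carbon isotope data.

A two-pool mixing model: particulate organic carbon (POC) is a mixture of
ambient carbon at the baseline (t0) atom fraction and substrate-derived
carbon at the substrate's atom fraction.  The carbon incorporation rate over
the incubation is the POC pool times the fractional isotopic enrichment,
divided by the enrichment of the added substrate over baseline and the
incubation time; dividing by the carbons per substrate molecule gives a
substrate uptake rate in nM/day.  Input atom fractions are assumed already
instrument-corrected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Naphthalene: C10H8.
NAPHTHALENE_CARBONS = 10
NAPHTHALENE_MOLAR_MASS = 128.17  # g/mol
NAPHTHALENE_SOLUBILITY_MG_L = 30.0


@dataclass(frozen=True)
class TracerMeasurement:
    """One incubation's isotope-ratio measurement.

    ``poc`` is particulate organic carbon in nM C; atom fractions are 13C
    atom fractions of the particulate pool at time t (``af_t``), at baseline
    (``af_t0``) and of the added substrate (``af_substrate``); ``delta_t``
    is the incubation length in days.
    """

    poc: float
    af_t: float
    af_t0: float
    delta_t: float
    af_substrate: float = 0.99
    carbons_per_molecule: int = NAPHTHALENE_CARBONS
    substrate_added: float = 400.0  # nM

    def __post_init__(self) -> None:
        for name in ("af_t", "af_t0", "af_substrate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} outside [0, 1]: {v}")
        if self.delta_t <= 0:
            raise ValueError("delta_t must be positive")
        if self.af_substrate <= self.af_t0:
            raise ValueError(
                "substrate atom fraction must exceed the baseline "
                f"({self.af_substrate} <= {self.af_t0})"
            )


@dataclass(frozen=True)
class UptakeResult:
    """Carbon and substrate uptake rates; ``below_detection`` flags zero/negative enrichment."""

    carbon_rate: float  # nM C / day
    substrate_rate: float  # nM substrate / day
    below_detection: bool

    @property
    def fractional_daily_removal(self) -> float | None:
        return None if self._added is None or self._added == 0 else self.substrate_rate / self._added

    _added: float | None = None


def uptake_rate(m: TracerMeasurement) -> UptakeResult:
    """Substrate-carbon incorporation rate by tracer mass balance.

    ``carbon_rate = poc * (af_t - af_t0) / ((af_substrate - af_t0) * delta_t)``
    and ``substrate_rate = carbon_rate / carbons_per_molecule``.  Negative
    enrichment (af_t <= af_t0) is reported as rate 0 with the
    below-detection flag set.
    """
    enrichment = m.af_t - m.af_t0
    if enrichment <= 0:
        return UptakeResult(0.0, 0.0, True, _added=m.substrate_added)
    carbon = m.poc * enrichment / ((m.af_substrate - m.af_t0) * m.delta_t)
    return UptakeResult(
        carbon_rate=carbon,
        substrate_rate=carbon / m.carbons_per_molecule,
        below_detection=False,
        _added=m.substrate_added,
    )


@dataclass(frozen=True)
class AmendmentReport:
    solubility_um: float
    concentration_nm: float
    solubility_ratio: float
    exceeds_solubility: bool


def check_amendment(
    concentration_nm: float,
    solubility_mg_per_l: float = NAPHTHALENE_SOLUBILITY_MG_L,
    molar_mass: float = NAPHTHALENE_MOLAR_MASS,
) -> AmendmentReport:
    """Sanity-check an amendment concentration against aqueous solubility.

    Converts the solubility to µM (``1000 * mg_per_l / molar_mass``) and
    reports its ratio to the amended concentration; warns when the
    amendment exceeds solubility.
    """
    if molar_mass <= 0:
        raise ValueError("molar mass must be positive")
    if concentration_nm <= 0 or solubility_mg_per_l <= 0:
        raise ValueError("concentration and solubility must be positive")
    solubility_um = 1000.0 * solubility_mg_per_l / molar_mass
    concentration_um = concentration_nm / 1000.0
    ratio = solubility_um / concentration_um
    exceeds = concentration_um > solubility_um
    if exceeds:
        warnings.warn(
            f"amendment {concentration_um:.1f} uM exceeds solubility "
            f"{solubility_um:.1f} uM",
            stacklevel=2,
        )
    return AmendmentReport(solubility_um, concentration_nm, ratio, exceeds)


def aggregate_rates(df: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD of replicate substrate uptake rates per site.

    ``df`` needs columns site, poc, af_t, af_t0, delta_t and optionally
    af_substrate, carbons_per_molecule, substrate_added; one row per
    replicate bottle.
    """
    rows = []
    for _, r in df.iterrows():
        kwargs = {
            k: r[k]
            for k in ("af_substrate", "carbons_per_molecule", "substrate_added")
            if k in df.columns and not pd.isna(r[k])
        }
        m = TracerMeasurement(
            poc=float(r["poc"]), af_t=float(r["af_t"]), af_t0=float(r["af_t0"]),
            delta_t=float(r["delta_t"]), **kwargs,
        )
        res = uptake_rate(m)
        rows.append(
            {
                "site": r["site"],
                "substrate_rate": res.substrate_rate,
                "below_detection": res.below_detection,
            }
        )
    per = pd.DataFrame(rows)
    agg = per.groupby("site").agg(
        mean_rate=("substrate_rate", "mean"),
        sd_rate=("substrate_rate", lambda x: float(np.std(x, ddof=1)) if len(x) > 1 else 0.0),
        n=("substrate_rate", "size"),
        all_below_detection=("below_detection", "all"),
    )
    return agg.reset_index()
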