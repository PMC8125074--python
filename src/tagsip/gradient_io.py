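"""Reading, validating and writing per-fraction gradient tables.

One isopycnic gradient is one tab-separated file: a header line, optional
``#`` comment lines, one row per 100-µl fraction.  Reserved columns are
``fraction`` (integer id), ``n_c`` (refractive index), ``density`` (buoyant
density, g/ml) and ``dna_ng`` (DNA mass recovered from the fraction); every
other column is interpreted as an OTU read-count column.  Either ``n_c`` or
``density`` must be present; density is filled in from refractometry with the
CsCl calibration ``rho = 10.927 * n_c - 13.593``.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: CsCl refractive-index -> buoyant-density calibration (g/ml per RI unit).
DENSITY_SLOPE = 10.927
DENSITY_INTERCEPT = -13.593

#: Plausible refractive-index range for CsCl gradient fractions.
RI_RANGE = (1.33, 1.46)

RESERVED_COLUMNS = frozenset({"fraction", "n_c", "density", "dna_ng"})

#: Fractions with less DNA than this (ng) are kept in files but excluded
#: from density distributions ("each fraction with detectable DNA").
DEFAULT_MIN_DNA_NG = 0.1


def refraction_to_density(n_c, fraction_id=None):
    """Convert a refractive index to CsCl buoyant density (g/ml).

    Accepts a scalar or array.  Values outside the plausible CsCl range
    trigger a warning (not an error); non-finite values are rejected with a
    message naming the offending fraction when known.
    """
    arr = np.asarray(n_c, dtype=float)
    if not np.all(np.isfinite(arr)):
        where = f" (fraction {fraction_id})" if fraction_id is not None else ""
        raise ValueError(f"non-finite refractive index{where}: {n_c!r}")
    lo, hi = RI_RANGE
    if np.any(arr < lo) or np.any(arr > hi):
        warnings.warn(
            f"refractive index outside plausible CsCl range [{lo}, {hi}]",
            stacklevel=2,
        )
    out = DENSITY_SLOPE * arr + DENSITY_INTERCEPT
    return float(out) if np.isscalar(n_c) else out


def density_to_refraction(density):
    """Inverse of :func:`refraction_to_density` (used by the simulator)."""
    return (np.asarray(density, dtype=float) - DENSITY_INTERCEPT) / DENSITY_SLOPE


@dataclass
class FractionRecord:
    """One gradient fraction: density, DNA mass and OTU read counts."""

    fraction_id: int
    buoyant_density: float
    dna_mass: float
    counts: Mapping[str, int]
    refractive_index: float | None = None

    def __post_init__(self) -> None:
        if self.fraction_id < 1:
            raise ValueError(f"fraction id must be >= 1: {self.fraction_id}")
        if not math.isfinite(self.buoyant_density):
            raise ValueError(
                f"non-finite density in fraction {self.fraction_id}"
            )
        if self.dna_mass < 0:
            raise ValueError(
                f"negative DNA mass in fraction {self.fraction_id}: {self.dna_mass}"
            )
        if any(c < 0 for c in self.counts.values()):
            raise ValueError(f"negative count in fraction {self.fraction_id}")
        if self.refractive_index is not None:
            implied = refraction_to_density(self.refractive_index)
            if abs(implied - self.buoyant_density) > 1e-4:
                raise ValueError(
                    f"fraction {self.fraction_id}: density {self.buoyant_density:.5f} "
                    f"disagrees with refractometry-implied {implied:.5f}"
                )


@dataclass
class GradientProfile:
    """An ordered set of fractions from one gradient of one sample.

    Fractions are stored in increasing buoyant-density order regardless of
    the order they were read in (gradients are commonly retrieved
    heavy-to-light).  All fractions share one OTU universe; OTUs missing
    from a fraction count as zero.
    """

    sample_id: str
    isotope: str
    fractions: list[FractionRecord]

    def __post_init__(self) -> None:
        self._counts_cache: pd.DataFrame | None = None
        if self.isotope not in ("12C", "13C"):
            raise ValueError(f"isotope must be '12C' or '13C': {self.isotope!r}")
        ids = [f.fraction_id for f in self.fractions]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate fraction ids: {dupes}")
        rho = [f.buoyant_density for f in self.fractions]
        increasing = all(a < b for a, b in zip(rho, rho[1:]))
        decreasing = all(a > b for a, b in zip(rho, rho[1:]))
        if not (increasing or decreasing):
            bad = [
                self.fractions[i + 1].fraction_id
                for i, (a, b) in enumerate(zip(rho, rho[1:]))
                if (a < b) != (rho[0] < rho[1]) or a == b
            ]
            raise ValueError(
                f"densities not monotonic along fraction order; offending "
                f"fractions: {bad}"
            )
        if decreasing:
            self.fractions = list(reversed(self.fractions))

    @property
    def densities(self) -> np.ndarray:
        return np.array([f.buoyant_density for f in self.fractions])

    @property
    def dna_masses(self) -> np.ndarray:
        return np.array([f.dna_mass for f in self.fractions])

    @property
    def otu_ids(self) -> list[str]:
        universe: set[str] = set()
        for f in self.fractions:
            universe.update(f.counts)
        return sorted(universe)

    def count_matrix(self) -> pd.DataFrame:
        """Fractions x OTUs read-count matrix (missing OTUs filled with 0).

        Cached after first use; the profile is treated as immutable once
        analysis starts.
        """
        if self._counts_cache is None:
            df = pd.DataFrame(
                [f.counts for f in self.fractions],
                index=[f.fraction_id for f in self.fractions],
            ).fillna(0).astype(np.int64)
            self._counts_cache = df.reindex(columns=self.otu_ids)
        return self._counts_cache

    def total_reads(self) -> int:
        return int(sum(sum(f.counts.values()) for f in self.fractions))

    def validate_for_analysis(self, min_dna_ng: float = DEFAULT_MIN_DNA_NG) -> None:
        """Require at least 5 fractions with analyzable DNA."""
        n = int(np.sum(self.dna_masses > min_dna_ng))
        if n < 5:
            raise ValueError(
                f"gradient {self.sample_id}: only {n} fractions with "
                f"DNA mass > {min_dna_ng} ng; >= 5 required for analysis"
            )


@dataclass
class SampleMetadata:
    """Incubation metadata for one mesocosm sample."""

    site: str
    date: str
    incubation_hours: float
    light_regime: str = "dark"
    substrate_concentration: float = 400.0  # nM

    def __post_init__(self) -> None:
        if self.incubation_hours <= 0:
            raise ValueError("incubation_hours must be positive")
        if self.substrate_concentration < 0:
            raise ValueError("substrate_concentration must be >= 0")


def read_gradient_table(
    path: str | Path,
    sample_id: str | None = None,
    isotope: str = "12C",
) -> GradientProfile:
    """Read one gradient's tab-separated fraction table.

    The file must have a header with a ``fraction`` column, ``dna_ng``, and
    at least one of ``n_c`` / ``density``; all other columns are OTU counts.
    When only ``n_c`` is present, density is computed per row; when both are
    present they must agree within 1e-4 g/ml.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    cols = set(df.columns)
    missing = {"fraction", "dna_ng"} - cols
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if "n_c" not in cols and "density" not in cols:
        raise ValueError(f"{path}: need an 'n_c' or 'density' column")

    otu_cols = [c for c in df.columns if c not in RESERVED_COLUMNS]
    fractions = []
    for _, row in df.iterrows():
        fid = int(row["fraction"])
        n_c = float(row["n_c"]) if "n_c" in cols else None
        if "density" in cols and not pd.isna(row["density"]):
            rho = float(row["density"])
        else:
            rho = refraction_to_density(n_c, fraction_id=fid)
        counts = {c: int(row[c]) for c in otu_cols}
        fractions.append(
            FractionRecord(
                fraction_id=fid,
                buoyant_density=rho,
                dna_mass=float(row["dna_ng"]),
                counts=counts,
                refractive_index=n_c,
            )
        )
    profile = GradientProfile(
        sample_id=sample_id or path.stem, isotope=isotope, fractions=fractions
    )
    log.info(
        "%s: %d fractions, %d OTUs, %d reads",
        path, len(profile.fractions), len(profile.otu_ids), profile.total_reads(),
    )
    return profile


def write_gradient_table(profile: GradientProfile, path: str | Path) -> None:
    """Write a gradient profile back to the tab-separated fraction format."""
    otus = profile.otu_ids
    rows = []
    for f in profile.fractions:
        row: dict = {"fraction": f.fraction_id}
        if f.refractive_index is not None:
            row["n_c"] = f"{f.refractive_index:.6f}"
        row["density"] = f"{f.buoyant_density:.6f}"
        row["dna_ng"] = f"{f.dna_mass:.6f}"
        for otu in otus:
            row[otu] = f.counts.get(otu, 0)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


RESULT_COLUMNS = [
    "otu_id", "taxonomy", "ks_p_12C", "ks_p_13C", "wm_12C", "wm_13C",
    "delta_wm", "significant", "eaf", "ape",
]


def write_results_table(results: Sequence, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    """Write per-OTU shift results as TSV (one row per OTU, fixed schema)."""
    if not results:
        raise ValueError("refusing to write an empty results table")
    rows = []
    for r in results:
        rows.append(
            {
                "otu_id": r.otu_id,
                "taxonomy": r.taxonomy or "",
                "ks_p_12C": _fmt(r.ks_p_12C),
                "ks_p_13C": _fmt(r.ks_p_13C),
                "wm_12C": _fmt(r.wm_12C),
                "wm_13C": _fmt(r.wm_13C),
                "delta_wm": _fmt(r.delta_wm),
                "significant": r.significant,
                "eaf": _fmt(r.eaf),
                "ape": _fmt(r.ape),
            }
        )
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(fh, sep="\t", index=False)


def _fmt(x) -> str:
    return "" if x is None or (isinstance(x, float) and math.isnan(x)) else f"{x:.6f}"


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read a results TSV written by :func:`write_results_table`."""
    return pd.read_csv(path, sep="\t", comment="#")
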