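"""GC–density calibration and the DNA molecular-weight labeling model.

Converts a taxon's buoyant-density shift in a CsCl gradient into the excess
atom fraction (EAF) of :sup:`13`\\ C in its DNA, and back.  The model is the
standard qSIP chain: the *unlabeled* buoyant density of DNA is a linear
function of its GC content; GC content fixes the average molar mass of a
nucleotide and the number of carbon atoms it carries; a relative density
increase translates into a relative molar-mass increase, and the fraction of
the maximum possible :sup:`13`\\ C-driven mass gain — corrected for natural
:sup:`13`\\ C abundance — is the excess atom fraction.

All calibration constants are explicit fields of :class:`LabelingModel` and
can be overridden from a run configuration; the defaults are the published
qSIP calibration values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict


@dataclass(frozen=True)
class LabelingModel:
    """Constants of the GC–density–molecular-weight calibration.

    Attributes
    ----------
    gc_slope, gc_intercept
        Linear calibration of unlabeled buoyant density (g/ml) against GC
        fraction: ``rho = gc_intercept + gc_slope * G``.
    mw_slope, mw_intercept
        Average nucleotide molar mass (g/mol) against GC fraction:
        ``M = mw_intercept + mw_slope * G``.
    delta_mass_13c
        Mass difference between one 13C and one 12C atom (g/mol).
    natural_13c
        Natural abundance of 13C as an atom fraction.
    """

    gc_slope: float = 0.083506
    gc_intercept: float = 1.646057
    mw_slope: float = 0.496
    mw_intercept: float = 307.691
    delta_mass_13c: float = 1.003355
    natural_13c: float = 0.011112

    def __post_init__(self) -> None:
        if not (0.0 <= self.natural_13c < 1.0):
            raise ValueError(f"natural_13c must be in [0, 1): {self.natural_13c}")
        if self.gc_slope <= 0 or self.delta_mass_13c <= 0:
            raise ValueError("gc_slope and delta_mass_13c must be positive")

    def carbon_atoms(self, gc: float) -> float:
        """Carbon atoms per average nucleotide at GC fraction ``gc``.

        A, T and G nucleotides carry 10 carbons, C carries 9, so an average
        nucleotide in DNA of GC fraction G has ``10 - 0.5*G`` carbons.
        """
        return 10.0 - 0.5 * gc

    def nucleotide_mass(self, gc: float) -> float:
        """Average unlabeled nucleotide molar mass (g/mol) at GC fraction ``gc``."""
        return self.mw_intercept + self.mw_slope * gc

    def as_dict(self) -> dict:
        return asdict(self)


DEFAULT_MODEL = LabelingModel()


def density_to_gc(w_light: float, model: LabelingModel = DEFAULT_MODEL) -> float:
    """GC fraction implied by an *unlabeled* buoyant density ``w_light`` (g/ml).

    Inverts the linear GC–density calibration; results outside [0, 1] are
    clipped with a warning (densities slightly outside the calibrated band
    occur for noisy weighted means).
    """
    if not math.isfinite(w_light):
        raise ValueError(f"non-finite unlabeled density: {w_light!r}")
    g = (w_light - model.gc_intercept) / model.gc_slope
    if -1e-9 <= g < 0.0 or 1.0 < g <= 1.0 + 1e-9:  # float round-off only
        return min(max(g, 0.0), 1.0)
    if g < 0.0 or g > 1.0:
        warnings.warn(
            f"GC fraction {g:.4f} from density {w_light:.5f} g/ml clipped to [0, 1]",
            stacklevel=2,
        )
        g = min(max(g, 0.0), 1.0)
    return g


def gc_to_density(gc: float, model: LabelingModel = DEFAULT_MODEL) -> float:
    """Unlabeled buoyant density (g/ml) of DNA with GC fraction ``gc``."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"GC fraction outside [0, 1]: {gc}")
    return model.gc_intercept + model.gc_slope * gc


def excess_atom_fraction(
    w_light: float, delta_w: float, model: LabelingModel = DEFAULT_MODEL
) -> float:
    """Excess atom fraction of 13C implied by a buoyant-density shift.

    Parameters
    ----------
    w_light
        Weighted-mean buoyant density of the taxon in the *control*
        (unlabeled) gradient, g/ml.
    delta_w
        Labeled-minus-control weighted-mean density difference, g/ml.  Small
        negative shifts are allowed and yield negative EAF so that
        control–control comparisons stay symmetric around zero.

    Returns
    -------
    float
        Atom fraction of the taxon's DNA carbon that is 13C in excess of
        natural abundance (multiply by 100 for atom percent excess).
    """
    if w_light <= 0:
        raise ValueError(f"unlabeled density must be positive: {w_light}")
    gc = density_to_gc(w_light, model)
    m_light = model.nucleotide_mass(gc)
    m_labeled = m_light * (1.0 + delta_w / w_light)
    dm_max = model.carbon_atoms(gc) * model.delta_mass_13c
    return (m_labeled - m_light) / dm_max * (1.0 - model.natural_13c)


def atom_percent_excess(
    w_light: float, delta_w: float, model: LabelingModel = DEFAULT_MODEL
) -> float:
    """``excess_atom_fraction`` expressed in percent (APE)."""
    return 100.0 * excess_atom_fraction(w_light, delta_w, model)


def density_shift_for_eaf(
    w_light: float, eaf: float, model: LabelingModel = DEFAULT_MODEL
) -> float:
    """Buoyant-density shift (g/ml) that a given excess atom fraction produces.

    Exact inverse of :func:`excess_atom_fraction` at fixed ``w_light``; used
    by the gradient simulator to place labeled bands.
    """
    if not 0.0 <= eaf <= 1.0:
        raise ValueError(f"excess atom fraction outside [0, 1]: {eaf}")
    gc = density_to_gc(w_light, model)
    m_light = model.nucleotide_mass(gc)
    dm_max = model.carbon_atoms(gc) * model.delta_mass_13c
    return w_light * eaf * dm_max / ((1.0 - model.natural_13c) * m_light)
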