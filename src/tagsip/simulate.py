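"""Forward simulator of paired 13C/12C isopycnic gradients.

Generates the data structure the shift analysis assumes: ~50 fractions
spanning 1.66–1.77 g/ml, a community of taxa whose unlabeled band centers
follow the GC–density calibration, labeled bands displaced by the density
shift their true excess atom fraction implies, Gaussian band shapes
integrated over fraction intervals, multinomial amplicon sampling per
fraction, and lognormal noise on per-fraction DNA yield.  Refractive indices
are emitted by inverting the density calibration and adding measurement
noise, so the written tables look like real refractometry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import labeling
from .gradient_io import (
    FractionRecord,
    GradientProfile,
    refraction_to_density,
    density_to_refraction,
    write_gradient_table,
)
from .labeling import DEFAULT_MODEL, LabelingModel


@dataclass(frozen=True)
class SyntheticTaxon:
    """Ground truth for one simulated taxon.

    ``band_sigma`` is the standard deviation (g/ml) of the taxon's Gaussian
    band at diffusion–sedimentation equilibrium; 0.006 g/ml is an assumed
    default since band spread is not otherwise constrained.
    """

    otu_id: str
    gc: float
    rel_abundance: float
    true_eaf: float = 0.0
    band_sigma: float = 0.006

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError(f"{self.otu_id}: GC outside [0, 1]")
        if not 0.0 <= self.true_eaf <= 1.0:
            raise ValueError(f"{self.otu_id}: true EAF outside [0, 1]")
        if self.rel_abundance < 0:
            raise ValueError(f"{self.otu_id}: negative abundance")


@dataclass(frozen=True)
class GradientSimConfig:
    """Simulator settings (defaults mirror the study's gradient geometry)."""

    n_fractions: int = 50
    density_min: float = 1.66
    density_max: float = 1.77
    reads_per_fraction: int = 20_000
    dna_total: float = 500.0  # ng recovered over the whole gradient
    dna_noise_cv: float = 0.05
    refraction_noise_sd: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.density_min >= self.density_max:
            raise ValueError("density_min must be < density_max")
        if self.n_fractions < 5:
            raise ValueError("need at least 5 fractions")


def validate_community(community: list[SyntheticTaxon]) -> None:
    total = sum(t.rel_abundance for t in community)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"community relative abundances sum to {total}, not 1")


def band_centers(
    community: list[SyntheticTaxon], model: LabelingModel = DEFAULT_MODEL
) -> pd.DataFrame:
    """Control and labeled band-center densities for every taxon."""
    rows = []
    for t in community:
        control = labeling.gc_to_density(t.gc, model)
        shift = labeling.density_shift_for_eaf(control, t.true_eaf, model)
        rows.append(
            {
                "otu_id": t.otu_id,
                "gc": t.gc,
                "rel_abundance": t.rel_abundance,
                "true_eaf": t.true_eaf,
                "band_sigma": t.band_sigma,
                "control_center": control,
                "labeled_center": control + shift,
            }
        )
    return pd.DataFrame(rows)


def _fraction_masses(
    centers: np.ndarray,
    sigmas: np.ndarray,
    abundances: np.ndarray,
    edges: np.ndarray,
) -> np.ndarray:
    """Taxa x fractions expected DNA-mass matrix.

    Each taxon's Gaussian band is integrated over each fraction's half-open
    density interval (lower edge inclusive), which conserves the band mass
    that falls inside the gradient exactly.
    """
    z_hi = (edges[None, 1:] - centers[:, None]) / sigmas[:, None]
    z_lo = (edges[None, :-1] - centers[:, None]) / sigmas[:, None]
    frac = stats.norm.cdf(z_hi) - stats.norm.cdf(z_lo)
    return abundances[:, None] * frac


def simulate_gradient(
    community: list[SyntheticTaxon],
    centers: np.ndarray,
    cfg: GradientSimConfig,
    rng: np.random.Generator,
    sample_id: str,
    isotope: str,
) -> GradientProfile:
    """Simulate one gradient given each taxon's band center."""
    edges = np.linspace(cfg.density_min, cfg.density_max, cfg.n_fractions + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    sigmas = np.array([t.band_sigma for t in community])
    abund = np.array([t.rel_abundance for t in community])

    out_of_range = [
        t.otu_id
        for t, c in zip(community, centers)
        if c < cfg.density_min - 3 * t.band_sigma
        or c > cfg.density_max + 3 * t.band_sigma
    ]
    if out_of_range:
        warnings.warn(
            f"band centers outside the gradient by > 3 sigma: {out_of_range}",
            stacklevel=2,
        )

    mass = _fraction_masses(centers, sigmas, abund, edges)  # taxa x fractions
    frac_mass = mass.sum(axis=0)
    reads = np.broadcast_to(
        np.asarray(cfg.reads_per_fraction), (cfg.n_fractions,)
    )

    dna_noise = rng.lognormal(
        mean=-0.5 * np.log1p(cfg.dna_noise_cv**2),
        sigma=np.sqrt(np.log1p(cfg.dna_noise_cv**2)),
        size=cfg.n_fractions,
    ) if cfg.dna_noise_cv > 0 else np.ones(cfg.n_fractions)
    dna = cfg.dna_total * frac_mass * dna_noise

    n_c_true = density_to_refraction(mids)
    n_c = n_c_true + (
        rng.normal(0.0, cfg.refraction_noise_sd, cfg.n_fractions)
        if cfg.refraction_noise_sd > 0
        else 0.0
    )
    measured_rho = refraction_to_density(n_c)

    fractions = []
    otu_ids = [t.otu_id for t in community]
    for f in range(cfg.n_fractions):
        if frac_mass[f] > 0:
            counts = rng.multinomial(int(reads[f]), mass[:, f] / frac_mass[f])
        else:
            counts = np.zeros(len(community), dtype=int)
        fractions.append(
            FractionRecord(
                fraction_id=f + 1,
                buoyant_density=float(measured_rho[f]),
                dna_mass=float(dna[f]),
                counts=dict(zip(otu_ids, (int(c) for c in counts))),
                refractive_index=float(n_c[f]),
            )
        )
    # refractometry noise can invert neighboring fractions; order by the
    # measured density, as the analysis does, keeping each fraction's counts
    fractions.sort(key=lambda fr: fr.buoyant_density)
    for i, fr in enumerate(fractions):
        fr.fraction_id = i + 1
    return GradientProfile(sample_id=sample_id, isotope=isotope, fractions=fractions)


def simulate_pair(
    community: list[SyntheticTaxon],
    cfg: GradientSimConfig = GradientSimConfig(),
    model: LabelingModel = DEFAULT_MODEL,
) -> tuple[GradientProfile, GradientProfile, pd.DataFrame]:
    """Simulate a paired 13C/12C gradient experiment.

    Returns the labeled profile, the control profile and the ground-truth
    table (otu_id, gc, rel_abundance, true_eaf, band centers).  The same
    seed always reproduces the same pair.
    """
    validate_community(community)
    truth = band_centers(community, model)
    rng = np.random.default_rng(cfg.seed)
    labeled = simulate_gradient(
        community, truth["labeled_center"].to_numpy(), cfg, rng,
        sample_id="sim_13C", isotope="13C",
    )
    control = simulate_gradient(
        community, truth["control_center"].to_numpy(), cfg, rng,
        sample_id="sim_12C", isotope="12C",
    )
    return labeled, control, truth


def make_community(
    n_taxa: int = 200,
    n_labeled: int = 30,
    seed: int = 0,
    eaf_range: tuple[float, float] = (0.09, 0.55),
    gc_range: tuple[float, float] = (0.30, 0.65),
    abundance_sigma: float = 1.5,
    band_sigma: float = 0.006,
) -> list[SyntheticTaxon]:
    """Random community shaped after a coastal amplicon survey.

    Relative abundances are lognormal (a few dominant taxa, a long rare
    tail); GC contents span the marine bacterioplankton range; a minority of
    taxa are truly labeled with EAF drawn uniformly from ``eaf_range``,
    scattered across the abundance spectrum.
    """
    rng = np.random.default_rng(seed)
    abund = rng.lognormal(0.0, abundance_sigma, n_taxa)
    abund /= abund.sum()
    gc = rng.uniform(*gc_range, n_taxa)
    eaf = np.zeros(n_taxa)
    labeled_idx = rng.choice(n_taxa, size=n_labeled, replace=False)
    eaf[labeled_idx] = rng.uniform(*eaf_range, n_labeled)
    width = int(np.ceil(np.log10(n_taxa + 1)))
    community = [
        SyntheticTaxon(
            otu_id=f"OTU{i + 1:0{width}d}",
            gc=float(gc[i]),
            rel_abundance=float(abund[i]),
            true_eaf=float(eaf[i]),
            band_sigma=band_sigma,
        )
        for i in range(n_taxa)
    ]
    # exact renormalization after float round-trips
    total = sum(t.rel_abundance for t in community)
    return [
        SyntheticTaxon(t.otu_id, t.gc, t.rel_abundance / total, t.true_eaf, t.band_sigma)
        for t in community
    ]


def make_study_fixture(
    seed: int,
    outdir: str | Path | None = None,
    n_taxa: int = 200,
    n_labeled: int = 30,
    cfg: GradientSimConfig | None = None,
    model: LabelingModel = DEFAULT_MODEL,
) -> tuple[GradientProfile, GradientProfile, pd.DataFrame]:
    """Paired-gradient fixture: ~200 taxa, ~30 truly labeled at EAF 0.09–0.55.

    When ``outdir`` is given, writes ``labeled.tsv``, ``control.tsv`` and
    ``truth.tsv`` there; a fixed seed reproduces byte-identical files.
    """
    community = make_community(n_taxa=n_taxa, n_labeled=n_labeled, seed=seed)
    cfg = cfg or GradientSimConfig(seed=seed)
    labeled, control, truth = simulate_pair(community, cfg, model)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gradient_table(labeled, outdir / "labeled.tsv")
        write_gradient_table(control, outdir / "control.tsv")
        truth.to_csv(outdir / "truth.tsv", sep="\t", index=False, float_format="%.8f")
    return labeled, control, truth
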