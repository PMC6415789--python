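"""Truth-tagged synthetic DNA-SIP experiments.

Generates four-sample amplicon experiments (12C-light, 12C-heavy, 13C-light,
13C-heavy) with known ground truth, emulating the statistical structure the
labelling screen assumes:

1. a community of taxa with long-tailed (lognormal) relative abundances,
   per-taxon genomic GC content, and a chosen subset of taxa carrying excess
   13C;
2. a deterministic buoyant-density model: in CsCl, DNA density rises with GC
   content and with 13C incorporation,

       rho = 1.660 + 0.098 * GC + 0.036 * atom_excess   [g/mL]

   (1.660 g/mL for GC-free unlabelled DNA; +0.036 g/mL for fully labelled);
3. gradient fractionation: each taxon's DNA spreads as a Gaussian around its
   mean density (width sigma_rho) over a 12-bin gradient, and the bins
   containing 1.725 and 1.700 g/mL are sequenced as the heavy and light
   fraction samples;
4. sequencing: each sample is an independent multinomial draw of fixed depth
   from that fraction's renormalised taxon composition.

The 12C samples are always generated with atom excess forced to zero, so the
label affects the 13C samples only; a taxon's truth flag is simply
``atom_excess > 0``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .io import FractionMeta, SipCountTable

__all__ = [
    "DENSITY_BASE",
    "DENSITY_GC_SLOPE",
    "DENSITY_LABEL_SHIFT",
    "CommunityProfile",
    "GradientConfig",
    "SimulatedExperiment",
    "simulate_community",
    "buoyant_density",
    "fractionate_taxon",
    "sample_reads",
    "simulate_sip_experiment",
    "ri_to_density",
    "write_truth_table",
]

#: Buoyant density of hypothetical GC-free, unlabelled DNA (g/mL).
DENSITY_BASE = 1.660
#: Density increase per unit GC fraction (g/mL).
DENSITY_GC_SLOPE = 0.098
#: Density increase for fully 13C-labelled DNA (g/mL).
DENSITY_LABEL_SHIFT = 0.036

# CsCl refractive-index -> density calibration (AR200-style refractometer)
_RI_SLOPE = 10.8601
_RI_INTERCEPT = -13.4974
_RI_RANGE = (1.33, 1.46)


@dataclass
class CommunityProfile:
    """A synthetic community: abundances, GC content and label status."""

    taxon_ids: list[str]
    abundances: np.ndarray  # relative, sums to 1
    gc: np.ndarray  # genomic GC fraction in [0, 1]
    atom_excess: np.ndarray  # excess 13C atom fraction in [0, 1]; 0 = unlabelled

    def __post_init__(self) -> None:
        self.taxon_ids = list(self.taxon_ids)
        self.abundances = np.asarray(self.abundances, dtype=float)
        self.gc = np.asarray(self.gc, dtype=float)
        self.atom_excess = np.asarray(self.atom_excess, dtype=float)
        n = len(self.taxon_ids)
        for name, arr in (
            ("abundances", self.abundances),
            ("gc", self.gc),
            ("atom_excess", self.atom_excess),
        ):
            if arr.shape != (n,):
                raise ValidationError(f"{name} must have shape ({n},), got {arr.shape}")
        if np.any(self.abundances < 0):
            raise ValidationError("abundances must be non-negative")
        if abs(self.abundances.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"abundances must sum to 1 (got {self.abundances.sum():.12f})"
            )
        for name, arr in (("gc", self.gc), ("atom_excess", self.atom_excess)):
            if np.any((arr < 0) | (arr > 1)):
                raise ValidationError(f"{name} values must lie in [0, 1]")

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def labelled(self) -> np.ndarray:
        """Ground-truth boolean flag: carries excess 13C."""
        return self.atom_excess > 0


@dataclass(frozen=True)
class GradientConfig:
    """Geometry of the simulated CsCl gradient and sequencing depth.

    Twelve uniform density bins spanning 1.66-1.78 g/mL by default; the bins
    containing ``heavy_density`` (1.725) and ``light_density`` (1.700) are
    the ones sequenced. ``sigma_rho`` is the within-taxon density spread of
    DNA in the gradient.
    """

    n_fractions: int = 12
    density_min: float = 1.66
    density_max: float = 1.78
    heavy_density: float = 1.725
    light_density: float = 1.700
    sigma_rho: float = 0.006
    depth: int = 50_000

    def __post_init__(self) -> None:
        if self.n_fractions < 2:
            raise ValidationError("need at least two gradient fractions")
        if not (self.density_min < self.density_max):
            raise ValidationError("density_min must be below density_max")
        if self.sigma_rho <= 0:
            raise ValidationError("sigma_rho must be positive")
        if self.depth < 0:
            raise ValidationError("depth must be non-negative")
        for name in ("heavy_density", "light_density"):
            rho = getattr(self, name)
            if not (self.density_min <= rho < self.density_max):
                raise ValidationError(
                    f"{name}={rho} outside the gradient range "
                    f"[{self.density_min}, {self.density_max})"
                )
        if self.heavy_bin == self.light_bin:
            raise ValidationError(
                "heavy_density and light_density fall in the same fraction; "
                "increase n_fractions or separate the densities"
            )

    @property
    def bin_edges(self) -> np.ndarray:
        return np.linspace(self.density_min, self.density_max, self.n_fractions + 1)

    def bin_index(self, density: float) -> int:
        """Index of the half-open bin [edge_j, edge_{j+1}) containing density."""
        edges = self.bin_edges
        if not (edges[0] <= density < edges[-1]):
            raise ValidationError(f"density {density} outside the gradient range")
        return int(np.searchsorted(edges, density, side="right") - 1)

    @property
    def heavy_bin(self) -> int:
        return self.bin_index(self.heavy_density)

    @property
    def light_bin(self) -> int:
        return self.bin_index(self.light_density)


@dataclass
class SimulatedExperiment:
    """A simulated four-sample SIP experiment with ground truth.

    ``compositions`` maps isotope -> (taxa x fractions) matrix of expected
    read proportions per fraction (each column sums to 1), useful for power
    and calibration diagnostics before multinomial noise.
    """

    table: SipCountTable
    truth: pd.Series  # bool per taxon: carries excess 13C
    profile: CommunityProfile
    config: GradientConfig
    seed: int | None
    compositions: dict[str, np.ndarray] = field(default_factory=dict)

    def expected_counts(self, isotope: str, fraction_role: str) -> np.ndarray:
        """Expected per-taxon reads in the given sequenced sample."""
        j = self.config.heavy_bin if fraction_role == "heavy" else self.config.light_bin
        return self.compositions[isotope][:, j] * self.config.depth


# ---------------------------------------------------------------------------
# elementary pieces
# ---------------------------------------------------------------------------


def buoyant_density(gc, atom_excess_13c):
    """Mean CsCl buoyant density (g/mL) of a taxon's DNA.

    Linear in genomic GC fraction and in excess 13C atom fraction; both
    inputs must lie in [0, 1]. Accepts scalars or arrays.
    """
    gc_arr = np.asarray(gc, dtype=float)
    ae = np.asarray(atom_excess_13c, dtype=float)
    if np.any((gc_arr < 0) | (gc_arr > 1)):
        raise ValidationError("gc must lie in [0, 1]")
    if np.any((ae < 0) | (ae > 1)):
        raise ValidationError("atom_excess_13c must lie in [0, 1]")
    out = DENSITY_BASE + DENSITY_GC_SLOPE * gc_arr + DENSITY_LABEL_SHIFT * ae
    return float(out) if out.ndim == 0 else out


def fractionate_taxon(
    mean_density: float, sigma_rho: float, config: GradientConfig | None = None
) -> np.ndarray:
    """Per-fraction mass proportions of one taxon's DNA in the gradient.

    Gaussian(mean_density, sigma_rho) probability mass within each density
    bin, renormalised over the gradient range (truncation). Sums to 1.
    """
    config = config or GradientConfig()
    if sigma_rho <= 0:
        raise ValidationError("sigma_rho must be positive")
    props = _fraction_matrix(np.array([mean_density]), sigma_rho, config)[0]
    return props


def _fraction_matrix(
    mean_densities: np.ndarray, sigma_rho: float, config: GradientConfig
) -> np.ndarray:
    """(taxa x fractions) Gaussian bin masses, truncated to the gradient."""
    edges = config.bin_edges
    z = (edges[None, :] - mean_densities[:, None]) / sigma_rho
    cdf = stats.norm.cdf(z)
    mass = np.diff(cdf, axis=1)
    total = cdf[:, -1] - cdf[:, 0]
    out = np.empty_like(mass)
    ok = total > 1e-12
    out[ok] = mass[ok] / total[ok, None]
    if np.any(~ok):
        # limit of the truncated Gaussian: all mass collapses onto the bin
        # nearest the mean (interior bin if the mean is inside the range,
        # else the boundary bin)
        centers = 0.5 * (edges[:-1] + edges[1:])
        for i in np.nonzero(~ok)[0]:
            out[i] = 0.0
            out[i, int(np.argmin(np.abs(centers - mean_densities[i])))] = 1.0
    return out


def sample_reads(
    composition: Sequence[float], depth: int, seed=None
) -> np.ndarray:
    """Multinomial read draw of ``depth`` reads from a composition.

    ``seed`` may be an int, a Generator, or None (fresh entropy).
    """
    comp = np.asarray(composition, dtype=float)
    if np.any(comp < 0):
        raise ValidationError("composition proportions must be non-negative")
    if abs(comp.sum() - 1.0) > 1e-9:
        raise ValidationError(f"composition must sum to 1 (got {comp.sum():.12f})")
    if depth < 0:
        raise ValidationError("depth must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.multinomial(int(depth), comp / comp.sum())


def ri_to_density(refractive_index: float) -> float:
    """CsCl solution density (g/mL) from a refractometer reading.

    Standard linear calibration rho = 10.8601 * n - 13.4974 for CsCl at
    20 degrees C. Readings must lie in the refractometer range [1.33, 1.46];
    values mapping below the CsCl gradient working range are accepted but
    flagged with a warning (a reading of 1.3330 is essentially water).
    """
    ri = float(refractive_index)
    if not (_RI_RANGE[0] <= ri <= _RI_RANGE[1]):
        raise ValidationError(
            f"refractive index {ri} outside the supported range {_RI_RANGE}"
        )
    rho = _RI_SLOPE * ri + _RI_INTERCEPT
    if rho < 1.60:
        warnings.warn(
            f"density {rho:.5f} g/mL is below the CsCl gradient working range; "
            "check the refractometer reading",
            stacklevel=2,
        )
    return rho


# ---------------------------------------------------------------------------
# community + experiment generation
# ---------------------------------------------------------------------------


def simulate_community(
    n_taxa: int,
    abundance_mu: float = 0.0,
    abundance_sigma: float = 1.5,
    gc_low: float = 0.40,
    gc_high: float = 0.50,
    labelled_fraction: float = 0.05,
    atom_excess: float = 1.0,
    seed=None,
) -> CommunityProfile:
    """Draw a synthetic community profile.

    Relative abundances are normalised draws from lognormal(mu, sigma) — a
    long-tailed rank-abundance curve typical of 16S surveys. GC content is
    uniform on [gc_low, gc_high]. Exactly ``round(labelled_fraction *
    n_taxa)`` taxa (chosen uniformly at random) carry ``atom_excess``
    excess 13C; the rest carry 0. Reproducible for a fixed seed.
    """
    if n_taxa < 1:
        raise ValidationError("n_taxa must be at least 1")
    if abundance_sigma < 0:
        raise ValidationError("abundance_sigma must be non-negative")
    if not (0.0 <= gc_low <= gc_high <= 1.0):
        raise ValidationError("need 0 <= gc_low <= gc_high <= 1")
    if not (0.0 <= labelled_fraction <= 1.0):
        raise ValidationError("labelled_fraction must lie in [0, 1]")
    if not (0.0 <= atom_excess <= 1.0):
        raise ValidationError("atom_excess must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    raw = rng.lognormal(mean=abundance_mu, sigma=abundance_sigma, size=n_taxa)
    abundances = raw / raw.sum()
    gc = rng.uniform(gc_low, gc_high, size=n_taxa)
    n_labelled = int(round(labelled_fraction * n_taxa))
    ae = np.zeros(n_taxa)
    if n_labelled:
        chosen = rng.choice(n_taxa, size=n_labelled, replace=False)
        ae[chosen] = atom_excess
    width = max(4, len(str(n_taxa)))
    ids = [f"Otu{i + 1:0{width}d}" for i in range(n_taxa)]
    return CommunityProfile(taxon_ids=ids, abundances=abundances, gc=gc, atom_excess=ae)


def simulate_sip_experiment(
    profile: CommunityProfile,
    config: GradientConfig | None = None,
    seed=None,
    treatment: str = "synthetic",
) -> SimulatedExperiment:
    """Generate the four sequenced fraction samples for one experiment.

    The 12C incubation is simulated with every taxon's atom excess forced to
    zero (the unlabelled control), the 13C incubation with the profile's
    atom excess. For each isotope the community is fractionated on the
    gradient, the heavy/light bins' compositions are renormalised, and each
    of the four samples is an independent multinomial draw of ``config.depth``
    reads. Identical seeds give identical experiments.
    """
    config = config or GradientConfig()
    seed_int = None if seed is None else int(seed)
    ss = np.random.SeedSequence(seed_int)
    rngs = [np.random.default_rng(s) for s in ss.spawn(4)]

    abund = profile.abundances
    compositions: dict[str, np.ndarray] = {}
    for isotope, ae in (("C12", np.zeros(profile.n_taxa)), ("C13", profile.atom_excess)):
        rho = buoyant_density(profile.gc, ae)
        mass = _fraction_matrix(np.asarray(rho), config.sigma_rho, config)
        weighted = abund[:, None] * mass
        col_tot = weighted.sum(axis=0)
        if col_tot[config.heavy_bin] <= 0 or col_tot[config.light_bin] <= 0:
            raise ValidationError(
                "no DNA mass in a sequenced fraction; community and gradient "
                "configuration are inconsistent"
            )
        comp = np.zeros_like(weighted)
        nz = col_tot > 0
        comp[:, nz] = weighted[:, nz] / col_tot[nz]
        compositions[isotope] = comp

    sample_order = [
        ("C12", "light"),
        ("C12", "heavy"),
        ("C13", "light"),
        ("C13", "heavy"),
    ]
    counts = np.empty((profile.n_taxa, 4), dtype=np.int64)
    sample_ids = []
    meta = {}
    for j, ((isotope, role), rng) in enumerate(zip(sample_order, rngs)):
        bin_j = config.heavy_bin if role == "heavy" else config.light_bin
        counts[:, j] = sample_reads(compositions[isotope][:, bin_j], config.depth, rng)
        sid = f"{treatment}_{isotope}_{role}"
        sample_ids.append(sid)
        meta[sid] = FractionMeta(
            isotope=isotope,
            fraction_role=role,
            treatment=treatment,
            density=config.heavy_density if role == "heavy" else config.light_density,
        )

    table = SipCountTable(
        otu_ids=list(profile.taxon_ids),
        sample_ids=sample_ids,
        counts=counts,
        meta=meta,
    )
    truth = pd.Series(profile.labelled, index=list(profile.taxon_ids), name="labelled")
    return SimulatedExperiment(
        table=table,
        truth=truth,
        profile=profile,
        config=config,
        seed=seed_int,
        compositions=compositions,
    )


def write_truth_table(experiment: SimulatedExperiment, path: str | Path) -> None:
    """Write the ground-truth TSV (otu_id, labelled, atom_excess, gc)."""
    frame = pd.DataFrame(
        {
            "otu_id": experiment.profile.taxon_ids,
            "labelled": experiment.truth.to_numpy(),
            "atom_excess": experiment.profile.atom_excess,
            "gc": experiment.profile.gc,
        }
    )
    frame.to_csv(path, sep="\t", index=False)
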