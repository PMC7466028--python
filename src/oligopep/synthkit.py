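"""Seeded synthetic-data generators for every input class of the pipeline.

Each generator draws from a named substream of one integer seed, so adding a
generator never perturbs existing fixtures, and identical (seed, config)
pairs are byte-identical.  The generators share their forward models with
the analysis modules (the two-state equations come from :mod:`dscfit`), so
there is a single source of truth for every formula.

Defaults encode the study conditions: a free 17-bp duplex melting at
66.8 C with dH_M = 183 kcal/mol and dCp = 2 kcal/(mol*K); the peptide
conjugate at 68.8 C with dH_M = 246 and dCp = 1.4 plus an ~8 kcal/mol
intermediate component near 64 C; a 220 nm CD melt with midpoint 64 C; and
DNase I digests of the GCRE-carrying strand with the protein footprint
attenuating cleavage over bonds 5-9.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import dscfit
from .cdspec import CDSpectrum, MeltTrace
from .digestor import PeakList, fragment_oligo
from .dscfit import Thermogram, two_state_excess_cp, two_state_theta
from .errors import ConfigError, ProfileError
from .massbook import ModifiedOligo, mz_for_charges, ssdna_a

# Fixed substream tags: one integer seed fans out to independent generators.
_STREAMS = {"thermogram": 1, "cd_heating": 2, "cd_cooling": 3, "digest": 4,
            "spectrum": 5}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Named, reproducible substream of a single integer seed."""
    return np.random.default_rng([int(seed), _STREAMS[stream]])


# ---------------------------------------------------------------------------
# DSC thermograms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianSpec:
    """An extra heat-capacity component: (center K, sigma K, area kcal/mol)."""

    center: float
    sigma: float
    area: float


@dataclass(frozen=True)
class ThermogramConfig:
    """Forward-model parameters for one synthetic thermogram.

    Defaults are the free-duplex conditions (T_M = 66.8 C, dH_M = 183,
    dCp = 2); :func:`conjugate_thermogram_config` returns the bound-complex
    variant.  The folded baseline is linear ``b0 + b1*T``; the unfolded
    baseline is the folded one shifted by dCp, interpolated by the unfolded
    fraction.
    """

    t_m: float = 66.8 + dscfit.C_TO_K  # K
    dh_m: float = 183.0  # kcal/mol
    dcp: float = 2.0  # kcal/(mol*K)
    baseline_b0: float = -4.0  # kcal/(mol*K) at T = 0 K (linear coefficients)
    baseline_b1: float = 0.015  # kcal/(mol*K^2)
    gaussians: tuple[GaussianSpec, ...] = ()
    noise_sigma: float = 0.05  # kcal/(mol*K)
    t_min: float = 25.0 + dscfit.C_TO_K
    t_max: float = 92.0 + dscfit.C_TO_K
    n_points: int = 269
    include_two_state_peak: bool = True
    label: str = "dsDNA"


def duplex_thermogram_config(**overrides) -> ThermogramConfig:
    """Free-duplex study conditions."""
    return replace(ThermogramConfig(), **overrides)


def conjugate_thermogram_config(**overrides) -> ThermogramConfig:
    """Bound-complex study conditions (T_M = 68.8 C, dH_M = 246, dCp = 1.4)."""
    cfg = ThermogramConfig(
        t_m=68.8 + dscfit.C_TO_K,
        dh_m=246.0,
        dcp=1.4,
        label="dsDNA*-PEP",
    )
    return replace(cfg, **overrides)


#: Component-resolved transition layouts for the deconvolution picture:
#: duplex-ends relaxation (lowest center), cooperatively melting peptide
#: (middle, conjugate only), and the core duplex transition (highest).
#: Centers/widths are separated by >= 2 sigma so the mixture is resolvable;
#: areas sum to the calorimetric enthalpy of each system.
DUPLEX_COMPONENTS = (
    GaussianSpec(56.0 + dscfit.C_TO_K, 2.5, 25.0),  # ends relaxation
    GaussianSpec(66.8 + dscfit.C_TO_K, 1.5, 158.0),  # core duplex melting
)
CONJUGATE_COMPONENTS = (
    GaussianSpec(58.0 + dscfit.C_TO_K, 2.5, 30.0),  # ends relaxation
    GaussianSpec(64.0 + dscfit.C_TO_K, 2.0, 8.0),  # peptide helix melting
    GaussianSpec(68.8 + dscfit.C_TO_K, 1.5, 208.0),  # core duplex melting
)


def component_thermogram_config(conjugate: bool = True, **overrides) -> ThermogramConfig:
    """Thermogram whose transition is the resolved component mixture.

    The two-state peak is replaced by the Gaussian components themselves
    (ends / peptide / core for the conjugate; ends / core for the free
    duplex); the dCp step follows the enthalpy-weighted progress.  This is
    the trace on which Gaussian deconvolution is well-posed.
    """
    base = conjugate_thermogram_config() if conjugate else ThermogramConfig()
    cfg = replace(
        base,
        include_two_state_peak=False,
        gaussians=CONJUGATE_COMPONENTS if conjugate else DUPLEX_COMPONENTS,
    )
    return replace(cfg, **overrides)


def simulate_thermogram(config: ThermogramConfig, seed: int) -> Thermogram:
    """Two-state thermogram with folded/unfolded baselines and extra peaks.

    Cp(T) = (b0 + b1*T) + progress(T)*dCp + dH(T)*dtheta/dT
            + sum of Gaussian components + N(0, noise_sigma^2)

    where ``progress`` is the enthalpy-weighted unfolding progress (the
    normalized running integral of the total excess heat capacity).  For a
    pure two-state trace this equals the van't Hoff theta up to the small
    dCp*(T-T_M)/dH_M correction.  With ``include_two_state_peak=False`` the
    transition itself is emulated as the sum of the configured Gaussian
    components (the component-resolved picture the deconvolution assumes)
    while the dCp step still follows the overall progress.
    """
    if config.n_points < 50:
        raise ConfigError(
            f"temperature grid too coarse: {config.n_points} points (< 50)"
        )
    if config.noise_sigma < 0:
        raise ConfigError("noise_sigma must be >= 0")
    rng = stream_rng(seed, "thermogram")
    T = np.linspace(config.t_min, config.t_max, config.n_points)
    excess = np.zeros_like(T)
    if config.include_two_state_peak:
        excess += two_state_excess_cp(T, config.t_m, config.dh_m, config.dcp)
    for g in config.gaussians:
        excess += dscfit.GaussianComponent(g.center, g.sigma, g.area).evaluate(T)
    integral = np.concatenate(
        ([0.0], np.cumsum(0.5 * (excess[1:] + excess[:-1]) * np.diff(T)))
    )
    if integral[-1] > 0:
        progress = integral / integral[-1]
    else:
        progress = two_state_theta(T, config.t_m, config.dh_m, config.dcp)
    cp = (
        config.baseline_b0
        + config.baseline_b1 * T
        + progress * config.dcp
        + excess
        + rng.normal(0.0, config.noise_sigma, size=T.shape)
    )
    return Thermogram(temperature=T, cp=cp, label=config.label)


# ---------------------------------------------------------------------------
# CD melts and spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CDMeltConfig:
    """Sigmoidal 220 nm melt between two linear baselines.

    The helix signal at 220 nm is negative and rises toward zero on
    melting; ``amplitude`` is the total transition height (mdeg),
    ``width`` the logistic scale (C).  ``noise_sigma`` is expressed as a
    fraction of the amplitude.  ``hysteresis`` shifts the cooling midpoint
    down by that many degrees.
    """

    t_m: float = 64.0  # C
    amplitude: float = 15.0  # mdeg
    width: float = 2.5  # C
    baseline_intercept: float = -20.0  # mdeg (folded baseline at 0 C)
    baseline_slope: float = 0.02  # mdeg / C
    noise_sigma: float = 0.02  # fraction of amplitude
    hysteresis: float = 0.0  # C
    t_min: float = 0.0
    t_max: float = 90.0
    step: float = 1.0
    wavelength: float = 220.0


def _sigmoid_melt(T, cfg: CDMeltConfig, t_m: float):
    base = cfg.baseline_intercept + cfg.baseline_slope * T
    if cfg.amplitude == 0.0:
        return base
    return base + cfg.amplitude / (1.0 + np.exp(-(T - t_m) / cfg.width))


def simulate_cd_melt(config: CDMeltConfig, seed: int) -> tuple[MeltTrace, MeltTrace]:
    """Heating and cooling melt traces with independent noise."""
    if config.noise_sigma < 0:
        raise ConfigError("noise_sigma must be >= 0")
    T = np.arange(config.t_min, config.t_max + 0.5 * config.step, config.step)
    sigma = config.noise_sigma * abs(config.amplitude)
    rng_h = stream_rng(seed, "cd_heating")
    rng_c = stream_rng(seed, "cd_cooling")
    y_heat = _sigmoid_melt(T, config, config.t_m) + rng_h.normal(0, sigma, T.shape)
    t_cool = T[::-1]
    y_cool = _sigmoid_melt(t_cool, config, config.t_m - config.hysteresis)
    y_cool = y_cool + rng_c.normal(0, sigma, T.shape)
    heating = MeltTrace(T, y_heat, "heating", config.wavelength)
    cooling = MeltTrace(t_cool, y_cool, "cooling", config.wavelength)
    return heating, cooling


def alpha_helix_band(wavelength: np.ndarray) -> np.ndarray:
    """Template alpha-helix CD band shape (mdeg, unit depth at 222 nm).

    Double minimum at 208/222 nm and a positive band at 192 nm — the
    canonical helix signature used by the difference-spectrum check.
    """
    wl = np.asarray(wavelength, dtype=float)
    return (
        -1.0 * np.exp(-0.5 * ((wl - 222.0) / 6.5) ** 2)
        - 1.0 * np.exp(-0.5 * ((wl - 208.0) / 5.5) ** 2)
        + 1.8 * np.exp(-0.5 * ((wl - 192.0) / 4.5) ** 2)
    )


def b_dna_band(wavelength: np.ndarray) -> np.ndarray:
    """Template B-DNA CD band shape: positive ~275 nm, negative ~245 nm."""
    wl = np.asarray(wavelength, dtype=float)
    return (
        1.0 * np.exp(-0.5 * ((wl - 275.0) / 12.0) ** 2)
        - 1.0 * np.exp(-0.5 * ((wl - 245.0) / 10.0) ** 2)
    )


@dataclass(frozen=True)
class CDSpectrumConfig:
    """Synthetic CD spectrum: weighted band templates plus noise."""

    dna_weight: float = 10.0  # mdeg
    helix_weight: float = 0.0  # mdeg
    noise_sigma: float = 0.1  # mdeg
    temperature: float = 25.0  # C
    concentration: float = 0.4  # mg/mL
    wl_min: float = 190.0
    wl_max: float = 350.0
    step: float = 1.0
    label: str = "dsDNA"


def simulate_cd_spectrum(config: CDSpectrumConfig, seed: int) -> CDSpectrum:
    rng = stream_rng(seed, "spectrum")
    wl = np.arange(config.wl_min, config.wl_max + 0.5 * config.step, config.step)
    y = config.dna_weight * b_dna_band(wl) + config.helix_weight * alpha_helix_band(wl)
    y = y + rng.normal(0.0, config.noise_sigma, wl.shape)
    return CDSpectrum(
        wavelength=wl,
        ellipticity=y,
        temperature=config.temperature,
        label=config.label,
        concentration=config.concentration,
    )


# ---------------------------------------------------------------------------
# DNase I digest peak lists
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DigestConfig:
    """Partial-digest sampling model for one strand.

    Each of ``n_events`` parent molecules receives 0, 1 or 2 cuts
    (``cut_number_probs``); cut bonds are drawn with probability
    proportional to ``propensities`` times the protection ``attenuation``
    inside ``mask_bonds`` (1-based inclusive bond span, or None for no
    protection).  The resulting fragment census is ionized: each fragment
    molecule draws a charge state from ``charge_probs`` (for z = 1..6),
    predicted m/z is perturbed by relative N(0, ppm_sigma^2) error, and the
    per-(species, z) area gets log-normal noise at the stated CV.
    """

    parent: ModifiedOligo = field(default_factory=ssdna_a)
    propensities: tuple[float, ...] | None = None  # per bond; None = uniform
    mask_bonds: tuple[int, int] | None = None
    attenuation: float = 1.0
    n_events: int = 10_000
    cut_number_probs: tuple[float, float, float] = (0.2, 0.5, 0.3)
    charge_probs: tuple[float, ...] = (0.05, 0.15, 0.30, 0.30, 0.15, 0.05)
    ppm_sigma: float = 5.0
    area_cv: float = 0.2
    label: str = "dsDNA"


def gcre_protected_digest_config(attenuation: float = 0.05, **overrides) -> DigestConfig:
    """Digest of the target strand with the footprint over the GCRE site.

    The peptide blocks DNase access over bonds 5-9 (the backbone within the
    5'-GTCATC-3' half-site at positions 5-10).
    """
    cfg = DigestConfig(
        mask_bonds=(5, 9), attenuation=attenuation, label="dsDNA*-PEP"
    )
    return replace(cfg, **overrides)


def _bond_weights(config: DigestConfig) -> np.ndarray:
    n_bonds = len(config.parent) - 1
    if config.propensities is None:
        w = np.ones(n_bonds)
    else:
        w = np.asarray(config.propensities, dtype=float)
        if len(w) != n_bonds or np.any(w < 0):
            raise ConfigError(
                f"propensities must be {n_bonds} non-negative values"
            )
    if config.mask_bonds is not None:
        lo, hi = config.mask_bonds
        if not 1 <= lo <= hi <= n_bonds:
            raise ConfigError(f"mask bonds [{lo},{hi}] outside 1..{n_bonds}")
        if not 0.0 <= config.attenuation <= 1.0:
            raise ConfigError("attenuation must be in [0, 1]")
        w = w.copy()
        w[lo - 1 : hi] *= config.attenuation
    if w.sum() <= 0:
        raise ConfigError("total cleavage propensity is zero")
    return w / w.sum()


def sample_fragment_census(
    config: DigestConfig, seed: int
) -> tuple[Counter, np.ndarray]:
    """Sample cut events and return (fragment span census, cuts per molecule).

    The census conserves molecules: a molecule with k cuts yields k+1
    fragments, so ``sum(census.values()) == sum(cuts + 1)``.
    """
    rng = stream_rng(seed, "digest")
    return _sample_census(rng, config)


def _sample_census(rng: np.random.Generator, config: DigestConfig):
    n = len(config.parent)
    p_bond = _bond_weights(config)
    probs = np.asarray(config.cut_number_probs, dtype=float)
    if probs.sum() <= 0 or np.any(probs < 0):
        raise ConfigError("cut_number_probs must be non-negative, nonzero")
    probs = probs / probs.sum()
    cuts = rng.choice(len(probs), size=config.n_events, p=probs)
    census: Counter = Counter()
    n_zero = int(np.sum(cuts == 0))
    if n_zero:
        census[(1, n)] += n_zero
    n_one = int(np.sum(cuts == 1))
    if n_one:
        bonds = rng.choice(len(p_bond), size=n_one, p=p_bond) + 1
        for b, c in zip(*np.unique(bonds, return_counts=True)):
            census[(1, int(b))] += int(c)
            census[(int(b) + 1, n)] += int(c)
    n_two = int(np.sum(cuts == 2))
    if n_two:
        # two independent draws; coinciding bonds collapse to a single cut
        b1 = rng.choice(len(p_bond), size=n_two, p=p_bond) + 1
        b2 = rng.choice(len(p_bond), size=n_two, p=p_bond) + 1
        lo = np.minimum(b1, b2)
        hi = np.maximum(b1, b2)
        for l, h in zip(lo, hi):
            l, h = int(l), int(h)
            if l == h:
                census[(1, l)] += 1
                census[(l + 1, n)] += 1
            else:
                census[(1, l)] += 1
                census[(l + 1, h)] += 1
                census[(h + 1, n)] += 1
    # Record effective cut counts (pair draws that collided count as 1)
    return census, cuts


def simulate_digest_peaks(config: DigestConfig, seed: int) -> PeakList:
    """Peak list for one digested sample (see :class:`DigestConfig`)."""
    rng = stream_rng(seed, "digest")
    census, _ = _sample_census(rng, config)
    charge_p = np.asarray(config.charge_probs, dtype=float)
    charge_p = charge_p / charge_p.sum()
    zs = np.arange(1, len(charge_p) + 1)

    mz_out, area_out = [], []
    for (s, e), count in sorted(census.items()):
        frag = fragment_oligo(config.parent, s, e)
        mass = frag.neutral_mass("monoisotopic")
        per_z = rng.multinomial(count, charge_p)
        mz_by_z = dict(mz_for_charges(mass, zs, scale="monoisotopic"))
        for z, cz in zip(zs, per_z):
            if cz == 0:
                continue
            mz_pred = mz_by_z[int(z)]
            mz_obs = mz_pred * (1.0 + rng.normal(0.0, config.ppm_sigma * 1e-6))
            area = float(cz)
            if config.area_cv > 0:
                sigma_ln = np.sqrt(np.log(1.0 + config.area_cv**2))
                area *= rng.lognormal(-0.5 * sigma_ln**2, sigma_ln)
            mz_out.append(mz_obs)
            area_out.append(area)
    return PeakList(
        mz=np.asarray(mz_out), area=np.asarray(area_out), label=config.label
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Bundle of generator configurations sharing one seed."""

    seed: int = 0
    thermogram: ThermogramConfig = field(default_factory=ThermogramConfig)
    cd_melt: CDMeltConfig = field(default_factory=CDMeltConfig)
    digest: DigestConfig = field(default_factory=DigestConfig)
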