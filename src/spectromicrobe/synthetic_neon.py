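"""Seeded synthetic multi-plot datasets with known ground truth.

The generator emulates the structure of a continental plot network
observed by an imaging spectrometer: ecoclimatic *domains* carry latent
environmental gradients; *plots* within a domain perturb those gradients;
*cores* within a plot add fine-scale sampling noise. From the latent
gradients it derives, with a fully known causal structure:

* foliar traits (gradient-driven plus trait-specific variation),
* 426-band canopy reflectance on 380-2500 nm: a smooth vegetation-like
  baseline, Gaussian absorption features whose depths are linear in the
  traits (the planted informative wavelengths), a NIR structural plateau
  term scaled by an independent "structure" covariate, and
  heteroscedastic sensor noise (SD = 0.5% of reflectance),
* core-level PLFA lipid concentrations for the standard biomarker set,
* 16S ASV count tables with uneven read depths (multinomial sampling,
  uniform-integer depths that deliberately straddle the 5000-read
  filter), taxonomy including Archaea and undefined labels to exercise
  the taxonomy filter,
* soil, climate/location and land-cover covariates structured by the same
  gradients, with observation dates aligned to a synthetic image date.

Signal calibration
------------------
Each planted microbial response is built as
``y = sqrt(s) * eta_hat + sqrt(1 - s) * noise`` where ``eta_hat`` is the
empirically standardized planted linear predictor and ``s`` is
``signal_fraction``; the realized R-squared between predictor and
response therefore matches ``signal_fraction`` up to sampling error.
``confound_weight`` moves the predictor between purely direct trait
effects (0) and purely shared environmental-gradient effects (1): at 1,
traits correlate with the responses only through the gradients, so
partial correlations controlling the gradients vanish.

Every draw's provenance is retained in :class:`SyntheticTruth`, making
parameter-recovery tests possible for each downstream stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .microbial_derive import (
    ACTINOMYCETALES,
    AM_FUNGI,
    GRAM_NEGATIVE,
    GRAM_POSITIVE,
    SAPROPHYTIC_FUNGI,
)
from .spectra_prep import SpectraMatrix, WavelengthGrid, default_aop_grid

# Gaussian absorption features: (centre nm, width nm, base depth).
# All centres sit inside the kept band ranges so trimming never removes them.
ABSORPTION_FEATURES: tuple[tuple[float, float, float], ...] = (
    (490.0, 18.0, 0.020),
    (673.0, 20.0, 0.040),
    (980.0, 30.0, 0.035),
    (1200.0, 35.0, 0.035),
    (1660.0, 30.0, 0.030),
    (2100.0, 40.0, 0.030),
    (2300.0, 35.0, 0.025),
)

TRAIT_NAMES = ("nitrogen", "carbon", "sla", "lignin", "cellulose", "leaf_water")

# Relative sensitivity of each feature depth to each trait (rows follow
# ABSORPTION_FEATURES, columns TRAIT_NAMES). Distinct mixes per feature keep
# the trait->spectrum map full rank, loosely following which compounds absorb
# where (pigments in the visible, water in the NIR, lignin/cellulose in the
# SWIR).
TRAIT_SLOPES = np.array(
    [
        [0.32, 0.10, 0.00, 0.00, -0.08, 0.00],   # 490 nm: pigments
        [0.38, 0.00, 0.15, 0.00, 0.00, -0.10],   # 673 nm: chlorophyll
        [0.00, 0.00, 0.10, 0.00, 0.00, 0.36],    # 980 nm: water
        [0.00, -0.08, 0.00, 0.00, 0.10, 0.34],   # 1200 nm: water
        [0.00, 0.30, 0.00, 0.22, 0.12, 0.00],    # 1660 nm: carbon/lignin
        [0.00, 0.10, 0.00, 0.34, 0.00, -0.08],   # 2100 nm: lignin
        [0.00, 0.12, 0.00, 0.10, 0.34, 0.00],    # 2300 nm: cellulose
    ]
)

#: Planted plot-level microbial responses: name -> (mean, sd) on the
#: nmol/g scale typical of PLFA group abundances.
RESPONSE_SCALES: dict[str, tuple[float, float]] = {
    "gram_positive": (35.0, 10.0),
    "gram_negative": (14.0, 4.0),
    "actinomycetes": (10.0, 3.0),
    "saprophytic_fungi": (16.0, 5.0),
    "am_fungi": (5.0, 1.5),
}

_GROUP_MEMBERS = {
    "gram_positive": GRAM_POSITIVE,
    "gram_negative": GRAM_NEGATIVE,
    "actinomycetes": ACTINOMYCETALES,
    "saprophytic_fungi": SAPROPHYTIC_FUNGI,
    "am_fungi": AM_FUNGI,
}

LAND_COVERS = ("evergreen_forest", "deciduous_forest", "grassland", "shrubland", "wetland")

_PHYLA = (
    ("Proteobacteria", 0.24),
    ("Acidobacteria", 0.18),
    ("Actinobacteria", 0.15),
    ("Verrucomicrobia", 0.08),
    ("Bacteroidetes", 0.08),
    ("Planctomycetes", 0.06),
    ("Chloroflexi", 0.05),
    ("Firmicutes", 0.05),
    ("Gemmatimonadetes", 0.03),
    ("Nitrospirae", 0.03),
    ("__archaea__", 0.03),
    ("__undefined__", 0.02),
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-design parameters for one synthetic dataset."""

    n_domains: int = 15
    n_plots_per_domain: int = 20
    n_cores_per_plot: int = 3
    wavelength_grid: np.ndarray = field(default_factory=lambda: default_aop_grid().wavelengths)
    signal_fraction: float = 0.8
    confound_weight: float = 0.5
    asv_richness_pool: int = 300
    read_depth_range: tuple[int, int] = (3000, 30000)
    core_noise_sd: float = 0.15  # fraction of each response's plot-level SD
    seed: int = 0

    def validate(self) -> None:
        if self.n_domains < 1:
            raise ConfigError("n_domains must be >= 1")
        if self.n_plots_per_domain < 1:
            raise ConfigError("n_plots_per_domain must be >= 1")
        if self.n_cores_per_plot < 1:
            raise ConfigError("n_cores_per_plot must be >= 1")
        if not (0.0 <= self.signal_fraction <= 1.0):
            raise ConfigError("signal_fraction must be in [0, 1]")
        if not (0.0 <= self.confound_weight <= 1.0):
            raise ConfigError("confound_weight must be in [0, 1]")
        if self.asv_richness_pool < 2:
            raise ConfigError("asv_richness_pool must be >= 2")
        lo, hi = self.read_depth_range
        if lo < 1 or hi < lo:
            raise ConfigError("read_depth_range must satisfy 1 <= min <= max")
        wl = np.asarray(self.wavelength_grid, dtype=float)
        if wl.ndim != 1 or wl.size < 2 or np.any(np.diff(wl) <= 0):
            raise ConfigError("wavelength_grid must be strictly increasing")
        if self.core_noise_sd < 0:
            raise ConfigError("core_noise_sd must be >= 0")

    @property
    def n_plots(self) -> int:
        return self.n_domains * self.n_plots_per_domain


@dataclass
class SyntheticTruth:
    """Ground truth behind one generated dataset."""

    domain_gradients: pd.DataFrame      # domain x (g1, g2)
    plot_gradients: pd.DataFrame        # plot x (z1, z2)
    trait_loadings: pd.DataFrame        # trait x (z1, z2)
    spectral_features: pd.DataFrame     # feature x (centre, width, base_depth, per-trait slope)
    microbe_effects: pd.DataFrame       # response x (trait betas, gradient gammas)
    planted_informative_wavelengths: np.ndarray
    linear_predictors: pd.DataFrame     # plot x response, standardized eta
    plot_responses: pd.DataFrame        # plot x response, realized plot-level values

    def to_json(self) -> str:
        return json.dumps(
            {
                "domain_gradients": self.domain_gradients.to_dict(),
                "plot_gradients": self.plot_gradients.to_dict(),
                "trait_loadings": self.trait_loadings.to_dict(),
                "spectral_features": self.spectral_features.to_dict(),
                "microbe_effects": self.microbe_effects.to_dict(),
                "planted_informative_wavelengths": self.planted_informative_wavelengths.tolist(),
            },
            indent=2,
        )


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    truth: SyntheticTruth
    spectra: SpectraMatrix
    lipids: pd.DataFrame        # plot_id, core_id, sample_id, lipid, concentration_nmol_g
    asv_counts: pd.DataFrame    # sample_id x asv
    taxonomy: pd.DataFrame      # asv_id, kingdom, phylum
    foliar: pd.DataFrame        # plot_id, date, traits
    soil: pd.DataFrame          # plot_id, core_id, variable, value, date
    climate: pd.DataFrame       # plot_id, domain, mat, map, latitude, longitude
    plot_meta: pd.DataFrame     # plot_id, domain, land_cover, image_date, soil_date

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.spectra.write_csv(out / "spectra.csv")
        self.lipids.to_csv(out / "lipids.csv", index=False)
        self.asv_counts.to_csv(out / "asv_counts.tsv", sep="\t", index_label="sample_id")
        self.taxonomy.to_csv(out / "taxonomy.tsv", sep="\t", index=False)
        self.foliar.to_csv(out / "foliar.csv", index=False)
        self.soil.to_csv(out / "soil.csv", index=False)
        self.climate.to_csv(out / "climate.csv", index=False)
        self.plot_meta.to_csv(out / "plot_meta.csv", index=False)
        (out / "truth.json").write_text(self.truth.to_json())


def baseline_reflectance(wl: np.ndarray) -> np.ndarray:
    """A smooth vegetation-like reflectance curve on the given grid (nm)."""
    wl = np.asarray(wl, dtype=float)

    def gauss(c: float, s: float) -> np.ndarray:
        return np.exp(-0.5 * ((wl - c) / s) ** 2)

    def sig(c: float, s: float) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-(wl - c) / s))

    r = (
        0.10
        + 0.045 * gauss(550.0, 35.0)          # green peak
        + 0.38 * sig(715.0, 12.0)             # red edge to NIR plateau
        - 0.16 * sig(1380.0, 120.0)           # SWIR roll-off
        - 0.17 * gauss(1450.0, 55.0)          # water absorption
        - 0.23 * gauss(1940.0, 70.0)          # deep water absorption
        - 0.04 * gauss(2500.0, 180.0)
    )
    return np.clip(r, 0.01, None)


def nir_plateau_weight(wl: np.ndarray) -> np.ndarray:
    """Weight of the structural (scattering) term: NIR plateau, fading in SWIR."""
    wl = np.asarray(wl, dtype=float)
    rise = 1.0 / (1.0 + np.exp(-(wl - 720.0) / 15.0))
    fade = 1.0 / (1.0 + np.exp((wl - 1350.0) / 120.0))
    return rise * fade


def generate_asv_counts(
    composition_logits: np.ndarray,
    depth: int,
    seed: int | np.random.Generator | None = 0,
    dirichlet_overdispersion: float | None = None,
) -> np.ndarray:
    """Draw one sample's ASV counts from a multinomial over softmax(logits).

    ``dirichlet_overdispersion`` (a positive concentration scale), when
    given, first perturbs the composition with a Dirichlet draw. Counts
    are non-negative integers summing exactly to ``depth``.
    """
    logits = np.asarray(composition_logits, dtype=float)
    if not np.isfinite(logits).all():
        raise DataError("composition logits must be finite")
    if depth < 1:
        raise DataError("read depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = logits - logits.max()
    probs = np.exp(z)
    probs /= probs.sum()
    if dirichlet_overdispersion is not None:
        if dirichlet_overdispersion <= 0:
            raise DataError("dirichlet_overdispersion must be positive")
        probs = rng.dirichlet(probs * dirichlet_overdispersion)
    return rng.multinomial(depth, probs)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a complete seeded dataset (see module docstring).

    Deterministic given ``config`` (including its seed): identical
    configurations produce byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    nd, npl, nc = config.n_domains, config.n_plots_per_domain, config.n_cores_per_plot
    n_plots = config.n_plots
    wl = np.asarray(config.wavelength_grid, dtype=float)
    grid = WavelengthGrid(wl)

    domains = [f"D{d + 1:02d}" for d in range(nd)]
    plot_ids = [f"{dom}_P{p + 1:03d}" for dom in domains for p in range(npl)]
    plot_domain = np.repeat(np.arange(nd), npl)

    # latent gradients: domain level + plot-level perturbation
    g_dom = rng.normal(size=(nd, 2))
    z = g_dom[plot_domain] + 0.6 * rng.normal(size=(n_plots, 2))

    # foliar traits: shared gradient loading + trait-specific variation
    alpha = rng.normal(scale=0.6, size=(len(TRAIT_NAMES), 2))
    u = rng.normal(size=(n_plots, len(TRAIT_NAMES)))
    traits = z @ alpha.T + 0.6 * u

    # independent canopy-structure covariate (drives the NIR plateau only)
    structure = rng.normal(size=n_plots)

    # spectra
    base = baseline_reflectance(wl)
    plateau = nir_plateau_weight(wl)
    feat_rows = []
    refl = np.tile(base, (n_plots, 1))
    refl *= 1.0 + 0.05 * structure[:, None] * plateau[None, :]
    for fi, (centre, width, depth0) in enumerate(ABSORPTION_FEATURES):
        depth = depth0 * np.clip(1.0 + traits @ TRAIT_SLOPES[fi], 0.0, None)
        shape = np.exp(-0.5 * ((wl - centre) / width) ** 2)
        refl -= depth[:, None] * shape[None, :]
        feat_rows.append(
            dict(centre_nm=centre, width_nm=width, base_depth=depth0,
                 **{f"slope_{t}": TRAIT_SLOPES[fi, k] for k, t in enumerate(TRAIT_NAMES)})
        )
    refl = np.clip(refl, 0.005, None)
    refl += rng.normal(size=refl.shape) * (0.005 * refl)  # SD = 0.5% of reflectance
    refl = np.clip(refl, 0.0, None)
    spectra = SpectraMatrix(plot_ids, grid, refl)

    # planted microbial responses
    cw, sf = config.confound_weight, config.signal_fraction
    resp_names = list(RESPONSE_SCALES)
    betas = rng.normal(loc=0.4, scale=0.4, size=(len(resp_names), len(TRAIT_NAMES)))
    gammas = rng.normal(loc=0.4, scale=0.4, size=(len(resp_names), 2))
    etas = np.zeros((n_plots, len(resp_names)))
    plot_resp = np.zeros_like(etas)
    for ri, name in enumerate(resp_names):
        eta = (1.0 - cw) * traits @ betas[ri] + cw * z @ gammas[ri]
        eta_hat = _standardize(eta)
        noise = rng.normal(size=n_plots)
        noise = _standardize(noise)
        signal = np.sqrt(sf) * eta_hat + np.sqrt(1.0 - sf) * noise
        mu, sd = RESPONSE_SCALES[name]
        etas[:, ri] = eta_hat
        plot_resp[:, ri] = np.clip(mu + sd * signal, 0.5, None)

    responses = pd.DataFrame(plot_resp, index=plot_ids, columns=resp_names)
    responses["total_plfa"] = responses[resp_names].sum(axis=1)

    # core-level lipid table: core group value = plot value + core noise,
    # then distributed across member lipids with fixed within-group weights
    lipid_rows = []
    sample_ids = []
    for pi, pid in enumerate(plot_ids):
        for ci in range(nc):
            sid = f"{pid}_C{ci + 1}"
            sample_ids.append(sid)
            for ri, name in enumerate(resp_names):
                mu, sd = RESPONSE_SCALES[name]
                core_val = plot_resp[pi, ri] + rng.normal() * config.core_noise_sd * sd
                core_val = max(core_val, 0.05)
                members = _GROUP_MEMBERS[name]
                weights = np.linspace(1.5, 0.5, len(members))
                weights /= weights.sum()
                for lip, wgt in zip(members, weights):
                    lipid_rows.append(
                        dict(plot_id=pid, core_id=f"C{ci + 1}", sample_id=sid,
                             lipid=lip, concentration_nmol_g=core_val * wgt)
                    )
    lipids = pd.DataFrame(lipid_rows)

    # ASV table: base abundances + gradient-loaded subset, core-level noise
    n_asv = config.asv_richness_pool
    base_logits = rng.normal(scale=1.2, size=n_asv)
    loaded = rng.random(n_asv) < 0.3
    asv_load = np.where(loaded[:, None], rng.normal(scale=0.8, size=(n_asv, 2)), 0.0)
    lo, hi = config.read_depth_range
    count_rows = []
    for pi in range(n_plots):
        for ci in range(nc):
            logits = base_logits + asv_load @ z[pi] + 0.3 * rng.normal(size=n_asv)
            depth = int(rng.integers(lo, hi + 1))
            count_rows.append(generate_asv_counts(logits, depth, rng))
    asv_ids = [f"ASV{i + 1:05d}" for i in range(n_asv)]
    asv_counts = pd.DataFrame(
        np.array(count_rows, dtype=np.int64),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=asv_ids,
    )
    phylum_names = [p for p, _ in _PHYLA]
    phylum_probs = np.array([w for _, w in _PHYLA])
    phylum_probs = phylum_probs / phylum_probs.sum()
    assignment = rng.choice(len(phylum_names), size=n_asv, p=phylum_probs)
    tax_rows = []
    for asv, k in zip(asv_ids, assignment):
        name = phylum_names[k]
        if name == "__archaea__":
            tax_rows.append(dict(asv_id=asv, kingdom="Archaea", phylum="Crenarchaeota"))
        elif name == "__undefined__":
            tax_rows.append(dict(asv_id=asv, kingdom="Bacteria", phylum=""))
        else:
            tax_rows.append(dict(asv_id=asv, kingdom="Bacteria", phylum=name))
    taxonomy = pd.DataFrame(tax_rows)

    # covariates and dates
    image_base = pd.Timestamp("2019-06-15")
    image_dates = [
        image_base + pd.Timedelta(days=int(rng.integers(-20, 21))) for _ in range(n_plots)
    ]
    soil_dates = [
        d + pd.Timedelta(days=int(rng.integers(-30, 31))) for d in image_dates
    ]
    foliar_dates = [
        d + pd.Timedelta(days=int(rng.integers(-45, 46))) for d in image_dates
    ]

    foliar = pd.DataFrame(traits, index=plot_ids, columns=TRAIT_NAMES)
    foliar.insert(0, "plot_id", plot_ids)
    foliar["date"] = foliar_dates
    foliar = foliar.reset_index(drop=True)

    soil_vars = {
        "ph": 6.0 + 0.6 * z[:, 0] - 0.3 * z[:, 1],
        "soil_moisture": np.clip(0.25 + 0.08 * z[:, 1] + 0.03 * z[:, 0], 0.02, None),
        "organic_carbon": np.clip(3.0 + 1.2 * z[:, 1], 0.1, None),
        "nitrogen": np.clip(0.25 + 0.1 * z[:, 1], 0.01, None),
        "cn_ratio": np.clip(12.0 + 2.0 * z[:, 0], 3.0, None),
    }
    soil_rows = []
    for pi, pid in enumerate(plot_ids):
        for ci in range(nc):
            for var, vals in soil_vars.items():
                soil_rows.append(
                    dict(plot_id=pid, core_id=f"C{ci + 1}", variable=var,
                         value=vals[pi] + 0.1 * abs(vals[pi]) * rng.normal(),
                         date=soil_dates[pi])
                )
    soil = pd.DataFrame(soil_rows)

    climate = pd.DataFrame(
        {
            "plot_id": plot_ids,
            "domain": [domains[d] for d in plot_domain],
            "mat": 10.0 + 6.0 * g_dom[plot_domain, 0] + 0.3 * rng.normal(size=n_plots),
            "map": np.clip(
                800.0 + 300.0 * g_dom[plot_domain, 1] + 20.0 * rng.normal(size=n_plots),
                50.0, None,
            ),
            "latitude": 40.0 + 4.0 * g_dom[plot_domain, 0] + 0.2 * rng.normal(size=n_plots),
            "longitude": -100.0 + 10.0 * g_dom[plot_domain, 1] + 0.5 * rng.normal(size=n_plots),
        }
    )

    # land cover correlated with the first gradient
    lc_logits = np.outer(z[:, 0], np.linspace(-1.0, 1.0, len(LAND_COVERS)))
    lc_logits += rng.normal(scale=0.5, size=lc_logits.shape)
    land_cover = [LAND_COVERS[int(np.argmax(row))] for row in lc_logits]

    plot_meta = pd.DataFrame(
        {
            "plot_id": plot_ids,
            "domain": [domains[d] for d in plot_domain],
            "land_cover": land_cover,
            "image_date": image_dates,
            "soil_date": soil_dates,
        }
    )

    truth = SyntheticTruth(
        domain_gradients=pd.DataFrame(g_dom, index=domains, columns=["g1", "g2"]),
        plot_gradients=pd.DataFrame(z, index=plot_ids, columns=["z1", "z2"]),
        trait_loadings=pd.DataFrame(alpha, index=TRAIT_NAMES, columns=["z1", "z2"]),
        spectral_features=pd.DataFrame(feat_rows),
        microbe_effects=pd.DataFrame(
            np.hstack([betas, gammas]),
            index=resp_names,
            columns=[f"beta_{t}" for t in TRAIT_NAMES] + ["gamma_z1", "gamma_z2"],
        ),
        planted_informative_wavelengths=np.array([c for c, _, _ in ABSORPTION_FEATURES]),
        linear_predictors=pd.DataFrame(etas, index=plot_ids, columns=resp_names),
        plot_responses=responses,
    )

    return SyntheticDataset(
        config=config,
        truth=truth,
        spectra=spectra,
        lipids=lipids,
        asv_counts=asv_counts,
        taxonomy=taxonomy,
        foliar=foliar,
        soil=soil,
        climate=climate,
        plot_meta=plot_meta,
    )
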