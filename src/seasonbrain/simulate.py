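"""Synthetic trees, traits and climate with the structure PGLS assumes.

The generator is the generative twin of the analysis model: a Yule
(pure-birth) ultrametric tree supplies the species covariance; the
response is ``y = X b + e`` with ``e ~ N(0, sigma2 * V(lambda))`` drawn
through a Cholesky factor; climate is a 12-month sinusoid with tunable
amplitude and noise, from which the seasonality predictors are computed
by the same code that analyses real data.  Default parameters emulate a
30-species / 171-individual montane-frog study design with a planted
negative temperature-seasonality slope on log brain volume.
"""

from __future__ import annotations

import io
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml

from . import climate as clim
from .morphometrics import REGIONS
from .tree import PhyloCovariance, lambda_transform, newick_string, vcv_matrix

__all__ = [
    "SimulationConfig",
    "simulate_yule_tree",
    "simulate_traits",
    "simulate_monthly_climate",
    "generate_study_dataset",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Trait model (log10 scale of 1000 x mm^3 volumes):
    ``log_brain = b0 + b_seas * cv_temp + b_svl * log_svl
    + b_mass * log_mass + e``, ``e ~ N(0, sigma2 * V(lambda))`` on a
    Yule tree rescaled to unit height.  Climate per species is a
    sinusoidal seasonal cycle whose amplitude varies across species so
    localities span a range of temperature seasonality.
    """

    n_species: int = 30
    n_individuals_total: int = 171
    birth_rate: float = 1.0
    # regression truth: intercept, seasonality slope, SVL slope, mass slope
    beta: tuple[float, ...] = (-4.23, -0.25, 2.1, -0.18)
    lam: float = 0.7
    sigma2: float = 0.01
    # climate: locality mean temps drawn in [temp_mean_low, temp_mean_high] C,
    # seasonal amplitude in [amp_low, amp_high] C, month-to-month noise SD
    temp_mean_low: float = 8.0
    temp_mean_high: float = 22.0
    temp_amp_low: float = 4.0
    temp_amp_high: float = 14.0
    temp_noise_sd: float = 0.5
    precip_mean: float = 90.0
    precip_amp: float = 70.0
    precip_noise_sd: float = 10.0
    # within-species individual scatter (SD of log10 volumes / sizes)
    individual_log_sd: float = 0.02
    n_years_daily: int = 5
    daily_noise_sd: float = 2.0
    year_effect_sd: float = 0.4
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        if "beta" in raw:
            raw["beta"] = tuple(raw["beta"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["beta"] = list(d["beta"])
        return d


def simulate_yule_tree(
    n: int, birth_rate: float = 1.0, seed: int | None = None
) -> dendropy.Tree:
    """Pure-birth ultrametric tree with exactly ``n`` tips.

    Waiting times between speciations are exponential with rate
    ``birth_rate * k`` for ``k`` extant lineages; after the n-th lineage
    appears one final waiting time is added and all tips are extended
    to the present.
    """
    if n < 2:
        raise ValueError("need at least 2 tips")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = np.random.default_rng(seed)
    tns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=tns)
    root = tree.seed_node
    # root is the first speciation event, at time 0
    active: list[tuple[dendropy.Node, float]] = []
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, 0.0))
    t = 0.0
    while len(active) < n:
        t += rng.exponential(1.0 / (birth_rate * len(active)))
        i = int(rng.integers(len(active)))
        node, born = active.pop(i)
        node.edge.length = t - born
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    t += rng.exponential(1.0 / (birth_rate * n))
    # deterministic tip labeling in left-to-right tree order
    for node, born in active:
        node.edge.length = t - born
    k = 0
    for leaf in tree.leaf_node_iter():
        k += 1
        leaf.taxon = tns.new_taxon(f"sp{k:03d}")
    return tree


def rescale_tree_height(tree: dendropy.Tree, height: float = 1.0) -> dendropy.Tree:
    """Scale all branch lengths so the maximum root-to-tip depth is ``height``."""
    depth = max(leaf.distance_from_root() for leaf in tree.leaf_node_iter())
    f = height / depth
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length *= f
    return tree


def simulate_traits(
    tree: dendropy.Tree,
    X: np.ndarray,
    beta,
    lam: float,
    sigma2: float,
    seed: int | None = None,
    species_order=None,
) -> np.ndarray:
    """Draw ``y = X b + e`` with lambda-transformed Brownian residuals.

    ``X`` rows are aligned to ``species_order`` (default: tree tip
    order) and must already include the intercept column if one is
    wanted.  The residual is a zero-mean multivariate normal with
    covariance ``sigma2 * V(lambda)``, realized as a Cholesky factor
    times standard normals.
    """
    rng = np.random.default_rng(seed)
    V = vcv_matrix(tree, species_order=species_order)
    Vl = lambda_transform(V, lam).matrix
    X = np.atleast_2d(np.asarray(X, dtype=float))
    beta = np.asarray(beta, dtype=float)
    if sigma2 == 0:  # noiseless limit
        return X @ beta
    try:
        L = np.linalg.cholesky(sigma2 * Vl + 0.0)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            f"covariance not positive definite at lambda={lam}: {err}"
        ) from err
    eps = L @ rng.standard_normal(Vl.shape[0])
    return X @ beta + eps


def simulate_monthly_climate(
    mean_temp_c: float,
    temp_amplitude_c: float,
    precip_mean_mm: float = 90.0,
    precip_amplitude_mm: float = 70.0,
    temp_noise_sd: float = 0.0,
    precip_noise_sd: float = 0.0,
    phase_month: float = 4.0,
    seed: int | None = None,
) -> clim.MonthlyClimate:
    """Sinusoidal seasonal cycle: warm wet summers, cool dry winters.

    ``temp[m] = mean + A sin(2 pi (m - phase)/12) + noise``;
    precipitation analogous and clamped at zero (clamping is logged by
    the caller when it distorts the target CV).
    """
    if temp_amplitude_c < 0 or precip_amplitude_mm < 0:
        raise ValueError("amplitudes must be non-negative")
    rng = np.random.default_rng(seed)
    m = np.arange(1, 13, dtype=float)
    phase = np.sin(2.0 * np.pi * (m - phase_month) / 12.0)
    temp = mean_temp_c + temp_amplitude_c * phase
    precip = precip_mean_mm + precip_amplitude_mm * phase
    if temp_noise_sd > 0:
        temp = temp + rng.normal(0.0, temp_noise_sd, 12)
    if precip_noise_sd > 0:
        precip = precip + rng.normal(0.0, precip_noise_sd, 12)
    precip = np.clip(precip, 0.0, None)
    return clim.MonthlyClimate(temp_c=temp, precip_mm=precip)


def _daily_series(
    species: str,
    monthly: clim.MonthlyClimate,
    n_years: int,
    year_effect_sd: float,
    daily_noise_sd: float,
    rng: np.random.Generator,
    first_year: int = 2011,
) -> pd.DataFrame:
    """Multi-year daily temperatures sharing the monthly means."""
    frames = []
    for j in range(n_years):
        year = first_year + j
        dates = pd.date_range(f"{year}-01-01", f"{year}-12-31", freq="D")
        month_temp = monthly.temp_c[dates.month - 1]
        tavg = (
            month_temp
            + rng.normal(0.0, year_effect_sd)
            + rng.normal(0.0, daily_noise_sd, len(dates))
        )
        frames.append(
            pd.DataFrame(
                {
                    "species": species,
                    "date": dates.strftime("%Y-%m-%d"),
                    "tavg_c": np.round(tavg, 4),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


#: Mean fraction of whole-brain volume per region (log10 intercepts are
#: log10 of these); the sum stays well below 1 so region volumes never
#: exceed the whole brain at the scatter used.
_REGION_FRACTION = {
    "olfactory_nerves": 0.040,
    "olfactory_bulbs": 0.060,
    "telencephalon": 0.280,
    "optic_tectum": 0.140,
    "cerebellum": 0.045,
}
_REGION_LOG_SD = 0.03


def _individual_counts(cfg: SimulationConfig) -> np.ndarray:
    base, extra = divmod(cfg.n_individuals_total, cfg.n_species)
    if base < 1:
        raise ValueError("need at least one individual per species")
    counts = np.full(cfg.n_species, base, dtype=int)
    counts[:extra] += 1
    return counts


def generate_study_dataset(
    cfg: SimulationConfig | None = None,
    outdir: str | Path | None = None,
    write_daily: bool = True,
):
    """Generate one complete synthetic study.

    Returns ``(traits, climate_table, tree, daily)`` where ``traits``
    is the individual-level trait table, ``climate_table`` the
    species-indexed monthly climate table, ``tree`` the Yule phylogeny
    (unit height) and ``daily`` the long-format daily temperature table
    (or None).  With ``outdir`` set, writes ``traits.csv``,
    ``climate.csv``, ``tree.nwk`` and ``daily.csv`` in the dialects the
    readers consume; outputs are bit-identical for a fixed seed.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    tree = simulate_yule_tree(
        cfg.n_species, cfg.birth_rate, seed=int(rng.integers(2**31))
    )
    rescale_tree_height(tree, 1.0)
    species = [leaf.taxon.label for leaf in tree.leaf_node_iter()]

    # --- climate per species locality
    clim_rows, daily_frames, seas = [], [], {}
    for sp in species:
        mc = simulate_monthly_climate(
            mean_temp_c=rng.uniform(cfg.temp_mean_low, cfg.temp_mean_high),
            temp_amplitude_c=rng.uniform(cfg.temp_amp_low, cfg.temp_amp_high),
            precip_mean_mm=cfg.precip_mean,
            precip_amplitude_mm=rng.uniform(0.3, 1.0) * cfg.precip_amp,
            temp_noise_sd=cfg.temp_noise_sd,
            precip_noise_sd=cfg.precip_noise_sd,
            seed=int(rng.integers(2**31)),
        )
        seas[sp] = clim.seasonality_metrics(mc)
        clim_rows.append(
            {"species": sp}
            | {c: round(v, 4) for c, v in zip(clim.TEMP_COLUMNS, mc.temp_c)}
            | {c: round(v, 4) for c, v in zip(clim.PRECIP_COLUMNS, mc.precip_mm)}
        )
        if write_daily:
            daily_frames.append(
                _daily_series(
                    sp,
                    mc,
                    cfg.n_years_daily,
                    cfg.year_effect_sd,
                    cfg.daily_noise_sd,
                    rng,
                )
            )
    climate_table = pd.DataFrame(clim_rows).set_index("species")
    daily = pd.concat(daily_frames, ignore_index=True) if write_daily else None

    # --- species-level traits on the log10(1000 x) scale
    # body size evolves as Brownian motion on the tree; mass is allometric
    log_svl = simulate_traits(
        tree,
        np.ones((cfg.n_species, 1)),
        [4.70],
        lam=1.0,
        sigma2=0.02,
        seed=int(rng.integers(2**31)),
        species_order=species,
    )
    log_mass = -10.02 + 3.0 * log_svl + rng.normal(0.0, 0.05, cfg.n_species)
    cv_temp = np.array([seas[sp].cv_temp for sp in species])
    X = np.column_stack([np.ones(cfg.n_species), cv_temp, log_svl, log_mass])
    log_brain = simulate_traits(
        tree,
        X,
        cfg.beta,
        lam=cfg.lam,
        sigma2=cfg.sigma2,
        seed=int(rng.integers(2**31)),
        species_order=species,
    )
    log_regions = {
        r: np.log10(_REGION_FRACTION[r])
        + log_brain
        + rng.normal(0.0, _REGION_LOG_SD, cfg.n_species)
        for r in REGIONS
    }

    # back-transform species values to raw units (mm, mg, mm^3)
    def raw(logv):
        return 10.0**logv / 1000.0

    sp_svl = raw(log_svl)
    sp_mass = raw(log_mass)
    sp_vols = {"brain": raw(log_brain)} | {r: raw(log_regions[r]) for r in REGIONS}

    # --- individuals: species value times a small log-normal scatter
    counts = _individual_counts(cfg)
    alt = np.round(rng.uniform(500.0, 3500.0, cfg.n_species), 1)
    lon = np.round(rng.uniform(98.0, 104.0, cfg.n_species), 4)
    lat = np.round(rng.uniform(26.0, 33.0, cfg.n_species), 4)
    rows = []
    for i, sp in enumerate(species):
        for k in range(counts[i]):
            jit = 10.0 ** rng.normal(0.0, cfg.individual_log_sd, 2 + len(sp_vols))
            vols = {
                f"{s}_volume": round(float(v[i]) * j, 6)
                for (s, v), j in zip(sp_vols.items(), jit[2:])
            }
            rows.append(
                {
                    "species": sp,
                    "individual_id": f"{sp}_{k + 1:02d}",
                    "svl_mm": round(sp_svl[i] * jit[0], 4),
                    "mass_mg": round(sp_mass[i] * jit[1], 2),
                    "altitude_m": alt[i],
                    "longitude_deg": lon[i],
                    "latitude_deg": lat[i],
                }
                | vols
            )
    traits = pd.DataFrame(rows)

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        traits.to_csv(outdir / "traits.csv", index=False)
        climate_table.to_csv(outdir / "climate.csv")
        with open(outdir / "tree.nwk", "w") as fh:
            fh.write(newick_string(tree))
        if daily is not None:
            daily.to_csv(outdir / "daily.csv", index=False)
        with open(outdir / "sim_config.yaml", "w") as fh:
            yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
    return traits, climate_table, tree, daily
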