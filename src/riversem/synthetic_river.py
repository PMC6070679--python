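"""Synthetic stream-community generator with a known causal diagram.

Emulates the study design the pipeline is built for: sites along a stream
with a single effluent discharge point, sampled repeatedly over time.
Environmental state combines natural spatiotemporal variation (a seasonal
sinusoid and a downstream trend) with an anthropogenic signal — a nutrient
pulse from the discharge, attenuating exponentially downstream.  A latent
"treatment plant operation" variable drives both discharge loads, inducing
their correlation (the diagram's bidirected arrow).  Taxa respond
log-linearly to the nutrient and distance gradients, and counts are drawn
from a Poisson or negative-binomial model.

Because the generating diagram is known exactly, every pipeline stage can be
checked against ground truth: d-separation statements that must hold, an
effluent arrow whose removal must be detected, intervention effects with
known coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .causal_graph import BasisSet, CausalDiagram, basis_set, build_diagram, write_diagram

__all__ = [
    "SyntheticRiverConfig",
    "generate",
    "true_diagram",
    "true_formulas",
    "derived_features",
    "true_independencies",
    "write_dataset",
]


@dataclass(frozen=True)
class SyntheticRiverConfig:
    """Generator parameters.

    Distances are kilometres along the stream; the effluent indicator uses
    the upstream-1 / downstream-0 coding.  Effect sizes are on the scale of
    the nutrient variable (arbitrary concentration units with noise SD
    ``nutrient_noise_sd``); taxon gradient strengths are SDs of per-taxon
    log-linear coefficients on the z-scored gradients.
    """

    n_sites: int = 20
    n_times: int = 8
    stream_length: float = 20.0
    discharge_distance: float = 10.0
    # effect sizes
    effluent_nutrient_beta: float = 0.8     # nutrient rise per unit load at the outfall
    distance_trend: float = 0.03            # natural downstream drift per km
    seasonal_amplitude: float = 0.4
    latent_load_loading: float = 0.7        # plant operation -> each discharge load
    gradient_nutrient: float = 0.6          # SD of taxon coefficients on z(nutrient)
    gradient_distance: float = 0.4          # SD of taxon coefficients on z(distance)
    decay_length: float = 5.0               # e-folding distance of the plume (km)
    # noise
    nutrient_noise_sd: float = 0.3
    load_noise_sd: float = 0.3
    load_mean: float = 1.0
    nutrient_baseline: float = 1.0
    # community
    n_taxa: int = 20
    taxa_log_abundance_mean: float = 2.0
    taxa_log_abundance_sd: float = 0.8
    abundance_model: str = "poisson"        # or "negative_binomial"
    nb_dispersion: float = 5.0              # NB size parameter k (smaller = noisier)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sites < 4:
            raise ValueError("n_sites must be >= 4")
        if self.n_taxa < 3:
            raise ValueError("n_taxa must be >= 3")
        if self.n_times < 1:
            raise ValueError("n_times must be >= 1")
        if self.decay_length <= 0:
            raise ValueError("decay_length must be positive")
        for name in ("nutrient_noise_sd", "load_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.abundance_model not in ("poisson", "negative_binomial"):
            raise ValueError("abundance_model must be 'poisson' or 'negative_binomial'")
        if not 0 < self.discharge_distance < self.stream_length:
            raise ValueError("discharge point must lie strictly inside the stream")


def true_diagram() -> CausalDiagram:
    """The generating causal diagram, including the bidirected arrow that
    stands for the latent plant-operation variable."""
    return build_diagram(
        nodes=["time", "distance", "effluent", "load1", "load2", "nutrient", "COMMUNITY"],
        directed_arrows=[
            ("distance", "effluent"),
            ("time", "nutrient"),
            ("distance", "nutrient"),
            ("effluent", "nutrient"),
            ("load1", "nutrient"),
            ("nutrient", "COMMUNITY"),
            ("distance", "COMMUNITY"),
        ],
        bidirected_arrows=[("load1", "load2")],
    )


def true_formulas() -> dict[str, list[str]]:
    """Structural-equation terms of the generating process.

    The nutrient equation's ``exposure`` term is the load x plume-decay x
    downstream interaction; ``season`` is the sinusoidal transform of the
    time index.  Both are columns of the generated site table and have
    recipes in :func:`derived_features`.
    """
    return {
        "effluent": ["distance"],
        "nutrient": ["season", "distance", "exposure"],
        # second-order trend surface: the count -> Bray-Curtis -> embedding
        # map is nonlinear, so conditioning on the community's direct causes
        # needs curvature terms to absorb their full effect on the PCO scores
        "COMMUNITY": [
            "nutrient",
            "distance",
            "nutrient:nutrient",
            "distance:distance",
            "nutrient:distance",
        ],
    }


def derived_features(config: SyntheticRiverConfig):
    """Recipes recomputing the derived design columns from diagram variables.

    Needed when interventions change upstream variables (e.g. halving
    ``load1`` must update ``exposure`` before nutrient is re-predicted).
    """
    d0 = config.discharge_distance
    decay = config.decay_length
    n_times = config.n_times

    def season(table: pd.DataFrame) -> np.ndarray:
        return np.sin(2 * np.pi * table["time"].to_numpy(dtype=float) / n_times)

    def exposure(table: pd.DataFrame) -> np.ndarray:
        d = table["distance"].to_numpy(dtype=float)
        downstream = (d >= d0).astype(float)
        return table["load1"].to_numpy(dtype=float) * np.exp(
            -np.maximum(d - d0, 0.0) / decay
        ) * downstream

    return {"season": season, "exposure": exposure}


def generate(
    config: SyntheticRiverConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, CausalDiagram]:
    """Draw one synthetic dataset: (site table, community matrix, diagram).

    Draw order, from a single generator keyed by ``config.seed``: (1) latent
    plant operation per occasion, (2) discharge-load noise, (3) nutrient
    noise, (4) per-taxon baseline log-abundances and gradient coefficients,
    (5) abundance counts.  Same seed, bit-identical outputs.
    """
    config = config or SyntheticRiverConfig()
    rng = np.random.default_rng(config.seed)

    distances = np.linspace(0.0, config.stream_length, config.n_sites)
    times = np.arange(config.n_times)

    # long format: site-major blocks, one row per (site, occasion); each row
    # is its own sampling moment, so occasion-level sharing never
    # pseudo-replicates a value across rows
    dist_col = np.repeat(distances, config.n_times)
    time_col = np.tile(times, config.n_sites)
    n_rows = dist_col.size

    # (1) latent plant operation at each sampling moment
    plant = rng.normal(0.0, 1.0, n_rows)
    # (2) two discharge loads, both driven by the latent
    load1 = config.load_mean + config.latent_load_loading * plant + rng.normal(
        0.0, config.load_noise_sd, n_rows
    )
    load2 = config.load_mean + config.latent_load_loading * plant + rng.normal(
        0.0, config.load_noise_sd, n_rows
    )

    upstream = dist_col < config.discharge_distance
    effluent = upstream.astype(int)  # upstream 1 / downstream 0

    season = np.sin(2 * np.pi * time_col / config.n_times)
    delta = np.maximum(dist_col - config.discharge_distance, 0.0)
    exposure = load1 * np.exp(-delta / config.decay_length) * (~upstream)

    # (3) nutrient = baseline + seasonal + downstream trend + plume + noise
    nutrient = (
        config.nutrient_baseline
        + config.seasonal_amplitude * season
        + config.distance_trend * dist_col
        + config.effluent_nutrient_beta * exposure
        + rng.normal(0.0, config.nutrient_noise_sd, dist_col.size)
    )

    site_ids = [
        f"S{{s:02d}}T{{t:02d}}".format(s=s + 1, t=t + 1)
        for s in range(config.n_sites)
        for t in range(config.n_times)
    ]
    site_table = pd.DataFrame(
        {
            "distance": dist_col,
            "time": time_col.astype(float),
            "effluent": effluent,
            "load1": load1,
            "load2": load2,
            "nutrient": nutrient,
            "season": season,
            "exposure": exposure,
        },
        index=pd.Index(site_ids, name="site_id"),
    )

    # (4) taxa: log-linear response to the z-scored gradients
    alpha = rng.normal(
        config.taxa_log_abundance_mean, config.taxa_log_abundance_sd, config.n_taxa
    )
    b_nut = rng.normal(0.0, 1.0, config.n_taxa) * config.gradient_nutrient
    b_dist = rng.normal(0.0, 1.0, config.n_taxa) * config.gradient_distance

    def zscore(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else v - v.mean()

    z_nut = zscore(nutrient)
    z_dist = zscore(dist_col)
    log_lam = alpha[None, :] + np.outer(z_nut, b_nut) + np.outer(z_dist, b_dist)
    lam = np.exp(log_lam)

    # (5) counts
    if config.abundance_model == "poisson":
        counts = rng.poisson(lam)
    else:
        k = config.nb_dispersion
        counts = rng.negative_binomial(k, k / (k + lam))

    community = pd.DataFrame(
        counts,
        index=site_table.index,
        columns=[f"taxon{j + 1:02d}" for j in range(config.n_taxa)],
    )
    return site_table, community, true_diagram()


def true_independencies(config: SyntheticRiverConfig | None = None) -> BasisSet:
    """The basis set of d-separation statements the generated data satisfy.

    With the latent plant operation represented by the bidirected arrow, no
    latent node appears in any statement, so every statement is testable
    against the site table and community matrix.
    """
    return basis_set(true_diagram())


def write_dataset(
    outdir,
    config: SyntheticRiverConfig | None = None,
) -> dict[str, Path]:
    """Generate a dataset and write it in the formats the pipeline reads.

    Produces ``community.csv`` (first column site id, taxon columns),
    ``site_table.csv``, ``diagram.txt`` (edge-list dialect), and a
    ``provenance.txt`` log recording the configuration.
    """
    config = config or SyntheticRiverConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    site_table, community, diagram = generate(config)

    paths = {
        "community": outdir / "community.csv",
        "site_table": outdir / "site_table.csv",
        "diagram": outdir / "diagram.txt",
        "provenance": outdir / "provenance.txt",
    }
    community.to_csv(paths["community"])
    site_table.to_csv(paths["site_table"])
    write_diagram(diagram, paths["diagram"])
    with open(paths["provenance"], "w") as fh:
        fh.write("riversem synthetic dataset\n")
        for key, val in vars(config).items():
            fh.write(f"{key} = {val}\n")
    return paths
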