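"""Synthetic data with the statistical structure the pipeline assumes.

Three generators mirror the study's three data streams:

* ``simulate_counts`` — negative-binomial gene counts for the 18 pooled
  libraries (each condition is three biological replicates mixed evenly
  before sequencing, so one column per condition), with planted
  WT-responsive/mutant-silent gene sets and planted co-expression blocks
  driven by per-sample latent factors.
* ``simulate_growth`` — replicate colony diameters on control and
  stressed plates, from configured true diameters.
* ``simulate_ecar`` — plate-reader fluorescence time series (readings
  every 4 min over 100 min) for measurement, 2-DG control and blank
  wells, with configured linear trends.

Every generator records its ground truth so downstream recovery can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import (MUTANT_SENSITIVE_STRESS, SampleDesign, default_design,
                     sample_id)
from .matrix import CountMatrix

STRESS_TIME_COMBOS = [(s, t) for s in ("sorbitol", "menadione", "congo_red", "heat")
                      for t in (0.5, 12.0)]


@dataclass
class PlantedResponse:
    """A WT-responsive gene set for one stress × time combination.

    ``wt_log2_effect`` is the planted magnitude; signs alternate across the
    set so both up- and down-responses occur. The mutant effect is forced
    to zero ("silent").
    """
    size: int = 25
    wt_log2_effect: float = 3.0


@dataclass
class PlantedModules:
    """Co-expression blocks: per block, one latent factor per sample shared
    by all block members through positive loadings around ``loading_sd``.

    ``block_size`` and ``loading_sd`` may be sequences (one entry per
    block) to plant heterogeneous structure; scalars apply to every block.
    ``loading_spread`` is the relative standard deviation of the per-gene
    loadings around the block's ``loading_sd``: small values give tight,
    well-separated modules; larger values give the graded hub/periphery
    connectivity of real co-expression networks.
    """
    n_blocks: int = 3
    block_size: int | tuple = 60
    loading_sd: float | tuple = 0.8
    loading_spread: float = 0.25

    def blocks(self) -> list[tuple[int, float]]:
        sizes = (self.block_size,) * self.n_blocks \
            if np.isscalar(self.block_size) else tuple(self.block_size)
        loads = (self.loading_sd,) * self.n_blocks \
            if np.isscalar(self.loading_sd) else tuple(self.loading_sd)
        if len(sizes) != self.n_blocks or len(loads) != self.n_blocks:
            raise ValueError("block_size/loading_sd length must match n_blocks")
        return list(zip(sizes, loads))

    @property
    def total_genes(self) -> int:
        return sum(s for s, _ in self.blocks())


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    design: list = field(default_factory=default_design)
    baseline_logmean_mu: float = 5.0      # log2 scale of relative expression
    baseline_logmean_sd: float = 1.8
    nb_dispersion: float = 0.05           # per-replicate; var = mu + phi*mu^2
    n_pool: int = 3                       # replicates mixed per library
    planted_response: dict = field(
        default_factory=lambda: {c: PlantedResponse() for c in STRESS_TIME_COMBOS})
    planted_modules: PlantedModules = field(default_factory=PlantedModules)
    length_range_bp: tuple = (500, 4000)
    libsize_range: tuple = (4_000_000, 6_000_000)
    noise_model: str = "nb"               # "nb" or "none" (counts = rounded means)
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0 or self.n_pool <= 0:
            raise ValueError("sizes must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if self.noise_model not in ("nb", "none"):
            raise ValueError("noise_model must be 'nb' or 'none'")
        n_planted = sum(p.size for p in self.planted_response.values())
        n_module = self.planted_modules.total_genes
        if n_planted + n_module > self.n_genes:
            raise ValueError(
                f"planted sets ({n_planted} response + {n_module} module genes) "
                f"exceed n_genes = {self.n_genes}")
        if len({sample_id(*c) for c in self.design}) != len(self.design):
            raise ValueError("design conditions are not unique")


@dataclass
class GroundTruth:
    """Planted labels and expectations for recovery scoring."""
    response: pd.DataFrame       # gene, stress, time_h, wt_log2_effect
    module_id: pd.Series         # gene -> block index, -1 if unplanted
    mean_matrix: pd.DataFrame    # expected counts, genes × samples
    rgi_true: pd.DataFrame | None = None
    ecar_true: pd.DataFrame | None = None

    def expected_labels(self, stress: str, time_h: float,
                        deg_cut: float = 2.0) -> pd.Series:
        """Expected mutant-responsiveness label per gene for the mutant
        contrast at (stress, time): WT responds by the planted effect, the
        mutant stays silent, so a +effect plants ``down_in_mutant`` and a
        −effect plants ``up_in_mutant``."""
        labels = pd.Series("none", index=self.mean_matrix.index)
        sub = self.response[(self.response["stress"] == stress)
                            & (self.response["time_h"] == time_h)]
        for gene, eff in zip(sub["gene"], sub["wt_log2_effect"]):
            if eff >= deg_cut:
                labels.loc[gene] = "down_in_mutant"
            elif eff <= -deg_cut:
                labels.loc[gene] = "up_in_mutant"
        return labels


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, SampleDesign, GroundTruth]:
    """Draw the count matrix, its design, and the planted ground truth.

    Mean model per gene g and library s:
        mu_gs = libsize_s * w_g / W * 2^(response effect) * 2^(loading_g * z_bs)
    where w_g is the gene's relative baseline abundance (lognormal) and W
    their sum. Counts pool ``n_pool`` gamma-perturbed biological replicates
    (per-replicate dispersion ``nb_dispersion``) and add Poisson sequencing
    noise, so the pooled library behaves negative-binomially with effective
    dispersion ``nb_dispersion / n_pool``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = [f"BBA_{i:05d}" for i in range(1, config.n_genes + 1)]
    samples = [sample_id(*c) for c in config.design]
    design = SampleDesign.from_conditions(config.design)

    rel = 2.0 ** rng.normal(config.baseline_logmean_mu, config.baseline_logmean_sd,
                            config.n_genes)
    lengths = pd.Series(rng.integers(*config.length_range_bp, config.n_genes),
                        index=genes, name="length_bp")
    libsizes = rng.uniform(*config.libsize_range, len(samples))

    # planted response effects: alternate signs within each stress × time set
    free = list(range(config.n_genes))
    effect = np.zeros((config.n_genes, len(samples)))
    resp_rows = []
    cursor = 0
    for (stress, time_h), planted in sorted(config.planted_response.items()):
        idx = free[cursor:cursor + planted.size]
        cursor += planted.size
        signs = np.where(np.arange(len(idx)) % 2 == 0, 1.0, -1.0)
        cols = [j for j, (st, sx, t) in enumerate(config.design)
                if st == "WT" and sx == stress and t == time_h]
        for i, sign in zip(idx, signs):
            eff = sign * planted.wt_log2_effect
            for j in cols:
                effect[i, j] = eff
            resp_rows.append((genes[i], stress, time_h, eff))
    response = pd.DataFrame(resp_rows, columns=["gene", "stress", "time_h",
                                                "wt_log2_effect"])

    # planted co-expression blocks on genes untouched by the response sets
    module_id = pd.Series(-1, index=genes, name="module_id")
    pm = config.planted_modules
    block_effect = np.zeros_like(effect)
    if pm.n_blocks > 0:
        # latent factors orthogonalized against each other and the intercept:
        # between-block Pearson correlation is exactly 0
        z_raw = rng.normal(0.0, 1.0, (len(samples), pm.n_blocks))
        basis = np.hstack([np.ones((len(samples), 1)), z_raw])
        q = np.linalg.qr(basis)[0][:, 1:]
        z_all = q * np.sqrt(len(samples))
        for b, (size, loading) in enumerate(pm.blocks()):
            idx = free[cursor:cursor + size]
            cursor += size
            loadings = np.clip(rng.normal(loading, pm.loading_spread * loading,
                                          len(idx)), 0.05 * loading, None)
            block_effect[idx, :] = np.outer(loadings, z_all[:, b])
            module_id.iloc[idx] = b

    w = rel / rel.sum()
    mean = (w[:, None] * libsizes[None, :]) * 2.0 ** (effect + block_effect)
    mean_df = pd.DataFrame(mean, index=genes, columns=samples)

    if config.noise_model == "none":
        counts = np.round(mean).astype(int)
    else:
        phi = config.nb_dispersion
        if phi > 0:
            shape = 1.0 / phi
            bio = rng.gamma(shape, 1.0 / shape,
                            (config.n_pool,) + mean.shape).mean(axis=0)
            lam = mean * bio
        else:
            lam = mean
        counts = rng.poisson(lam)
    cm = CountMatrix(pd.DataFrame(counts, index=genes, columns=samples,
                                  dtype=int), lengths)
    truth = GroundTruth(response=response, module_id=module_id, mean_matrix=mean_df)
    return cm, design, truth


# --- colony growth ---------------------------------------------------------

#: true (Dc control diameter, RGI %) per strain × medium × stress; the RGI
#: values are the study conditions this simulator emulates.
DEFAULT_GROWTH_TRUTH = {
    # (strain, medium, stress): (Dc_mm, true_RGI_percent)
    ("WT", "SDA", "sorbitol"): (50.0, 58.69),
    ("WT", "CZA", "sorbitol"): (46.0, 57.75),
    ("dHog1", "SDA", "sorbitol"): (47.0, 99.04),
    ("dHog1", "CZA", "sorbitol"): (43.0, 98.46),
    ("dSlt2", "SDA", "sorbitol"): (45.0, 50.0),
    ("dSlt2", "CZA", "sorbitol"): (42.0, 44.0),
    ("dMpk1", "SDA", "sorbitol"): (46.0, 55.45),
    ("dMpk1", "CZA", "sorbitol"): (43.0, 32.26),
    ("WT", "SDA", "heat"): (50.0, 68.25),
    ("WT", "CZA", "heat"): (46.0, 81.23),
    ("dHog1", "SDA", "heat"): (47.0, 51.37),
    ("dHog1", "CZA", "heat"): (43.0, 62.57),
    ("dSlt2", "SDA", "heat"): (45.0, 87.0),
    ("dSlt2", "CZA", "heat"): (42.0, 75.43),
    ("dMpk1", "SDA", "heat"): (46.0, 67.38),
    ("dMpk1", "CZA", "heat"): (43.0, 70.0),
    ("WT", "SDA", "congo_red"): (50.0, 15.0),
    ("WT", "CZA", "congo_red"): (46.0, 5.0),
    ("dHog1", "SDA", "congo_red"): (47.0, 16.0),
    ("dHog1", "CZA", "congo_red"): (43.0, 5.5),
    ("dSlt2", "SDA", "congo_red"): (45.0, 22.40),
    ("dSlt2", "CZA", "congo_red"): (42.0, 8.73),
    ("dMpk1", "SDA", "congo_red"): (46.0, 30.00),
    ("dMpk1", "CZA", "congo_red"): (43.0, 9.64),
    ("WT", "SDA", "menadione"): (50.0, 12.0),
    ("WT", "CZA", "menadione"): (46.0, 15.0),
    ("dHog1", "SDA", "menadione"): (47.0, 12.5),
    ("dHog1", "CZA", "menadione"): (43.0, 15.5),
    ("dSlt2", "SDA", "menadione"): (45.0, 12.0),
    ("dSlt2", "CZA", "menadione"): (42.0, 15.0),
    ("dMpk1", "SDA", "menadione"): (46.0, 1.95),
    ("dMpk1", "CZA", "menadione"): (43.0, 4.08),
}

PLUG_DIAMETER_MM = 5.0


@dataclass
class GrowthSimConfig:
    truth: dict = field(default_factory=lambda: dict(DEFAULT_GROWTH_TRUTH))
    plug_mm: float = PLUG_DIAMETER_MM
    n_replicates: int = 3
    noise_sd: float = 0.5
    seed: int = 0


def _ds_from_rgi(dc: float, rgi_pct: float, d: float) -> float:
    """Invert RGI = (Dc − Ds)/(Ds − d) × 100 for the stressed diameter."""
    r = rgi_pct / 100.0
    return (dc + d * r) / (1.0 + r)


def simulate_growth(config: GrowthSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Replicate colony-diameter records and the true-RGI table.

    Returns (records, rgi_true): records has one row per plate with columns
    strain, medium, stress, replicate, diameter_mm, is_control.
    """
    rng = np.random.default_rng(config.seed)
    if config.n_replicates <= 0:
        raise ValueError("n_replicates must be positive")
    rows, truth_rows = [], []
    for (strain, medium, stress), (dc, rgi_pct) in sorted(config.truth.items()):
        ds = _ds_from_rgi(dc, rgi_pct, config.plug_mm)
        if ds <= config.plug_mm:
            raise ValueError(
                f"stressed diameter {ds:.2f} ≤ plug {config.plug_mm} for "
                f"{strain}/{medium}/{stress}")
        truth_rows.append((strain, medium, stress, dc, ds, rgi_pct))
        for rep in range(1, config.n_replicates + 1):
            rows.append((strain, medium, stress, rep,
                         dc + rng.normal(0, config.noise_sd), True))
            rows.append((strain, medium, stress, rep,
                         ds + rng.normal(0, config.noise_sd), False))
    records = pd.DataFrame(rows, columns=["strain", "medium", "stress",
                                          "replicate", "diameter_mm", "is_control"])
    rgi_true = pd.DataFrame(truth_rows, columns=["strain", "medium", "stress",
                                                 "dc_mm", "ds_mm", "rgi_pct"])
    return records, rgi_true


# --- glycolysis stress assay ----------------------------------------------

#: true fluorescence slopes (signal units/min) per strain and well type.
#: Chosen so the WT's hexokinase-mediated ECAR exceeds the osmosensing
#: mutant's by 58% and the mutant's total ECAR is 34% lower than the WT's.
DEFAULT_ECAR_TRUTH = {
    "WT": {"measurement": 10.0, "2dg_control": 4.0},
    "dHog1": {"measurement": 6.668, "2dg_control": 2.871},
}


@dataclass
class EcarSimConfig:
    truth: dict = field(default_factory=lambda: {k: dict(v) for k, v in
                                                 DEFAULT_ECAR_TRUTH.items()})
    blank_slope: float = 0.2       # shared instrument drift
    intercept: float = 100.0
    n_wells: int = 3
    n_readings: int = 26           # every 4 min over 100 min
    interval_min: float = 4.0
    noise_sd: float = 0.5
    seed: int = 0


def simulate_ecar(config: EcarSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plate-reader series and true-slope table.

    Returns (plate, ecar_true): plate has columns well, strain, well_type,
    t_min, signal; blanks carry the shared drift slope and strain "none".
    """
    if config.n_readings < 2 or config.n_wells <= 0:
        raise ValueError("need at least 2 readings and 1 well per type")
    rng = np.random.default_rng(config.seed)
    t = np.arange(config.n_readings) * config.interval_min
    rows, truth_rows = [], []

    def emit(well, strain, wtype, slope):
        noise = rng.normal(0, config.noise_sd, t.size) if config.noise_sd > 0 else 0.0
        signal = config.intercept + slope * t + noise
        for ti, si in zip(t, signal):
            rows.append((well, strain, wtype, ti, si))

    for strain, slopes in sorted(config.truth.items()):
        for wtype, slope in sorted(slopes.items()):
            truth_rows.append((strain, wtype, slope))
            for w in range(1, config.n_wells + 1):
                emit(f"{strain}_{wtype}_{w}", strain, wtype, slope)
    truth_rows.append(("none", "blank", config.blank_slope))
    for w in range(1, config.n_wells + 1):
        emit(f"blank_{w}", "none", "blank", config.blank_slope)

    plate = pd.DataFrame(rows, columns=["well", "strain", "well_type",
                                        "t_min", "signal"])
    ecar_true = pd.DataFrame(truth_rows, columns=["strain", "well_type",
                                                  "slope_per_min"])
    return plate, ecar_true


def write_simulation(outdir, cm: CountMatrix, truth: GroundTruth,
                     growth: pd.DataFrame | None = None,
                     plate: pd.DataFrame | None = None) -> None:
    """Write counts/lengths TSVs, assay CSVs and the ground-truth sidecar."""
    import pathlib
    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cm.to_tsv(out / "counts.tsv", out / "gene_lengths.tsv")
    truth.response.to_csv(out / "ground_truth_response.tsv", sep="\t", index=False)
    truth.module_id.rename_axis("gene_id").to_csv(out / "ground_truth_modules.tsv",
                                                  sep="\t")
    if growth is not None:
        growth.to_csv(out / "growth.csv", index=False)
    if plate is not None:
        plate.to_csv(out / "plate.csv", index=False)
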