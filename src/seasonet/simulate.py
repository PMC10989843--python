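"""Synthetic OTU tables with planted co-occurrence structure.

The generator emulates a warming experiment sampled monthly over one year:
2 treatments x 4 blocks x 12 months = 96 samples.  Soil temperature follows
a seasonal sinusoid with a +4.3 degC warming offset; moisture follows a
seasonal curve scaled by 0.793 under warming (a 20.7% decrease); the other
soil and flux variables respond linearly to temperature and moisture plus
noise.

Community counts come from a log-normal latent-factor model: each planted
module has one latent Gaussian factor per sample, and member OTUs load on
it so that the pairwise latent correlation within a module equals
``assoc_strength`` (between-module latent correlation is 0).  A configurable
fraction of members load negatively, planting negative associations.
Latent log-abundances are exponentiated, closed to proportions, and sampled
multinomially at a fixed depth — reproducing the compositional, fixed-depth
character of rarefied OTU data.  Ground truth (module membership, signed
association matrix, drivers, effect sizes) is retained for recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import OtuTable, season_of_month, validate_metadata

__all__ = [
    "EnvParams",
    "CommunityParams",
    "SyntheticTruth",
    "generate_design",
    "generate_env",
    "generate_counts",
    "simulate_study",
]


def generate_design(
    n_blocks: int = 4,
    n_months: int = 12,
    treatments=("warming", "control"),
    seed: int | None = None,
) -> pd.DataFrame:
    """Fully crossed design: one sample per (treatment, block, month)."""
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    if not 1 <= n_months <= 12:
        raise ValueError("n_months must be in 1..12")
    rows = []
    for trt in treatments:
        for block in range(1, n_blocks + 1):
            for month in range(1, n_months + 1):
                sid = f"{trt[0].upper()}{block}_M{month:02d}"
                rows.append(
                    {
                        "sample_id": sid,
                        "treatment": trt,
                        "block": block,
                        "month": month,
                        "season": season_of_month(month),
                    }
                )
    meta = pd.DataFrame(rows).set_index("sample_id")
    return validate_metadata(meta)


@dataclass
class EnvParams:
    """Environmental driver parameters (units in comments).

    The defaults encode the study conditions: warming raises soil
    temperature by 4.3 degC and multiplies moisture by 0.793 (a 20.7%
    decrease).
    """

    temp_mean: float = 12.0          # degC annual mean, 0-15 cm soil
    temp_amplitude: float = 13.0     # degC seasonal half-range, peak in July
    temp_noise_sd: float = 1.0       # degC residual month/block noise
    warming_temp_offset: float = 4.3  # degC added under warming
    moisture_mean: float = 0.30      # volumetric fraction
    moisture_amplitude: float = 0.08  # seasonal half-range, peak in spring
    moisture_noise_sd: float = 0.02
    warming_moisture_multiplier: float = 0.793


def _seasonal(month: np.ndarray, peak_month: float) -> np.ndarray:
    return np.cos(2 * np.pi * (month - peak_month) / 12.0)


def generate_env(
    meta: pd.DataFrame, params: EnvParams | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Per-sample environmental and flux variables driven by the design."""
    params = params or EnvParams()
    rng = np.random.default_rng(seed)
    month = meta["month"].to_numpy(float)
    warm = (meta["treatment"] == "warming").to_numpy()

    temp = (
        params.temp_mean
        + params.temp_amplitude * _seasonal(month, peak_month=7.0)
        + np.where(warm, params.warming_temp_offset, 0.0)
        + rng.normal(0, params.temp_noise_sd, len(meta))
    )
    moist = (
        params.moisture_mean + params.moisture_amplitude * _seasonal(month, 4.0)
    ) * np.where(warm, params.warming_moisture_multiplier, 1.0) + rng.normal(
        0, params.moisture_noise_sd, len(meta)
    )
    moist = np.clip(moist, 0.0, 1.0)

    def lin(a, b_t, b_m, sd):
        return a + b_t * (temp - params.temp_mean) + b_m * (moist - params.moisture_mean) \
            + rng.normal(0, sd, len(meta))

    env = pd.DataFrame(index=meta.index)
    env["temperature"] = temp
    env["moisture"] = moist
    env["pH"] = np.clip(lin(6.2, -0.01, -0.8, 0.05), 3.0, 9.0)
    env["SOC"] = lin(18.0, 0.0, 12.0, 1.0)          # g/kg
    env["TN"] = lin(1.5, 0.0, 1.0, 0.05)            # g/kg
    env["NO3"] = np.maximum(lin(2.0, 0.12, -2.0, 0.3), 0.0)   # mg/kg
    env["NH4"] = np.maximum(lin(3.0, 0.02, 2.0, 0.3), 0.0)    # mg/kg
    rh = np.maximum(lin(1.2, 0.06, 0.8, 0.1), 0.0)
    ra = np.maximum(lin(0.8, 0.05, 0.6, 0.1), 0.0)
    env["R_h"] = rh                                  # umol CO2 m-2 s-1
    env["R_a"] = ra
    env["R_t"] = rh + ra
    env["R_eco"] = rh + ra + np.maximum(lin(0.3, 0.02, 0.2, 0.05), 0.0)
    gpp = np.maximum(lin(3.0, 0.15, 3.0, 0.3), 0.0)
    env["GPP"] = gpp
    env["NEE"] = env["R_eco"] - gpp
    return env


@dataclass
class CommunityParams:
    """Latent-factor community model parameters."""

    n_otus: int = 600
    n_modules: int = 5
    module_size: int = 20
    assoc_strength: float = 0.95   # within-module pairwise latent correlation
    negative_fraction: float = 0.1  # members loading negatively on their factor
    depth: int = 17700              # reads per sample (multinomial)
    planted_base_mean: float = 3.0  # natural-log abundance scale of planted OTUs
    planted_base_sd: float = 0.5
    noise_base_mean: float = 0.0
    noise_base_sd: float = 2.0      # heavy tail so prevalence filtering has bite
    biological_sd: float = 1.0      # sd of the latent log-abundance signal
    planted_seasonal_amplitude: float = 0.0  # keep planted modules season-free
    noise_seasonal_sd: float = 0.5  # per-OTU seasonal amplitude sd (noise OTUs)
    treatment_module_sd: float = 0.2  # per-module warming shift on log scale
    treatment_noise_sd: float = 0.3   # per-OTU warming shift sd (noise OTUs)
    treatment_affected_fraction: float = 0.3


@dataclass
class SyntheticTruth:
    """Ground truth retained by the generator for recovery tests."""

    module_of: dict        # planted OTU id -> module id
    association: pd.DataFrame | None  # signed latent association among planted OTUs
    drivers: pd.DataFrame | None      # month -> temperature/moisture curves
    effect_sizes: dict     # warming offsets / multipliers / selection coefficients
    seed: int | None
    latent: pd.DataFrame | None = None  # latent log-abundance (OTU x sample)

    def validate(self) -> None:
        if self.association is not None:
            a = self.association.to_numpy()
            if not np.allclose(a, a.T):
                raise ValueError("association matrix not symmetric")
            if not np.allclose(np.diag(a), 1.0):
                raise ValueError("association diagonal must be 1")
        planted = {o for o in self.module_of}
        if self.association is not None and set(self.association.index) != planted:
            raise ValueError("association index must cover planted OTUs")

    def to_json(self) -> str:
        payload = {
            "module_of": self.module_of,
            "effect_sizes": self.effect_sizes,
            "seed": self.seed,
        }
        if self.association is not None:
            payload["association"] = {
                "otus": list(self.association.index),
                "matrix": self.association.to_numpy().round(6).tolist(),
            }
        if self.drivers is not None:
            payload["drivers"] = self.drivers.round(6).to_dict(orient="list")
        return json.dumps(payload, sort_keys=True, indent=1)


def generate_counts(
    meta: pd.DataFrame,
    env: pd.DataFrame | None = None,
    params: CommunityParams | None = None,
    seed: int | None = None,
) -> tuple[OtuTable, SyntheticTruth]:
    """Draw an OTU count table with planted modular correlation structure.

    Returns the rarefied-depth count table and the :class:`SyntheticTruth`
    describing what was planted.
    """
    p = params or CommunityParams()
    n_planted = p.n_modules * p.module_size
    if n_planted > p.n_otus:
        raise ValueError(
            f"n_modules*module_size={n_planted} exceeds n_otus={p.n_otus}"
        )
    if not (0 <= p.assoc_strength < 1) and p.assoc_strength != 0:
        if not (0 < p.assoc_strength < 1):
            raise ValueError("assoc_strength must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_samples = len(meta)
    month = meta["month"].to_numpy(float)
    warm = (meta["treatment"] == "warming").to_numpy(float)

    otu_ids = [f"OTU{i+1:04d}" for i in range(p.n_otus)]
    planted_ids = otu_ids[:n_planted]
    module_of = {
        oid: f"M{i // p.module_size + 1}" for i, oid in enumerate(planted_ids)
    }

    # latent signal: z_i = s_i * (sqrt(a) f_m + sqrt(1-a) eps_i)
    a = p.assoc_strength
    factors = rng.standard_normal((p.n_modules, n_samples))
    eps = rng.standard_normal((p.n_otus, n_samples))
    signs = np.where(rng.random(n_planted) < p.negative_fraction, -1.0, 1.0)
    z = eps.copy()
    for i, oid in enumerate(planted_ids):
        m = i // p.module_size
        z[i] = signs[i] * (np.sqrt(a) * factors[m] + np.sqrt(1 - a) * eps[i])

    base = np.concatenate(
        [
            rng.normal(p.planted_base_mean, p.planted_base_sd, n_planted),
            rng.normal(p.noise_base_mean, p.noise_base_sd, p.n_otus - n_planted),
        ]
    )

    # seasonal terms: planted OTUs stay season-free by default so module
    # structure is clean ground truth; noise OTUs wander with season
    amp = np.zeros(p.n_otus)
    phase = rng.uniform(0, 12, p.n_otus)
    amp[:n_planted] = p.planted_seasonal_amplitude
    amp[n_planted:] = np.abs(rng.normal(0, p.noise_seasonal_sd, p.n_otus - n_planted))
    seasonal = amp[:, None] * np.cos(2 * np.pi * (month[None, :] - phase[:, None]) / 12)

    # warming selection: per-module shift for planted, per-OTU for noise
    module_coef = rng.normal(0, p.treatment_module_sd, p.n_modules)
    noise_coef = np.where(
        rng.random(p.n_otus - n_planted) < p.treatment_affected_fraction,
        rng.normal(0, p.treatment_noise_sd, p.n_otus - n_planted),
        0.0,
    )
    sel = np.zeros(p.n_otus)
    for i in range(n_planted):
        sel[i] = module_coef[i // p.module_size]
    sel[n_planted:] = noise_coef

    log_abund = base[:, None] + p.biological_sd * z + seasonal + sel[:, None] * warm[None, :]
    props = np.exp(log_abund - log_abund.max(axis=0, keepdims=True))
    props /= props.sum(axis=0, keepdims=True)

    counts = np.column_stack(
        [rng.multinomial(p.depth, props[:, j]) for j in range(n_samples)]
    )
    table = OtuTable(
        pd.DataFrame(counts, index=otu_ids, columns=meta.index),
        taxonomy=pd.Series(
            ["Bacteria;unclassified"] * p.n_otus, index=otu_ids, name="taxonomy"
        ),
    )

    assoc = None
    if n_planted:
        s = signs[:, None] * signs[None, :]
        blocks = np.zeros((n_planted, n_planted))
        for m in range(p.n_modules):
            sl = slice(m * p.module_size, (m + 1) * p.module_size)
            blocks[sl, sl] = a
        assoc_mat = s * blocks
        np.fill_diagonal(assoc_mat, 1.0)
        assoc = pd.DataFrame(assoc_mat, index=planted_ids, columns=planted_ids)

    months = np.arange(1, 13, dtype=float)
    ep = EnvParams()
    drivers = pd.DataFrame(
        {
            "month": months.astype(int),
            "temperature": ep.temp_mean + ep.temp_amplitude * _seasonal(months, 7.0),
            "moisture": ep.moisture_mean + ep.moisture_amplitude * _seasonal(months, 4.0),
        }
    )
    truth = SyntheticTruth(
        module_of=module_of,
        association=assoc,
        drivers=drivers,
        effect_sizes={
            "warming_temp_offset": ep.warming_temp_offset,
            "warming_moisture_multiplier": ep.warming_moisture_multiplier,
            "module_selection": {f"M{m+1}": float(module_coef[m]) for m in range(p.n_modules)},
        },
        seed=seed,
        latent=pd.DataFrame(log_abund, index=otu_ids, columns=meta.index),
    )
    truth.validate()
    return table, truth


def simulate_study(
    seed: int,
    env_params: EnvParams | None = None,
    community_params: CommunityParams | None = None,
    n_blocks: int = 4,
    n_months: int = 12,
):
    """Full study simulation: design, environment and counts from one seed."""
    ss = np.random.SeedSequence(seed)
    s_env, s_counts = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(2))
    meta = generate_design(n_blocks=n_blocks, n_months=n_months)
    env = generate_env(meta, env_params, seed=s_env)
    table, truth = generate_counts(meta, env, community_params, seed=s_counts)
    return table, meta, env, truth
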