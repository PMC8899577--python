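"""Synthetic inputs with the statistical structure the pipeline assumes.

Every stage of the screening/validation workflow can be exercised without
any external download: bioactivity tables with a latent-feature logistic
activity structure, screening libraries with vendor-availability and
DMSO-solubility flags, SPR sensorgrams from the package's own forward
model, one-compartment (Bateman) plasma concentration profiles, and
four-parameter-logistic dose-response curves. All generators are seeded and
byte-deterministic; noiseless outputs agree exactly with the corresponding
analysis module's closed form, so simulate-then-fit recovery is a meaningful
oracle.

Structures are deliberately placeholders (deterministic id-derived SMILES):
the learnable signal lives in latent binary feature columns ``f0..f{d-1}``,
which keeps the achievable classification accuracy a dial
(``signal_strength`` vs ``noise_sd``) rather than a property of any real
chemistry space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bioeval import DoseResponse, PKProfile, four_param_logistic
from .exceptions import InputError
from .sprkin import InjectionSchedule, KineticParams, Sensorgram, simulate_sensorgram

__all__ = [
    "BioSynthConfig",
    "SensorgramSynthConfig",
    "PKSynthConfig",
    "generate_bioactivity_dataset",
    "generate_screening_library",
    "generate_sensorgram",
    "generate_pk_profile",
    "generate_dose_response",
    "generate_docking_energies",
    "dummy_smiles",
]


def dummy_smiles(compound_id: str) -> str:
    """Deterministic, parsable placeholder SMILES derived from the id.

    Simple branched alkanols — enough for a chemistry toolkit to parse, with
    no pretence of resembling screening-library chemistry.
    """
    h = sum(ord(c) * (i + 1) for i, c in enumerate(compound_id))
    chain = 2 + h % 8
    s = "C" * chain
    if h % 3 == 0:
        s += "O"
    if h % 5 == 0 and chain > 3:
        s = s[:2] + "(C)" + s[2:]
    return s


@dataclass(frozen=True)
class BioSynthConfig:
    """Parameters of the synthetic bioactivity table.

    The latent model: each compound carries d binary features x; a sparse
    weight vector w (``n_informative`` nonzero entries, the rest
    distractors) gives a standardized latent score z; the noiseless
    pAffinity is ``threshold + signal_strength * (z - cutoff)`` with the
    cutoff chosen so a ``active_fraction`` share of compounds clears the
    activity threshold; Gaussian noise of SD ``noise_sd`` (log units) is
    added on top, and the active label is recomputed from the noisy value.
    ``signal_strength`` therefore sets how far typical compounds sit from
    the class boundary relative to the noise — the dial controlling
    achievable accuracy/MCC. With few informative features the score takes
    discrete levels, so at ``noise_sd = 0`` the labels are an exactly
    learnable function of the features.
    """

    n_compounds: int = 1200
    active_fraction: float = 0.35
    fa_fraction: float = 0.5  # FA/BA assay mix
    signal_strength: float = 3.0
    noise_sd: float = 0.4
    n_latent_features: int = 32
    n_informative: int = 8
    activity_threshold: float = 6.0  # pAffinity class boundary (1 µM)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_compounds <= 0:
            raise InputError("n_compounds must be positive")
        if not 0 < self.active_fraction < 1:
            raise InputError("active_fraction must be in (0, 1)")
        if not 0 <= self.fa_fraction <= 1:
            raise InputError("fa_fraction must be in [0, 1]")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")
        if self.n_latent_features <= 0:
            raise InputError("n_latent_features must be positive")
        if not 0 < self.n_informative <= self.n_latent_features:
            raise InputError("n_informative must be in (0, n_latent_features]")


def generate_bioactivity_dataset(config: BioSynthConfig) -> pd.DataFrame:
    """Synthetic curated-style bioactivity records.

    Columns: compound_id, smiles, target_id, assay_class, endpoint,
    relation, value, units (raw-record style, value in µM), plus
    p_affinity, active and the latent feature columns f0..f{d-1}.
    """
    rng = np.random.default_rng(config.seed)
    n, d = config.n_compounds, config.n_latent_features
    X = rng.integers(0, 2, size=(n, d)).astype(float)
    w = np.zeros(d)
    w[: config.n_informative] = rng.normal(size=config.n_informative)
    raw = X @ w
    sd = raw.std()
    z = (raw - raw.mean()) / (sd if sd > 0 else 1.0)
    cutoff = float(np.quantile(z, 1.0 - config.active_fraction))
    mu = config.activity_threshold + config.signal_strength * (z - cutoff)
    p_aff = mu + rng.normal(scale=config.noise_sd, size=n) if config.noise_sd > 0 else mu
    active = p_aff >= config.activity_threshold

    ids = [f"SYN{i:05d}" for i in range(n)]
    assay = np.where(rng.random(n) < config.fa_fraction, "FA", "BA")
    value_uM = 10.0 ** (6.0 - p_aff)  # pAff 6 == 1 µM
    df = pd.DataFrame(
        {
            "compound_id": ids,
            "smiles": [dummy_smiles(i) for i in ids],
            "target_id": "BCL2",
            "assay_class": assay,
            "endpoint": np.where(assay == "FA", "IC50", "KD"),
            "relation": "=",
            "value": value_uM,
            "units": "uM",
            "p_affinity": p_aff,
            "active": active.astype(int),
        }
    )
    feats = pd.DataFrame(X, columns=[f"f{j}" for j in range(d)])
    return pd.concat([df, feats], axis=1)


def generate_screening_library(
    n: int,
    unavailable_rate: float = 0.05,
    precipitate_rate: float = 0.1,
    seed: int = 0,
    n_latent_features: int = 32,
    force_unavailable: tuple[str, ...] = (),
    force_insoluble: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Screening library with availability/solubility flags and features.

    Flags are drawn independently at the stated rates; ``force_*`` lists
    pin specific ids (deterministic fixture mode, e.g. exactly 3
    unavailable + 8 precipitating among 60 candidates).
    """
    if n <= 0:
        raise InputError("library size must be positive")
    for name, r in (("unavailable_rate", unavailable_rate), ("precipitate_rate", precipitate_rate)):
        if not 0 <= r <= 1:
            raise InputError(f"{name} must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = [f"LIB{i:06d}" for i in range(n)]
    X = rng.integers(0, 2, size=(n, n_latent_features)).astype(float)
    available = rng.random(n) >= unavailable_rate
    soluble = rng.random(n) >= precipitate_rate
    df = pd.DataFrame(
        {
            "compound_id": ids,
            "smiles": [dummy_smiles(i) for i in ids],
            "vendor": np.where(rng.random(n) < 0.5, "vitas_m", "chem_space"),
            "available": available,
            "soluble_in_dmso": soluble,
        }
    )
    feats = pd.DataFrame(X, columns=[f"f{j}" for j in range(n_latent_features)])
    df = pd.concat([df, feats], axis=1)
    df.loc[df["compound_id"].isin(force_unavailable), "available"] = False
    df.loc[df["compound_id"].isin(force_insoluble), "soluble_in_dmso"] = False
    return df


@dataclass(frozen=True)
class SensorgramSynthConfig:
    """Ground-truth kinetics + acquisition settings for a synthetic sensorgram."""

    params: KineticParams
    sampling_interval: float = 0.5  # s
    noise_sd: float = 0.0  # RU, additive i.i.d. Gaussian
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_interval <= 0:
            raise InputError("sampling interval must be positive")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be >= 0")


def generate_sensorgram(
    config: SensorgramSynthConfig, schedule: InjectionSchedule
) -> Sensorgram:
    """Forward-model sensorgram plus optional additive RU noise.

    With ``noise_sd = 0`` the output is bit-identical to
    :func:`bclscreen.sprkin.simulate_sensorgram`.
    """
    clean = simulate_sensorgram(config.params, schedule, config.sampling_interval)
    if config.noise_sd == 0:
        return clean
    rng = np.random.default_rng(config.seed)
    noisy = clean.response + rng.normal(scale=config.noise_sd, size=clean.response.shape)
    return Sensorgram(times=clean.times, response=noisy)


@dataclass(frozen=True)
class PKSynthConfig:
    """One-compartment first-order absorption (Bateman) profile settings.

    dose in mg/kg, rates in 1/h, V in L/kg. With ``mw`` (g/mol) given,
    concentrations are expressed in µM; otherwise in mg/L. Noise is
    proportional (constant CV), the conventional error model for plasma
    quantitation.
    """

    dose: float = 50.0  # mg/kg
    ka_abs: float = 1.7  # 1/h  (peak ~2 h post-dose)
    ke: float = 0.063  # 1/h  (terminal t1/2 = ln2/ke = 11 h)
    volume: float = 25.0  # L/kg apparent (lipophilic compound)
    bioavailability: float = 1.0
    sample_times: tuple[float, ...] = (0.0, 0.5, 1, 2, 4, 8, 12, 16, 24, 36, 48)
    cv: float = 0.0  # proportional noise
    mw: float | None = 775.0  # g/mol
    seed: int = 0

    def __post_init__(self) -> None:
        for name, v in (("dose", self.dose), ("ka_abs", self.ka_abs), ("ke", self.ke), ("volume", self.volume)):
            if v <= 0:
                raise InputError(f"{name} must be positive")
        if self.ka_abs == self.ke:
            raise InputError("ka_abs == ke is the degenerate Bateman case")
        if not 0 < self.bioavailability <= 1:
            raise InputError("bioavailability must be in (0, 1]")
        if self.cv < 0:
            raise InputError("cv must be >= 0")


def bateman_concentration(t: np.ndarray, config: PKSynthConfig) -> np.ndarray:
    """Noiseless Bateman curve C(t) = F·D·ka/(V·(ka−ke))·(e^{−ke t} − e^{−ka t})."""
    t = np.asarray(t, float)
    ka, ke = config.ka_abs, config.ke
    pref = config.bioavailability * config.dose * ka / (config.volume * (ka - ke))
    c_mg_L = pref * (np.exp(-ke * t) - np.exp(-ka * t))
    if config.mw is not None:
        return c_mg_L / config.mw * 1000.0  # mg/L -> µM
    return c_mg_L


def bateman_tmax(config: PKSynthConfig) -> float:
    """Analytic time of peak concentration: ln(ka/ke)/(ka − ke)."""
    return float(np.log(config.ka_abs / config.ke) / (config.ka_abs - config.ke))


def generate_pk_profile(config: PKSynthConfig) -> PKProfile:
    """Sampled (optionally noisy) plasma concentration-time profile."""
    t = np.asarray(config.sample_times, float)
    if np.any(np.diff(t) <= 0):
        raise InputError("sample times must be strictly increasing")
    c = bateman_concentration(t, config)
    if config.cv > 0:
        rng = np.random.default_rng(config.seed)
        c = np.maximum(c * (1.0 + config.cv * rng.normal(size=c.shape)), 0.0)
    return PKProfile(
        times=t,
        concentrations=c,
        dose=config.dose,
        route="intraperitoneal",
        conc_unit="uM" if config.mw is not None else "mg/L",
    )


def generate_dose_response(
    ic50: float,
    hill: float = 1.0,
    top: float = 100.0,
    bottom: float = 0.0,
    concs: tuple[float, ...] = (5, 10, 15, 20, 25, 30, 40, 50),
    noise_sd: float = 0.0,
    seed: int = 0,
) -> DoseResponse:
    """Viability dose-response from a 4PL curve, optional Gaussian noise (%)."""
    if ic50 <= 0:
        raise InputError("ic50 must be positive")
    c = np.asarray(concs, float)
    if np.any(c <= 0):
        raise InputError("concentrations must be positive")
    resp = four_param_logistic(c, top, bottom, ic50, hill)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        resp = resp + rng.normal(scale=noise_sd, size=resp.shape)
    return DoseResponse(concentrations=c, viability=resp)


def generate_docking_energies(
    p_kd: np.ndarray,
    r_target: float = 0.85,
    energy_scale: float = 1.2,
    energy_offset: float = -8.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic docking energies with an exact target |correlation| to pKD.

    Builds energies as a linear map of pKD (more negative = tighter binding)
    plus a residual component orthogonalized against pKD and scaled so the
    sample Pearson correlation between energy and pKD is exactly
    ``-r_target``. Stands in for score-vs-affinity concordance data whose
    real counterpart is not redistributable.
    """
    x = np.asarray(p_kd, float)
    if len(x) < 3 or np.ptp(x) == 0:
        raise InputError("need >= 3 non-constant pKD values")
    if not 0 < r_target < 1:
        raise InputError("r_target must be in (0, 1)")
    rng = np.random.default_rng(seed)
    u = x - x.mean()
    u = u / np.linalg.norm(u)
    e = rng.normal(size=len(x))
    e = e - u * (u @ e)
    e = e - e.mean()
    # re-orthogonalize after centering (centering can reintroduce a u component)
    e = e - u * (u @ e)
    e = e / np.linalg.norm(e)
    y = r_target * u + np.sqrt(1.0 - r_target**2) * e
    return energy_offset - energy_scale * (y / y.std())
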