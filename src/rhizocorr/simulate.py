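"""Synthetic plant-level datasets with the study's statistical structure.

The generator draws, for each soil environment, one latent bivariate
genotypic value per plant-genotype x rhizobium-mix association from a
Normal(mu + effects, Cov_G[env]) and adds independent Normal(0, Cov_E)
residual noise per replicate plant.  Trait order is fixed everywhere as
(nodule count, ln fruit).  The nodule trait is rounded and truncated at zero
to an integer; the ln-fruit trait is exponentiated, rounded and truncated so
fruit counts are integers.  Uninoculated control plants carry zero nodules
and a penalised ln-fruit mean (larger penalty on carvacrol soil, where
plants deprived of rhizobia fare worst).

A latent-Gaussian-then-round model is used for the counts rather than a
Poisson-family model: the downstream estimator is a Gaussian moment method,
and at the study's scale (mean nodule counts in the tens to hundreds)
rounding preserves the moment structure.  ``return_latent=True`` exposes the
pre-rounding values so convergence tests are not polluted by rounding bias.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io import CONTROL_MIX, SOIL_LEVELS, DesignSpec, REQUIRED_COLUMNS

DEFAULT_GENOTYPES = ("NA1021", "NA216", "NA632", "A17", "DZA012", "F20089-B")
#: genotypes collected where thyme co-occurs (the "home" site for the b mix)
HOME_GENOTYPES = ("NA1021", "NA216", "NA632")
#: "b" = mix isolated from thyme soil, "g" = thyme-naive mix
DEFAULT_MIXES = ("b", "g")


@dataclass
class SimParams:
    """Full generative specification; the seed determines the output.

    ``mu_by_env`` maps each soil environment to the 2-vector of latent trait
    means (nodules, ln fruit); ``cov_G_by_env`` to the 2x2 genetic covariance
    among association-level values.  ``cov_E`` is the residual covariance,
    shared across environments.  ``home_effect`` is added to the latent
    nodule mean of home-genotype x home-mix cells on the home soil,
    reproducing the home/away advantage seen in the reaction norms.
    """

    design: DesignSpec = field(default_factory=DesignSpec)
    mu_by_env: Dict[str, Sequence[float]] = field(
        default_factory=lambda: {"control": (115.0, 3.0), "carvacrol": (105.0, 3.0)}
    )
    cov_G_by_env: Dict[str, np.ndarray] = field(
        default_factory=lambda: {
            "control": np.array([[900.0, 0.0], [0.0, 0.36]]),
            "carvacrol": np.array([[900.0, 10.8], [10.8, 0.36]]),
        }
    )
    cov_E: np.ndarray = field(
        default_factory=lambda: np.array([[1936.0, 1.9712], [1.9712, 0.3136]])
    )
    home_effect: float = 0.0
    home_genotypes: Tuple[str, ...] = HOME_GENOTYPES
    home_mix: str = "b"
    home_soil: str = "carvacrol"
    control_fruit_penalty: float = 0.0
    control_penalty_carvacrol_extra: float = 0.0
    seed: int = 0

    def environments(self) -> Tuple[str, ...]:
        return tuple(SOIL_LEVELS[: self.design.n_soils])

    def validate(self):
        for env in self.environments():
            if env not in self.mu_by_env:
                raise ParameterError(f"mu_by_env missing environment {env!r}")
            if env not in self.cov_G_by_env:
                raise ParameterError(f"cov_G_by_env missing environment {env!r}")
            _check_cov(np.asarray(self.cov_G_by_env[env], float), f"cov_G[{env}]",
                       positive_definite=False)
        _check_cov(np.asarray(self.cov_E, float), "cov_E", positive_definite=True)


def _check_cov(m: np.ndarray, name: str, *, positive_definite: bool):
    if m.shape != (2, 2):
        raise ParameterError(f"{name} must be 2x2, got {m.shape}")
    if not np.allclose(m, m.T, rtol=1e-10, atol=1e-12):
        raise ParameterError(f"{name} must be symmetric")
    eigvals = np.linalg.eigvalsh(m)
    if positive_definite:
        if eigvals.min() <= 0:
            raise ParameterError(f"{name} must be positive-definite")
    elif eigvals.min() < -1e-10 * max(1.0, abs(eigvals).max()):
        raise ParameterError(f"{name} must be positive-semidefinite")


def study_params(seed: int = 0) -> SimParams:
    """Preset emulating the study's design and reported statistical structure.

    The genetic correlation encoded in ``cov_G_by_env`` is 0.6 on carvacrol
    soil and 0 on control soil (the generative idealisation of the reported
    contrast).  Residual scales are calibrated so the per-association SEM at
    k = 5 is about 19–20 nodules and 0.2–0.3 ln-fruit units, and the residual
    correlation is 0.08.  Genetic standard deviations (30 nodules, 0.6
    ln-fruit) put the between-association mean squares at a few times the
    residual mean squares, the regime the fitness ANOVAs exhibit.
    """
    return SimParams(
        design=DesignSpec(),
        home_effect=25.0,
        control_fruit_penalty=0.8,
        control_penalty_carvacrol_extra=0.7,
        seed=seed,
    )


def _genotype_labels(n: int) -> Tuple[str, ...]:
    if n == len(DEFAULT_GENOTYPES):
        return DEFAULT_GENOTYPES
    return tuple(f"G{i + 1:02d}" for i in range(n))


def _mix_labels(n: int) -> Tuple[str, ...]:
    if n == len(DEFAULT_MIXES):
        return DEFAULT_MIXES
    return tuple(f"mix{i + 1}" for i in range(n))


def generate_dataset(params: SimParams, *, return_latent: bool = False):
    """Draw one full factorial dataset.

    Returns a validated plant-level DataFrame (and, with ``return_latent``,
    a second frame of the pre-rounding latent values for each inoculated
    plant, with its association's genotypic values attached).
    """
    params.validate()
    design = params.design
    rng = np.random.default_rng(params.seed)

    genotypes = _genotype_labels(design.n_genotypes)
    mixes = _mix_labels(design.n_mixes)
    envs = params.environments()
    k = design.k

    rows = []
    latent_rows = []
    plant_counter = 0

    for env in envs:
        mu = np.asarray(params.mu_by_env[env], float)
        cov_g = np.asarray(params.cov_G_by_env[env], float)
        cov_e = np.asarray(params.cov_E, float)

        # latent genotypic values, one bivariate draw per M x R association
        assoc = [(geno, mix) for geno in genotypes for mix in mixes]
        shifts = np.zeros((len(assoc), 2))
        for i, (geno, mix) in enumerate(assoc):
            if (
                geno in params.home_genotypes
                and mix == params.home_mix
                and env == params.home_soil
            ):
                shifts[i, 0] += params.home_effect
        genovals = rng.multivariate_normal(np.zeros(2), cov_g, size=len(assoc))
        genovals += mu + shifts

        for i, (geno, mix) in enumerate(assoc):
            resid = rng.multivariate_normal(np.zeros(2), cov_e, size=k)
            latent = genovals[i] + resid
            nodules = np.maximum(np.rint(latent[:, 0]), 0).astype(int)
            fruit = np.maximum(np.rint(np.exp(latent[:, 1])), 0).astype(int)
            for rep in range(k):
                plant_counter += 1
                rows.append(
                    (
                        f"P{plant_counter:04d}",
                        geno,
                        mix,
                        env,
                        rep + 1,
                        int(nodules[rep]),
                        int(fruit[rep]),
                    )
                )
                latent_rows.append(
                    (
                        f"P{plant_counter:04d}",
                        geno,
                        mix,
                        env,
                        rep + 1,
                        genovals[i, 0],
                        genovals[i, 1],
                        latent[rep, 0],
                        latent[rep, 1],
                    )
                )

        if design.include_control:
            sd_g_fruit = float(np.sqrt(max(cov_g[1, 1], 0.0)))
            sd_e_fruit = float(np.sqrt(cov_e[1, 1]))
            penalty = params.control_fruit_penalty
            if env == "carvacrol":
                penalty += params.control_penalty_carvacrol_extra
            for geno in genotypes:
                g_fruit = mu[1] - penalty + rng.normal(0.0, sd_g_fruit)
                latent_fruit = g_fruit + rng.normal(0.0, sd_e_fruit, size=k)
                fruit = np.maximum(np.rint(np.exp(latent_fruit)), 0).astype(int)
                for rep in range(k):
                    plant_counter += 1
                    rows.append(
                        (
                            f"P{plant_counter:04d}",
                            geno,
                            CONTROL_MIX,
                            env,
                            rep + 1,
                            0,
                            int(fruit[rep]),
                        )
                    )

    df = pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))
    if not return_latent:
        return df
    latent_df = pd.DataFrame(
        latent_rows,
        columns=[
            "plant_id",
            "medicago_genotype",
            "rhizobium_mix",
            "soil_treatment",
            "replicate",
            "geno_nodules",
            "geno_ln_fruit",
            "latent_nodules",
            "latent_ln_fruit",
        ],
    )
    return df, latent_df


def params_from_config(config: dict, *, base: SimParams | None = None) -> SimParams:
    """Build SimParams from a plain dict (parsed JSON/YAML config).

    Keys mirror the SimParams field names; covariance matrices are nested
    lists.  Unknown keys raise, so typos do not silently vanish.
    """
    params = copy.deepcopy(base) if base is not None else SimParams()
    known = set(SimParams.__dataclass_fields__)
    for key, value in config.items():
        if key not in known:
            raise ParameterError(f"unknown simulation parameter {key!r}")
        if key == "design":
            value = DesignSpec(**value)
        elif key == "cov_E":
            value = np.asarray(value, float)
        elif key == "cov_G_by_env":
            value = {env: np.asarray(m, float) for env, m in value.items()}
        elif key == "mu_by_env":
            value = {env: tuple(map(float, v)) for env, v in value.items()}
        elif key in ("home_genotypes",):
            value = tuple(value)
        params = replace(params, **{key: value})
    params.validate()
    return params
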