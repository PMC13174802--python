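"""Synthetic LD scores and multi-trait GWAS summary statistics.

Simulation happens at the z-score level, directly under the cross-trait
LD-score regression generative model: for SNP j the vector of z-scores
across k traits is multivariate normal with

    Sigma_j[k,l] = sqrt(N_k N_l) * cov_g[k,l] * l_j / M + I[k,l]

where ``cov_g[k,l] = Rg[k,l] * sqrt(h2_obs_k * h2_obs_l)`` is the
observed-scale genetic covariance, ``l_j`` the LD score, and ``I`` the
intercept matrix (unit diagonal; off-diagonal
``N_shared * rho_pheno / sqrt(N_k N_l)`` from participant overlap).
SNPs are independent given their LD scores.  This is exactly the estimand
of the downstream regression, so recovery can be checked without
genotype-level simulation.

Binary traits are parameterized on the liability scale; under the summed
effective-sample-size convention their observed-scale heritability is the
liability value divided by the conversion factor at sample prevalence
0.5, which makes the round trip through the engine's liability conversion
exact.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from ._linalg import is_psd, nearest_correlation
from .exceptions import ConfigurationInfeasibleError, InvalidArgumentError
from .ldsc import TraitMeta, liability_factor

__all__ = [
    "LDShape",
    "SimTraitSpec",
    "SimBatteryConfig",
    "TruthRecord",
    "make_ld_scores",
    "draw_z_scores",
    "simulate_battery",
    "asd_strata_config",
    "write_ldscores",
    "read_ldscores",
]

_NONAMBIGUOUS_PAIRS = [("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
                       ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G")]


@dataclass(frozen=True)
class LDShape:
    """Shifted-gamma distribution of LD scores: floor + Gamma(shape, scale).

    ``scale`` is derived from the requested mean; ``mean == floor`` gives
    the degenerate distribution (every LD score equal to the floor).
    Positive and right-skewed, like real LD scores.
    """

    mean: float = 40.0
    shape: float = 2.0
    floor: float = 1.0

    def __post_init__(self):
        if self.mean < self.floor:
            raise InvalidArgumentError("LD-score mean cannot lie below the floor")
        if self.shape <= 0 or self.floor <= 0:
            raise InvalidArgumentError("LD shape and floor must be positive")

    @property
    def scale(self) -> float:
        return (self.mean - self.floor) / self.shape

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.shape) * self.scale)

    def draw(self, m: int, rng: np.random.Generator) -> np.ndarray:
        if self.scale == 0.0:
            return np.full(m, self.floor)
        return self.floor + rng.gamma(self.shape, self.scale, size=m)


@dataclass(frozen=True)
class SimTraitSpec:
    """Generating parameters for one simulated trait.

    ``h2`` is the liability-scale SNP heritability for binary traits and
    the plain heritability for continuous ones.  Binary traits need a
    population prevalence ``K`` and case/control counts; continuous
    traits need ``n_total``.
    """

    name: str
    measurement: str = "binary"
    h2: float = 0.1
    K: float | None = None
    n_cases: int | None = None
    n_controls: int | None = None
    n_total: int | None = None

    def __post_init__(self):
        if self.measurement not in ("binary", "continuous"):
            raise InvalidArgumentError(
                f"measurement must be 'binary' or 'continuous', got {self.measurement!r}")
        if not 0.0 <= self.h2 <= 1.0:
            raise InvalidArgumentError(f"h2={self.h2} must be in [0, 1]")
        # delegate the remaining per-measurement checks
        self.to_meta()

    def to_meta(self) -> TraitMeta:
        if self.measurement == "binary":
            return TraitMeta(name=self.name, binary=True,
                             population_prevalence=self.K,
                             n_cases=self.n_cases, n_controls=self.n_controls)
        return TraitMeta(name=self.name, binary=False, n_total=self.n_total)

    @property
    def is_binary(self) -> bool:
        return self.measurement == "binary"

    @property
    def n_effective(self) -> float:
        return self.to_meta().n_effective

    @property
    def h2_observed(self) -> float:
        """Observed-scale heritability under the effective-N convention."""
        if self.is_binary:
            return self.h2 / liability_factor(self.K, 0.5)
        return self.h2


@dataclass
class SimBatteryConfig:
    """Full configuration of a simulated battery of GWAS.

    ``Rg`` is the generating genetic correlation matrix (symmetric, unit
    diagonal, PSD).  ``overlap[k,l]`` is the product of shared-participant
    count and phenotypic correlation for the pair, which becomes the
    cross-trait intercept ``overlap[k,l] / sqrt(N_k N_l)``.
    """

    traits: list[SimTraitSpec]
    Rg: np.ndarray
    overlap: np.ndarray | None = None
    M: int = 2000
    n_chromosome_blocks: int = 200
    seed: int = 0
    ld_shape: LDShape = field(default_factory=LDShape)
    emit_maf_info: bool = False

    def __post_init__(self):
        k = len(self.traits)
        self.Rg = np.asarray(self.Rg, dtype=float)
        if self.Rg.shape != (k, k):
            raise InvalidArgumentError("Rg dimension must equal the number of traits")
        if not np.allclose(self.Rg, self.Rg.T, atol=1e-10):
            raise InvalidArgumentError("Rg must be symmetric")
        if not np.allclose(np.diag(self.Rg), 1.0, atol=1e-10):
            raise InvalidArgumentError("Rg must have a unit diagonal")
        if np.any(np.abs(self.Rg) > 1.0 + 1e-10):
            raise InvalidArgumentError("Rg entries must lie in [-1, 1]")
        if not is_psd(self.Rg):
            raise InvalidArgumentError("Rg must be positive semidefinite")
        if self.overlap is None:
            self.overlap = np.zeros((k, k))
        self.overlap = np.asarray(self.overlap, dtype=float)
        if self.overlap.shape != (k, k):
            raise InvalidArgumentError("overlap dimension must equal the number of traits")
        if not np.allclose(self.overlap, self.overlap.T, atol=1e-8):
            raise InvalidArgumentError("overlap must be symmetric")
        if self.M < 200:
            raise InvalidArgumentError("M must be at least 200")
        if self.n_chromosome_blocks < 1:
            raise InvalidArgumentError("need at least one chromosome block")

    @property
    def names(self) -> list[str]:
        return [t.name for t in self.traits]

    def trait_metas(self) -> list[TraitMeta]:
        return [t.to_meta() for t in self.traits]


@dataclass
class TruthRecord:
    """Generating values of a simulated battery, for recovery checks."""

    names: list[str]
    Rg: np.ndarray
    h2_liability: np.ndarray
    h2_observed: np.ndarray
    n_effective: np.ndarray
    intercepts: np.ndarray
    seed: int
    psd_projection_delta: float = 0.0

    def to_yaml(self, path: str) -> None:
        doc = {
            "names": list(self.names),
            "Rg": np.asarray(self.Rg).tolist(),
            "h2_liability": np.asarray(self.h2_liability).tolist(),
            "h2_observed": np.asarray(self.h2_observed).tolist(),
            "n_effective": np.asarray(self.n_effective).tolist(),
            "intercepts": np.asarray(self.intercepts).tolist(),
            "seed": int(self.seed),
            "psd_projection_delta": float(self.psd_projection_delta),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh)

    @classmethod
    def from_yaml(cls, path: str) -> "TruthRecord":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(names=list(doc["names"]),
                   Rg=np.asarray(doc["Rg"], dtype=float),
                   h2_liability=np.asarray(doc["h2_liability"], dtype=float),
                   h2_observed=np.asarray(doc["h2_observed"], dtype=float),
                   n_effective=np.asarray(doc["n_effective"], dtype=float),
                   intercepts=np.asarray(doc["intercepts"], dtype=float),
                   seed=int(doc["seed"]),
                   psd_projection_delta=float(doc["psd_projection_delta"]))


# ---------------------------------------------------------------------------


def make_ld_scores(M: int, seed: int, ld_shape: LDShape | None = None) -> pd.DataFrame:
    """Draw an LD-score table with columns CHR, SNP, BP, L2.

    SNPs are spread over up to 22 synthetic chromosomes with contiguous
    1-based positions; LD scores are i.i.d. from ``ld_shape``.
    Deterministic given ``seed``.
    """
    if M < 1:
        raise InvalidArgumentError("M must be positive")
    ld_shape = ld_shape or LDShape()
    rng = np.random.default_rng(seed)
    l2 = ld_shape.draw(M, rng)
    n_chrom = int(min(22, max(1, M // 50))) or 1
    chrom = 1 + (np.arange(M) * n_chrom // M)
    bp = np.empty(M, dtype=int)
    for c in np.unique(chrom):
        mask = chrom == c
        bp[mask] = np.arange(1, mask.sum() + 1)
    return pd.DataFrame({
        "CHR": chrom.astype(int),
        "SNP": [f"rs{i + 1:07d}" for i in range(M)],
        "BP": bp,
        "L2": l2,
    })


def write_ldscores(ld: pd.DataFrame, path: str) -> None:
    """Write CHR SNP BP L2 (tab-delimited) plus an M-count sidecar file."""
    ld.to_csv(path, sep="\t", index=False)
    with open(path + ".M", "w") as fh:
        fh.write(f"{len(ld)}\n")


def read_ldscores(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"CHR": int, "BP": int})


def _check_intercept_matrix(B: np.ndarray, names: list[str]) -> None:
    k = B.shape[0]
    for j in range(k):
        for i in range(j + 1, k):
            if B[i, i] * B[j, j] < B[i, j] ** 2 - 1e-10:
                raise ConfigurationInfeasibleError(
                    f"overlap between {names[j]!r} and {names[i]!r} implies a "
                    f"cross-trait intercept of {B[i, j]:.3f}, outside the "
                    "feasible region", pair=(names[j], names[i]))
    if not is_psd(B):
        # no single 2x2 minor fails; blame the most entangled pair
        off = np.abs(B - np.diag(np.diag(B)))
        i, j = np.unravel_index(np.argmax(off), off.shape)
        raise ConfigurationInfeasibleError(
            "intercept matrix is not positive semidefinite "
            f"(largest off-diagonal involves {names[j]!r} and {names[i]!r})",
            pair=(names[j], names[i]))


def draw_z_scores(ell: np.ndarray, covg: np.ndarray, n_eff: np.ndarray,
                  intercept: np.ndarray, M: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw the (m, k) z-score matrix under the generative model.

    ``covg`` is the observed-scale genetic covariance matrix, ``n_eff``
    the per-trait sample-size vector, ``intercept`` the intercept matrix
    and ``M`` the SNP count entering the per-SNP covariance
    ``Sigma_j = sqrt(N N') * covg * l_j / M + intercept``.
    """
    ell = np.asarray(ell, dtype=float)
    n_eff = np.asarray(n_eff, dtype=float)
    k = covg.shape[0]
    A = np.sqrt(np.outer(n_eff, n_eff)) * covg / float(M)
    sigma = ell[:, None, None] * A[None] + intercept[None]
    w, u = np.linalg.eigh(sigma)
    if w.min() < -1e-6 * max(1.0, w.max()):
        raise ConfigurationInfeasibleError(
            "per-SNP covariance not positive semidefinite")
    w = np.clip(w, 0.0, None)
    eps = rng.standard_normal((len(ell), k))
    # z_j = U_j sqrt(W_j) eps_j  ->  Cov = U W U' = Sigma_j
    return np.einsum("mij,mj->mi", u * np.sqrt(w)[:, None, :], eps)


def simulate_battery(config: SimBatteryConfig):
    """Simulate a battery of GWAS summary statistics.

    Returns ``(tables, ld, truth)``: one munged-dialect DataFrame per
    trait (SNP A1 A2 Z N, optional MAF/INFO), the shared LD-score table,
    and a :class:`TruthRecord` with the exact generating values.
    Deterministic given ``config.seed``.
    """
    k = len(config.traits)
    ss = np.random.SeedSequence(config.seed)
    seed_ld, seed_alleles, seed_z, seed_qc = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    ld = make_ld_scores(config.M, seed_ld, config.ld_shape)
    ell = ld["L2"].to_numpy()

    h2_obs = np.array([t.h2_observed for t in config.traits])
    h2_liab = np.array([t.h2 for t in config.traits])
    n_eff = np.array([t.n_effective for t in config.traits])
    covg = config.Rg * np.sqrt(np.outer(h2_obs, h2_obs))

    B = np.eye(k)
    denom = np.sqrt(np.outer(n_eff, n_eff))
    B += (config.overlap - np.diag(np.diag(config.overlap))) / denom
    _check_intercept_matrix(B, config.names)

    rng_z = np.random.default_rng(seed_z)
    Z = draw_z_scores(ell, covg, n_eff, B, config.M, rng_z)

    rng_alleles = np.random.default_rng(seed_alleles)
    pair_idx = rng_alleles.integers(0, len(_NONAMBIGUOUS_PAIRS), size=config.M)
    a1 = np.array([_NONAMBIGUOUS_PAIRS[i][0] for i in pair_idx])
    a2 = np.array([_NONAMBIGUOUS_PAIRS[i][1] for i in pair_idx])

    tables = []
    rng_qc = np.random.default_rng(seed_qc)
    for t, spec in enumerate(config.traits):
        tab = pd.DataFrame({
            "SNP": ld["SNP"],
            "A1": a1,
            "A2": a2,
            "Z": Z[:, t],
            "N": np.full(config.M, spec.n_effective),
        })
        if config.emit_maf_info:
            tab["MAF"] = rng_qc.uniform(0.005, 0.5, size=config.M)
            tab["INFO"] = rng_qc.uniform(0.85, 1.0, size=config.M)
        tables.append(tab)

    truth = TruthRecord(names=config.names, Rg=config.Rg.copy(),
                        h2_liability=h2_liab, h2_observed=h2_obs,
                        n_effective=n_eff, intercepts=B, seed=config.seed,
                        psd_projection_delta=getattr(config, "psd_projection_delta", 0.0))
    return tables, ld, truth


# ---------------------------------------------------------------------------
# preset


def asd_strata_config(M: int = 2000, seed: int = 0, n_external: int = 0,
                      external_rg: float = 0.2,
                      ld_shape: LDShape | None = None,
                      n_chromosome_blocks: int = 200) -> SimBatteryConfig:
    """Battery preset: four ASD strata (male, female, early, late).

    The stratum pairs use the generating correlations
    Rg(male, female) = 0.81, Rg(early, late) = 0.42,
    Rg(late, male) = 0.99 and Rg(late, female) = 0.91; the remaining
    entries are package defaults.  Sample sizes follow the iPSYCH
    sex-stratified counts (15,025/19,763 male cases/controls;
    4,845/19,315 female) and the stratified effective sizes 33,608
    (early) and 21,775 (late).  Optional external traits are continuous
    with a common correlation to every stratum.  If the assembled matrix
    is not PSD it is projected to the nearest unit-diagonal PSD matrix
    and the largest entry change is recorded in the truth record (the
    projection delta is exposed on the config as ``psd_projection_delta``).
    """
    strata = [
        SimTraitSpec("asd_male", "binary", h2=0.12, K=0.016,
                     n_cases=15025, n_controls=19763),
        SimTraitSpec("asd_female", "binary", h2=0.12, K=0.004,
                     n_cases=4845, n_controls=19315),
        SimTraitSpec("asd_early", "binary", h2=0.12, K=0.0075,
                     n_cases=16804, n_controls=16804),
        SimTraitSpec("asd_late", "binary", h2=0.12, K=0.0025,
                     n_cases=10888, n_controls=10887),
    ]
    k0 = 4
    Rg0 = np.eye(k0)
    pairs = {("asd_male", "asd_female"): 0.81,
             ("asd_early", "asd_late"): 0.42,
             ("asd_late", "asd_male"): 0.99,
             ("asd_late", "asd_female"): 0.91,
             ("asd_early", "asd_male"): 0.50,
             ("asd_early", "asd_female"): 0.45}
    names0 = [t.name for t in strata]
    for (a, b), v in pairs.items():
        i, j = names0.index(a), names0.index(b)
        Rg0[i, j] = Rg0[j, i] = v

    traits = list(strata)
    k = k0 + n_external
    Rg = np.eye(k)
    Rg[:k0, :k0] = Rg0
    for e in range(n_external):
        traits.append(SimTraitSpec(f"ext{e + 1:02d}", "continuous",
                                   h2=0.30, n_total=50000))
        Rg[k0 + e, :k0] = Rg[:k0, k0 + e] = external_rg
        for f in range(e):
            Rg[k0 + e, k0 + f] = Rg[k0 + f, k0 + e] = 0.3

    delta = 0.0
    if not is_psd(Rg):
        projected = nearest_correlation(Rg)
        delta = float(np.max(np.abs(projected - Rg)))
        Rg = projected

    # modest iPSYCH-style participant overlap between sex- and
    # age-stratified GWAS (shared N x phenotypic correlation)
    overlap = np.zeros((k, k))
    for (a, b), v in {("asd_male", "asd_early"): 4000.0,
                      ("asd_male", "asd_late"): 1500.0,
                      ("asd_female", "asd_early"): 1500.0,
                      ("asd_female", "asd_late"): 500.0}.items():
        i, j = names0.index(a), names0.index(b)
        overlap[i, j] = overlap[j, i] = v

    cfg = SimBatteryConfig(traits=traits, Rg=Rg, overlap=overlap, M=M,
                           n_chromosome_blocks=n_chromosome_blocks, seed=seed,
                           ld_shape=ld_shape or LDShape())
    cfg.psd_projection_delta = delta
    return cfg
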