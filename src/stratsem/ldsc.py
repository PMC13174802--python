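"""Multivariable LD-score regression with block-jackknife sampling covariance.

The regression model: for trait k at SNP j,

    E[z_kj^2]        = 1 + N_k * h2_k * l_j / M        (univariate)
    E[z_kj * z_lj]   = rho_N + sqrt(N_k N_l) * cov_g[k,l] * l_j / M

where ``l_j`` is the LD score, ``M`` the number of SNPs, ``N`` the
(effective) sample size, and the intercepts absorb confounding
(univariate) or participant sample overlap (cross-trait).  Regressing the
per-SNP response on ``N * l / M`` therefore estimates heritabilities and
genetic covariances directly; the delete-one-block jackknife over
contiguous SNP blocks supplies the full sampling covariance of every
estimate, including cross-entry dependencies.

Observed-scale estimates for case-control traits are rescaled to the
liability scale using the population prevalence; under the summed
effective-sample-size convention the sample prevalence entering the
conversion is fixed at 0.5.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from ._linalg import (
    diag_positions,
    is_psd,
    jackknife_cov,
    offdiag_positions,
    unvech,
    vech,
    vech_pairs,
    vech_position,
)
from .exceptions import (
    InsufficientOverlapError,
    InvalidArgumentError,
    RankDeficiencyError,
    TraitError,
)

__all__ = [
    "TraitMeta",
    "LiabilityParams",
    "LdscFit",
    "GeneticCovariance",
    "MultivariableLDSC",
    "ldsc_regression",
    "multivariable_ldsc",
    "liability_factor",
    "liability_conversion",
    "standardize",
]

MIN_SHARED_SNPS = 200


# ---------------------------------------------------------------------------
# liability conversion


@dataclass(frozen=True)
class LiabilityParams:
    """Population prevalence K and sample prevalence P of a binary trait."""

    K: float
    P: float = 0.5

    def __post_init__(self):
        for name, v in (("K", self.K), ("P", self.P)):
            if not 0.0 < v < 1.0:
                raise InvalidArgumentError(f"{name}={v} must be in (0, 1)")


def liability_factor(K: float, P: float = 0.5) -> float:
    """Observed-to-liability conversion factor for a binary trait.

    c = K^2 (1-K)^2 / ( P (1-P) * phi(Phi^-1(1-K))^2 )

    Multiplying an observed-scale heritability by ``c`` yields the
    liability-scale estimate; covariances pick up ``sqrt(c)`` per binary
    trait.  At K = P = 0.5 the factor equals pi/2.
    """
    p = LiabilityParams(K, P)
    t = norm.ppf(1.0 - p.K)
    phi = norm.pdf(t)
    return (p.K**2 * (1.0 - p.K) ** 2) / (p.P * (1.0 - p.P) * phi**2)


def liability_conversion(value, p1: LiabilityParams | None = None,
                         p2: LiabilityParams | None = None) -> float:
    """Convert an observed-scale (co)variance to the liability scale.

    ``p1``/``p2`` are the liability parameters of the two traits involved;
    ``None`` marks a continuous trait contributing factor 1.  The
    univariate case passes the same params twice (or ``p2=None`` with
    ``p1`` set is the mixed binary-continuous covariance).
    """
    c1 = liability_factor(p1.K, p1.P) if p1 is not None else 1.0
    c2 = liability_factor(p2.K, p2.P) if p2 is not None else 1.0
    return float(value) * float(np.sqrt(c1 * c2))


# ---------------------------------------------------------------------------
# trait metadata


@dataclass(frozen=True)
class TraitMeta:
    """Per-trait metadata needed by the regression and liability conversion.

    Binary traits carry a population prevalence and case/control counts;
    the regression then uses the effective sample size
    ``4 / (1/n_cases + 1/n_controls)`` and converts to the liability scale
    at sample prevalence 0.5.  Continuous traits carry ``n_total`` and are
    left on the observed scale.
    """

    name: str
    binary: bool = False
    population_prevalence: float | None = None
    n_cases: int | None = None
    n_controls: int | None = None
    n_total: int | None = None

    def __post_init__(self):
        if self.binary:
            if self.population_prevalence is None:
                raise InvalidArgumentError(
                    f"binary trait {self.name!r} needs a population prevalence")
            if not 0.0 < self.population_prevalence < 1.0:
                raise InvalidArgumentError(
                    f"prevalence of {self.name!r} must be in (0, 1)")
            if not self.n_cases or not self.n_controls or self.n_cases <= 0 or self.n_controls <= 0:
                raise InvalidArgumentError(
                    f"binary trait {self.name!r} needs positive case/control counts")
        else:
            if not self.n_total or self.n_total <= 0:
                raise InvalidArgumentError(
                    f"continuous trait {self.name!r} needs a positive n_total")

    @property
    def n_effective(self) -> float:
        if self.binary:
            return 4.0 / (1.0 / self.n_cases + 1.0 / self.n_controls)
        return float(self.n_total)

    @property
    def liability(self) -> LiabilityParams | None:
        if self.binary:
            return LiabilityParams(self.population_prevalence, 0.5)
        return None


# ---------------------------------------------------------------------------
# single regression


@dataclass
class LdscFit:
    """One LD-score regression: slope (h2 or cov_g scale), intercept,
    jackknife leave-one-block-out re-estimates and derived SEs."""

    slope: float
    intercept: float
    loo_slope: np.ndarray
    loo_intercept: np.ndarray

    @property
    def n_blocks(self) -> int:
        return len(self.loo_slope)

    @property
    def slope_se(self) -> float:
        return float(np.sqrt(jackknife_cov(self.loo_slope[:, None])[0, 0]))

    @property
    def intercept_se(self) -> float:
        return float(np.sqrt(jackknife_cov(self.loo_intercept[:, None])[0, 0]))


def _wls_sufficient(x, y, w, blocks, n_blocks, with_intercept):
    """Per-block and total sufficient statistics for weighted LS of y on x."""
    if with_intercept:
        design = np.column_stack([np.ones_like(x), x])
    else:
        design = x[:, None]
    q = design.shape[1]
    xtwx = np.zeros((n_blocks, q, q))
    xtwy = np.zeros((n_blocks, q))
    wd = design * w[:, None]
    for a in range(q):
        xtwy[:, a] = np.bincount(blocks, weights=wd[:, a] * y, minlength=n_blocks)
        for b in range(a, q):
            s = np.bincount(blocks, weights=wd[:, a] * design[:, b], minlength=n_blocks)
            xtwx[:, a, b] = s
            xtwx[:, b, a] = s
    return xtwx, xtwy


def _solve(xtwx, xtwy):
    try:
        return np.linalg.solve(xtwx, xtwy[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise RankDeficiencyError(f"singular weighted design: {exc}") from exc


def ldsc_regression(y, ell, n_scale, M, blocks, fix_intercept: float | None = None) -> LdscFit:
    """Two-step weighted regression of a per-SNP response on LD scores.

    Parameters
    ----------
    y : per-SNP response (chi-square, or a cross-trait z-product)
    ell : per-SNP LD scores, all non-negative
    n_scale : scalar or per-SNP sample-size scale (N, or sqrt(N_k N_l))
    M : number of SNPs the heritability refers to
    blocks : integer block labels (0..b-1), contiguous in genome order
    fix_intercept : constrain the intercept to this value if given

    The regressor is ``x = n_scale * ell / M`` so the slope is already on
    the heritability / genetic-covariance scale.  Step one uses
    heteroskedasticity weights evaluated at intercept 1 and unit slope;
    step two re-evaluates them at the step-one fit, with the slope clamped
    to ``[0, M * max(ell) / mean(n_scale)]`` for weighting only.  Weights
    also carry the usual ``1 / max(ell, 1)`` over-counting correction.
    Jackknife re-estimates keep the step-two weights fixed.
    """
    y = np.asarray(y, dtype=float)
    ell = np.asarray(ell, dtype=float)
    blocks = np.asarray(blocks)
    n = np.broadcast_to(np.asarray(n_scale, dtype=float), y.shape)
    if y.shape != ell.shape or y.shape != blocks.shape:
        raise InvalidArgumentError("y, ell and blocks must be aligned")
    if np.any(ell < 0):
        raise InvalidArgumentError("LD scores must be non-negative")
    n_blocks = int(blocks.max()) + 1 if blocks.size else 0
    if n_blocks < 2:
        raise InvalidArgumentError("need at least 2 jackknife blocks")
    if np.ptp(ell) == 0.0:
        raise RankDeficiencyError("constant LD scores: slope unidentified")

    M = float(M)
    x = n * ell / M
    base_w = 1.0 / np.maximum(ell, 1.0)
    free = fix_intercept is None
    a0 = 1.0 if free else float(fix_intercept)

    def het(intercept, slope):
        mean = np.maximum(np.abs(intercept) + slope * x, 1e-2)
        return 1.0 / (2.0 * mean**2)

    def fit_once(w):
        if free:
            xtwx, xtwy = _wls_sufficient(x, y, w, blocks, n_blocks, True)
            total_xtwx = xtwx.sum(axis=0)
            total_xtwy = xtwy.sum(axis=0)
            beta = _solve(total_xtwx, total_xtwy)
            loo = _solve(total_xtwx[None] - xtwx, total_xtwy[None] - xtwy)
            return beta[1], beta[0], loo[:, 1], loo[:, 0]
        yy = y - a0
        xtwx, xtwy = _wls_sufficient(x, yy, w, blocks, n_blocks, False)
        total_xtwx = xtwx.sum(axis=0)
        total_xtwy = xtwy.sum(axis=0)
        beta = _solve(total_xtwx, total_xtwy)
        loo = _solve(total_xtwx[None] - xtwx, total_xtwy[None] - xtwy)
        return beta[0], a0, loo[:, 0], np.full(n_blocks, a0)

    # step 1: weights at intercept 1 (or the fixed value) and unit slope
    w1 = base_w * het(a0, 1.0)
    slope1, int1, _, _ = fit_once(w1)

    # step 2: weights at the step-one fit, slope clamped for weighting only
    upper = M * float(np.max(ell)) / float(np.mean(n))
    slope_w = float(np.clip(slope1, 0.0, upper))
    int_w = int1 if free else a0
    w2 = base_w * het(int_w, slope_w)
    slope, intercept, loo_slope, loo_intercept = fit_once(w2)
    return LdscFit(float(slope), float(intercept),
                   np.asarray(loo_slope, dtype=float),
                   np.asarray(loo_intercept, dtype=float))


# ---------------------------------------------------------------------------
# multivariable engine


@dataclass
class GeneticCovariance:
    """Genetic covariance estimates with full jackknife sampling covariance.

    Attributes
    ----------
    names : trait labels, fixing the row/column order everywhere
    S : k x k symmetric genetic covariance (or correlation) matrix
    V : p* x p* sampling covariance of vech(S), p* = k(k+1)/2, vech order
        = columns of the lower triangle including the diagonal
    intercepts : k x k; diagonal = univariate LDSC intercepts, off-diagonal
        = cross-trait intercepts (sample-overlap diagnostics)
    M : number of SNPs used by the regressions
    h2_z : per-trait heritability z-statistic (estimate / jackknife SE)
    replicates : (b, p*) leave-one-block-out vech(S) re-estimates; carried
        so standardization can re-apply the jackknife within replicates
    scale : per-trait scale flag, "liability" or "observed"
    is_correlation : True after :meth:`standardize`
    """

    names: list[str]
    S: np.ndarray
    V: np.ndarray
    intercepts: np.ndarray
    M: int
    h2_z: np.ndarray
    replicates: np.ndarray
    scale: list[str]
    is_correlation: bool = False

    @property
    def k(self) -> int:
        return len(self.names)

    def _idx(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise InvalidArgumentError(f"unknown trait {name!r}") from None

    def pair_position(self, a: str, b: str) -> int:
        return vech_position(self._idx(a), self._idx(b), self.k)

    def value(self, a: str, b: str) -> float:
        return float(self.S[self._idx(a), self._idx(b)])

    def se(self, a: str, b: str) -> float:
        pos = self.pair_position(a, b)
        return float(np.sqrt(max(self.V[pos, pos], 0.0)))

    def rg(self, a: str, b: str) -> float:
        i, j = self._idx(a), self._idx(b)
        return float(self.S[i, j] / np.sqrt(self.S[i, i] * self.S[j, j]))

    def subset(self, names: list[str]) -> "GeneticCovariance":
        """Restrict to a subset of traits, keeping sampling dependencies."""
        idx = [self._idx(n) for n in names]
        k_new = len(idx)
        keep = [vech_position(idx[i], idx[j], self.k)
                for j in range(k_new) for i in range(j, k_new)]
        # vech_position is order-free, and vech_pairs(k_new) traverses
        # (i>=j) columns left-to-right, matching the comprehension above.
        return GeneticCovariance(
            names=list(names),
            S=self.S[np.ix_(idx, idx)].copy(),
            V=self.V[np.ix_(keep, keep)].copy(),
            intercepts=self.intercepts[np.ix_(idx, idx)].copy(),
            M=self.M,
            h2_z=self.h2_z[idx].copy(),
            replicates=self.replicates[:, keep].copy(),
            scale=[self.scale[i] for i in idx],
            is_correlation=self.is_correlation,
        )

    def standardize(self) -> "GeneticCovariance":
        return standardize(self)

    # -- persistence (plain-text) ------------------------------------------

    def save(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        pd.DataFrame(self.S, index=self.names, columns=self.names).to_csv(
            os.path.join(out_dir, "S.tsv"), sep="\t")
        pd.DataFrame(self.V).to_csv(os.path.join(out_dir, "V.tsv"), sep="\t", index=False)
        pd.DataFrame(self.intercepts, index=self.names, columns=self.names).to_csv(
            os.path.join(out_dir, "intercepts.tsv"), sep="\t")
        pd.DataFrame(self.replicates).to_csv(
            os.path.join(out_dir, "replicates.tsv"), sep="\t", index=False)
        meta = {
            "names": list(self.names),
            "M": int(self.M),
            "h2_z": [float(z) for z in self.h2_z],
            "scale": list(self.scale),
            "is_correlation": bool(self.is_correlation),
        }
        with open(os.path.join(out_dir, "meta.yaml"), "w") as fh:
            yaml.safe_dump(meta, fh)

    @classmethod
    def load(cls, out_dir: str) -> "GeneticCovariance":
        with open(os.path.join(out_dir, "meta.yaml")) as fh:
            meta = yaml.safe_load(fh)
        S = pd.read_csv(os.path.join(out_dir, "S.tsv"), sep="\t", index_col=0).to_numpy()
        V = pd.read_csv(os.path.join(out_dir, "V.tsv"), sep="\t").to_numpy()
        intercepts = pd.read_csv(os.path.join(out_dir, "intercepts.tsv"),
                                 sep="\t", index_col=0).to_numpy()
        reps = pd.read_csv(os.path.join(out_dir, "replicates.tsv"), sep="\t").to_numpy()
        return cls(names=list(meta["names"]), S=S, V=V, intercepts=intercepts,
                   M=int(meta["M"]), h2_z=np.asarray(meta["h2_z"], dtype=float),
                   replicates=reps, scale=list(meta["scale"]),
                   is_correlation=bool(meta["is_correlation"]))

    def summary(self) -> str:
        kind = "genetic correlation" if self.is_correlation else "genetic covariance"
        lines = [f"Multivariable LDSC {kind} matrix "
                 f"({self.k} traits, M={self.M} SNPs, "
                 f"{self.replicates.shape[0]} jackknife blocks)", ""]
        head = "trait".ljust(16) + "".join(n[:12].rjust(13) for n in self.names)
        lines.append(head)
        for i, n in enumerate(self.names):
            row = n[:16].ljust(16) + "".join(f"{self.S[i, j]:13.4f}" for j in range(self.k))
            lines.append(row)
        lines.append("")
        lines.append("trait".ljust(16) + "scale".rjust(12) + "h2_z".rjust(10)
                     + "intercept".rjust(12))
        for i, n in enumerate(self.names):
            lines.append(n[:16].ljust(16) + self.scale[i].rjust(12)
                         + f"{self.h2_z[i]:10.2f}" + f"{self.intercepts[i, i]:12.4f}")
        return "\n".join(lines)


def standardize(gc: GeneticCovariance) -> GeneticCovariance:
    """Rescale to the genetic correlation metric.

    R[k,l] = S[k,l] / sqrt(S[k,k] S[l,l]).  The sampling covariance of
    vech(R) is obtained by standardizing within each jackknife replicate
    and re-applying the jackknife formula, so the nonlinearity of the
    ratio propagates into V_R.  Unit-diagonal entries are fixed: their
    rows and columns of V_R are exactly zero.
    """
    if gc.is_correlation:
        return replace(gc, S=gc.S.copy(), V=gc.V.copy(),
                       replicates=gc.replicates.copy(),
                       intercepts=gc.intercepts.copy(), h2_z=gc.h2_z.copy(),
                       names=list(gc.names), scale=list(gc.scale))
    d = np.diag(gc.S)
    for i, val in enumerate(d):
        if val <= 0:
            raise TraitError(
                f"non-positive heritability for trait {gc.names[i]!r}", trait=gc.names[i])
    k = gc.k
    dd = np.sqrt(d)
    R = gc.S / np.outer(dd, dd)
    np.fill_diagonal(R, 1.0)

    reps_R = np.empty_like(gc.replicates)
    for b in range(gc.replicates.shape[0]):
        s_b = unvech(gc.replicates[b], k)
        d_b = np.sqrt(np.clip(np.diag(s_b), 1e-12, None))
        r_b = s_b / np.outer(d_b, d_b)
        np.fill_diagonal(r_b, 1.0)
        reps_R[b] = vech(r_b)
    V_R = jackknife_cov(reps_R)
    for pos in diag_positions(k):
        V_R[pos, :] = 0.0
        V_R[:, pos] = 0.0
    return GeneticCovariance(
        names=list(gc.names), S=R, V=V_R, intercepts=gc.intercepts.copy(),
        M=gc.M, h2_z=gc.h2_z.copy(), replicates=reps_R,
        scale=["correlation"] * k, is_correlation=True)


class MultivariableLDSC:
    """Model object: multivariable LDSC over a battery of summary statistics.

    Parameters
    ----------
    tables : list of munged summary-statistics DataFrames
        Columns SNP, A1, A2, Z, N; one per trait, allele-aligned (munged).
    ld : LD-score DataFrame with columns CHR, SNP, BP, L2.
    specs : list of :class:`TraitMeta`, same order as ``tables``.

    ``fit(n_blocks)`` returns a :class:`GeneticCovariance` results object.
    """

    def __init__(self, tables, ld, specs):
        if len(tables) < 2:
            raise InvalidArgumentError("need at least 2 traits")
        if len(tables) != len(specs):
            raise InvalidArgumentError("one TraitMeta per table required")
        self.specs = list(specs)
        self.names = [s.name for s in specs]
        self._assemble(tables, ld)

    def _assemble(self, tables, ld):
        merged = ld[["CHR", "SNP", "BP", "L2"]].copy()
        ref = tables[0][["SNP", "A1", "A2"]]
        for t, tab in enumerate(tables):
            cols = tab[["SNP", "A1", "A2", "Z", "N"]].copy()
            cols = cols.merge(ref, on="SNP", suffixes=("", "_ref"))
            direct = (cols["A1"] == cols["A1_ref"]) & (cols["A2"] == cols["A2_ref"])
            flipped = (cols["A1"] == cols["A2_ref"]) & (cols["A2"] == cols["A1_ref"])
            cols = cols[direct | flipped]
            z = np.where(direct[direct | flipped], cols["Z"], -cols["Z"])
            sub = pd.DataFrame({"SNP": cols["SNP"], f"Z{t}": z, f"N{t}": cols["N"].to_numpy()})
            merged = merged.merge(sub, on="SNP", how="inner")
        if len(merged) < MIN_SHARED_SNPS:
            raise InsufficientOverlapError(
                f"only {len(merged)} SNPs shared across traits and LD scores "
                f"(floor {MIN_SHARED_SNPS})")
        chrom = pd.to_numeric(merged["CHR"], errors="coerce")
        merged = merged.assign(_chrom=chrom).sort_values(
            ["_chrom", "BP"], kind="mergesort").reset_index(drop=True)
        self.data = merged
        self.n_snps = len(merged)

    def fit(self, n_blocks: int = 200) -> GeneticCovariance:
        m = self.n_snps
        n_blocks = int(min(n_blocks, m))
        blocks = (np.arange(m) * n_blocks // m).astype(int)
        ell = self.data["L2"].to_numpy(dtype=float)
        k = len(self.names)
        Z = np.column_stack([self.data[f"Z{t}"].to_numpy(dtype=float) for t in range(k)])
        N = np.column_stack([self.data[f"N{t}"].to_numpy(dtype=float) for t in range(k)])

        S = np.zeros((k, k))
        intercepts = np.zeros((k, k))
        h2_z = np.zeros(k)
        p_star = k * (k + 1) // 2
        loo = np.zeros((n_blocks, p_star))

        conv = np.array([np.sqrt(liability_factor(s.population_prevalence, 0.5))
                         if s.binary else 1.0 for s in self.specs])
        scale = ["liability" if s.binary else "observed" for s in self.specs]

        for i in range(k):
            fit = ldsc_regression(Z[:, i] ** 2, ell, N[:, i], m, blocks)
            if fit.slope_se > 0:
                h2_z[i] = fit.slope / fit.slope_se
            else:
                h2_z[i] = np.inf if fit.slope != 0 else 0.0
            # liability conversion applied to the estimate and, identically,
            # inside each jackknife replicate (a constant factor commutes)
            S[i, i] = fit.slope * conv[i] ** 2
            intercepts[i, i] = fit.intercept
            loo[:, vech_position(i, i, k)] = fit.loo_slope * conv[i] ** 2
            for j in range(i):
                pfit = ldsc_regression(Z[:, i] * Z[:, j], ell,
                                       np.sqrt(N[:, i] * N[:, j]), m, blocks)
                S[i, j] = S[j, i] = pfit.slope * conv[i] * conv[j]
                intercepts[i, j] = intercepts[j, i] = pfit.intercept
                loo[:, vech_position(i, j, k)] = pfit.loo_slope * conv[i] * conv[j]

        V = jackknife_cov(loo)
        if not is_psd(V, tol=1e-6):  # pragma: no cover - outer-product sum
            raise RuntimeError("jackknife covariance unexpectedly not PSD")
        return GeneticCovariance(names=list(self.names), S=S, V=V,
                                 intercepts=intercepts, M=m, h2_z=h2_z,
                                 replicates=loo, scale=scale)


def multivariable_ldsc(tables, ld, specs, n_blocks: int = 200) -> GeneticCovariance:
    """Functional wrapper around :class:`MultivariableLDSC`."""
    return MultivariableLDSC(tables, ld, specs).fit(n_blocks=n_blocks)
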