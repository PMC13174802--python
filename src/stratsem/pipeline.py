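"""Battery-level orchestration: screening, model comparisons, FDR, reports.

For each external trait the two focal strata's genetic correlations are
compared by fitting the equality-constrained 3-variable model; the
residual-based model chi-square (1 df) is the difference test, with the
Wald contrast carried alongside as a cross-check.  p-values are
Benjamini-Hochberg corrected across the battery; per-stratum correlation
significance is corrected as a separate family.  The factor-adjustment
analysis reruns the comparison on residual associations after removing a
common internalizing-style factor, and classifies how each trait's
difference flag transitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm
from statsmodels.stats.multitest import multipletests

from ._linalg import is_psd
from .exceptions import InvalidArgumentError
from .ldsc import GeneticCovariance
from .sem import (
    StructuralModel,
    equality_constrained_spec,
    factor_residual_model,
    residual_chisq,
    wald_equality_test,
)

__all__ = [
    "screen_traits",
    "bh_fdr",
    "BatteryRow",
    "BatteryTable",
    "battery_compare",
    "AdjustmentRow",
    "AdjustmentResult",
    "adjustment_comparison",
    "plot_battery",
]

logger = logging.getLogger("stratsem")


def screen_traits(gc: GeneticCovariance, z_min: float = 4.0):
    """Split traits into included/excluded by heritability z-statistic.

    A trait is included iff ``h2_z > z_min`` (strict); the conventional
    power floor for interpretable genetic correlations is ``z_min = 4``.
    Returns ``(included_names, excluded: {name: z})``.
    """
    included, excluded = [], {}
    for name, z in zip(gc.names, gc.h2_z):
        if z > z_min:
            included.append(name)
        else:
            excluded[name] = float(z)
            logger.info("screen: excluding %s (h2 z = %.2f <= %.2f)", name, z, z_min)
    return included, excluded


def bh_fdr(pvals, q: float = 0.05):
    """Benjamini-Hochberg step-up: returns (adjusted p, reject flags).

    Rejection is ``adjusted p <= q``.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size and (np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p))):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


@dataclass
class BatteryRow:
    """One external trait's comparison between the two focal strata."""

    trait: str
    r1: float
    se1: float
    r2: float
    se2: float
    chisq_diff: float
    df: int
    p_diff: float
    wald_chisq: float
    wald_p: float
    p_fdr: float = np.nan
    sig_diff: bool = False
    p1: float = np.nan
    p2: float = np.nan
    sig1: bool = False
    sig2: bool = False


class BatteryTable:
    """Ordered collection of :class:`BatteryRow` with TSV round-trip."""

    def __init__(self, stratum_a: str, stratum_b: str, rows, q: float = 0.05,
                 skipped=None):
        self.stratum_a = stratum_a
        self.stratum_b = stratum_b
        self.rows = list(rows)
        self.q = q
        self.skipped = dict(skipped or {})

    def __len__(self):
        return len(self.rows)

    def __iter__(self):
        return iter(self.rows)

    def to_frame(self) -> pd.DataFrame:
        cols = [f.name for f in fields(BatteryRow)]
        return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in self.rows])

    def write(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str, stratum_a: str = "", stratum_b: str = "",
             q: float = 0.05) -> "BatteryTable":
        df = pd.read_csv(path, sep="\t")
        rows = []
        for rec in df.to_dict("records"):
            rec["df"] = int(rec["df"])
            for flag in ("sig_diff", "sig1", "sig2"):
                rec[flag] = bool(rec[flag])
            rows.append(BatteryRow(**rec))
        return cls(stratum_a, stratum_b, rows, q=q)

    def summary(self) -> str:
        n_sig = sum(r.sig_diff for r in self.rows)
        lines = [f"battery comparison {self.stratum_a} vs {self.stratum_b}: "
                 f"{len(self.rows)} traits, {n_sig} significantly divergent "
                 f"(FDR q = {self.q})"]
        lines.append(f"{'trait':<16}{'r1':>8}{'r2':>8}{'chi2':>9}{'p_diff':>11}"
                     f"{'p_fdr':>11}{'sig':>5}")
        for r in self.rows:
            lines.append(f"{r.trait:<16}{r.r1:>8.3f}{r.r2:>8.3f}"
                         f"{r.chisq_diff:>9.3f}{r.p_diff:>11.3g}{r.p_fdr:>11.3g}"
                         f"{'*' if r.sig_diff else '':>5}")
        return "\n".join(lines)


def _compare_pair(sub: GeneticCovariance, stratum_a: str, stratum_b: str,
                  trait: str, seed: int = 0):
    """Constrained-vs-free comparison on a 3-trait correlation submatrix."""
    spec = equality_constrained_spec(stratum_a, stratum_b, trait, sub.names)
    model = StructuralModel(spec, sub.S, sub.V)
    fit = model.fit(seed=seed)
    chisq, df, p = residual_chisq(fit, sub.V)
    wald_chisq, _, wald_p = wald_equality_test(
        sub.S, sub.V, (stratum_a, trait), (stratum_b, trait), names=sub.names)
    return chisq, df, p, wald_chisq, wald_p


def battery_compare(gc: GeneticCovariance, stratum_a: str, stratum_b: str,
                    externals, q: float = 0.05, seed: int = 0) -> BatteryTable:
    """Run the constrained-vs-free comparison over a battery of externals.

    ``gc`` must be on the correlation scale (standardize first).  Returns
    a :class:`BatteryTable`; traits whose extracted sampling covariance is
    not PSD are skipped with a logged reason.
    """
    gcs = gc.standardize()
    rows = []
    skipped = {}
    for trait in externals:
        if trait in (stratum_a, stratum_b):
            raise InvalidArgumentError("externals must be disjoint from the strata")
        sub = gcs.subset([stratum_a, stratum_b, trait])
        if not is_psd(sub.V, tol=1e-6):
            skipped[trait] = "extracted sampling covariance not PSD"
            logger.warning("skipping %s: %s", trait, skipped[trait])
            continue
        chisq, df, p, wald_chisq, wald_p = _compare_pair(
            sub, stratum_a, stratum_b, trait, seed=seed)
        r1 = sub.value(stratum_a, trait)
        r2 = sub.value(stratum_b, trait)
        se1 = sub.se(stratum_a, trait)
        se2 = sub.se(stratum_b, trait)
        rows.append(BatteryRow(trait=trait, r1=r1, se1=se1, r2=r2, se2=se2,
                               chisq_diff=chisq, df=df, p_diff=p,
                               wald_chisq=wald_chisq, wald_p=wald_p))
    _apply_fdr(rows, q)
    return BatteryTable(stratum_a, stratum_b, rows, q=q, skipped=skipped)


def _two_sided_p(est, se):
    if se <= 0:
        return 0.0 if est != 0 else 1.0
    return float(2.0 * norm.sf(abs(est) / se))


def _apply_fdr(rows, q):
    if not rows:
        return
    p_diff = [r.p_diff for r in rows]
    p_fdr, rej = bh_fdr(p_diff, q)
    for r, padj, flag in zip(rows, p_fdr, rej):
        r.p_fdr = float(padj)
        r.sig_diff = bool(flag)
    # per-stratum correlation significance, corrected as separate families
    for attr_p, attr_sig, est, se in (("p1", "sig1", "r1", "se1"),
                                      ("p2", "sig2", "r2", "se2")):
        raw = [_two_sided_p(getattr(r, est), getattr(r, se)) for r in rows]
        padj, rej = bh_fdr(raw, q)
        for r, p0, pa, flag in zip(rows, raw, padj, rej):
            setattr(r, attr_p, float(p0))
            setattr(r, attr_sig, bool(flag))


# ---------------------------------------------------------------------------
# factor adjustment


TRANSITIONS = {
    (True, True): "persists",
    (True, False): "attenuated-to-ns",
    (False, True): "newly-significant",
    (False, False): "stable-ns",
}


def classify_transition(sig_unadjusted: bool, sig_adjusted: bool) -> str:
    """Transition class as a pure function of the two FDR flags."""
    return TRANSITIONS[(bool(sig_unadjusted), bool(sig_adjusted))]


@dataclass
class AdjustmentRow:
    """Unadjusted vs factor-adjusted stratum associations for one trait."""

    trait: str
    beta_unadjusted_1: float
    se_unadjusted_1: float
    beta_unadjusted_2: float
    se_unadjusted_2: float
    beta_adjusted_1: float
    se_adjusted_1: float
    beta_adjusted_2: float
    se_adjusted_2: float
    p_diff_unadjusted: float
    p_diff_adjusted: float
    p_fdr_unadjusted: float = np.nan
    p_fdr_adjusted: float = np.nan
    sig_unadjusted: bool = False
    sig_adjusted: bool = False
    transition: str = "stable-ns"


@dataclass
class AdjustmentResult:
    """Output of :func:`adjustment_comparison`."""

    unadjusted: BatteryTable
    rows: list
    skipped: dict

    def to_frame(self) -> pd.DataFrame:
        cols = [f.name for f in fields(AdjustmentRow)]
        return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in self.rows])

    def write(self, path: str) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def transition_counts(self) -> dict:
        out = {}
        for r in self.rows:
            out[r.transition] = out.get(r.transition, 0) + 1
        return out


def adjustment_comparison(gc: GeneticCovariance, indicators, stratum_a: str,
                          stratum_b: str, externals, q: float = 0.05,
                          seed: int = 0) -> AdjustmentResult:
    """Compare stratum differences before and after factor residualization.

    The unadjusted analysis is :func:`battery_compare` on raw genetic
    correlations.  The adjusted analysis fits, per external trait, a
    common factor over ``indicators`` predicting both strata and the
    trait, and tests equality of the two standardized residual
    associations with a Wald contrast on their sandwich covariance.
    """
    gcs = gc.standardize()
    unadj = battery_compare(gcs, stratum_a, stratum_b, externals, q=q, seed=seed)
    unadj_by_trait = {r.trait: r for r in unadj.rows}

    adj_records = []
    skipped = dict(unadj.skipped)
    for trait in externals:
        if trait not in unadj_by_trait:
            continue
        try:
            fr = factor_residual_model(gcs.S, gcs.V, indicators,
                                       (stratum_a, stratum_b, trait),
                                       names=gcs.names, seed=seed)
        except Exception as exc:  # pragma: no cover - per-trait resilience
            skipped[trait] = f"factor fit failed: {exc}"
            logger.warning("skipping %s in adjustment: %s", trait, exc)
            continue
        pair_a = (stratum_a, trait)
        pair_b = (stratum_b, trait)
        a_val = fr.adjusted_value(pair_a)
        b_val = fr.adjusted_value(pair_b)
        ia = fr.pair_order.index(pair_a)
        ib = fr.pair_order.index(pair_b)
        var_a = fr.adjusted_cov[ia, ia]
        var_b = fr.adjusted_cov[ib, ib]
        cov_ab = fr.adjusted_cov[ia, ib]
        denom = var_a + var_b - 2.0 * cov_ab
        if denom <= 0:
            skipped[trait] = "degenerate adjusted contrast"
            logger.warning("skipping %s: %s", trait, skipped[trait])
            continue
        stat = (a_val - b_val) ** 2 / denom
        p_adj_diff = float(chi2.sf(stat, 1))
        adj_records.append((trait, fr, a_val, b_val,
                            float(np.sqrt(max(var_a, 0))),
                            float(np.sqrt(max(var_b, 0))), p_adj_diff))

    p_adj_list = [rec[6] for rec in adj_records]
    p_adj_fdr, rej_adj = bh_fdr(p_adj_list, q) if adj_records else ([], [])

    rows = []
    for rec, padj, flag in zip(adj_records, p_adj_fdr, rej_adj):
        trait, fr, a_val, b_val, se_a, se_b, p_adj_diff = rec
        u = unadj_by_trait[trait]
        rows.append(AdjustmentRow(
            trait=trait,
            beta_unadjusted_1=u.r1, se_unadjusted_1=u.se1,
            beta_unadjusted_2=u.r2, se_unadjusted_2=u.se2,
            beta_adjusted_1=a_val, se_adjusted_1=se_a,
            beta_adjusted_2=b_val, se_adjusted_2=se_b,
            p_diff_unadjusted=u.p_diff, p_diff_adjusted=p_adj_diff,
            p_fdr_unadjusted=u.p_fdr, p_fdr_adjusted=float(padj),
            sig_unadjusted=u.sig_diff, sig_adjusted=bool(flag),
            transition=classify_transition(u.sig_diff, bool(flag))))
    return AdjustmentResult(unadjusted=unadj, rows=rows, skipped=skipped)


def plot_battery(table: BatteryTable, path: str | None = None):
    """Forest-style plot of the two strata's correlations per trait."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    traits = [r.trait for r in table.rows]
    y = np.arange(len(traits))[::-1]
    fig, ax = plt.subplots(figsize=(6, max(2, 0.35 * len(traits) + 1)))
    for offset, (attr_r, attr_se, label, color) in enumerate(
            (("r1", "se1", table.stratum_a, "#1f77b4"),
             ("r2", "se2", table.stratum_b, "#d62728"))):
        vals = np.array([getattr(r, attr_r) for r in table.rows])
        ses = np.array([getattr(r, attr_se) for r in table.rows])
        ax.errorbar(vals, y + (0.15 if offset else -0.15), xerr=1.96 * ses,
                    fmt="o", label=label, color=color, markersize=4,
                    linestyle="none")
    ax.axvline(0.0, color="grey", lw=0.8)
    ax.set_yticks(y)
    ax.set_yticklabels(traits)
    ax.set_xlabel("genetic correlation")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return None
    return fig
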